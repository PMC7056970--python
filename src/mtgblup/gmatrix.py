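"""SNP quality control, {-1, 0, +1} coding and the realized additive relationship matrix.

Genotypes are held as a lines x markers table of codes -1 (minor allele),
0 (heterozygote) and +1 (major allele), with NaN for missing calls, plus a
marker map (chromosome, genetic position).  The kinship matrix K is the
VanRaden method-1 genomic relationship computed on this coding:

    K = W W' / (2 * sum_k p_k (1 - p_k))

with W the column-centered genotype matrix and p_k the +1-allele frequency
at marker k.  For fully inbred material (doubled haploids) the diagonal of
K is close to 2 = 1 + f with inbreeding coefficient f = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "KinshipMatrix",
    "qc_filter",
    "additive_relationship",
    "read_hapmap",
]

_ALLOWED_CODES = frozenset({-1.0, 0.0, 1.0})


class MonomorphicError(ValueError):
    """All markers are monomorphic; no relationship can be computed."""


@dataclass
class MarkerMatrix:
    """Genotype codes with a marker map.

    Parameters
    ----------
    geno
        lines x markers DataFrame with values in {-1, 0, +1} and NaN for
        missing calls.  Index = line ids, columns = marker ids.
    map
        Per-marker DataFrame indexed by marker id with columns
        ``chrom`` (may be NaN for unmapped markers) and ``pos_cM``.
    families
        Optional per-line family labels (index = line ids).
    qc_state
        ``"raw"`` or ``"filtered"``.
    qc_report
        Markers removed per rule, populated by :func:`qc_filter`.
    """

    geno: pd.DataFrame
    map: pd.DataFrame
    families: pd.Series | None = None
    qc_state: str = "raw"
    qc_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = set(np.unique(self.geno.to_numpy(dtype=float)))
        bad = {c for c in codes if not np.isnan(c)} - _ALLOWED_CODES
        if bad:
            raise ValueError(f"genotype codes outside {{-1,0,+1,NaN}}: {sorted(bad)}")
        missing_map = set(self.geno.columns) - set(self.map.index)
        if missing_map:
            raise ValueError(f"{len(missing_map)} markers absent from the map")

    @property
    def line_ids(self) -> list[str]:
        return list(self.geno.index)

    @property
    def n_lines(self) -> int:
        return self.geno.shape[0]

    @property
    def n_markers(self) -> int:
        return self.geno.shape[1]


@dataclass
class KinshipMatrix:
    """Realized additive relationship matrix with its line ordering."""

    values: np.ndarray
    ids: list[str]
    jitter: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match id list")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, jitter: float = 0.0) -> "KinshipMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), jitter)

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        idx = [self.ids.index(i) for i in ids]
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(ids), self.jitter)


def _plus_allele_freq(geno: np.ndarray) -> np.ndarray:
    """Frequency of the +1 allele per marker, counting alleles (hets count 1 of 2)."""
    counts = np.nansum(geno + 1.0, axis=0)
    n_obs = np.sum(~np.isnan(geno), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return counts / (2.0 * n_obs)


def qc_filter(
    markers: MarkerMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
) -> MarkerMatrix:
    """Remove low call-rate, low-MAF and unmapped markers; orient -1 = minor.

    A marker is dropped when its call rate is strictly below
    ``call_rate_min``, its minor allele frequency is strictly below
    ``maf_min`` (a marker exactly at the threshold is kept), or it has no
    chromosome assignment.  Allele orientation is recomputed after
    filtering so that -1 is the minor allele in the retained set of lines.
    """
    geno = markers.geno.to_numpy(dtype=float)
    n = geno.shape[0]

    call_rate = np.sum(~np.isnan(geno), axis=0) / n
    p = _plus_allele_freq(geno)
    maf = np.minimum(p, 1.0 - p)
    mapped = markers.map.loc[markers.geno.columns, "chrom"].notna().to_numpy()

    fail_call = call_rate < call_rate_min
    fail_maf = maf < maf_min
    fail_map = ~mapped
    keep = ~(fail_call | fail_maf | fail_map)

    report = {
        "n_input": int(geno.shape[1]),
        "removed_call_rate": int(fail_call.sum()),
        "removed_maf": int(fail_maf.sum()),
        "removed_unmapped": int(fail_map.sum()),
        "n_retained": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError(f"all markers removed by QC: {report}")

    kept_cols = markers.geno.columns[keep]
    geno_f = markers.geno.loc[:, kept_cols].copy()

    # re-orient so +1 is the major allele in the filtered set
    p_kept = _plus_allele_freq(geno_f.to_numpy(dtype=float))
    flip = p_kept < 0.5
    geno_f.loc[:, kept_cols[flip]] *= -1.0

    return MarkerMatrix(
        geno=geno_f,
        map=markers.map.loc[kept_cols].copy(),
        families=markers.families,
        qc_state="filtered",
        qc_report=report,
    )


def additive_relationship(markers: MarkerMatrix, jitter: float = 1e-6) -> KinshipMatrix:
    """VanRaden method-1 kinship from {-1,0,+1} codes.

    Missing codes are mean-imputed per marker, each marker is centered by
    its mean 2(p - 0.5), and K = WW' / (2 * sum p(1-p)).  If the smallest
    eigenvalue is negative, ``jitter`` is added to the diagonal so the
    matrix can be factorized downstream.
    """
    if markers.qc_state != "filtered":
        warnings.warn("computing kinship on a non-QC'd marker matrix", stacklevel=2)

    geno = markers.geno.to_numpy(dtype=float)
    p = _plus_allele_freq(geno)
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise MonomorphicError("no polymorphic markers; kinship undefined")

    col_mean = np.nanmean(geno, axis=0)
    W = np.where(np.isnan(geno), col_mean, geno) - 2.0 * (p - 0.5)
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0

    applied = 0.0
    if np.linalg.eigvalsh(K)[0] < 0.0:
        K = K + jitter * np.eye(K.shape[0])
        applied = jitter
    return KinshipMatrix(K, markers.line_ids, applied)


_IUPAC_HET = {"R", "Y", "S", "W", "K", "M"}


def read_hapmap(path) -> MarkerMatrix:
    """Read a HapMap-format genotype text file into the internal coding.

    Expects the standard 11 leading columns (rs#, alleles, chrom, pos, ...)
    followed by one column per line with diploid letter codes (``AA``,
    ``CT`` or single IUPAC letters); ``NN``/``N`` is missing.  The major
    allele is coded +1 and the minor allele -1.
    """
    hm = pd.read_csv(path, sep=r"\s+|,", engine="python", dtype=str)
    meta, calls = hm.iloc[:, :11], hm.iloc[:, 11:]
    markers = meta.iloc[:, 0].tolist()

    codes = np.full((calls.shape[1], calls.shape[0]), np.nan)
    for j in range(calls.shape[0]):
        col = calls.iloc[j].astype(str).str.upper()
        alleles = str(meta.iloc[j, 1]).upper().replace("/", "")
        a, b = (alleles + "NN")[:2]
        for i, g in enumerate(col):
            g = g.strip()
            if not g or "N" in g or g in ("NA", "--"):
                continue
            if len(g) == 1:
                g = g + g if g not in _IUPAC_HET else g
            if len(g) == 1 or g[0] != g[-1]:
                codes[i, j] = 0.0
            elif g[0] == a:
                codes[i, j] = 1.0
            elif g[0] == b:
                codes[i, j] = -1.0

    geno = pd.DataFrame(codes, index=list(calls.columns), columns=markers)
    # orient so +1 is major
    p = _plus_allele_freq(geno.to_numpy())
    flip_cols = geno.columns[np.nan_to_num(p, nan=1.0) < 0.5]
    geno.loc[:, flip_cols] *= -1.0

    chrom = meta.iloc[:, 2].where(meta.iloc[:, 2].notna())
    try:
        pos = pd.to_numeric(meta.iloc[:, 3], errors="coerce")
    except Exception:
        pos = pd.Series(np.nan, index=meta.index)
    mp = pd.DataFrame({"chrom": chrom.to_numpy(), "pos_cM": pos.to_numpy()}, index=markers)
    return MarkerMatrix(geno=geno, map=mp, qc_state="raw")
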