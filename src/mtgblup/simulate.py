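"""Synthetic doubled-haploid families with multi-trait, multi-environment phenotypes.

The generator emulates a small spring-barley breeding experiment: a set of
connected biparental crosses from a handful of parents, doubled-haploid
(DH) progeny genotyped at mapped biallelic SNPs, and plot-level phenotypes
for several correlated traits measured in multiple environments under an
augmented partially replicated design (a few check lines repeated in every
block, the rest unreplicated).

Meiosis follows the Haldane model: crossovers are a Poisson process along
the genetic map (no interference), so the recombination fraction between
two loci d cM apart is c = (1 - exp(-2d/100)) / 2.  Chromosome doubling of
a single gamete makes every line fully homozygous, so genotype codes are
-1/+1 with no heterozygotes.

Trait genetic (co)variance is induced through additive marker effects: a
marker x trait effect matrix is drawn multivariate-normal across traits
and linearly recalibrated so the realized covariance of breeding values
equals the requested trait covariance exactly.  This keeps the additive
identity (breeding values = centered genotypes x effects) while giving
known simulation truth for heritability and genetic-correlation recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmatrix import MarkerMatrix

__all__ = [
    "SimConfig",
    "TrueGenetics",
    "ConfigurationError",
    "DEFAULT_TRAITS",
    "default_trait_covariance",
    "simulate_dh_families",
    "simulate_true_values",
    "simulate_plot_phenotypes",
    "simulate_dataset",
]

#: agronomic traits (yield, grains/m2, thousand grain weight, plumpness)
#: followed by malting quality traits (beta-glucan, extract, soluble
#: nitrogen, grain protein content)
DEFAULT_TRAITS = ("YLD", "GM2", "TGW", "PLM", "BGL", "EXT", "SNI", "GPC")

_AGRO = ("YLD", "GM2", "TGW", "PLM")
_MALT = ("BGL", "EXT", "SNI", "GPC")


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


def default_trait_covariance() -> np.ndarray:
    """Default 8x8 genetic covariance: correlated agronomic and malting blocks.

    Agronomic traits are mutually positively correlated; malting traits
    form a second block; grain protein content additionally correlates
    with plumpness, beta-glucan and soluble nitrogen so that
    correlation-driven trait-set strategies have structure to find.
    """
    t = list(DEFAULT_TRAITS)
    C = np.eye(8)

    def set_r(a, b, r):
        i, j = t.index(a), t.index(b)
        C[i, j] = C[j, i] = r

    for i, a in enumerate(_AGRO):
        for b in _AGRO[i + 1:]:
            set_r(a, b, 0.5)
    for i, a in enumerate(_MALT):
        for b in _MALT[i + 1:]:
            set_r(a, b, 0.4)
    set_r("GPC", "PLM", 0.45)
    set_r("GPC", "BGL", 0.5)
    set_r("GPC", "SNI", 0.5)
    set_r("TGW", "GPC", 0.35)
    # make sure the hand-tuned matrix is PD
    w = np.linalg.eigvalsh(C)[0]
    if w < 1e-6:
        C += (1e-6 - w) * np.eye(8)
    return C


def _as_psd(M, name: str) -> np.ndarray:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if not np.allclose(M, M.T, atol=1e-10):
        raise ConfigurationError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(M)[0] < -1e-8:
        raise ConfigurationError(f"{name} must be positive semi-definite")
    return M


@dataclass
class SimConfig:
    """Configuration of the synthetic experiment.

    Defaults mirror a connected four-cross DH population of 145 lines
    (33/39/45/28 per family) from five parents, ~6.5k mapped SNPs on seven
    chromosomes, eight traits and nine environments with two blocks each,
    eight replicated check lines per environment.
    """

    n_families: int = 4
    lines_per_family: tuple = (33, 39, 45, 28)
    n_parents: int = 5
    chrom_lengths_cM: tuple = (150.0,) * 7
    n_markers: int = 6482
    n_traits: int = 8
    Sigma_g: np.ndarray = field(default_factory=default_trait_covariance)
    Sigma_e: np.ndarray | None = None
    n_envs: int = 9
    n_blocks: int = 2
    var_env: float = 1.0
    var_block: float = 0.25
    var_gei: float = 1.0
    replicate_fraction: float = 8.0 / 145.0
    missing_geno_rate: float = 0.0
    trait_means: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_parents < 2 or self.n_traits < 1:
            raise ConfigurationError("counts must be >= 1 (parents >= 2)")
        if len(self.lines_per_family) != self.n_families:
            raise ConfigurationError(
                f"lines_per_family has {len(self.lines_per_family)} entries "
                f"for n_families={self.n_families}"
            )
        if any(n < 1 for n in self.lines_per_family):
            raise ConfigurationError("each family needs >= 1 line")
        if any(length <= 0 for length in self.chrom_lengths_cM):
            raise ConfigurationError("chromosome lengths must be > 0")
        if self.n_markers < len(self.chrom_lengths_cM):
            raise ConfigurationError("need at least one marker per chromosome")
        self.Sigma_g = _as_psd(self.Sigma_g, "Sigma_g")
        if self.Sigma_g.shape != (self.n_traits, self.n_traits):
            raise ConfigurationError("Sigma_g shape does not match n_traits")
        if self.Sigma_e is None:
            self.Sigma_e = np.eye(self.n_traits)
        self.Sigma_e = _as_psd(self.Sigma_e, "Sigma_e")
        if self.Sigma_e.shape != (self.n_traits, self.n_traits):
            raise ConfigurationError("Sigma_e shape does not match n_traits")
        for nm in ("var_env", "var_block", "var_gei"):
            if getattr(self, nm) < 0:
                raise ConfigurationError(f"{nm} must be >= 0")
        if not 0.0 <= self.replicate_fraction <= 1.0:
            raise ConfigurationError("replicate_fraction must be in [0,1]")
        if not 0.0 <= self.missing_geno_rate < 1.0:
            raise ConfigurationError("missing_geno_rate must be in [0,1)")
        if self.n_envs < 1 or self.n_blocks < 1:
            raise ConfigurationError("need >= 1 environment and >= 1 block")
        if self.trait_means is None:
            self.trait_means = np.zeros(self.n_traits)
        self.trait_means = np.asarray(self.trait_means, dtype=float)

    @property
    def trait_names(self) -> list[str]:
        if self.n_traits == len(DEFAULT_TRAITS):
            return list(DEFAULT_TRAITS)
        return [f"T{i + 1}" for i in range(self.n_traits)]

    @property
    def n_lines(self) -> int:
        return int(sum(self.lines_per_family))


@dataclass
class TrueGenetics:
    """Simulation truth: additive effects and the breeding values they imply."""

    breeding_values: pd.DataFrame   # lines x traits
    marker_effects: pd.DataFrame    # markers x traits
    realized_Sigma_g: np.ndarray    # trait x trait empirical covariance


# sub-stream labels: one independent RNG per generator stage
_STAGE_PARENTS, _STAGE_MEIOSIS, _STAGE_MISSING, _STAGE_EFFECTS, _STAGE_PHENO = range(5)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


def _marker_map(config: SimConfig) -> pd.DataFrame:
    """Distribute markers across chromosomes proportional to genetic length."""
    lengths = np.asarray(config.chrom_lengths_cM, dtype=float)
    share = lengths / lengths.sum()
    counts = np.floor(share * config.n_markers).astype(int)
    counts = np.maximum(counts, 1)
    # largest-remainder top-up to hit n_markers exactly
    while counts.sum() < config.n_markers:
        counts[np.argmax(share * config.n_markers - counts)] += 1
    while counts.sum() > config.n_markers:
        over = np.where(counts > 1)[0]
        counts[over[np.argmin((share * config.n_markers - counts)[over])]] -= 1
    if (counts < 1).any():
        raise ConfigurationError("a chromosome received zero markers")

    rows = []
    for c, (L, m) in enumerate(zip(lengths, counts)):
        pos = np.linspace(0.0, L, m) if m > 1 else np.array([L / 2.0])
        for x in pos:
            rows.append((f"chr{c + 1}", x))
    mp = pd.DataFrame(rows, columns=["chrom", "pos_cM"])
    mp.index = [f"M{i + 1:05d}" for i in range(len(mp))]
    return mp


def _gamete(hapA: np.ndarray, hapB: np.ndarray, pos: np.ndarray, length: float,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from an F1 under the Haldane (Poisson) model."""
    n_xo = rng.poisson(length / 100.0)
    phase = rng.integers(0, 2)  # which parental haplotype at the left end
    if n_xo == 0:
        return hapA if phase == 0 else hapB
    xo = np.sort(rng.uniform(0.0, length, n_xo))
    # phase at each marker = start phase + number of crossovers to its left
    k = np.searchsorted(xo, pos)
    use_b = (phase + k) % 2 == 1
    return np.where(use_b, hapB, hapA)


def simulate_dh_families(config: SimConfig) -> MarkerMatrix:
    """Generate DH genotypes for connected biparental families.

    Parents are independent fully homozygous haplotypes with allele
    frequency 0.5; family f crosses parents (f mod P, f+1 mod P), a chain
    that uses every parent and shares parents between crosses.  Each DH
    line is one recombinant gamete doubled, so all non-missing codes are
    in {-1, +1}.
    """
    mp = _marker_map(config)
    pos_by_chrom = [
        (mp.index[mp["chrom"] == f"chr{c + 1}"],
         mp.loc[mp["chrom"] == f"chr{c + 1}", "pos_cM"].to_numpy())
        for c in range(len(config.chrom_lengths_cM))
    ]

    rng_p = _rng(config.seed, _STAGE_PARENTS)
    parents = rng_p.choice([-1.0, 1.0], size=(config.n_parents, len(mp)))

    rng_m = _rng(config.seed, _STAGE_MEIOSIS)
    geno = np.empty((config.n_lines, len(mp)))
    line_ids, fams = [], []
    row = 0
    for f, n_lines in enumerate(config.lines_per_family):
        pa = parents[f % config.n_parents]
        pb = parents[(f + 1) % config.n_parents]
        fam = f"FAM{f + 1}"
        for i in range(n_lines):
            for (cols, pos), L in zip(pos_by_chrom, config.chrom_lengths_cM):
                idx = mp.index.get_indexer(cols)
                geno[row, idx] = _gamete(pa[idx], pb[idx], pos, L, rng_m)
            line_ids.append(f"{fam}_L{i + 1:03d}")
            fams.append(fam)
            row += 1

    if config.missing_geno_rate > 0:
        rng_x = _rng(config.seed, _STAGE_MISSING)
        mask = rng_x.random(geno.shape) < config.missing_geno_rate
        geno = np.where(mask, np.nan, geno)

    gdf = pd.DataFrame(geno, index=line_ids, columns=mp.index)
    return MarkerMatrix(
        geno=gdf, map=mp,
        families=pd.Series(fams, index=line_ids, name="family"),
        qc_state="raw",
    )


def _sqrtm_psd(M: np.ndarray, inv: bool = False, floor: float = 1e-12) -> np.ndarray:
    w, V = np.linalg.eigh(M)
    w = np.clip(w, 0.0, None)
    if inv:
        s = np.where(w > floor * w.max(initial=1.0), 1.0 / np.sqrt(np.maximum(w, floor)), 0.0)
    else:
        s = np.sqrt(w)
    return (V * s) @ V.T


def simulate_true_values(markers: MarkerMatrix, config: SimConfig) -> TrueGenetics:
    """Draw additive marker effects and the breeding values they generate.

    Effects are drawn MVN across traits with covariance Sigma_g / m_eff
    (m_eff = sum 2p(1-p)) and then linearly recalibrated so the realized
    line x trait breeding-value covariance equals Sigma_g exactly; the
    identity breeding_values = centered_genotypes @ marker_effects is
    preserved by construction.
    """
    Sg = config.Sigma_g
    geno = markers.geno.to_numpy(dtype=float)
    col_mean = np.nanmean(geno, axis=0)
    X = np.where(np.isnan(geno), col_mean, geno)
    p = (X.mean(axis=0) + 1.0) / 2.0
    m_eff = float(2.0 * np.sum(p * (1.0 - p)))
    if m_eff <= 0:
        raise ValueError("all markers monomorphic; cannot place genetic variance")
    W = X - col_mean

    t = config.n_traits
    traits = config.trait_names
    if not np.any(Sg):
        zeros_u = pd.DataFrame(0.0, index=markers.line_ids, columns=traits)
        zeros_a = pd.DataFrame(0.0, index=markers.geno.columns, columns=traits)
        return TrueGenetics(zeros_u, zeros_a, np.zeros((t, t)))

    rng = _rng(config.seed, _STAGE_EFFECTS)
    A_raw = rng.standard_normal((markers.n_markers, t)) @ _sqrtm_psd(Sg / m_eff).T
    U_raw = W @ A_raw
    C_raw = np.cov(U_raw, rowvar=False, ddof=0).reshape(t, t)
    # exact calibration: T C_raw T' = Sigma_g
    T = _sqrtm_psd(Sg) @ _sqrtm_psd(C_raw, inv=True)
    A = A_raw @ T.T
    U = W @ A

    bv = pd.DataFrame(U, index=markers.line_ids, columns=traits)
    eff = pd.DataFrame(A, index=markers.geno.columns, columns=traits)
    realized = np.cov(U, rowvar=False, ddof=0).reshape(t, t)
    return TrueGenetics(bv, eff, realized)


def simulate_plot_phenotypes(truth: TrueGenetics, config: SimConfig) -> pd.DataFrame:
    """Plot-level phenotypes under the augmented partially replicated design.

    Each environment has ``n_blocks`` blocks; the first
    round(replicate_fraction * n) lines are checks present in every block,
    the remaining lines appear once (spread over blocks round-robin).  Per
    plot and trait:

        y = mu_trait + E_env + B_block(env) + u_line + GE_line,env + e

    with E, B, GE independent normals at the configured variances and e
    drawn across traits with covariance Sigma_e within a plot.
    """
    lines = list(truth.breeding_values.index)
    traits = list(truth.breeding_values.columns)
    U = truth.breeding_values.to_numpy()
    t = len(traits)
    n = len(lines)
    rng = _rng(config.seed, _STAGE_PHENO)

    n_rep = int(round(config.replicate_fraction * n))
    checks = set(range(n_rep))

    fam = None
    if isinstance(truth.breeding_values.index, pd.Index):
        fam = {lid: lid.split("_")[0] if "_" in lid else "" for lid in lines}

    records = []
    for e in range(config.n_envs):
        env = f"E{e + 1}"
        E_eff = rng.normal(0.0, np.sqrt(config.var_env), size=t)
        B_eff = rng.normal(0.0, np.sqrt(config.var_block), size=(config.n_blocks, t))
        GE = rng.normal(0.0, np.sqrt(config.var_gei), size=(n, t))
        Le = _sqrtm_psd(config.Sigma_e)
        plots = []  # (line index, block index)
        for i in range(n):
            if i in checks:
                plots.extend((i, b) for b in range(config.n_blocks))
            else:
                plots.append((i, i % config.n_blocks))
        for i, b in plots:
            resid = Le @ rng.standard_normal(t)
            y = config.trait_means + E_eff + B_eff[b] + U[i] + GE[i] + resid
            for j in range(t):
                records.append(
                    (lines[i], fam[lines[i]] if fam else "", env, f"B{b + 1}",
                     traits[j], y[j])
                )

    return pd.DataFrame(
        records, columns=["line_id", "family", "environment", "block", "trait", "value"]
    )


def simulate_dataset(config: SimConfig):
    """Convenience: genotypes, simulation truth and plot phenotypes in one call."""
    markers = simulate_dh_families(config)
    truth = simulate_true_values(markers, config)
    plots = simulate_plot_phenotypes(truth, config)
    return markers, truth, plots
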