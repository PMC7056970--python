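"""CSV readers/writers for genotypes, maps, plot tables, BLUEs and kinship."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .gmatrix import KinshipMatrix, MarkerMatrix

__all__ = [
    "write_genotypes", "read_genotypes",
    "write_plots", "read_plots",
    "write_blues", "read_blues",
    "write_kinship", "read_kinship",
    "write_manifest",
]


def write_genotypes(markers: MarkerMatrix, geno_path, map_path) -> None:
    """Genotypes as lines x markers CSV (empty cell = missing) plus a map CSV."""
    g = markers.geno.copy()
    g.index.name = "line_id"
    g.to_csv(geno_path, float_format="%.0f")
    m = markers.map.copy()
    m.index.name = "marker"
    m.to_csv(map_path)


def read_genotypes(geno_path, map_path, families: pd.Series | None = None) -> MarkerMatrix:
    g = pd.read_csv(geno_path, index_col=0)
    m = pd.read_csv(map_path, index_col=0)
    return MarkerMatrix(geno=g.astype(float), map=m, families=families)


def write_plots(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, index=False)


def read_plots(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_blues(blues: pd.DataFrame, path) -> None:
    blues.to_csv(path, index=False)


def read_blues(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_kinship(K: KinshipMatrix, path) -> None:
    df = K.to_dataframe()
    df.index.name = "line_id"
    df.to_csv(path)


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return KinshipMatrix.from_dataframe(df)


def write_manifest(path, **entries) -> None:
    """Run manifest (seed, config, versions) as YAML or JSON by extension."""
    path = Path(path)
    payload = {k: v for k, v in entries.items()}
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
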