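"""CV1/CV2 cross-validation schemes, trait-set strategies and predictive ability.

CV1 predicts entirely unphenotyped lines: the test lines' phenotypes are
masked for every trait in the model.  CV2 predicts partially phenotyped
lines: test lines keep their phenotypes for the correlated (helper)
traits and are masked only for the target trait, so the model can borrow
information through the genetic covariance.  Both schemes use random
60/40 line splits repeated many times; predictive ability r_PA is the
Pearson correlation between predicted genetic values and the held-out
BLUEs of the target trait on the test lines.

Trait-set strategies mirror a barley malting-quality program: AGRO (the
four agronomic traits), A+M (agronomic plus malting), COR1 (traits
positively correlated with grain protein content) and COR2/COR3 (top-4
|loading| traits on PC1/PC2 of the trait correlation matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gmatrix import KinshipMatrix
from .mt_model import MultiTraitGBLUP, fit_mt
from .pheno import blues_to_wide, trait_pca
from .st_model import GibbsConfig, SingleTraitGBLUP, _as_kinship, fit_st

__all__ = [
    "CVScheme", "TraitSet", "CVResult",
    "make_partitions", "predictive_ability", "build_trait_sets",
    "run_cv", "compare_schemes", "env_prediction",
    "AGRO_TRAITS", "MALT_TRAITS",
]

AGRO_TRAITS = ("YLD", "TGW", "GM2", "PLM")
MALT_TRAITS = ("BGL", "EXT", "SNI", "GPC")
COR1_TRAITS = ("BGL", "PLM", "SNI", "GPC")


@dataclass
class CVScheme:
    scheme: str = "CV1"
    train_fraction: float = 0.6
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("CV1", "CV2"):
            raise ValueError("scheme must be 'CV1' or 'CV2'")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0,1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class TraitSet:
    name: str
    members: tuple
    target: str

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        if len(set(self.members)) != len(self.members):
            raise ValueError("trait-set members must be distinct")
        if self.target not in self.members:
            self.members = self.members + (self.target,)


@dataclass
class CVResult:
    """Per-repeat predictive abilities with partition bookkeeping."""

    results: pd.DataFrame          # target, strategy, scheme, scope, repeat, r_pa, n_test
    partitions: list = field(repr=False, default_factory=list)

    def summary(self) -> pd.DataFrame:
        def agg(g):
            r = g["r_pa"].dropna()
            q = r.quantile([0.0, 0.25, 0.5, 0.75, 1.0]) if len(r) else \
                pd.Series(np.nan, index=[0.0, 0.25, 0.5, 0.75, 1.0])
            return pd.Series({
                "mean": r.mean(), "sd": r.std(ddof=1),
                "min": q[0.0], "q25": q[0.25], "median": q[0.5],
                "q75": q[0.75], "max": q[1.0],
                "n_repeats": len(g), "n_missing": int(g["r_pa"].isna().sum()),
            })
        keys = ["target", "strategy", "scheme", "scope"]
        return (self.results.groupby(keys, sort=False)
                .apply(agg, include_groups=False).reset_index())


def make_partitions(line_ids, scheme: CVScheme) -> list:
    """Reproducible 60/40 train/test splits, one per repeat.

    Each repeat uses an independent RNG stream derived from the scheme
    seed, so the full list is reproducible and repeats are exchangeable.
    """
    ids = list(line_ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need >= 10 lines for cross-validation")
    n_train = int(round(scheme.train_fraction * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("train and test sets need >= 2 lines each")
    parts = []
    for r in range(scheme.n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([int(scheme.seed), r]))
        perm = rng.permutation(n)
        train = [ids[i] for i in sorted(perm[:n_train])]
        test = [ids[i] for i in sorted(perm[n_train:])]
        parts.append((train, test))
    return parts


def predictive_ability(predicted, observed) -> float:
    """Pearson correlation of predictions with held-out BLUEs (NaN if degenerate)."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def build_trait_sets(blues: pd.DataFrame, target: str,
                     scope: str = "ALL") -> list:
    """The five standard strategies for one target trait.

    AGRO and A+M are fixed memberships; COR1 is the protein-correlated
    set; COR2/COR3 take the four largest-|loading| traits on PC1/PC2 of
    the BLUE-based trait correlation matrix.  The target is appended to a
    set that does not already contain it.
    """
    present = set(blues["trait"].unique())
    needed = set(AGRO_TRAITS) | set(MALT_TRAITS)
    absent = sorted(needed - present)
    if absent:
        raise ValueError(f"default trait sets need traits {absent} "
                         "(use custom TraitSets instead)")
    pca = trait_pca(blues, scope)
    cor2 = tuple(pca.ranked_traits[0][:4])
    cor3 = tuple(pca.ranked_traits[1][:4])
    return [
        TraitSet("AGRO", AGRO_TRAITS, target),
        TraitSet("A+M", AGRO_TRAITS + MALT_TRAITS, target),
        TraitSet("COR1", COR1_TRAITS, target),
        TraitSet("COR2", cor2, target),
        TraitSet("COR3", cor3, target),
    ]


def _cv_mask(ids, members, target, test_lines, scheme: str) -> pd.DataFrame:
    mask = pd.DataFrame(True, index=ids, columns=list(members))
    test = [i for i in test_lines if i in set(ids)]
    if scheme == "CV1":
        mask.loc[test, :] = False
    else:  # CV2: only the target trait is hidden on test lines
        mask.loc[test, target] = False
    return mask


def run_cv(blues: pd.DataFrame, K, strategy: TraitSet, scheme: CVScheme,
           cfg: GibbsConfig | None = None, scope: str = "ALL",
           partitions: list | None = None) -> CVResult:
    """Cross-validated predictive ability for one strategy and scheme.

    Splits the lines that have an observed target BLUE; per repeat masks
    test-line phenotypes according to the scheme, fits the multi-trait
    model (single-trait when the strategy has one member), and scores
    r_PA on the test lines.  Pass a shared ``partitions`` list to pair
    comparisons across strategies and schemes.
    """
    cfg = cfg or GibbsConfig()
    Kv, ids = _as_kinship(K)
    kin = KinshipMatrix(Kv, ids)
    wide = blues_to_wide(blues, scope)
    scored = [i for i in ids if i in wide.index
              and pd.notna(wide.loc[i, strategy.target])]
    if partitions is None:
        partitions = make_partitions(scored, scheme)

    single = len(strategy.members) == 1
    rows = []
    for rep, (train, test) in enumerate(partitions):
        rep_cfg = GibbsConfig(burn_in=cfg.burn_in, n_iter=cfg.n_iter,
                              thin=cfg.thin, seed=int(cfg.seed) + rep,
                              prior_df=cfg.prior_df, prior_R2=cfg.prior_R2)
        if single:
            fit = fit_st(blues, strategy.target, kin, rep_cfg,
                         observed_ids=train, scope=scope)
            pred = fit.predict(test)
        else:
            mask = _cv_mask(ids, strategy.members, strategy.target, test,
                            scheme.scheme)
            fit = fit_mt(blues, strategy.members, kin, rep_cfg, mask=mask,
                         scope=scope)
            pred = fit.predict(test, trait=strategy.target)
        held = wide.loc[test, strategy.target].to_numpy()
        r = predictive_ability(pred, held)
        rows.append((strategy.target, strategy.name, scheme.scheme, scope,
                     rep, r, len(test)))

    df = pd.DataFrame(rows, columns=["target", "strategy", "scheme", "scope",
                                     "repeat", "r_pa", "n_test"])
    return CVResult(df, partitions)


def compare_schemes(blues: pd.DataFrame, K, strategy: TraitSet,
                    scheme: CVScheme, cfg: GibbsConfig | None = None,
                    scope: str = "ALL") -> CVResult:
    """ST-CV1, MT-CV1 and MT-CV2 for one target on shared partitions.

    Sharing the line splits makes the three predictive abilities paired
    per repeat, so scheme differences are not confounded with partition
    noise.
    """
    cfg = cfg or GibbsConfig()
    Kv, ids = _as_kinship(K)
    wide = blues_to_wide(blues, scope)
    scored = [i for i in ids if i in wide.index
              and pd.notna(wide.loc[i, strategy.target])]
    partitions = make_partitions(scored, scheme)

    st_set = TraitSet("ST", (strategy.target,), strategy.target)
    out = []
    for strat, scm in ((st_set, "CV1"), (strategy, "CV1"), (strategy, "CV2")):
        scheme_r = CVScheme(scm, scheme.train_fraction, scheme.n_repeats,
                            scheme.seed)
        res = run_cv(blues, K, strat, scheme_r, cfg, scope, partitions)
        lab = "ST-CV1" if strat is st_set else f"MT-{scm}"
        res.results["model"] = lab
        out.append(res.results)
    return CVResult(pd.concat(out, ignore_index=True), partitions)


def env_prediction(blues_by_env: pd.DataFrame, K, target_env: str,
                   target_trait: str, scheme: CVScheme,
                   cfg: GibbsConfig | None = None,
                   source_envs=None) -> CVResult:
    """Predict a trait in an un-phenotyped environment from other environments.

    Each (trait, environment) BLUE is stacked as a separate variable in
    the multi-trait model, with the target variable = (target_trait,
    target_env).  CV1 masks all variables for test lines; CV2 masks only
    the target variable, so test lines keep their source-environment
    records.  Works for leave-one-location-out or leave-one-year-out by
    choosing ``source_envs`` accordingly.
    """
    cfg = cfg or GibbsConfig()
    Kv, ids = _as_kinship(K)
    kin = KinshipMatrix(Kv, ids)

    envs = sorted(blues_by_env["scope"].unique())
    if source_envs is None:
        source_envs = [e for e in envs if e != target_env]
    if target_env in source_envs:
        raise ValueError("target environment cannot be among the sources")

    # stack (trait, env) variables into a synthetic tidy BLUE table
    d = blues_by_env[blues_by_env["scope"].isin(list(source_envs) + [target_env])]
    stacked = d.assign(trait=d["trait"] + "@" + d["scope"], scope="STACK")
    target_var = f"{target_trait}@{target_env}"
    members = sorted(stacked["trait"].unique())
    if target_var not in members:
        raise ValueError(f"no BLUEs for {target_trait} in {target_env}")
    strategy = TraitSet(f"ENV:{target_env}", tuple(members), target_var)

    res = run_cv(stacked, kin, strategy, scheme, cfg, scope="STACK")
    res.results["target"] = target_trait
    res.results["scope"] = target_env
    return res
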