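"""Genotype BLUEs, variance components, Cullis heritability, correlations and PCA.

Plot-level data follow the multi-environment trial model

    y_ijkl = mu + E_i + B_j(i) + G_k + GE_ik + e_ijkl

with environment, block-within-environment and genotype-by-environment
(GEI) effects random and genotype fixed (for BLUEs) or random (for
heritability).  For a single environment the E and GEI terms drop out.

Variance components are estimated by EM-REML on Henderson's mixed-model
equations: slower than average-information REML but monotone in the
restricted likelihood, which makes it robust at the small problem sizes
handled here.  Broad-sense heritability uses the Cullis form

    H2 = 1 - vbar_BLUP / (2 * var_g)

where vbar_BLUP is the mean pairwise prediction-error variance of the
genotype BLUPs, read off the inverse coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "VarianceComponents",
    "Heritability",
    "fit_blues",
    "fit_all_blues",
    "fit_h2",
    "trait_correlations",
    "correlations",
    "trait_pca",
    "blues_to_wide",
]

PLOT_COLUMNS = ("line_id", "environment", "block", "trait", "value")


@dataclass
class VarianceComponents:
    var_env: float
    var_block: float
    var_gei: float
    var_geno: float
    var_resid: float
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list, repr=False)


@dataclass
class Heritability:
    H2: float
    vbar_blup: float
    var_geno: float
    degenerate: bool = False


class _REMLFit:
    """Internal container for one EM-REML solve."""

    __slots__ = ("beta", "u", "variances", "var_resid", "converged", "n_iter",
                 "loglik_trace", "C_beta", "pev_blocks", "names")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


def _emreml(y, X, Zs, tol=1e-8, max_iter=500, pev_for=()):
    """EM-REML with i.i.d. random effects on Henderson's MME.

    Parameters
    ----------
    y : (n,) response
    X : (n,p) fixed-effect design (full column rank)
    Zs : list of (name, Z) random-effect incidence matrices
    pev_for : names whose full PEV block (inverse-coefficient block) to keep

    Returns a `_REMLFit` with solutions, variance components, the fixed
    effect covariance (x var_resid) and the restricted log-likelihood trace.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = [nm for nm, _ in Zs]
    qs = [Z.shape[1] for _, Z in Zs]
    W = np.hstack([X] + [Z for _, Z in Zs]) if Zs else X
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    vy = float(np.var(y)) or 1.0
    floor = 1e-10 * vy

    k = len(Zs)
    sig = np.full(k, vy / max(k + 1, 2))
    sig_e = vy / max(k + 1, 2)

    offs = np.cumsum([p] + qs)  # block boundaries in the MME solution
    blocks = [(offs[i + 1] - qs[i], offs[i + 1]) for i in range(k)]

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = WtW / sig_e
        for (a, b), s in zip(blocks, sig):
            M[np.arange(a, b), np.arange(a, b)] += 1.0 / s
        rhs = Wty / sig_e
        cf = cho_factor(M, lower=True)
        sol = cho_solve(cf, rhs)
        Minv = cho_solve(cf, np.eye(M.shape[0]))

        # restricted log-likelihood (up to a constant)
        logdetM = 2.0 * np.sum(np.log(np.diag(cf[0])))
        yPy = yty / sig_e - float(sol @ rhs)
        ll = -0.5 * (n * np.log(sig_e) + sum(q * np.log(s) for q, s in zip(qs, sig))
                     + logdetM + yPy)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            converged = True
            break

        new_sig = np.empty(k)
        for i, (a, b) in enumerate(blocks):
            u_i = sol[a:b]
            new_sig[i] = (float(u_i @ u_i) + np.trace(Minv[a:b, a:b])) / qs[i]
        resid = y - W @ sol
        new_sig_e = float(y @ resid) / (n - p)
        sig = np.maximum(new_sig, floor)
        sig_e = max(new_sig_e, floor)

    beta = sol[:p]
    u = {nm: sol[a:b] for nm, (a, b) in zip(names, blocks)}
    pev = {}
    for nm in pev_for:
        a, b = blocks[names.index(nm)]
        pev[nm] = Minv[a:b, a:b]  # PEV matrix (already on the variance scale)
    return _REMLFit(
        beta=beta, u=u,
        variances={nm: float(s) for nm, s in zip(names, sig)},
        var_resid=float(sig_e), converged=converged, n_iter=it,
        loglik_trace=trace, C_beta=Minv[:p, :p], pev_blocks=pev, names=names,
    )


def _dummies(codes: pd.Series) -> tuple[np.ndarray, list]:
    levels = pd.Categorical(codes)
    Z = np.zeros((len(codes), len(levels.categories)))
    Z[np.arange(len(codes)), levels.codes] = 1.0
    return Z, list(levels.categories)


def _prepare(plots: pd.DataFrame, trait: str, scope) -> pd.DataFrame:
    for col in PLOT_COLUMNS[:3]:
        if col not in plots.columns:
            raise ValueError(f"plot table missing column {col!r}")
    d = plots[plots["trait"] == trait].dropna(subset=["value"]).copy()
    if scope is not None and scope != "ALL":
        envs = [scope] if isinstance(scope, str) else list(scope)
        d = d[d["environment"].isin(envs)]
    if d["line_id"].nunique() < 2:
        raise ValueError("need data on >= 2 lines in scope")
    return d


def _scope_label(scope) -> str:
    if scope is None or scope == "ALL":
        return "ALL"
    if isinstance(scope, str):
        return scope
    return "+".join(scope)


def _designs(d: pd.DataFrame, genotype_fixed: bool):
    """Fixed design, random incidence list and genotype level order."""
    multi_env = d["environment"].nunique() > 1
    eb = d["environment"].astype(str) + ":" + d["block"].astype(str)
    if not multi_env and eb.nunique() == 1 and not d.duplicated(["line_id"]).any():
        raise ValueError("single environment with one block and no replication: "
                         "model unidentifiable")
    Zg, g_levels = _dummies(d["line_id"])
    Zs = []
    if multi_env:
        Ze, _ = _dummies(d["environment"])
        Zs.append(("env", Ze))
    Zb, _ = _dummies(eb)
    if Zb.shape[1] > 1:
        Zs.append(("block", Zb))
    if multi_env:
        Zge, _ = _dummies(d["environment"].astype(str) + "/" + d["line_id"].astype(str))
        Zs.append(("gei", Zge))
    if genotype_fixed:
        X = np.hstack([np.ones((len(d), 1)), Zg[:, 1:]])  # reference = first level
    else:
        X = np.ones((len(d), 1))
        Zs.insert(0, ("geno", Zg))
    return X, Zs, g_levels, multi_env


def _components(fit: _REMLFit, multi_env: bool) -> VarianceComponents:
    v = fit.variances
    return VarianceComponents(
        var_env=v.get("env", 0.0) if multi_env else 0.0,
        var_block=v.get("block", 0.0),
        var_gei=v.get("gei", 0.0) if multi_env else 0.0,
        var_geno=v.get("geno", float("nan")),
        var_resid=fit.var_resid,
        converged=fit.converged,
        n_iter=fit.n_iter,
        loglik_trace=fit.loglik_trace,
    )


def fit_blues(plots: pd.DataFrame, trait: str, scope=None,
              tol: float = 1e-8, max_iter: int = 500):
    """Genotype BLUEs for one trait over an environment scope.

    Genotype is fixed; environment, block-in-environment and GEI are
    random with EM-REML variances.  For a single-environment scope the E
    and GEI terms are dropped.  BLUEs are reported on the trait scale as
    intercept + genotype effect (first genotype is the reference), with
    standard errors from the inverse coefficient matrix.  Non-convergence
    is flagged on the returned components, not raised.

    Returns
    -------
    (blues, components) : (pd.DataFrame, VarianceComponents)
        ``blues`` has columns line_id, trait, scope, blue, se.
    """
    d = _prepare(plots, trait, scope)
    X, Zs, g_levels, multi_env = _designs(d, genotype_fixed=True)
    fit = _emreml(d["value"].to_numpy(), X, Zs, tol=tol, max_iter=max_iter)

    mu = fit.beta[0]
    eff = np.concatenate([[0.0], fit.beta[1:]])
    C = fit.C_beta  # covariance of fixed effects (variance scale)
    se = np.empty(len(g_levels))
    se[0] = np.sqrt(max(C[0, 0], 0.0))
    for i in range(1, len(g_levels)):
        se[i] = np.sqrt(max(C[0, 0] + C[i, i] + 2.0 * C[0, i], 0.0))

    blues = pd.DataFrame({
        "line_id": g_levels,
        "trait": trait,
        "scope": _scope_label(scope),
        "blue": mu + eff,
        "se": se,
    })
    return blues, _components(fit, multi_env)


def fit_all_blues(plots: pd.DataFrame, scope=None, **kw) -> pd.DataFrame:
    """BLUEs for every trait present in the plot table (one scope)."""
    out = []
    for trait in sorted(plots["trait"].unique()):
        blues, _ = fit_blues(plots, trait, scope, **kw)
        out.append(blues)
    return pd.concat(out, ignore_index=True)


def fit_h2(plots: pd.DataFrame, trait: str, scope=None,
           tol: float = 1e-8, max_iter: int = 500) -> Heritability:
    """Cullis broad-sense heritability for one trait.

    Refits the trial model with genotype random and computes the mean
    pairwise prediction-error variance of the genotype BLUPs from the
    inverse coefficient matrix; H2 = 1 - vbar/(2 var_g), clamped to [0,1].
    """
    d = _prepare(plots, trait, scope)
    X, Zs, g_levels, multi_env = _designs(d, genotype_fixed=False)
    fit = _emreml(d["value"].to_numpy(), X, Zs, tol=tol, max_iter=max_iter,
                  pev_for=("geno",))

    var_g = fit.variances["geno"]
    P = fit.pev_blocks["geno"]
    m = P.shape[0]
    # mean over pairs of PEV_ii + PEV_jj - 2 PEV_ij
    vbar = 2.0 * (m * np.trace(P) - P.sum()) / (m * (m - 1))
    if var_g <= 1e-8 * (np.var(d["value"]) or 1.0):
        return Heritability(H2=0.0, vbar_blup=float(vbar), var_geno=var_g,
                            degenerate=True)
    h2 = float(np.clip(1.0 - vbar / (2.0 * var_g), 0.0, 1.0))
    return Heritability(H2=h2, vbar_blup=float(vbar), var_geno=var_g)


def blues_to_wide(blues: pd.DataFrame, scope: str = "ALL",
                  column: str = "trait") -> pd.DataFrame:
    """Pivot a tidy BLUE table to lines x traits (or lines x environments)."""
    d = blues if scope is None else blues[blues["scope"] == scope]
    return d.pivot_table(index="line_id", columns=column, values="blue",
                         aggfunc="first")


def correlations(wide: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Works on any lines x variables frame (traits or environments).  Pairs
    with fewer than 3 complete observations get NaN.
    """
    cols = list(wide.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            pair = wide[[a, b]].dropna() if a != b else wide[[a]].dropna()
            n = len(pair)
            if a == b:
                r, p = (1.0, 0.0) if n >= 3 else (np.nan, np.nan)
            elif n < 3:
                r, p = np.nan, np.nan
            else:
                x, y = pair[a].to_numpy(), pair[b].to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    r, p = np.nan, np.nan
                else:
                    res = stats.pearsonr(x, y)
                    r, p = float(res.statistic), float(res.pvalue)
            rows.append((a, b, r, p, n))
    return pd.DataFrame(rows, columns=["var1", "var2", "r", "p", "n"])


def trait_correlations(blues: pd.DataFrame, scope: str = "ALL") -> pd.DataFrame:
    """Pearson correlations among traits based on line BLUEs."""
    return correlations(blues_to_wide(blues, scope))


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    pve: np.ndarray                # proportion of variance explained per PC
    loadings: pd.DataFrame         # traits x PCs
    ranked_traits: list            # per PC, traits sorted by |loading| desc


def trait_pca(blues: pd.DataFrame, scope: str = "ALL") -> PCAResult:
    """Eigendecomposition of the trait correlation matrix (complete cases).

    Loadings are the eigenvectors of the correlation matrix, sign-fixed so
    the largest-magnitude loading on each PC is positive; ``ranked_traits``
    orders traits by |loading| per PC, the basis for correlation-driven
    trait-set strategies.
    """
    wide = blues_to_wide(blues, scope).dropna()
    if wide.shape[1] < 2 or wide.shape[0] < 3:
        raise ValueError("PCA needs >= 2 traits and >= 3 complete lines")
    sd = wide.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant trait column(s): {bad}")
    R = np.corrcoef(wide.to_numpy(), rowvar=False)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] *= -1.0
    pcs = [f"PC{j + 1}" for j in range(len(w))]
    loadings = pd.DataFrame(V, index=wide.columns, columns=pcs)
    ranked = [list(loadings.index[np.argsort(-np.abs(loadings[pc].to_numpy()))])
              for pc in pcs]
    return PCAResult(eigenvalues=w, pve=w / w.sum(), loadings=loadings,
                     ranked_traits=ranked)
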