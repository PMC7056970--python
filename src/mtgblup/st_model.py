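"""Single-trait Bayesian GBLUP fitted by Gibbs sampling.

Model for observed line means (BLUEs) y:

    y = 1 mu + u + e,   u ~ N(0, K var_g),   e ~ N(0, R var_e)

with K the realized additive relationship matrix and R = I by default, or
diag(1/w) for per-observation precision weights w (e.g. 1/se^2 of the
BLUEs).  Scaled-inverse-chi-square priors on the variances, flat prior on
the intercept.  Genetic values of unphenotyped lines are drawn each
iteration from their conditional normal given the phenotyped lines' values
(data augmentation), so prediction is a read-off of posterior means.

The sampler works in the eigenbasis of the observed-lines kinship block:
one O(n^3) eigendecomposition per fit, O(n) conjugate updates per
iteration.  With precision weights the update is a dense n x n Cholesky
per iteration instead (the rotation no longer diagonalizes jointly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .gmatrix import KinshipMatrix

__all__ = ["GibbsConfig", "SingleTraitGBLUP", "fit_st", "predict_st"]


@dataclass
class GibbsConfig:
    """Chain settings shared by the single- and multi-trait samplers."""

    burn_in: int = 1500
    n_iter: int = 3000
    thin: int = 1
    seed: int = 0
    prior_df: float = 5.0
    prior_R2: float = 0.5

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.prior_df <= 0:
            raise ValueError("prior_df must be > 0")
        if not 0.0 < self.prior_R2 < 1.0:
            raise ValueError("prior_R2 must be in (0,1)")


def _as_kinship(K) -> tuple[np.ndarray, list]:
    if isinstance(K, KinshipMatrix):
        return K.values, list(K.ids)
    K = np.asarray(K, dtype=float)
    return K, list(range(K.shape[0]))


class SingleTraitGBLUP(BaseEstimator):
    """Bayesian ridge-regression-equivalent GBLUP on a precomputed kinship.

    Parameters
    ----------
    n_iter, burn_in, thin, seed
        Gibbs chain settings (defaults 3000 total, 1500 burn-in, no
        thinning).
    prior_df, prior_R2
        Scaled-inverse-chi-square prior degrees of freedom, and the
        fraction of phenotypic variance placed at the genetic prior mode
        (the residual prior mode gets the complement).
    fix_var_g, fix_var_e
        Freeze a variance at this value instead of sampling it (used for
        closed-form-BLUP cross-checks).
    weights
        Optional per-line precision weights (R = diag(1/w)); entries for
        unobserved lines are ignored.

    Attributes
    ----------
    mu_ : float                  posterior mean intercept
    u_ : ndarray (n,)            posterior mean genetic values, all lines
    var_g_, var_e_ : float       posterior mean variances
    ids_ : list                  line ordering (from the kinship)
    samples_ : dict              variance chains and split-half u means
    split_correlation_ : float   correlation of first/second half u means
    """

    def __init__(self, n_iter=3000, burn_in=1500, thin=1, seed=0,
                 prior_df=5.0, prior_R2=0.5,
                 fix_var_g=None, fix_var_e=None, weights=None):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_df = prior_df
        self.prior_R2 = prior_R2
        self.fix_var_g = fix_var_g
        self.fix_var_e = fix_var_e
        self.weights = weights

    def fit(self, K, y):
        """Run the Gibbs sampler.

        Parameters
        ----------
        K : KinshipMatrix or (n,n) array
        y : (n,) array aligned with K's line order; NaN marks a line
            without a phenotype (its genetic value is still sampled).
        """
        Kv, ids = _as_kinship(K)
        y = np.asarray(y, dtype=float).ravel()
        n = Kv.shape[0]
        if y.shape[0] != n:
            raise ValueError("y length does not match kinship dimension")
        obs = ~np.isnan(y)
        n_obs = int(obs.sum())
        if n_obs < 10:
            raise ValueError("need >= 10 phenotyped lines")

        rng = np.random.default_rng(self.seed)
        y_o = y[obs]
        Koo = Kv[np.ix_(obs, obs)]
        d, U = np.linalg.eigh(Koo)
        if d[0] < -1e-8:
            raise ValueError("kinship is not PSD; apply diagonal jitter "
                             "(see additive_relationship)")
        d = np.clip(d, 1e-12, None)

        w = None
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float).ravel()
            w = w[obs] if w.shape[0] == n else w
            if w.shape[0] != n_obs or np.any(w <= 0):
                raise ValueError("weights must be positive, one per line")
            Koo_inv = (U / d) @ U.T

        # prior scales: split the phenotypic variance at the prior mode
        vy = float(np.var(y_o)) or 1.0
        df0 = float(self.prior_df)
        mode_factor = (df0 + 2.0) / df0
        S_g = self.prior_R2 * vy * mode_factor / max(float(np.mean(np.diag(Koo))), 1e-12)
        S_e = (1.0 - self.prior_R2) * vy * mode_factor

        unobs = ~obs
        n_un = int(unobs.sum())
        if n_un:
            Kuo = Kv[np.ix_(unobs, obs)]
            B = (Kuo @ U / d) @ U.T           # K_uo K_oo^-1
            S = Kv[np.ix_(unobs, unobs)] - B @ Kuo.T
            S = (S + S.T) / 2.0
            ws, Vs = np.linalg.eigh(S)
            Ls = Vs * np.sqrt(np.clip(ws, 0.0, None))

        mu = float(np.mean(y_o))
        var_g = self.fix_var_g if self.fix_var_g is not None else 0.5 * vy
        var_e = self.fix_var_e if self.fix_var_e is not None else 0.5 * vy
        u_o = np.zeros(n_obs)

        keep = range(self.burn_in, self.n_iter, self.thin)
        n_keep = len(keep)
        keep_set = set(keep)
        half = self.burn_in + (self.n_iter - self.burn_in) // 2

        u_sum = np.zeros(n)
        u_half = np.zeros((2, n))
        mu_sum = 0.0
        vg_chain, ve_chain = [], []

        for it in range(self.n_iter):
            # genetic values of observed lines
            if w is None:
                ytil = U.T @ (y_o - mu)
                c = 1.0 / (1.0 / var_e + 1.0 / (d * var_g))
                v = c * ytil / var_e + np.sqrt(c) * rng.standard_normal(n_obs)
                u_o = U @ v
                ss_g = float(np.sum(v * v / d))
            else:
                P = np.diag(w / var_e) + Koo_inv / var_g
                L = np.linalg.cholesky(P)
                m = np.linalg.solve(P, w * (y_o - mu) / var_e)
                u_o = m + np.linalg.solve(L.T, rng.standard_normal(n_obs))
                ss_g = float(u_o @ Koo_inv @ u_o)

            # intercept (flat prior)
            if w is None:
                mu = rng.normal(np.mean(y_o - u_o), np.sqrt(var_e / n_obs))
            else:
                mu = rng.normal(np.sum(w * (y_o - u_o)) / np.sum(w),
                                np.sqrt(var_e / np.sum(w)))

            # variances (scaled-inverse-chi-square)
            if self.fix_var_g is None:
                var_g = (df0 * S_g + ss_g) / rng.chisquare(df0 + n_obs)
            r = y_o - mu - u_o
            ss_e = float(np.sum((w if w is not None else 1.0) * r * r))
            if self.fix_var_e is None:
                var_e = (df0 * S_e + ss_e) / rng.chisquare(df0 + n_obs)

            # unphenotyped lines given observed-line effects
            u_all = np.empty(n)
            u_all[obs] = u_o
            if n_un:
                u_all[unobs] = B @ u_o + np.sqrt(var_g) * (
                    Ls @ rng.standard_normal(n_un))

            if it in keep_set:
                u_sum += u_all
                u_half[0 if it < half else 1] += u_all
                mu_sum += mu
                vg_chain.append(var_g)
                ve_chain.append(var_e)

        self.ids_ = ids
        self.u_ = u_sum / n_keep
        self.mu_ = mu_sum / n_keep
        self.var_g_ = float(np.mean(vg_chain))
        self.var_e_ = float(np.mean(ve_chain))
        n1 = sum(1 for it in keep if it < half) or 1
        n2 = n_keep - n1 or 1
        h1, h2 = u_half[0] / n1, u_half[1] / n2
        with np.errstate(invalid="ignore"):
            self.split_correlation_ = float(np.corrcoef(h1, h2)[0, 1])
        self.samples_ = {"var_g": np.array(vg_chain), "var_e": np.array(ve_chain),
                         "u_first_half": h1, "u_second_half": h2}
        self.observed_ = obs
        return self

    def predict(self, ids=None):
        """Posterior-mean genetic values for the given line ids (or indices)."""
        if not hasattr(self, "u_"):
            raise RuntimeError("call fit first")
        if ids is None:
            return self.u_.copy()
        out = np.empty(len(ids))
        lookup = {lid: i for i, lid in enumerate(self.ids_)}
        for j, lid in enumerate(ids):
            if lid not in lookup:
                raise KeyError(f"unknown line id {lid!r}")
            out[j] = self.u_[lookup[lid]]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"line_id": self.ids_, "u_hat": self.u_})


def fit_st(blues: pd.DataFrame, trait: str, K, cfg: GibbsConfig | None = None,
           observed_ids=None, scope: str = "ALL",
           use_weights: bool = False) -> SingleTraitGBLUP:
    """Fit the single-trait model from a tidy BLUE table.

    ``observed_ids`` restricts which lines contribute phenotypes (the
    training set); all lines in K get sampled genetic values.  With
    ``use_weights`` the BLUE standard errors become precision weights
    1/se^2 (the heterogeneous-precision residual structure).
    """
    cfg = cfg or GibbsConfig()
    Kv, ids = _as_kinship(K)
    d = blues[(blues["trait"] == trait)]
    if scope is not None and "scope" in d.columns:
        d = d[d["scope"] == scope]
    if d.empty:
        raise ValueError(f"trait {trait!r} absent from BLUE table")
    vals = dict(zip(d["line_id"], d["blue"]))
    ses = dict(zip(d["line_id"], d.get("se", pd.Series(dtype=float))))
    allowed = set(observed_ids) if observed_ids is not None else None
    if allowed is not None and not allowed <= set(ids):
        raise ValueError("observed_ids contains lines absent from K")

    y = np.full(len(ids), np.nan)
    w = np.ones(len(ids))
    for i, lid in enumerate(ids):
        if lid in vals and (allowed is None or lid in allowed):
            y[i] = vals[lid]
            if use_weights and lid in ses and ses[lid] > 0:
                w[i] = 1.0 / ses[lid] ** 2
    model = SingleTraitGBLUP(
        n_iter=cfg.n_iter, burn_in=cfg.burn_in, thin=cfg.thin, seed=cfg.seed,
        prior_df=cfg.prior_df, prior_R2=cfg.prior_R2,
        weights=w if use_weights else None,
    )
    return model.fit(KinshipMatrix(Kv, ids), y)


def predict_st(fit: SingleTraitGBLUP, target_ids) -> np.ndarray:
    """Posterior-mean genetic values for a set of target lines."""
    return fit.predict(list(target_ids))
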