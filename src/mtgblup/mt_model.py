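"""Multi-trait Bayesian GBLUP with Kronecker covariance Sigma (x) K.

Model for the n x t matrix of line-by-trait means Y:

    vec(Y) = mu + u + e,  u ~ MVN(0, Sigma (x) K),  e ~ MVN(0, R (x) I_n)

with Sigma an unstructured t x t genetic covariance (inverse-Wishart
prior), R a diagonal t x t residual covariance (scaled-inverse-chi-square
per trait) and per-trait intercepts with flat priors.  Missing phenotype
entries — arbitrary line x trait patterns, which is what the CV1/CV2
cross-validation schemes produce — are handled by data augmentation:
each Gibbs iteration draws them from their conditional normal, so a fit
yields predictions for unphenotyped and partially phenotyped lines alike.

Genetic values are updated jointly across traits in the eigenbasis of K:
with K = E D E' each eigencomponent has a t x t Gaussian full conditional,
and all n solves are batched through one t x t eigendecomposition per
iteration.  `conditional_mean_oracle` provides the closed-form conditional
mean of the same joint Gaussian at fixed parameters, the independent
cross-check used by the tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .gmatrix import KinshipMatrix
from .st_model import GibbsConfig, _as_kinship

__all__ = ["MultiTraitGBLUP", "fit_mt", "conditional_mean_oracle"]


class MultiTraitGBLUP(BaseEstimator):
    """Bayesian multivariate Gaussian GBLUP on a precomputed kinship.

    Parameters
    ----------
    n_iter, burn_in, thin, seed
        Gibbs chain settings.
    prior_df
        Residual scaled-inverse-chi-square prior df; the inverse-Wishart
        prior for Sigma uses df = t + 2 with scale 0.5 x diag of the
        phenotypic covariance of the observed entries.
    diagonal_sigma
        Constrain Sigma to a diagonal matrix (per-trait variances sampled
        independently); the fit then reduces to stacked single-trait fits.
    fix_Sigma, fix_R, fix_mu
        Freeze parameters instead of sampling them (closed-form
        cross-checks); ``fix_R`` is a length-t vector of residual
        variances.

    Attributes
    ----------
    mu_ : (t,)             posterior mean intercepts
    U_ : (n,t)             posterior mean genetic values
    Sigma_ : (t,t)         posterior mean genetic covariance
    R_ : (t,)              posterior mean residual variances
    imputed_Y_ : (n,t)     posterior mean of augmented entries (NaN where
                           the phenotype was observed)
    n_jitter_redraws_ : int  times the Sigma conditional needed jitter
    """

    def __init__(self, n_iter=3000, burn_in=1500, thin=1, seed=0, prior_df=5.0,
                 diagonal_sigma=False, fix_Sigma=None, fix_R=None, fix_mu=None,
                 min_obs_per_trait=5):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_df = prior_df
        self.diagonal_sigma = diagonal_sigma
        self.fix_Sigma = fix_Sigma
        self.fix_R = fix_R
        self.fix_mu = fix_mu
        self.min_obs_per_trait = min_obs_per_trait

    def fit(self, K, Y):
        """Run the Gibbs sampler on an n x t phenotype matrix (NaN = missing)."""
        Kv, ids = _as_kinship(K)
        traits = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
        Y = np.asarray(Y, dtype=float)
        n, t = Y.shape
        if t < 2:
            raise ValueError("multi-trait model needs >= 2 traits")
        if Kv.shape[0] != n:
            raise ValueError("Y rows do not match kinship dimension")
        obs = ~np.isnan(Y)
        params_fixed = self.fix_Sigma is not None and self.fix_R is not None
        n_obs_trait = obs.sum(axis=0)
        if not params_fixed and (n_obs_trait < self.min_obs_per_trait).any():
            bad = [i for i in range(t) if n_obs_trait[i] < self.min_obs_per_trait]
            raise ValueError(f"traits observed in < {self.min_obs_per_trait} "
                             f"lines: {bad}")

        rng = np.random.default_rng(self.seed)
        d, E = np.linalg.eigh(Kv)
        if d[0] < -1e-8:
            raise ValueError("kinship is not PSD; apply diagonal jitter")
        d = np.clip(d, 1e-12, None)

        # initialization and priors from the observed phenotypic covariance
        col_mean = np.array([np.nanmean(Y[:, j]) if n_obs_trait[j] else 0.0
                             for j in range(t)])
        col_var = np.array([np.nanvar(Y[:, j]) if n_obs_trait[j] > 1 else 1.0
                            for j in range(t)])
        col_var = np.where(col_var > 0, col_var, 1.0)

        df_sig0 = t + 2.0
        S_sig0 = 0.5 * np.diag(col_var)
        df_r0 = float(self.prior_df)
        S_r0 = 0.5 * col_var * (df_r0 + 2.0) / df_r0

        mu = col_mean.copy() if self.fix_mu is None else np.asarray(self.fix_mu, float)
        Sigma = (np.asarray(self.fix_Sigma, float) if self.fix_Sigma is not None
                 else 0.5 * np.diag(col_var))
        R = (np.asarray(self.fix_R, float).ravel() if self.fix_R is not None
             else 0.5 * col_var)
        U = np.zeros((n, t))
        Y_aug = np.where(obs, Y, col_mean)

        keep_set = set(range(self.burn_in, self.n_iter, self.thin))
        n_keep = len(keep_set)
        U_sum = np.zeros((n, t))
        Yimp_sum = np.zeros((n, t))
        Sig_sum = np.zeros((t, t))
        R_sum = np.zeros(t)
        mu_sum = np.zeros(t)
        n_jitter = 0
        jit = 1e-10

        for it in range(self.n_iter):
            # (a) augment missing phenotypes (R diagonal -> independent given U)
            noise = rng.standard_normal((n, t)) * np.sqrt(R)
            Y_aug = np.where(obs, Y, mu + U + noise)

            # (b) joint genetic-value update in the eigenbasis of K
            Yt = E.T @ (Y_aug - mu)
            try:
                L = np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                L = np.linalg.cholesky(Sigma + 1e-8 * np.eye(t) * np.trace(Sigma))
            Bm = (L.T / R) @ L
            phi, P = np.linalg.eigh((Bm + Bm.T) / 2.0)
            phi = np.clip(phi, 1e-12, None)
            M = L @ P
            G = 1.0 / (phi[None, :] + 1.0 / d[:, None])      # n x t
            A = (Yt / R) @ M
            V = (A * G) @ M.T + ((rng.standard_normal((n, t)) * np.sqrt(G)) @ M.T)
            U = E @ V

            # (c) genetic covariance
            if self.fix_Sigma is None:
                Sw = (V / d[:, None]).T @ V
                if self.diagonal_sigma:
                    diag = np.empty(t)
                    for j in range(t):
                        ss = df_sig0 * S_sig0[j, j] + Sw[j, j]
                        diag[j] = ss / rng.chisquare(df_sig0 + n)
                    Sigma = np.diag(diag)
                else:
                    scale = S_sig0 + Sw
                    for _ in range(3):
                        try:
                            Sigma = stats.invwishart.rvs(
                                df=df_sig0 + n, scale=scale, random_state=rng)
                            break
                        except np.linalg.LinAlgError:
                            n_jitter += 1
                            scale = scale + jit * np.trace(scale) * np.eye(t)
                    Sigma = np.atleast_2d(Sigma)

            # (d) residual variances per trait
            Eres = Y_aug - mu - U
            if self.fix_R is None:
                ss = df_r0 * S_r0 + np.sum(Eres * Eres, axis=0)
                R = ss / rng.chisquare(df_r0 + n, size=t)

            # (e) intercepts (flat prior)
            if self.fix_mu is None:
                mu = rng.normal(np.mean(Y_aug - U, axis=0), np.sqrt(R / n))

            if it in keep_set:
                U_sum += U
                Yimp_sum += Y_aug
                Sig_sum += Sigma
                R_sum += R
                mu_sum += mu

        self.ids_ = ids
        self.traits_ = traits if traits is not None else list(range(t))
        self.mu_ = mu_sum / n_keep
        self.U_ = U_sum / n_keep
        self.Sigma_ = (Sig_sum / n_keep + (Sig_sum / n_keep).T) / 2.0
        self.R_ = R_sum / n_keep
        imput = Yimp_sum / n_keep
        self.imputed_Y_ = np.where(obs, np.nan, imput)
        self.observed_ = obs
        self.n_jitter_redraws_ = n_jitter
        return self

    def genetic_correlation_(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.Sigma_))
        return self.Sigma_ / np.outer(sd, sd)

    def predict(self, ids=None, trait=None):
        """Posterior-mean genetic values (optionally one trait / line subset)."""
        if not hasattr(self, "U_"):
            raise RuntimeError("call fit first")
        Udf = pd.DataFrame(self.U_, index=self.ids_, columns=self.traits_)
        if ids is not None:
            missing = [i for i in ids if i not in set(Udf.index)]
            if missing:
                raise KeyError(f"unknown line ids {missing[:3]}")
            Udf = Udf.loc[list(ids)]
        return Udf[trait].to_numpy() if trait is not None else Udf


def fit_mt(blues: pd.DataFrame, traits, K, cfg: GibbsConfig | None = None,
           mask: pd.DataFrame | np.ndarray | None = None,
           scope: str = "ALL") -> MultiTraitGBLUP:
    """Fit the multi-trait model from a tidy BLUE table.

    ``mask`` is an optional line x trait boolean frame aligned with K's
    line order (True = phenotype visible to the model); entries absent
    from the BLUE table are missing regardless.
    """
    cfg = cfg or GibbsConfig()
    Kv, ids = _as_kinship(K)
    traits = list(traits)
    d = blues[blues["trait"].isin(traits)]
    if scope is not None and "scope" in d.columns:
        d = d[d["scope"] == scope]
    wide = d.pivot_table(index="line_id", columns="trait", values="blue",
                         aggfunc="first")
    Y = pd.DataFrame(np.nan, index=ids, columns=traits)
    common = [i for i in ids if i in wide.index]
    for tr in traits:
        if tr not in wide.columns:
            raise ValueError(f"trait {tr!r} absent from BLUE table")
        Y.loc[common, tr] = wide.loc[common, tr]
    if mask is not None:
        m = mask.loc[ids, traits].to_numpy() if isinstance(mask, pd.DataFrame) \
            else np.asarray(mask, bool)
        Y = Y.where(m)
    model = MultiTraitGBLUP(n_iter=cfg.n_iter, burn_in=cfg.burn_in,
                            thin=cfg.thin, seed=cfg.seed, prior_df=cfg.prior_df)
    return model.fit(KinshipMatrix(Kv, ids), Y)


def conditional_mean_oracle(K, Sigma, R, Y_obs, mask, mu=None) -> np.ndarray:
    """Exact conditional mean of masked entries under the joint MVN model.

    Builds cov(vec(Y)) = Sigma (x) K + R (x) I over all line x trait cells
    (trait-major stacking) and returns the conditional mean of the
    unobserved cells given the observed ones by a direct linear solve.
    Feasible up to n*t of a couple of thousand; the independent oracle for
    the sampler's missing-value predictions.

    Parameters
    ----------
    K : KinshipMatrix or (n,n) array
    Sigma : (t,t) genetic covariance
    R : (t,) or (t,t) diagonal residual covariance
    Y_obs : (n,t) phenotypes (values at masked cells are ignored)
    mask : (n,t) boolean, True = observed
    mu : optional (t,) means, default zeros

    Returns
    -------
    (n,t) array with the conditional mean at masked cells, NaN elsewhere.
    """
    Kv, _ = _as_kinship(K)
    Y_obs = np.asarray(Y_obs, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n, t = Y_obs.shape
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    Rd = np.asarray(R, dtype=float)
    if Rd.ndim == 1:
        Rd = np.diag(Rd)
    mu = np.zeros(t) if mu is None else np.asarray(mu, dtype=float)

    C = np.kron(Sigma, Kv) + np.kron(Rd, np.eye(n))
    m_vec = np.repeat(mu, n)                    # trait-major
    obs_vec = mask.flatten(order="F")
    y_vec = Y_obs.flatten(order="F")

    Coo = C[np.ix_(obs_vec, obs_vec)]
    Cmo = C[np.ix_(~obs_vec, obs_vec)]
    try:
        alpha = np.linalg.solve(Coo, y_vec[obs_vec] - m_vec[obs_vec])
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular joint covariance") from exc
    pred = np.full(n * t, np.nan)
    pred[~obs_vec] = m_vec[~obs_vec] + Cmo @ alpha
    return pred.reshape((n, t), order="F")
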