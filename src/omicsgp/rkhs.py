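"""Bayesian multi-kernel RKHS regression fitted by Gibbs sampling.

The model for a single quantitative trait on ``n`` lines is

    y = 1 mu + sum_k u_k + e,   u_k ~ N(0, sigma2_k K_k),   e ~ N(0, sigma2_e I)

where each ``K_k`` is a kernel (relationship) matrix over the same lines.
With a single linear-kernel term this is Bayesian GBLUP; arbitrary kernels
give RKHS regression.  Each kernel effect is reparameterized in the kernel's
eigenbasis, ``u_k = B_k delta_k`` with ``B_k = Gamma_k Lambda_k^{1/2}`` and
``delta_k ~ N(0, sigma2_k I)``, which makes every full conditional Gaussian
with a *diagonal* precision and the sampler exact and fast for n up to a few
hundred.

Variance components carry scaled-inverse-chi-square priors whose scale
splits a prior fraction ``prior_R2`` of the observed phenotypic variance
equally among the kernel terms (the remainder to the residual) — weakly
informative in the tradition of Bayesian genomic-prediction software.
Lines with masked (or missing) phenotypes are handled by data augmentation:
their records are sampled from the predictive full conditional each
iteration, so the posterior mean of the augmented values is the model's
prediction for them.

Usage::

    model = MultiKernelRKHS(y, kernels, masked=test_idx)
    res = model.fit(GibbsConfig(seed=1))
    res.summary()
    res.predictions          # posterior means for the masked lines
    res.heritability()       # VP / (VP + Ve)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kernels import KernelMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GibbsConfig:
    """MCMC settings for :meth:`MultiKernelRKHS.fit`.

    ``n_iter`` total iterations per chain, ``burn_in`` discarded, every
    ``thin``-th kept afterwards; at least 50 retained draws are required.
    ``prior_df``/``prior_R2`` control the scaled-inverse-chi-square variance
    priors.  ``fixed_variances`` (term variances followed by the residual)
    switches the variance updates off — used for closed-form validation.
    ``fix_mu`` holds the intercept at a constant instead of sampling it.
    """

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    prior_df: float = 5.0
    prior_R2: float = 0.5
    seed: int = 0
    n_chains: int = 1
    min_eigen_keep: float = 1e-8
    fixed_variances: Optional[Tuple[float, ...]] = None
    fix_mu: Optional[float] = None

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be positive")
        if not 0.0 < self.prior_R2 < 1.0:
            raise ValueError("prior_R2 must lie in (0, 1)")
        if self.n_retained < 50:
            raise ValueError(
                f"only {self.n_retained} retained draws; increase n_iter or "
                "reduce burn_in/thin (at least 50 required)"
            )

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def eigen_prepare(
    K: KernelMatrix, min_eigen_keep: float = 1e-8
) -> Tuple[np.ndarray, np.ndarray]:
    """Spectral factor of a PSD kernel: eigenvectors and eigenvalues.

    Eigenpairs with ``lambda < min_eigen_keep * lambda_max`` (numerical
    null space) are dropped; the retained factor reconstructs ``K`` up to
    the dropped mass.
    """
    A = K.values
    if not np.isfinite(A).all():
        raise ValueError(f"kernel {K.recipe!r} has non-finite entries")
    eigvals, eigvecs = np.linalg.eigh((A + A.T) / 2.0)
    lam_max = float(eigvals.max())
    if lam_max <= 0:
        raise ValueError(f"kernel {K.recipe!r} has no positive eigenvalue")
    keep = eigvals > min_eigen_keep * lam_max
    n_drop = int((~keep).sum())
    if n_drop:
        logger.debug("eigen_prepare %s: dropped %d eigenpairs", K.recipe, n_drop)
    return eigvecs[:, keep], eigvals[keep]


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  R-hat compares the pooled
    (between + within) variance estimate with the within-chain variance;
    values near 1 indicate the chains explore the same distribution.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains of equal length")
    c, m = chains.shape
    if m < 10:
        raise ValueError("chains too short for a stable R-hat (need >= 10 draws)")
    within = float(np.mean(np.var(chains, axis=1, ddof=1)))
    between_over_m = float(np.var(np.mean(chains, axis=1), ddof=1))
    if within == 0.0:
        return 1.0 if between_over_m == 0.0 else np.inf
    v_hat = (m - 1) / m * within + between_over_m
    return float(np.sqrt(v_hat / within))


@dataclass
class RKHSResults:
    """Posterior summaries from a :class:`MultiKernelRKHS` fit.

    ``variance_components`` is a DataFrame indexed by term label with
    columns ``post_mean``, ``post_sd`` and (for multi-chain fits) ``rhat``;
    the residual variance appears as the last row labelled ``residual``.
    """

    term_labels: Tuple[str, ...]
    variance_components: pd.DataFrame
    mu: float
    line_effects: Dict[str, np.ndarray]
    fitted: np.ndarray
    masked_index: np.ndarray
    predictions: np.ndarray
    retained_draws: int
    n_chains: int
    config: GibbsConfig
    variance_draws: np.ndarray  # (n_chains, n_retained, n_terms + 1)

    @property
    def vp(self) -> float:
        """Sum of all kernel-term posterior-mean variances."""
        return float(self.variance_components.loc[list(self.term_labels), "post_mean"].sum())

    @property
    def ve(self) -> float:
        return float(self.variance_components.loc["residual", "post_mean"])

    def heritability(self) -> float:
        """h2 = VP / (VP + Ve), VP the sum of kernel-term variances."""
        return self.vp / (self.vp + self.ve)

    def variance_fractions(self) -> pd.Series:
        """Each variance component as a fraction of VP + Ve."""
        means = self.variance_components["post_mean"]
        return means / means.sum()

    @property
    def max_rhat(self) -> float:
        if "rhat" not in self.variance_components:
            raise ValueError("R-hat requires a fit with n_chains >= 2")
        return float(self.variance_components["rhat"].max())

    def predict(self, masked_index: Optional[Sequence[int]] = None) -> np.ndarray:
        """Posterior-mean phenotype for the masked lines.

        If ``masked_index`` is given it must equal the mask used at fit
        time (order-insensitive); the returned vector follows its order.
        """
        if masked_index is None:
            return self.predictions.copy()
        req = np.asarray(masked_index, dtype=int)
        pos = {int(i): j for j, i in enumerate(self.masked_index)}
        try:
            sel = [pos[int(i)] for i in req]
        except KeyError as exc:
            raise ValueError(
                f"index {exc.args[0]} was not masked during fitting"
            ) from None
        return self.predictions[sel]

    def summary(self) -> str:
        lines = [
            "Multi-kernel Bayesian RKHS regression",
            f"  terms: {' + '.join(self.term_labels)}",
            f"  chains: {self.n_chains}   retained draws/chain: {self.retained_draws}",
            f"  intercept (posterior mean): {self.mu:.4f}",
            "",
            self.variance_components.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            f"  VP = {self.vp:.4f}   Ve = {self.ve:.4f}   h2 = {self.heritability():.4f}",
        ]
        return "\n".join(lines)


class MultiKernelRKHS:
    """Gaussian response with one or more kernel-covariance random effects.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Phenotype vector.  ``NaN`` entries are treated as masked.
    kernels : sequence of KernelMatrix
        Kernel per random-effect term, all on the same line order.
    masked : array-like of int, optional
        Additional indices to hold out (test set); their phenotypes are
        predicted by data augmentation.
    term_labels : sequence of str, optional
        Names for the variance components (defaults to kernel recipes).
    """

    def __init__(
        self,
        endog,
        kernels: Sequence[KernelMatrix],
        masked: Optional[Sequence[int]] = None,
        term_labels: Optional[Sequence[str]] = None,
    ):
        y = np.asarray(endog, dtype=float).ravel()
        if not kernels:
            raise ValueError("at least one kernel term is required")
        n = len(y)
        ids = kernels[0].line_ids
        for K in kernels:
            if K.n != n:
                raise ValueError(f"kernel {K.recipe!r} size {K.n} != len(y) {n}")
            if K.line_ids != ids:
                raise ValueError("kernels disagree on line order")
        mask = np.zeros(n, dtype=bool)
        mask[np.isnan(y)] = True
        if masked is not None:
            idx = np.asarray(masked, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError("masked index out of range")
            mask[idx] = True
        observed = ~mask
        if observed.sum() < 2:
            raise ValueError("need at least 2 observed phenotypes")
        y_obs = y[observed]
        if np.var(y_obs) == 0:
            raise ValueError("observed phenotypes are constant; nothing to fit")
        self.endog = y
        self.kernels = list(kernels)
        self.mask = mask
        self.observed = observed
        self.term_labels = tuple(
            term_labels if term_labels is not None else (K.recipe for K in kernels)
        )
        if len(self.term_labels) != len(self.kernels):
            raise ValueError("term_labels length must match kernels")

    @classmethod
    def from_dataset(cls, dataset, trait: str, kernels, masked=None, term_labels=None):
        """Build from a :class:`~omicsgp.data_io.Dataset` and a kernel list."""
        y = dataset.trait_vector(trait)
        return cls(y, kernels, masked=masked, term_labels=term_labels)

    # ------------------------------------------------------------------ fit

    def fit(self, config: Optional[GibbsConfig] = None, **overrides) -> RKHSResults:
        if config is None:
            config = GibbsConfig(**overrides)
        elif overrides:
            config = replace(config, **overrides)
        n_terms = len(self.kernels)
        if config.fixed_variances is not None and len(config.fixed_variances) != n_terms + 1:
            raise ValueError(
                "fixed_variances must list one value per kernel term plus the residual"
            )

        factors = [eigen_prepare(K, config.min_eigen_keep) for K in self.kernels]
        # B_k = Gamma sqrt(Lambda): B B^T = K and B^T B = diag(Lambda)
        B = [gamma * np.sqrt(lam) for gamma, lam in factors]
        lam = [l for _, l in factors]

        y = self.endog
        obs = self.observed
        n = len(y)
        var_y = float(np.var(y[obs], ddof=1))
        df0 = config.prior_df
        # prior scales: prior_R2 of var(y) split equally among terms, the
        # rest to the residual; mode of scaled-inv-chi2(df0, S) = S df0/(df0+2)
        mode_factor = (df0 + 2.0) / df0
        S_terms = config.prior_R2 * var_y / n_terms * mode_factor
        S_resid = (1.0 - config.prior_R2) * var_y * mode_factor

        m = config.n_retained
        n_chains = config.n_chains
        var_draws = np.empty((n_chains, m, n_terms + 1))
        mu_draws = np.empty((n_chains, m))
        u_sum = [np.zeros(n) for _ in range(n_terms)]
        genetic_sum = np.zeros(n)

        seeds = np.random.SeedSequence(config.seed).spawn(n_chains)
        for chain in range(n_chains):
            self._run_chain(
                rng=np.random.default_rng(seeds[chain]),
                config=config,
                B=B,
                lam=lam,
                S_terms=S_terms,
                S_resid=S_resid,
                var_out=var_draws[chain],
                mu_out=mu_draws[chain],
                u_sum=u_sum,
                genetic_sum=genetic_sum,
            )

        total = n_chains * m
        labels = list(self.term_labels) + ["residual"]
        pooled = var_draws.reshape(total, n_terms + 1)
        vc = pd.DataFrame(
            {
                "post_mean": pooled.mean(axis=0),
                "post_sd": pooled.std(axis=0, ddof=1),
            },
            index=labels,
        )
        if n_chains >= 2:
            vc["rhat"] = [gelman_rubin(var_draws[:, :, j]) for j in range(n_terms + 1)]
        mu_mean = float(mu_draws.mean())
        effects = {lab: u_sum[k] / total for k, lab in enumerate(self.term_labels)}
        fitted = mu_mean + genetic_sum / total
        masked_index = np.flatnonzero(self.mask)
        return RKHSResults(
            term_labels=self.term_labels,
            variance_components=vc,
            mu=mu_mean,
            line_effects=effects,
            fitted=fitted,
            masked_index=masked_index,
            predictions=fitted[masked_index],
            retained_draws=m,
            n_chains=n_chains,
            config=config,
            variance_draws=var_draws,
        )

    def _run_chain(
        self, rng, config, B, lam, S_terms, S_resid, var_out, mu_out, u_sum, genetic_sum
    ) -> None:
        y = self.endog
        obs = self.observed
        mask = self.mask
        n = len(y)
        n_terms = len(B)
        df0 = config.prior_df
        fixed = config.fixed_variances

        y_cur = y.copy()
        y_obs_mean = float(y[obs].mean())
        y_cur[mask] = y_obs_mean

        mu = y_obs_mean if config.fix_mu is None else float(config.fix_mu)
        delta = [np.zeros(len(l)) for l in lam]
        u = [np.zeros(n) for _ in range(n_terms)]
        total_u = np.zeros(n)
        if fixed is not None:
            sigma2 = list(fixed[:n_terms])
            sigma2_e = float(fixed[-1])
        else:
            sigma2 = [S_terms] * n_terms
            sigma2_e = S_resid

        keep = 0
        for it in range(config.n_iter):
            # intercept (flat prior)
            if config.fix_mu is None:
                resid_mean = float((y_cur - total_u).mean())
                mu = rng.normal(resid_mean, np.sqrt(sigma2_e / n))
            # kernel-term coefficients in the eigenbasis
            for k in range(n_terms):
                e_k = y_cur - mu - (total_u - u[k])
                rhs = B[k].T @ e_k
                prec = lam[k] / sigma2_e + 1.0 / sigma2[k]
                mean = rhs / (sigma2_e * prec)
                delta[k] = mean + rng.standard_normal(len(prec)) / np.sqrt(prec)
                new_u = B[k] @ delta[k]
                total_u += new_u - u[k]
                u[k] = new_u
            # variance components (scaled-inverse-chi-square full conditionals)
            if fixed is None:
                for k in range(n_terms):
                    ss = float(delta[k] @ delta[k])
                    df_post = df0 + len(delta[k])
                    sigma2[k] = (df0 * S_terms + ss) / rng.chisquare(df_post)
                resid = y_cur - mu - total_u
                ss_e = float(resid @ resid)
                sigma2_e = (df0 * S_resid + ss_e) / rng.chisquare(df0 + n)
            # data augmentation for masked phenotypes
            if mask.any():
                y_cur[mask] = mu + total_u[mask] + rng.normal(
                    0.0, np.sqrt(sigma2_e), size=int(mask.sum())
                )
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                var_out[keep, :n_terms] = sigma2
                var_out[keep, n_terms] = sigma2_e
                mu_out[keep] = mu
                for k in range(n_terms):
                    u_sum[k] += u[k]
                genetic_sum += total_u
                keep += 1
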