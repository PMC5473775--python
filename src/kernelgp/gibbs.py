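"""Gibbs sampler for Gaussian kernel-covariance mixed models.

The model is

    y = W beta + sum_k eta_k + eps,    eta_k ~ N(0, sigma2_k Omega_k),
    eps ~ N(0, sigma2_eps I),

with flat priors on the fixed effects beta and scaled-inverse-chi-square
priors on every variance.  Each record-level structure matrix Omega_k is
eigendecomposed once, Omega_k = B_k diag(lambda_k) B_k', and the effect is
reparameterized as eta_k = B_k b_k with independent coefficient priors
b_kj ~ N(0, sigma2_k lambda_kj).  Because the eigenvector bases are
orthonormal over the complete record set, every coefficient full
conditional is diagonal, giving O(n·m) per sweep.

Records flagged as unobserved (the prediction targets) are handled by data
augmentation: their phenotypes are sampled each iteration from the
predictive distribution N(linear predictor, sigma2_eps), so posterior means
of the linear predictor at those records are genomic predictions drawn from
the joint posterior and predictive distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CovarianceComponent, ModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "EigenComponent",
    "PosteriorSummary",
    "eigendecompose_component",
    "gibbs_fit",
    "summarize_posterior",
]


@dataclass
class EigenComponent:
    """Eigenbasis form of a covariance structure matrix.

    ``basis`` holds the orthonormal eigenvectors (records x m) for the m
    eigenvalues above the truncation threshold, ``eigenvalues`` the values
    sorted descending.
    """

    basis: np.ndarray
    eigenvalues: np.ndarray
    label: str
    variance_symbol: str

    @property
    def m(self) -> int:
        return self.eigenvalues.size

    @property
    def n_records(self) -> int:
        return self.basis.shape[0]


def eigendecompose_component(
    component: CovarianceComponent, rel_tol: float = 1e-10
) -> EigenComponent:
    """Eigendecompose Omega, keeping eigenpairs above rel_tol * lambda_max.

    Slightly negative eigenvalues (round-off) are discarded by the same
    threshold; a matrix with no positive eigenvalue raises.
    """
    O = component.omega
    if np.abs(O - O.T).max(initial=0.0) > 1e-8:
        raise ValueError(f"omega for {component.label!r} is not symmetric")
    w, V = np.linalg.eigh((O + O.T) / 2.0)
    lam_max = w[-1]
    if lam_max <= 0:
        raise ValueError(f"omega for {component.label!r} has no positive eigenvalue")
    keep = w > rel_tol * lam_max
    w, V = w[keep], V[:, keep]
    order = np.argsort(w)[::-1]
    return EigenComponent(
        basis=np.ascontiguousarray(V[:, order]),
        eigenvalues=w[order],
        label=component.label,
        variance_symbol=component.variance_symbol,
    )


@dataclass
class PosteriorSummary:
    """Posterior output of one Gibbs run.

    ``chains`` holds the retained post-burn-in samples for every variance
    component and fixed-effect coordinate; ``fitted_values`` the posterior
    mean of the linear predictor W beta + sum eta_k per record (the genomic
    prediction for masked records); ``fitted_sd`` its posterior SD.
    """

    chains: dict[str, np.ndarray]
    fixed_effects: np.ndarray
    fitted_values: np.ndarray
    fitted_sd: np.ndarray
    seed: int
    iterations: int
    burn_in: int
    thin: int
    observed_mask: np.ndarray = field(repr=False, default=None)

    def mean(self, symbol: str) -> float:
        return float(self.chains[symbol].mean())

    def sd(self, symbol: str) -> float:
        return float(self.chains[symbol].std(ddof=1))

    @property
    def variance_symbols(self) -> list[str]:
        return [s for s in self.chains if s.startswith("sigma2_")]

    def variance_means(self) -> dict[str, float]:
        return {s: self.mean(s) for s in self.variance_symbols}


def _prior_scale(df0: float, mode: float) -> float:
    # scaled-inv-chi2(df0, S0) has mode df0*S0/(df0 + 2)
    return mode * (df0 + 2.0) / df0


def gibbs_fit(
    y: np.ndarray,
    observed: np.ndarray,
    W: np.ndarray,
    components: list[EigenComponent],
    spec: ModelSpec,
    fix_variances: dict[str, float] | None = None,
) -> PosteriorSummary:
    """Run the Gibbs sampler.

    Parameters
    ----------
    y
        Phenotype vector over all records (standardized scale).  Values at
        unobserved records are never read.
    observed
        Boolean mask; False marks records whose phenotype is to be
        predicted.
    W
        Full-rank fixed-effect design (records x q).
    components
        Eigendecomposed covariance components.
    spec
        MCMC settings and prior hyperparameters.
    fix_variances
        Optional map variance_symbol -> value; listed variances are held
        fixed instead of sampled (used for validating the sampler against
        closed-form mixed-model solutions).  ``sigma2_e`` refers to the
        residual variance.

    Returns
    -------
    PosteriorSummary with variance/fixed-effect chains and posterior
    mean/SD of the linear predictor at every record.
    """
    y = np.asarray(y, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    n = y.size
    if observed.sum() < 1:
        raise ValueError("no observed records")
    if not components:
        raise ValueError("at least one covariance component is required")
    if W.shape[0] != n:
        raise ValueError("fixed-effect design row count mismatch")
    for c in components:
        if c.n_records != n:
            raise ValueError(f"component {c.label!r} sized for {c.n_records} records, not {n}")
    fix_variances = dict(fix_variances or {})
    rng = np.random.default_rng(spec.seed)

    q = W.shape[1]
    WtW = W.T @ W
    # Cholesky of (W'W)^{-1} for the fixed-effect draw
    L_wtw = np.linalg.cholesky(WtW)

    yc = np.where(observed, y, 0.0)  # masked records start at the TRN mean
    vary = float(np.var(y[observed], ddof=1)) if observed.sum() > 1 else 1.0
    if vary == 0.0:
        vary = 1.0

    ncomp = len(components)
    r2_each = spec.r2 / ncomp
    sigma2 = np.empty(ncomp)
    S0 = np.empty(ncomp)
    for k, c in enumerate(components):
        mean_diag = float(c.eigenvalues.sum()) / n
        mode = r2_each * vary / max(mean_diag, 1e-12)
        S0[k] = _prior_scale(spec.df0, mode)
        sigma2[k] = fix_variances.get(c.variance_symbol, mode)
    mode_e = (1.0 - spec.r2) * vary
    S0_e = _prior_scale(spec.df0, mode_e)
    sigma2_e = fix_variances.get("sigma2_e", mode_e)
    fixed = {c.variance_symbol in fix_variances for c in components}
    fix_resid = "sigma2_e" in fix_variances

    beta = np.zeros(q)
    b = [np.zeros(c.m) for c in components]
    eta = [np.zeros(n) for _ in components]
    e = yc.copy()  # residual of the complete data: yc - W beta - sum eta

    n_keep = spec.n_samples
    var_chain = np.empty((n_keep, ncomp))
    resid_chain = np.empty(n_keep)
    beta_chain = np.empty((n_keep, q))
    theta_sum = np.zeros(n)
    theta_sq = np.zeros(n)

    kept = 0
    for it in range(spec.iterations):
        # --- fixed effects: beta | rest ~ N((W'W)^-1 W' r, sigma2_e (W'W)^-1)
        e += W @ beta
        rhs = W.T @ e
        mean_b = np.linalg.solve(WtW, rhs)
        z = rng.standard_normal(q)
        beta = mean_b + np.sqrt(sigma2_e) * np.linalg.solve(L_wtw.T, z)
        e -= W @ beta

        # --- kernel coefficients, one diagonal block per component
        for k, c in enumerate(components):
            e += eta[k]
            cvec = c.basis.T @ e
            prec = 1.0 / sigma2_e + 1.0 / (sigma2[k] * c.eigenvalues)
            var_b = 1.0 / prec
            mean_bk = var_b * cvec / sigma2_e
            b[k] = mean_bk + np.sqrt(var_b) * rng.standard_normal(c.m)
            eta[k] = c.basis @ b[k]
            e -= eta[k]

        # --- variance components: scaled-inverse-chi-square full conditionals
        for k, c in enumerate(components):
            if c.variance_symbol in fix_variances:
                continue
            ss = float(np.sum(b[k] ** 2 / c.eigenvalues))
            df = spec.df0 + c.m
            sigma2[k] = (spec.df0 * S0[k] + ss) / rng.chisquare(df)
        if not fix_resid:
            df = spec.df0 + n
            sigma2_e = (spec.df0 * S0_e + float(e @ e)) / rng.chisquare(df)

        # --- predictive draw for masked records (data augmentation)
        theta = yc - e
        miss = ~observed
        if miss.any():
            noise = np.sqrt(sigma2_e) * rng.standard_normal(int(miss.sum()))
            yc[miss] = theta[miss] + noise
            e[miss] = noise

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            var_chain[kept] = sigma2
            resid_chain[kept] = sigma2_e
            beta_chain[kept] = beta
            theta_sum += theta
            theta_sq += theta * theta
            kept += 1

        if (it + 1) % 1000 == 0 and not np.isfinite(e).all():
            bad = [c.variance_symbol for k, c in enumerate(components)
                   if not np.isfinite(sigma2[k])]
            raise FloatingPointError(
                f"non-finite values in chain at iteration {it + 1} "
                f"(suspect symbols: {bad or ['residual/coefficients']})"
            )

    var_chain = var_chain[:kept]
    resid_chain = resid_chain[:kept]
    beta_chain = beta_chain[:kept]

    chains: dict[str, np.ndarray] = {}
    for k, c in enumerate(components):
        chains[c.variance_symbol] = var_chain[:, k]
    chains["sigma2_e"] = resid_chain
    for j in range(q):
        chains[f"beta_{j}"] = beta_chain[:, j]

    fitted = theta_sum / kept
    fitted_var = np.maximum(theta_sq / kept - fitted**2, 0.0)
    return PosteriorSummary(
        chains=chains,
        fixed_effects=beta_chain.mean(axis=0),
        fitted_values=fitted,
        fitted_sd=np.sqrt(fitted_var),
        seed=spec.seed,
        iterations=spec.iterations,
        burn_in=spec.burn_in,
        thin=spec.thin,
        observed_mask=observed,
    )


def summarize_posterior(summary: PosteriorSummary) -> pd.DataFrame:
    """Posterior mean, SD and effective sample size per monitored symbol."""
    import arviz as az

    rows = []
    for symbol, chain in summary.chains.items():
        if chain.size == 0:
            raise ValueError(f"empty chain for {symbol}")
        if np.allclose(chain, chain[0]):
            ess = float(chain.size)
            sd = 0.0
        else:
            ess = float(az.ess(np.asarray(chain)[None, :]))
            sd = float(np.std(chain, ddof=1))
        rows.append(
            {"symbol": symbol, "mean": float(np.mean(chain)), "sd": sd, "ess": ess}
        )
    return pd.DataFrame(rows)
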