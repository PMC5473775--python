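"""Model assembly for unbalanced multi-environment trials.

Builds, from long-format phenotype records and a genomic kernel K, the
incidence matrices and random-effect covariance structures of the four
prediction models:

* SM  — single-environment main genotypic effect: y = mu 1 + Zu u + e,
  u ~ N(0, sigma2_u K), fitted separately per environment.
* MM  — multi-environment main effect: y = mu 1 + ZE bE + Zu u0 + e,
  u0 ~ N(0, sigma2_u0 K).
* MDs — MM plus one G×E deviation with a single interaction variance:
  ue ~ N(0, sigma2_ue [Zu K Zu'] ∘ [ZE ZE']), the Hadamard structure that
  is block-diagonal in the per-environment kernels K_j.
* MDe — MM plus environment-specific deviations uE_j ~ N(0, sigma2_uEj K_j),
  one variance per environment; the blocks sum to the MDs structure.

Records are (line, environment, trait, value) rows; imbalance (lines absent
from some environments) is implicit in which rows exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kernels import KernelMatrix, subset_kernel

__all__ = [
    "PhenotypeRecords",
    "DesignMatrices",
    "CovarianceComponent",
    "ModelSpec",
    "MODELS",
    "METHODS",
    "standardize_phenotypes",
    "build_design_matrices",
    "fixed_effects_design",
    "hadamard_interaction",
    "env_specific_components",
    "assemble_model",
]

MODELS = ("SM", "MM", "MDs", "MDe")
METHODS = ("GB", "GK")


@dataclass
class PhenotypeRecords:
    """Unbalanced long-format phenotype observations.

    ``df`` has columns ``line``, ``env``, ``trait``, ``value`` with at most
    one row per (line, env, trait).  ``scaling`` maps a trait to the
    (mean, sd) used to standardize it, enabling back-transformation.
    """

    df: pd.DataFrame
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    REQUIRED = ("line", "env", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype records missing columns: {missing}")
        df = self.df.reset_index(drop=True).copy()
        df["line"] = df["line"].astype(str)
        df["env"] = df["env"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["value"] = df["value"].astype(float)
        dup = df.duplicated(subset=["line", "env", "trait"])
        if dup.any():
            rows = df.index[dup].tolist()
            raise ValueError(f"duplicate (line, env, trait) records at rows {rows}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    def for_trait(self, trait: str) -> "PhenotypeRecords":
        sub = self.df[self.df["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no records for trait {trait!r}")
        scaling = {trait: self.scaling[trait]} if trait in self.scaling else {}
        return PhenotypeRecords(sub.reset_index(drop=True), scaling)

    def for_env(self, env: str) -> "PhenotypeRecords":
        sub = self.df[self.df["env"] == env]
        if sub.empty:
            raise KeyError(f"no records for environment {env!r}")
        return PhenotypeRecords(sub.reset_index(drop=True), dict(self.scaling))

    def back_transform(self) -> "PhenotypeRecords":
        """Undo standardization using the stored (mean, sd) constants."""
        df = self.df.copy()
        for trait, (mu, sd) in self.scaling.items():
            sel = df["trait"] == trait
            df.loc[sel, "value"] = df.loc[sel, "value"] * sd + mu
        return PhenotypeRecords(df, {})


def standardize_phenotypes(
    records: PhenotypeRecords,
    reference_mask: np.ndarray | None = None,
) -> PhenotypeRecords:
    """Center and scale each trait by its overall across-environment mean/SD.

    ``reference_mask`` restricts the records used to compute the constants
    (boolean over rows); in cross-validation this is the training mask, so
    test values never leak into the standardization.  The constants are
    stored in ``scaling`` for back-transformation.
    """
    df = records.df.copy()
    if reference_mask is None:
        reference_mask = np.ones(len(df), dtype=bool)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != (len(df),):
        raise ValueError("reference_mask length does not match record count")
    scaling: dict[str, tuple[float, float]] = {}
    for trait in records.traits:
        sel = (df["trait"] == trait).to_numpy()
        ref = sel & reference_mask
        vals = df.loc[ref, "value"].to_numpy()
        if vals.size < 2:
            raise ValueError(f"trait {trait!r}: need >= 2 reference records")
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"trait {trait!r}: zero SD in reference records")
        df.loc[sel, "value"] = (df.loc[sel, "value"] - mu) / sd
        scaling[trait] = (mu, sd)
    return PhenotypeRecords(df, scaling)


@dataclass
class DesignMatrices:
    """Incidence matrices linking records to environments and lines.

    Z_E is records x environments, Z_u records x lines; each row has a
    single 1.  Environments and lines are ordered lexicographically so the
    construction is deterministic.
    """

    Z_E: np.ndarray
    Z_u: np.ndarray
    env_order: list[str]
    line_order: list[str]

    def __post_init__(self) -> None:
        if not np.all(self.Z_E.sum(axis=1) == 1):
            raise ValueError("every record must belong to exactly one environment")
        if not np.all(self.Z_u.sum(axis=1) == 1):
            raise ValueError("every record must belong to exactly one line")

    @property
    def n_records(self) -> int:
        return self.Z_E.shape[0]

    @property
    def n_envs(self) -> int:
        return self.Z_E.shape[1]

    @property
    def n_lines(self) -> int:
        return self.Z_u.shape[1]

    def record_envs(self) -> np.ndarray:
        return np.array(self.env_order, dtype=object)[self.Z_E.argmax(axis=1)]

    def record_lines(self) -> np.ndarray:
        return np.array(self.line_order, dtype=object)[self.Z_u.argmax(axis=1)]


def build_design_matrices(records: PhenotypeRecords) -> DesignMatrices:
    """Build Z_E and Z_u from (single-trait) phenotype records."""
    df = records.df
    if df.empty:
        raise ValueError("no records")
    if df["trait"].nunique() > 1:
        raise ValueError("design matrices are built per trait; filter first")
    env_order = sorted(df["env"].unique())
    line_order = sorted(df["line"].unique())
    e_idx = df["env"].map({e: i for i, e in enumerate(env_order)}).to_numpy()
    l_idx = df["line"].map({l: i for i, l in enumerate(line_order)}).to_numpy()
    n = len(df)
    Z_E = np.zeros((n, len(env_order)))
    Z_E[np.arange(n), e_idx] = 1.0
    Z_u = np.zeros((n, len(line_order)))
    Z_u[np.arange(n), l_idx] = 1.0
    return DesignMatrices(Z_E, Z_u, env_order, line_order)


def fixed_effects_design(design: DesignMatrices, model: str) -> np.ndarray:
    """Full-rank fixed-effect design matrix W.

    SM uses an intercept only.  Multi-environment models use an intercept
    plus treatment contrasts for all but the first environment — a full-rank
    reparameterization of (mu, beta_E); predictions are invariant to this
    choice.
    """
    n = design.n_records
    if model == "SM" or design.n_envs == 1:
        return np.ones((n, 1))
    return np.hstack([np.ones((n, 1)), design.Z_E[:, 1:]])


@dataclass
class CovarianceComponent:
    """One random effect's record-level covariance structure.

    ``omega`` is the n_records x n_records PSD structure matrix multiplying
    the component's variance; ``variance_symbol`` names that variance
    (sigma2_u, sigma2_u0, sigma2_ue, sigma2_uE_<env>).
    """

    label: str
    omega: np.ndarray
    variance_symbol: str

    def __post_init__(self) -> None:
        O = np.asarray(self.omega, dtype=float)
        if O.ndim != 2 or O.shape[0] != O.shape[1]:
            raise ValueError("omega must be square")
        self.omega = O


def _expand_kernel(design: DesignMatrices, K: KernelMatrix) -> np.ndarray:
    """Z_u K Z_u' — kernel lifted from lines to records."""
    missing = [l for l in design.line_order if l not in set(K.line_ids)]
    if missing:
        raise KeyError(f"kernel does not cover lines: {missing}")
    Ksub = subset_kernel(K, design.line_order).values
    return design.Z_u @ Ksub @ design.Z_u.T


def hadamard_interaction(design: DesignMatrices, K: KernelMatrix) -> CovarianceComponent:
    """Single-variance G×E structure [Zu K Zu'] ∘ [ZE ZE'].

    The Hadamard product zeroes entries between records in different
    environments, leaving the per-environment kernel blocks K_j on the
    (permuted) diagonal.
    """
    ZKZ = _expand_kernel(design, K)
    E = design.Z_E @ design.Z_E.T
    return CovarianceComponent("ue", ZKZ * E, "sigma2_ue")


def env_specific_components(
    design: DesignMatrices, K: KernelMatrix
) -> list[CovarianceComponent]:
    """One structure matrix per environment, each with its own variance.

    omega_j carries the kernel block K_j for the records of environment j
    and zeros elsewhere; the omegas sum exactly to the Hadamard interaction
    structure.
    """
    ZKZ = _expand_kernel(design, K)
    out = []
    for j, env in enumerate(design.env_order):
        z = design.Z_E[:, j : j + 1]
        out.append(
            CovarianceComponent(f"uE_{env}", ZKZ * (z @ z.T), f"sigma2_uE_{env}")
        )
    return out


def assemble_model(
    model: str, design: DesignMatrices, K: KernelMatrix
) -> list[CovarianceComponent]:
    """Random-effect covariance components for one model on one dataset."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    ZKZ = _expand_kernel(design, K)
    if model == "SM":
        if design.n_envs != 1:
            raise ValueError(
                "SM fits each environment separately; got "
                f"{design.n_envs} environments — filter records first"
            )
        return [CovarianceComponent("u", ZKZ, "sigma2_u")]
    main = CovarianceComponent("u0", ZKZ, "sigma2_u0")
    if model == "MM":
        return [main]
    if model == "MDs":
        return [main, hadamard_interaction(design, K)]
    return [main] + env_specific_components(design, K)


@dataclass
class ModelSpec:
    """One model-method combination plus MCMC settings and priors.

    The default chain (35,000 iterations, 5,000 burn-in, thin 5) matches
    the full-scale analyses; ``reduced()`` gives the short profile used in
    cross-validation and tests, where accuracy is insensitive to chain
    length at fixture scale.

    ``df0`` is the prior degrees of freedom of every scaled-inverse-chi-
    square variance prior; ``r2`` the prior proportion of phenotypic
    variance attributed to the genetic components jointly (split equally
    among them), the remainder going to the residual.
    """

    model: str = "MM"
    method: str = "GB"
    iterations: int = 35_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    df0: float = 5.0
    r2: float = 0.5

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must lie in (0, 1)")

    @property
    def abbreviation(self) -> str:
        return f"{self.model}-{self.method}"

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    def reduced(self) -> "ModelSpec":
        """Short-chain profile (3,500 iterations, 500 burn-in, thin 2)."""
        return replace(self, iterations=3_500, burn_in=500, thin=2)
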