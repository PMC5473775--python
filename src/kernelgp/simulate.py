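"""Synthetic hybrid-trial generator.

Emulates the data-generating process the prediction models assume: inbred
founder lines genotyped at biallelic SNPs, F1 hybrids from random crosses,
and unbalanced multi-environment phenotypes composed of environment means,
a main genetic effect shared across environments, per-environment G×E
deviations, and i.i.d. residual noise.

Each random component is built from marker effects (main effect u0 = X a,
per-environment deviations X a_j) and rescaled so its realized sample
variance hits the configured target exactly — not just in expectation —
which gives variance-component recovery tests sharp truth values.  An
optional epistatic share routes part of the genetic variance through
pairwise marker products, the non-additive architecture on which the
Gaussian kernel outperforms the linear kernel.

Trial imbalance ("sparse testing") is produced by deleting a random
fraction of (line, environment) cells, while guaranteeing every line keeps
at least one record and every environment at least two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PhenotypeRecords
from .markers import CrossTable, MarkerMatrix, standardize_markers

__all__ = [
    "SimConfig",
    "simulate_founders_and_hybrids",
    "simulate_multienv_phenotypes",
    "apply_sparsity",
]


@dataclass
class SimConfig:
    """Configuration of one synthetic hybrid trial.

    Defaults describe a mid-sized unbalanced maize-style trial: 40 inbred
    founders crossed into 200 hybrids genotyped at 1,000 SNPs, evaluated in
    4 environments with 70% of the hybrid-by-environment cells observed,
    and variance components sigma2_u0 = 0.4 (main genetic), sigma2_ue = 0.2
    (G×E), sigma2_e = 0.4 (residual) on the trait scale.
    """

    n_parents: int = 40
    n_hybrids: int = 200
    p: int = 1_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    s: int = 4
    env_means: tuple[float, ...] | None = None  # default: linspace(-0.5, 0.5, s)
    sigma2_u0: float = 0.4
    sigma2_ue: float = 0.2
    sigma2_uEj: tuple[float, ...] | None = None  # per-env variances (MDe-style)
    sigma2_e: float = 0.4
    epistasis_fraction: float = 0.0
    sparsity: float = 0.3
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.n_hybrids > self.n_parents * (self.n_parents - 1) // 2:
            raise ValueError("more hybrids requested than distinct parent pairs")
        if not (0 <= self.epistasis_fraction <= 1):
            raise ValueError("epistasis_fraction must lie in [0, 1]")
        if not (0 <= self.sparsity < 1):
            raise ValueError("sparsity must lie in [0, 1)")
        for v in (self.sigma2_u0, self.sigma2_ue, self.sigma2_e):
            if v < 0:
                raise ValueError("variance targets must be non-negative")
        if self.sigma2_uEj is not None and len(self.sigma2_uEj) != self.s:
            raise ValueError("sigma2_uEj must have one entry per environment")

    @property
    def beta_E(self) -> np.ndarray:
        if self.env_means is not None:
            if len(self.env_means) != self.s:
                raise ValueError("env_means must have one entry per environment")
            return np.asarray(self.env_means, dtype=float)
        if self.s == 1:
            return np.zeros(1)
        return np.linspace(-0.5, 0.5, self.s)

    @property
    def env_ids(self) -> list[str]:
        return [f"env{j + 1}" for j in range(self.s)]


def simulate_founders_and_hybrids(cfg: SimConfig) -> tuple[MarkerMatrix, CrossTable]:
    """Draw homozygous founder genotypes and a random set of F1 crosses.

    Each marker's minor-allele frequency is uniform in ``maf_range``;
    founders are fully inbred, so dosages are 0 or 2.  Crosses are distinct
    unordered parent pairs sampled without replacement.
    """
    rng = np.random.default_rng(cfg.seed)
    freq = rng.uniform(*cfg.maf_range, size=cfg.p)
    founders = 2.0 * (rng.random((cfg.n_parents, cfg.p)) < freq)
    parent_ids = [f"P{i + 1:03d}" for i in range(cfg.n_parents)]
    markers = MarkerMatrix(
        founders, parent_ids, [f"M{m + 1:05d}" for m in range(cfg.p)]
    )

    pairs = [(i, j) for i in range(cfg.n_parents) for j in range(i + 1, cfg.n_parents)]
    chosen = rng.choice(len(pairs), size=cfg.n_hybrids, replace=False)
    crosses = CrossTable(
        hybrid_ids=[f"H{k + 1:04d}" for k in range(cfg.n_hybrids)],
        parent1_ids=[parent_ids[pairs[c][0]] for c in chosen],
        parent2_ids=[parent_ids[pairs[c][1]] for c in chosen],
    )
    return markers, crosses


def _scaled_effect(raw: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale a raw effect vector to sample variance target_var."""
    if target_var == 0.0:
        return np.zeros_like(raw)
    raw = raw - raw.mean()
    v = raw.var(ddof=1)
    if v == 0.0:
        raise ValueError("degenerate effect vector: zero variance, cannot rescale")
    return raw * np.sqrt(target_var / v)


def _genetic_vector(
    Z: np.ndarray,
    pairs: np.ndarray,
    epi_frac: float,
    target_var: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One genetic effect vector with an additive and an epistatic part."""
    if target_var == 0.0:
        return np.zeros(Z.shape[0])
    add = Z @ rng.standard_normal(Z.shape[1])
    if epi_frac == 0.0:
        return _scaled_effect(add, target_var)
    prod = Z[:, pairs[:, 0]] * Z[:, pairs[:, 1]]
    epi = prod @ rng.standard_normal(pairs.shape[0])
    out = _scaled_effect(add, (1.0 - epi_frac) * target_var) + _scaled_effect(
        epi, epi_frac * target_var
    )
    # cross-term between the parts shifts the realized total; rescale once more
    return _scaled_effect(out, target_var)


def simulate_multienv_phenotypes(
    hybrids: MarkerMatrix, cfg: SimConfig
) -> PhenotypeRecords:
    """Generate unbalanced multi-environment phenotypes for given hybrids.

    Record value = beta_Ej + u0_i + g_ij + eps_ij with u0 the main genetic
    effect (sample variance exactly sigma2_u0), g_ij per-environment G×E
    deviations (variance sigma2_ue, or sigma2_uEj[j] when configured) and
    eps i.i.d. residuals (variance sigma2_e).  Sparsity deletes random
    cells afterwards.
    """
    if cfg.p == 0 and (cfg.sigma2_u0 > 0 or cfg.sigma2_ue > 0 or cfg.sigma2_uEj):
        raise ValueError("cannot hit a positive genetic variance with p = 0 markers")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    if hybrids.standardized:
        Z = hybrids.dosages
    else:
        with warnings.catch_warnings():
            # monomorphic hybrid columns are irrelevant to effect construction
            warnings.simplefilter("ignore", UserWarning)
            Z = standardize_markers(hybrids).dosages
    n = Z.shape[0]

    n_pairs = max(Z.shape[1] // 2, 1)
    perm = rng.permutation(Z.shape[1])
    pairs = perm[: 2 * n_pairs].reshape(-1, 2)

    u0 = _genetic_vector(Z, pairs, cfg.epistasis_fraction, cfg.sigma2_u0, rng)
    env_vars = (
        list(cfg.sigma2_uEj) if cfg.sigma2_uEj is not None else [cfg.sigma2_ue] * cfg.s
    )
    beta = cfg.beta_E

    rows = []
    for j, env in enumerate(cfg.env_ids):
        g_j = _genetic_vector(Z, pairs, cfg.epistasis_fraction, env_vars[j], rng)
        eps = _scaled_effect(rng.standard_normal(n), cfg.sigma2_e)
        values = beta[j] + u0 + g_j + eps
        for i, line in enumerate(hybrids.line_ids):
            rows.append((line, env, cfg.trait, values[i]))
    records = PhenotypeRecords(
        pd.DataFrame(rows, columns=["line", "env", "trait", "value"])
    )
    if cfg.sparsity > 0:
        records = apply_sparsity(records, cfg.sparsity, seed=cfg.seed)
    return records


def apply_sparsity(
    records: PhenotypeRecords, sparsity: float, seed: int = 0
) -> PhenotypeRecords:
    """Delete a uniform random fraction of (line, env) cells.

    Keeps every line in at least one environment and every environment
    with at least two lines, as a real incomplete trial would.
    """
    if not (0 <= sparsity < 1):
        raise ValueError("sparsity must lie in [0, 1)")
    if sparsity == 0:
        return records
    df = records.df
    n = len(df)
    n_drop = int(round(sparsity * n))
    if n_drop == 0:
        return records
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    lines = df["line"].to_numpy()
    envs = df["env"].to_numpy()
    line_counts = df["line"].value_counts().to_dict()
    env_counts = df["env"].value_counts().to_dict()

    order = rng.permutation(n)
    keep = np.ones(n, dtype=bool)
    dropped = 0
    for idx in order:
        if dropped == n_drop:
            break
        l, e = lines[idx], envs[idx]
        if line_counts[l] <= 1 or env_counts[e] <= 2:
            continue
        keep[idx] = False
        line_counts[l] -= 1
        env_counts[e] -= 1
        dropped += 1
    if dropped < n_drop:
        raise ValueError(
            f"sparsity {sparsity} infeasible: could only delete {dropped} of "
            f"{n_drop} cells without emptying a line or environment"
        )
    return PhenotypeRecords(df[keep].reset_index(drop=True), dict(records.scaling))
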