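"""Cross-validation schemes and prediction-accuracy summaries.

Three random partition schemes mirror how multi-environment hybrid trials
are evaluated:

* ``within_env`` — lines of a single environment split into folds (the
  scheme used with the single-environment SM model).
* ``CV1`` — whole lines held out: a test line's records are masked in every
  environment, mimicking prediction of newly developed, never-phenotyped
  lines.
* ``CV2`` — individual (line, environment) cells held out, so a test line
  typically remains observed in other environments: the sparse-testing /
  incomplete-trial setting.

Partitions are organized as ``replicates`` independent fold splits of
``folds`` folds each (default 10 x 5 = 50 partitions, 80% training).  For
each partition every model is refitted from training data only (including
training-only phenotype standardization) and accuracy is the Pearson
correlation between predictions and observed phenotypes in the test set,
computed within environment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    ModelSpec,
    PhenotypeRecords,
    assemble_model,
    build_design_matrices,
    fixed_effects_design,
    standardize_phenotypes,
)
from .gibbs import eigendecompose_component, gibbs_fit
from .kernels import KernelMatrix, gaussian_kernel, linear_kernel
from .markers import MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "AccuracyReport",
    "make_cv_plan",
    "run_cv_experiment",
    "pearson_within_env",
    "percent_change",
    "broad_sense_heritability",
]

SCHEMES = ("within_env", "CV1", "CV2")


@dataclass
class CVPlan:
    """A set of record-level training/test masks.

    ``partitions`` holds one boolean test-mask per (replicate, fold), in
    replicate-major order; True marks a test record.  Within a replicate
    the test sets are disjoint and cover the partitioned units exactly
    once.
    """

    scheme: str
    partitions: list[np.ndarray]
    replicates: int
    folds: int
    seed: int

    def __len__(self) -> int:
        return len(self.partitions)


def _fold_assignment(n_units: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random assignment of units to folds, sizes as equal as possible."""
    base = np.arange(n_units) % folds
    return rng.permutation(base)


def make_cv_plan(
    records: PhenotypeRecords,
    scheme: str,
    folds: int = 5,
    replicates: int = 10,
    seed: int = 0,
) -> CVPlan:
    """Generate random TRN/TST partitions for one scheme.

    With 5 folds each partition holds ~80% of units for training; a full
    replicate's folds cover every unit exactly once.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    df = records.df
    n = len(df)
    envs = df["env"].to_numpy()
    lines = df["line"].to_numpy()
    if scheme == "within_env" and len(set(envs)) != 1:
        raise ValueError("within_env requires records from a single environment")

    if scheme in ("within_env", "CV1"):
        units = sorted(set(lines))
        unit_of_record = lines
    else:  # CV2: the unit is the (line, env) record itself
        units = list(range(n))
        unit_of_record = np.arange(n)
    if len(units) < folds:
        raise ValueError(f"{len(units)} units but {folds} folds requested")

    rng = np.random.default_rng(seed)
    unit_index = {u: i for i, u in enumerate(units)}
    rec_unit = np.fromiter((unit_index[u] for u in unit_of_record), dtype=int, count=n)

    partitions: list[np.ndarray] = []
    for _ in range(replicates):
        assign = _fold_assignment(len(units), folds, rng)
        for f in range(folds):
            tst = assign[rec_unit] == f
            for env in set(envs):
                if not np.any(~tst & (envs == env)):
                    raise ValueError(
                        f"fold leaves environment {env!r} with no training records; "
                        "reduce folds or sparsity"
                    )
            partitions.append(tst)
    return CVPlan(scheme, partitions, replicates, folds, seed)


def pearson_within_env(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN when undefined.

    Undefined means fewer than 3 pairs or zero variance in either vector —
    reported as NaN (flagged), never coerced to 0.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation vectors differ in length")
    if pred.size < 3:
        return float("nan")
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        return float("nan")
    return float(stats.pearsonr(pred, obs).statistic)


def percent_change(acc_base: float, acc_new: float) -> int:
    """Percent change 100*(new - base)/base, rounded half away from zero.

    This is the rounding that reproduces published accuracy-gain tables
    from their two-decimal correlations (0.64 -> 0.73 gives 14.06 -> 14;
    0.33 -> 0.56 gives 69.7 -> 70).
    """
    if acc_base == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    x = 100.0 * (acc_new - acc_base) / acc_base
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def broad_sense_heritability(
    sigma_h2: float, sigma_hs2: float, sigma_e2: float, s: int, r: int
) -> float:
    """Plot-mean broad-sense heritability (repeatability).

    H2 = sigma_h2 / [sigma_h2 + sigma_hs2/s + sigma_e2/(s*r)] for hybrid
    variance sigma_h2, hybrid-by-location variance sigma_hs2 and residual
    sigma_e2, over s environments with r replicates each.
    """
    if min(sigma_h2, sigma_hs2, sigma_e2) < 0:
        raise ValueError("variances must be non-negative")
    if s < 1 or r < 1:
        raise ValueError("s and r must be >= 1")
    denom = sigma_h2 + sigma_hs2 / s + sigma_e2 / (s * r)
    if denom == 0:
        raise ZeroDivisionError("all variance components are zero")
    return sigma_h2 / denom


@dataclass
class AccuracyReport:
    """Per-partition within-environment prediction accuracies.

    ``df`` has one row per (model, method, env, partition) with the Pearson
    correlation ``r`` (NaN when undefined).  ``summary()`` aggregates to
    the mean and SD over partitions, excluding undefined correlations and
    reporting how many were excluded.
    """

    df: pd.DataFrame
    n_undefined: int = 0

    def summary(self) -> pd.DataFrame:
        g = self.df.groupby(["model", "method", "env"], sort=True)["r"]
        out = g.agg(
            mean=lambda x: float(np.nanmean(x)) if np.isfinite(x).any() else np.nan,
            sd=lambda x: float(np.nanstd(x, ddof=1)) if np.isfinite(x).sum() > 1 else np.nan,
            n_partitions=lambda x: int(np.isfinite(x).sum()),
        ).reset_index()
        return out

    def mean_accuracy(self, model: str, method: str, env: str | None = None) -> float:
        s = self.summary()
        sel = (s["model"] == model) & (s["method"] == method)
        if env is not None:
            sel &= s["env"] == env
        vals = s.loc[sel, "mean"].to_numpy()
        if vals.size == 0:
            raise KeyError(f"no accuracy rows for {model}-{method} env={env}")
        return float(np.nanmean(vals))

    def percent_change_table(self, base_method: str = "GB", new_method: str = "GK") -> pd.DataFrame:
        """Accuracy-gain table between kernel methods per model and environment."""
        s = self.summary()
        rows = []
        for (model, env), grp in s.groupby(["model", "env"]):
            try:
                b = float(grp.loc[grp["method"] == base_method, "mean"].iloc[0])
                nw = float(grp.loc[grp["method"] == new_method, "mean"].iloc[0])
            except IndexError:
                continue
            pct = percent_change(round(b, 2), round(nw, 2)) if b != 0 else np.nan
            rows.append(
                {"model": model, "env": env, base_method: b, new_method: nw,
                 "pct_change": pct}
            )
        return pd.DataFrame(rows)


def _kernels_for(markers_or_kernels, methods: set[str]) -> dict[str, KernelMatrix]:
    if isinstance(markers_or_kernels, MarkerMatrix):
        out = {}
        if "GB" in methods:
            out["GB"] = linear_kernel(markers_or_kernels)
        if "GK" in methods:
            out["GK"] = gaussian_kernel(markers_or_kernels)
        return out
    kernels = dict(markers_or_kernels)
    missing = methods - set(kernels)
    if missing:
        raise KeyError(f"no kernel supplied for method(s): {sorted(missing)}")
    return kernels


def run_cv_experiment(
    records: PhenotypeRecords,
    markers_or_kernels,
    specs: list[ModelSpec],
    plan: CVPlan,
    predictor=None,
) -> AccuracyReport:
    """Run every model-method spec over every partition of a CV plan.

    For each partition, phenotypes are standardized from training records
    only, the model is fitted with test records masked, and test records
    are predicted from the posterior mean linear predictor.  Accuracies are
    within-environment Pearson correlations of predictions vs observed
    phenotypes.

    ``markers_or_kernels`` is either a standardized MarkerMatrix (kernels
    are built as needed) or a mapping {"GB": KernelMatrix, "GK": ...}.

    ``predictor`` (testing hook) overrides the model fit: a callable
    ``(records, tst_mask, spec) -> predictions`` over all records.
    """
    df = records.df
    if df["trait"].nunique() > 1:
        raise ValueError("run one trait at a time; filter records first")
    for spec in specs:
        if spec.model == "SM" and plan.scheme != "within_env":
            raise ValueError("SM is only compatible with the within_env scheme")
        if spec.model != "SM" and plan.scheme == "within_env" and df["env"].nunique() > 1:
            raise ValueError("within_env plan requires single-environment records")

    design = build_design_matrices(records)
    envs = df["env"].to_numpy()
    obs_values = df["value"].to_numpy()

    prepared = {}
    if predictor is None:
        kernels = _kernels_for(markers_or_kernels, {s.method for s in specs})
        for spec in specs:
            key = (spec.model, spec.method)
            if key in prepared:
                continue
            comps = assemble_model(spec.model, design, kernels[spec.method])
            eigs = [eigendecompose_component(c) for c in comps]
            W = fixed_effects_design(design, spec.model)
            prepared[key] = (eigs, W)

    rows = []
    n_undefined = 0
    for pidx, tst in enumerate(plan.partitions):
        trn = ~tst
        std = standardize_phenotypes(records, reference_mask=trn)
        y = std.df["value"].to_numpy()
        for spec in specs:
            if predictor is not None:
                pred = np.asarray(predictor(records, tst, spec), dtype=float)
            else:
                eigs, W = prepared[(spec.model, spec.method)]
                # distinct, reproducible chain seed per partition
                part_spec = replace(spec, seed=(spec.seed * 10_007 + pidx) % (2**31 - 1))
                post = gibbs_fit(y, trn, W, eigs, part_spec)
                pred = post.fitted_values
            for env in sorted(set(envs)):
                sel = tst & (envs == env)
                if sel.sum() < 3:
                    n_undefined += 1
                    r = float("nan")
                else:
                    r = pearson_within_env(pred[sel], obs_values[sel])
                    if not np.isfinite(r):
                        n_undefined += 1
                rows.append(
                    {"model": spec.model, "method": spec.method, "env": env,
                     "partition": pidx, "r": r}
                )
    if n_undefined:
        logger.info("%d undefined correlations excluded from means", n_undefined)
    return AccuracyReport(pd.DataFrame(rows), n_undefined=n_undefined)
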