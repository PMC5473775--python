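"""High-level fitting workflow tying assembly and inference together."""

from __future__ import annotations

import numpy as np

from .design import (
    ModelSpec,
    PhenotypeRecords,
    assemble_model,
    build_design_matrices,
    fixed_effects_design,
    standardize_phenotypes,
)
from .gibbs import PosteriorSummary, eigendecompose_component, gibbs_fit
from .kernels import KernelMatrix, gaussian_kernel, linear_kernel
from .markers import MarkerMatrix

__all__ = ["fit_model", "kernel_for_method"]


def kernel_for_method(markers: MarkerMatrix, method: str, h: float = 1.0) -> KernelMatrix:
    """Build the kernel for one method tag from standardized markers."""
    if method == "GB":
        return linear_kernel(markers)
    if method == "GK":
        return gaussian_kernel(markers, h=h)
    raise ValueError(f"unknown kernel method {method!r}")


def fit_model(
    records: PhenotypeRecords,
    kernel: KernelMatrix,
    spec: ModelSpec,
    observed: np.ndarray | None = None,
    standardize: bool = True,
    fix_variances: dict[str, float] | None = None,
) -> PosteriorSummary:
    """Standardize phenotypes, assemble one model-method, and run the Gibbs fit.

    ``observed`` masks records to be predicted (default: all observed).
    When a mask is given, standardization constants come from the observed
    (training) records only.
    """
    df = records.df
    if df["trait"].nunique() > 1:
        raise ValueError("fit one trait at a time; use records.for_trait()")
    n = len(df)
    if observed is None:
        observed = np.ones(n, dtype=bool)
    observed = np.asarray(observed, dtype=bool)
    if standardize:
        records = standardize_phenotypes(records, reference_mask=observed)
    design = build_design_matrices(records)
    components = assemble_model(spec.model, design, kernel)
    eigs = [eigendecompose_component(c) for c in components]
    W = fixed_effects_design(design, spec.model)
    y = records.df["value"].to_numpy()
    return gibbs_fit(y, observed, W, eigs, spec, fix_variances=fix_variances)
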