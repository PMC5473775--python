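"""Genomic similarity kernels: linear (GBLUP) and Gaussian (RKHS).

Two kernel methods map a standardized marker matrix X (n lines x p markers)
to an n x n symmetric PSD similarity matrix K used as the genetic covariance
in the prediction models:

* GB — the linear kernel K = XX'/p, the genomic relationship matrix of
  GBLUP.  Captures additive marker effects.
* GK — the Gaussian kernel K_ii' = exp(-h * d²_ii' / median(d²)), with
  d²_ii' the squared Euclidean distance between marker rows, bandwidth
  h = 1 by default, and the median of the pairwise squared distances as a
  scaling factor.  Its implicit feature expansion includes marker products,
  so it can pick up epistatic (non-additive) signal the linear kernel
  misses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .markers import MarkerMatrix

__all__ = ["KernelMatrix", "linear_kernel", "gaussian_kernel", "subset_kernel"]

SYM_TOL = 1e-10
PSD_REL_TOL = 1e-8


@dataclass
class KernelMatrix:
    """Labeled symmetric PSD similarity matrix over a set of lines."""

    values: np.ndarray
    line_ids: list[str]
    method_tag: str = "GB"
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = [str(i) for i in self.line_ids]
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel is {self.values.shape} but there are {n} line ids"
            )
        if len(set(self.line_ids)) != n:
            raise ValueError("line ids are not unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        """Check symmetry and positive semi-definiteness (up to tolerance).

        Eigenvalues slightly negative from round-off (>= -1e-8 * lambda_max)
        are accepted; anything below raises.
        """
        K = self.values
        asym = np.abs(K - K.T).max(initial=0.0)
        if asym > SYM_TOL:
            raise ValueError(f"kernel asymmetric: max |K - K'| = {asym:.3g}")
        w = np.linalg.eigvalsh(K)
        lam_max = w[-1]
        if lam_max <= 0:
            raise ValueError("kernel has no positive eigenvalue")
        if w[0] < -PSD_REL_TOL * lam_max:
            raise ValueError(
                f"kernel not PSD: min eigenvalue {w[0]:.3g} vs max {lam_max:.3g}"
            )
        if self.method_tag == "GK":
            if not np.all(np.diag(K) == 1.0):
                raise ValueError("Gaussian kernel diagonal must be exactly 1")


def linear_kernel(X: MarkerMatrix) -> KernelMatrix:
    """Linear GBLUP kernel K = XX'/p from standardized markers.

    Division by the marker count p puts the average diagonal near 1, so the
    variance component multiplying K is on the phenotypic-variance scale.
    """
    if not X.standardized:
        raise ValueError(
            "linear kernel requires standardized markers (variance scaling "
            "of K = XX'/p assumes unit-variance columns)"
        )
    Z = X.dosages
    p = Z.shape[1]
    if p < 1:
        raise ValueError("no markers")
    K = Z @ Z.T / p
    K = (K + K.T) / 2.0
    return KernelMatrix(K, X.line_ids, method_tag="GB")


def gaussian_kernel(X: MarkerMatrix, h: float = 1.0) -> KernelMatrix:
    """Gaussian kernel exp(-h d²/median(d²)) from standardized markers.

    The median is taken over the off-diagonal pairwise squared Euclidean
    distances (i < i'); including the zero diagonal would deflate it.  With
    median scaling, h = 1 places half the off-diagonal similarities above
    exp(-1) and half below.
    """
    if not X.standardized:
        raise ValueError("Gaussian kernel requires standardized markers")
    if h <= 0:
        raise ValueError(f"bandwidth h must be positive, got {h}")
    Z = X.dosages
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 lines")
    d2 = pdist(Z, metric="sqeuclidean")
    med = float(np.median(d2))
    if med == 0.0:
        raise ValueError(
            "median pairwise squared distance is 0 (all lines identical); "
            "Gaussian kernel is undefined"
        )
    K = squareform(np.exp(-h * d2 / med))
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, X.line_ids, method_tag="GK", bandwidth=h)


def subset_kernel(K: KernelMatrix, ids: list[str]) -> KernelMatrix:
    """Principal submatrix of K for ``ids`` in the order given.

    Used to build the per-environment kernels K_j for the lines observed in
    environment j.
    """
    index = {lid: i for i, lid in enumerate(K.line_ids)}
    unknown = [i for i in ids if i not in index]
    if unknown:
        raise KeyError(f"ids not present in kernel: {unknown}")
    idx = np.array([index[i] for i in ids], dtype=int)
    return KernelMatrix(
        K.values[np.ix_(idx, idx)], list(ids), method_tag=K.method_tag,
        bandwidth=K.bandwidth,
    )


def clip_negative_eigenvalues(K: np.ndarray, rel_tol: float = PSD_REL_TOL) -> np.ndarray:
    """Project a nearly-PSD symmetric matrix onto the PSD cone.

    Eigenvalues in [-rel_tol * lambda_max, 0) are round-off and clipped to 0
    with a warning; more negative values raise.
    """
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    lam_max = w[-1]
    if lam_max <= 0:
        raise ValueError("matrix has no positive eigenvalue")
    if w[0] < -rel_tol * lam_max:
        raise ValueError(f"matrix not PSD: min eigenvalue {w[0]:.3g}")
    if w[0] < 0:
        warnings.warn(
            f"clipping {int((w < 0).sum())} slightly negative eigenvalue(s) to 0",
            UserWarning,
            stacklevel=2,
        )
        w = np.clip(w, 0.0, None)
        K = (V * w) @ V.T
        K = (K + K.T) / 2.0
    return K
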