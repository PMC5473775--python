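"""Marker matrix handling: QC, imputation, hybrid construction, standardization.

The marker matrix X holds biallelic SNP dosages (0/1/2 counts of the minor
allele) for a panel of inbred lines or their F1 hybrids.  Hybrid dosages are
the mean of the two inbred parents' dosages (the expected F1 dosage), so
half-integers appear after hybrid construction.  Downstream kernels require
the column-standardized form of X (each marker centered to mean 0, sample
SD 1), which is what ``standardize_markers`` produces.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "CrossTable",
    "QCReport",
    "qc_filter_markers",
    "impute_missing",
    "make_hybrid_genotypes",
    "standardize_markers",
]


@dataclass
class MarkerMatrix:
    """Lines-by-markers dosage matrix.

    Parameters
    ----------
    dosages
        ``(n_lines, n_markers)`` float array.  Raw entries are allele counts
        in ``{0, 1, 2}`` (hybrids may carry half-integers in ``[0, 2]``);
        missing values are ``NaN``.  Standardized entries are real-valued.
    line_ids, marker_ids
        Unique ordered identifiers for rows and columns.
    standardized
        If True, every column has mean 0 and sample SD 1 and no entry is
        missing.
    """

    dosages: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.line_ids = [str(i) for i in self.line_ids]
        self.marker_ids = [str(i) for i in self.marker_ids]
        n, p = self.dosages.shape
        if n != len(self.line_ids):
            raise ValueError(f"{n} rows but {len(self.line_ids)} line ids")
        if p != len(self.marker_ids):
            raise ValueError(f"{p} columns but {len(self.marker_ids)} marker ids")
        if len(set(self.line_ids)) != n:
            raise ValueError("line ids are not unique")
        if len(set(self.marker_ids)) != p:
            raise ValueError("marker ids are not unique")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def validate(self, atol: float = 1e-8) -> None:
        """Check the invariants of the current form; raise on violation."""
        X = self.dosages
        if self.standardized:
            if np.isnan(X).any():
                raise ValueError("standardized matrix contains missing entries")
            mu = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            if np.abs(mu).max(initial=0.0) > atol:
                raise ValueError("standardized columns are not mean-zero")
            if np.abs(sd - 1.0).max(initial=0.0) > atol:
                raise ValueError("standardized columns are not unit-SD")
        else:
            finite = X[~np.isnan(X)]
            if finite.size and (finite.min() < 0 or finite.max() > 2):
                raise ValueError("raw dosages outside [0, 2]")


@dataclass
class CrossTable:
    """Hybrid pedigree: one row per F1 cross (hybrid, parent1, parent2)."""

    hybrid_ids: list[str]
    parent1_ids: list[str]
    parent2_ids: list[str]

    def __post_init__(self) -> None:
        self.hybrid_ids = [str(i) for i in self.hybrid_ids]
        self.parent1_ids = [str(i) for i in self.parent1_ids]
        self.parent2_ids = [str(i) for i in self.parent2_ids]
        if not (len(self.hybrid_ids) == len(self.parent1_ids) == len(self.parent2_ids)):
            raise ValueError("cross table columns have unequal lengths")
        if len(set(self.hybrid_ids)) != len(self.hybrid_ids):
            raise ValueError("hybrid ids are not unique")

    def __len__(self) -> int:
        return len(self.hybrid_ids)


@dataclass
class QCReport:
    """Counts of markers removed by each QC rule."""

    n_input: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_retained: int


def qc_filter_markers(
    markers: MarkerMatrix,
    maf_threshold: float = 0.05,
    call_rate_threshold: float = 0.95,
    return_report: bool = False,
):
    """Filter markers on call rate and minor allele frequency.

    A marker is retained when its call rate (fraction of non-missing lines)
    is at least ``call_rate_threshold`` AND its MAF is strictly greater than
    ``maf_threshold``.  MAF is ``min(f, 1 - f)`` with ``f`` the mean dosage
    among non-missing lines divided by 2.  Column order is preserved.
    """
    if markers.standardized:
        raise ValueError("QC operates on raw dosages, not standardized markers")
    if not (0 <= maf_threshold <= 1 and 0 <= call_rate_threshold <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    X = markers.dosages
    n = X.shape[0]
    observed = ~np.isnan(X)
    call_rate = observed.sum(axis=0) / n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        f = np.nanmean(X, axis=0) / 2.0
    f = np.where(np.isnan(f), 0.0, f)
    maf = np.minimum(f, 1.0 - f)

    pass_cr = call_rate >= call_rate_threshold
    pass_maf = maf > maf_threshold
    keep = pass_cr & pass_maf
    report = QCReport(
        n_input=X.shape[1],
        n_removed_call_rate=int((~pass_cr).sum()),
        n_removed_maf=int((pass_cr & ~pass_maf).sum()),
        n_retained=int(keep.sum()),
    )
    logger.info(
        "QC: %d markers in, %d removed by call rate < %.3g, %d by MAF <= %.3g, %d retained",
        report.n_input, report.n_removed_call_rate, report.n_removed_maf,
        maf_threshold, report.n_retained,
    )
    if report.n_retained == 0:
        raise ValueError(
            f"all {X.shape[1]} markers removed by QC "
            f"(maf_threshold={maf_threshold}, call_rate_threshold={call_rate_threshold})"
        )
    out = MarkerMatrix(
        X[:, keep], markers.line_ids, [m for m, k in zip(markers.marker_ids, keep) if k]
    )
    return (out, report) if return_report else out


def impute_missing(markers: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing dosage by its column mean over non-missing lines.

    Column-mean imputation is deterministic and accurate at the high call
    rates the QC filter enforces.  A column that is entirely missing cannot
    be imputed and raises (it should have been removed by the call-rate
    filter).
    """
    X = markers.dosages.copy()
    missing = np.isnan(X)
    if not missing.any():
        return markers
    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = [m for m, a in zip(markers.marker_ids, all_missing) if a]
        raise ValueError(f"columns entirely missing, cannot impute: {bad}")
    col_mean = np.nanmean(X, axis=0)
    X[missing] = np.broadcast_to(col_mean, X.shape)[missing]
    return MarkerMatrix(X, markers.line_ids, markers.marker_ids)


def make_hybrid_genotypes(parents: MarkerMatrix, crosses: CrossTable) -> MarkerMatrix:
    """Build expected F1 hybrid dosages as the mean of the two parents.

    For inbred (homozygous) parents the F1 is heterozygous wherever the
    parents differ, so its expected minor-allele count at each marker is the
    arithmetic mean of the parental dosages.
    """
    if parents.has_missing():
        raise ValueError("parent matrix has missing entries; impute first")
    index = {lid: i for i, lid in enumerate(parents.line_ids)}
    unknown = sorted(
        {p for p in crosses.parent1_ids + crosses.parent2_ids if p not in index}
    )
    if unknown:
        raise KeyError(f"crosses reference unknown parent ids: {unknown}")
    i1 = np.fromiter((index[p] for p in crosses.parent1_ids), dtype=int)
    i2 = np.fromiter((index[p] for p in crosses.parent2_ids), dtype=int)
    hybrid = (parents.dosages[i1] + parents.dosages[i2]) / 2.0
    return MarkerMatrix(hybrid, crosses.hybrid_ids, parents.marker_ids)


def standardize_markers(markers: MarkerMatrix) -> MarkerMatrix:
    """Center each marker to mean 0 and scale to sample SD 1 (ddof=1).

    Zero-variance (monomorphic) columns carry no information and are dropped
    with a warning.  The result is the matrix X used by both kernel methods.
    """
    if markers.has_missing():
        raise ValueError("cannot standardize with missing entries; impute first")
    X = markers.dosages
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 lines")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [m for m, k in zip(markers.marker_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance marker(s): {dropped[:10]}"
            + ("..." if len(dropped) > 10 else ""),
            UserWarning,
            stacklevel=2,
        )
        if not keep.any():
            raise ValueError("all markers have zero variance")
    Xk = X[:, keep]
    Z = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0, ddof=1)
    out = MarkerMatrix(
        Z,
        markers.line_ids,
        [m for m, k in zip(markers.marker_ids, keep) if k],
        standardized=True,
    )
    return out
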