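"""Quality control: replicate outlier detection and negative-control calibration.

Outlier analysis asks whether the well/replicate curves measuring the
same (strain, phenotype, plate) agree with each other.  Curves in a group
are resampled to equal length, and for each member the *median* of its
pairwise Pearson correlations with every other member is computed; a
record whose median correlation falls below a user-chosen threshold is
flagged as aberrant.  The median-per-member reading makes a single bad
replicate stand out instead of dragging the whole group down.

Negative-control analysis estimates the assay's inherent noise band:
empirical quantile curves across all negative-control wells, per time
point, with the per-level maxima offered as candidate signal/noise
thresholds.  No boundary is chosen automatically — the quantiles guide
the user's choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .curves import CommonGrid, common_grid, resample
from .model import RecordSet

__all__ = [
    "OutlierReportRow",
    "QuantileCurves",
    "outlier_analysis",
    "negative_controls_analysis",
    "DEFAULT_OUTLIER_THRESHOLD",
    "DEFAULT_QUANTILE_LEVELS",
]

log = logging.getLogger(__name__)

DEFAULT_OUTLIER_THRESHOLD = 0.5
DEFAULT_QUANTILE_LEVELS = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass(frozen=True)
class OutlierReportRow:
    """Per-record outlier statistic within its (strain, phenotype, plate) group."""

    strain: str
    phenotype: str
    plate: str
    well: str
    replicate: int
    median_correlation: float  # NaN when degenerate
    group_median: float
    degenerate: bool
    flagged: bool


def _pairwise_pearson(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix with NaN rows for zero-variance members."""
    sd = mat.std(axis=1, ddof=1)
    ok = sd > 0
    corr = np.full((mat.shape[0], mat.shape[0]), np.nan)
    if ok.sum() >= 2:
        corr_ok = np.corrcoef(mat[ok])
        corr[np.ix_(ok, ok)] = corr_ok
    elif ok.sum() == 1:
        i = int(np.nonzero(ok)[0][0])
        corr[i, i] = 1.0
    return corr, ok


def outlier_analysis(
    rs: RecordSet, threshold: float = DEFAULT_OUTLIER_THRESHOLD
) -> list[OutlierReportRow]:
    """Median-correlation outlier screen over replicate groups.

    Records are grouped by (strain, phenotype, plate); all well×replicate
    curves of a group are resampled to the group's common grid, and each
    member receives the median of its Pearson correlations to every other
    member.  Members below ``threshold`` are flagged.  Groups of size 1
    are skipped with a warning (no partner to correlate against), and
    zero-variance members — a flat replicate among growing ones — are
    reported as degenerate and flagged.
    """
    if len(rs) == 0:
        raise ValueError("outlier_analysis requires a non-empty RecordSet")
    if not -1.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [-1, 1]")

    groups: dict[tuple, list] = {}
    for rec in rs:
        groups.setdefault((rec.strain, rec.phenotype, rec.plate), []).append(rec)

    rows: list[OutlierReportRow] = []
    for (strain, phenotype, plate), members in groups.items():
        if len(members) < 2:
            log.warning(
                "group (%s, %s, %s) has a single member; skipped",
                strain,
                phenotype,
                plate,
            )
            continue
        grid = common_grid([m.curve for m in members])
        mat = np.vstack([resample(m.curve, grid).values for m in members])
        corr, ok = _pairwise_pearson(mat)
        medians = np.full(len(members), np.nan)
        for i in range(len(members)):
            others = np.delete(corr[i], i)
            valid = others[~np.isnan(others)]
            if ok[i] and valid.size:
                medians[i] = np.median(valid)
        finite = medians[~np.isnan(medians)]
        group_median = float(np.median(finite)) if finite.size else float("nan")
        for i, member in enumerate(members):
            degenerate = not ok[i] or np.isnan(medians[i])
            flagged = degenerate or bool(medians[i] < threshold)
            rows.append(
                OutlierReportRow(
                    strain=strain,
                    phenotype=phenotype,
                    plate=plate,
                    well=member.well,
                    replicate=member.replicate,
                    median_correlation=float(medians[i]),
                    group_median=group_median,
                    degenerate=degenerate,
                    flagged=flagged,
                )
            )
    return rows


def outlier_report_rows(rows: Sequence[OutlierReportRow]) -> tuple[list, list[str]]:
    """Flatten outlier rows into a (rows, columns) report table."""
    columns = [
        "strain",
        "phenotype",
        "plate",
        "well",
        "replicate",
        "median_correlation",
        "group_median",
        "degenerate",
        "flagged",
    ]
    table = [
        [
            r.strain,
            r.phenotype,
            r.plate,
            r.well,
            r.replicate,
            r.median_correlation,
            r.group_median,
            r.degenerate,
            r.flagged,
        ]
        for r in rows
    ]
    return table, columns


@dataclass(frozen=True)
class QuantileCurves:
    """Per-time-point empirical quantiles of a set of control curves."""

    grid: CommonGrid
    levels: tuple[float, ...]
    curves: np.ndarray  # (n_levels, n_points)
    candidate_thresholds: np.ndarray  # (n_levels,) max over time per level

    def __post_init__(self) -> None:
        if self.curves.shape != (len(self.levels), len(self.grid)):
            raise ValueError("quantile curve matrix shape mismatch")
        # quantiles must be non-decreasing in level at every time point
        if np.any(np.diff(self.curves, axis=0) < -1e-12):
            raise ValueError("quantile curves not monotone in level")


def _quantile_curves(
    mat: np.ndarray, grid: CommonGrid, levels: tuple[float, ...]
) -> QuantileCurves:
    q = np.quantile(mat, levels, axis=0, method="linear")
    return QuantileCurves(
        grid=grid,
        levels=levels,
        curves=q,
        candidate_thresholds=q.max(axis=1),
    )


def negative_controls_analysis(
    neg: RecordSet,
    non_neg: Optional[RecordSet] = None,
    levels: Sequence[float] = DEFAULT_QUANTILE_LEVELS,
) -> tuple[QuantileCurves, Optional[QuantileCurves]]:
    """Quantile curves of negative controls, with optional overlay.

    All control curves are resampled to a shared grid (the joint grid of
    negatives and, if given, non-negatives, so the overlay is directly
    comparable); for each requested level the empirical quantile across
    curves is computed at every time point.  The per-level maximum over
    time is reported as a candidate signal/noise threshold.
    """
    if len(neg) == 0:
        raise ValueError("negative-control set must be non-empty")
    levels = tuple(sorted(float(l) for l in levels))
    if not levels or any(not 0.0 < l < 1.0 for l in levels):
        raise ValueError(f"quantile levels must lie in (0, 1): {levels}")
    if len(neg) == 1:
        log.warning("single negative control; all quantile curves coincide")

    all_curves = [r.curve for r in neg]
    if non_neg is not None and len(non_neg):
        all_curves += [r.curve for r in non_neg]
    grid = common_grid(all_curves)

    neg_mat = np.vstack([resample(r.curve, grid).values for r in neg])
    neg_q = _quantile_curves(neg_mat, grid, levels)

    overlay = None
    if non_neg is not None and len(non_neg):
        nn_mat = np.vstack([resample(r.curve, grid).values for r in non_neg])
        overlay = _quantile_curves(nn_mat, grid, levels)
    return neg_q, overlay
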