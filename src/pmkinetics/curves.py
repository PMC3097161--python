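"""Curve-level numerics shared by all analysis modules.

Kinetic curves from different runs rarely share an identical time grid
(runs are stopped at different times, occasional cycles are dropped), so
every multi-curve statistic first resamples its inputs onto a common,
evenly spaced grid spanning the *intersection* of the observed time
ranges — interpolation never extrapolates beyond what was measured.
Interpolation is linear: the minimal monotonicity-preserving choice for
15-minute-sampled growth data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import KineticCurve, WellRecord, RecordSet

__all__ = [
    "CommonGrid",
    "common_grid",
    "resample",
    "average_replicates",
    "zscore",
    "zscore_scale",
    "curve_summary",
    "SUMMARY_METHODS",
]

log = logging.getLogger(__name__)

_SPACING_RTOL = 1e-9


@dataclass(frozen=True)
class CommonGrid:
    """Evenly spaced time grid (minutes) shared by a set of curves."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2:
            raise ValueError("a grid needs at least 2 points")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("grid times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=_SPACING_RTOL, atol=0):
            raise ValueError("grid spacing must be constant")
        t.setflags(write=False)
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


def common_grid(curves: list[KineticCurve]) -> CommonGrid:
    """Joint grid for a set of curves.

    Spans ``[max_i min(times_i), min_i max(times_i)]`` with as many evenly
    spaced points as the longest member — the intersection of time ranges
    at maximal resolution.  Raises if any two curves do not overlap in
    time, naming the disjoint pair.
    """
    if not curves:
        raise ValueError("common_grid requires at least one curve")
    starts = np.array([c.times[0] for c in curves])
    stops = np.array([c.times[-1] for c in curves])
    t_lo = float(starts.max())
    t_hi = float(stops.min())
    if t_lo >= t_hi:
        i = int(starts.argmax())
        j = int(stops.argmin())
        raise ValueError(
            f"curves have disjoint time ranges: curve {i} starts at "
            f"{starts[i]:g} min but curve {j} ends at {stops[j]:g} min"
        )
    n = max(len(c) for c in curves)
    return CommonGrid(np.linspace(t_lo, t_hi, n))


def resample(curve: KineticCurve, grid: CommonGrid) -> KineticCurve:
    """Linearly interpolate a curve onto a grid inside its time range.

    Grid points that coincide with original observation times reproduce
    the original values exactly; extrapolation is refused.
    """
    lo, hi = curve.span
    glo, ghi = grid.span
    if glo < lo or ghi > hi:
        raise ValueError(
            f"grid [{glo:g}, {ghi:g}] extends outside curve range [{lo:g}, {hi:g}]"
        )
    vals = np.interp(grid.times, curve.times, curve.values)
    return KineticCurve(grid.times, vals, require_nonnegative=False)


def average_replicates(group: list[WellRecord]) -> WellRecord:
    """Pointwise mean of a replicate group on its common grid.

    Members must share a group key (strain, phenotype, plate, well,
    temperature); the result inherits that metadata and is marked as
    averaged (replicate index 0).
    """
    if not group:
        raise ValueError("cannot average an empty replicate group")
    keys = {r.group_key for r in group}
    if len(keys) > 1:
        raise ValueError(f"mixed replicate-group keys: {sorted(keys)}")
    grid = common_grid([r.curve for r in group])
    stack = np.vstack([resample(r.curve, grid).values for r in group])
    mean = stack.mean(axis=0)
    first = group[0]
    return WellRecord(
        project=first.project,
        species=first.species,
        strain=first.strain,
        phenotype=first.phenotype,
        plate=first.plate,
        well=first.well,
        replicate=0,
        temperature=first.temperature,
        curve=KineticCurve(grid.times, mean, require_nonnegative=False),
        averaged=True,
    )


def zscore(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Z-score a vector with sample (n-1) standard deviation.

    Returns ``(scaled, degenerate)``; a zero-variance vector maps to all
    zeros with ``degenerate=True``.
    """
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v), True
    return (v - v.mean()) / sd, False


def zscore_scale(curve: KineticCurve) -> KineticCurve:
    """Z-score a curve's values (mean 0, sample sd 1).

    A zero-variance curve maps to all zeros; the degeneracy is logged.
    """
    scaled, degenerate = zscore(curve.values)
    if degenerate:
        log.warning("z-scoring a zero-variance curve; returning all zeros")
    return KineticCurve(curve.times, scaled, require_nonnegative=False)


SUMMARY_METHODS = ("auc", "max", "endpoint")


def curve_summary(curve: KineticCurve, method: str = "auc") -> float:
    """Reduce a curve to a scalar growth summary.

    ``auc`` — trapezoid integral over time (intensity·minutes), the
    default because it integrates the whole kinetic response; ``max`` —
    peak intensity; ``endpoint`` — final reading.
    """
    if method == "auc":
        return float(np.trapezoid(curve.values, curve.times))
    if method == "max":
        return float(curve.values.max())
    if method == "endpoint":
        return float(curve.values[-1])
    raise ValueError(
        f"unknown summary method {method!r}; expected one of {SUMMARY_METHODS}"
    )


def resample_set(rs: RecordSet) -> tuple[CommonGrid, np.ndarray]:
    """Resample every record in a set onto the joint grid.

    Returns the grid and an ``(n_records, n_points)`` value matrix in
    record order.  Convenience used by the correlation, profile-search and
    clustering modules.
    """
    if len(rs) == 0:
        raise ValueError("empty record set")
    grid = common_grid([r.curve for r in rs])
    mat = np.vstack([resample(r.curve, grid).values for r in rs])
    return grid, mat
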