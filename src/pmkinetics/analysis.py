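"""Profile statistics: correlation matrix, profile search, k-means clustering.

All three operations work on curves resampled to a joint, equal-length
grid.  The correlation matrix gives pairwise Pearson r between every
selected record; profile search ranks records by similarity to a
user-drawn target profile; k-means groups z-scored kinetic shapes into
*k* clusters and reports each member's correlation to its centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .curves import CommonGrid, resample_set, zscore
from .model import RecordSet

__all__ = [
    "CorrelationMatrix",
    "ProfilePattern",
    "ProfileMatch",
    "ClusterResult",
    "correlation_matrix",
    "pearson_with_p",
    "profile_search",
    "kmeans_cluster",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric pairwise Pearson matrix over labelled records.

    ``labels`` are (strain, phenotype, plate, well, replicate) tuples in
    record order; rows/columns of degenerate (zero-variance) records are
    NaN and listed in ``degenerate``.
    """

    labels: tuple[tuple, ...]
    matrix: np.ndarray
    degenerate: tuple[int, ...] = ()

    def to_table(self) -> tuple[list, list[str]]:
        """Rows and columns for a labelled CSV report."""
        names = ["|".join(str(p) for p in lab) for lab in self.labels]
        columns = ["record", *names]
        rows = [
            [names[i], *[float(v) for v in self.matrix[i]]]
            for i in range(len(names))
        ]
        return rows, columns


def correlation_matrix(rs: RecordSet) -> CorrelationMatrix:
    """Pairwise Pearson correlation between all selected records.

    Curves are interpolated to equal length on the joint grid first.
    Zero-variance records yield NaN rows/columns (logged); diagonal
    entries of well-defined records are exactly 1.
    """
    if len(rs) < 2:
        raise ValueError("correlation_matrix requires at least 2 records")
    _, mat = resample_set(rs)
    sd = mat.std(axis=1, ddof=1)
    ok = sd > 0
    n = mat.shape[0]
    corr = np.full((n, n), np.nan)
    if ok.sum() >= 2:
        corr[np.ix_(ok, ok)] = np.corrcoef(mat[ok])
    for i in np.nonzero(ok)[0]:
        corr[i, i] = 1.0
    degenerate = tuple(int(i) for i in np.nonzero(~ok)[0])
    if degenerate:
        log.warning("%d zero-variance record(s) marked undefined", len(degenerate))
    return CorrelationMatrix(
        labels=tuple(r.label for r in rs), matrix=corr, degenerate=degenerate
    )


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the exact t-transform.

    ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom; a
    perfect |r| = 1 returns p = 0.  Constant inputs and n < 3 are errors
    (callers propagate them as degenerate matches).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = xv.size
    if n < 3:
        raise ValueError(f"need at least 3 points for a p-value, got {n}")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("correlation undefined for constant input")
    # direct covariance formula: exact ±1 in the perfect-correlation limit
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(1.0, p))


@dataclass(frozen=True)
class ProfilePattern:
    """User-specified target profile: piecewise-linear through anchor points."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("pattern times and values must match in length")
        if t.size < 2:
            raise ValueError("a profile pattern needs at least 2 anchor points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("pattern anchor times must be strictly increasing")
        t.setflags(write=False)
        v.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class ProfileMatch:
    """A record's similarity to the search pattern."""

    label: tuple  # (strain, phenotype, plate, well, replicate)
    r: float  # NaN when degenerate
    p: float
    rank: int


def profile_search(
    rs: RecordSet, pattern: ProfilePattern, *, scaled: bool = False
) -> list[ProfileMatch]:
    """Rank records by Pearson similarity to a target profile.

    The pattern and every record are resampled onto the record set's
    common grid restricted to the pattern's time range; records correlate
    on raw intensities by default (``scaled=True`` z-scores both sides
    first, which changes nothing for Pearson r but is offered for
    plotting symmetry).  Results are ordered by descending r; degenerate
    (constant) records carry NaN and sort last.
    """
    if len(rs) == 0:
        raise ValueError("profile_search requires a non-empty RecordSet")
    grid, mat = resample_set(rs)
    glo, ghi = grid.span
    plo, phi = pattern.span
    lo, hi = max(glo, plo), min(ghi, phi)
    if lo >= hi:
        raise ValueError(
            f"pattern range [{plo:g}, {phi:g}] does not overlap the records' "
            f"common range [{glo:g}, {ghi:g}]"
        )
    sub = CommonGrid(np.linspace(lo, hi, len(grid)))
    pat_vals = np.interp(sub.times, pattern.times, pattern.values)
    if pat_vals.std() == 0:
        raise ValueError("pattern is constant over the overlap; similarity undefined")

    scored = []
    for i, rec in enumerate(rs):
        rec_vals = np.interp(sub.times, grid.times, mat[i])
        if scaled:
            rec_vals, deg = zscore(rec_vals)
        else:
            deg = rec_vals.std() == 0
        if deg:
            log.warning("record %s is constant; similarity undefined", rec.label)
            scored.append((rec.label, float("nan"), float("nan")))
            continue
        r, p = pearson_with_p(rec_vals, pat_vals if not scaled else zscore(pat_vals)[0])
        scored.append((rec.label, r, p))

    scored.sort(key=lambda s: (np.isnan(s[1]), -(s[1] if not np.isnan(s[1]) else 0)))
    return [
        ProfileMatch(label=lab, r=r, p=p, rank=i + 1)
        for i, (lab, r, p) in enumerate(scored)
    ]


@dataclass(frozen=True)
class ClusterResult:
    """k-means partition of z-scored kinetic profiles.

    ``memberships`` maps record labels to cluster ids 1..k (ids numbered
    by first appearance in record order, for determinism); ``centroids``
    holds one z-scored curve per cluster, equal to the mean of its
    members' scaled vectors; ``member_centroid_r`` is each member's
    Pearson correlation to its own centroid.
    """

    k: int
    grid: CommonGrid
    memberships: dict[tuple, int]
    centroids: np.ndarray  # (k, n_points)
    member_centroid_r: dict[tuple, float]
    scaled_vectors: dict[tuple, np.ndarray]
    inertia: float
    seed: int
    excluded: tuple[tuple, ...] = ()

    def to_table(self) -> tuple[list, list[str]]:
        columns = [
            "strain",
            "phenotype",
            "plate",
            "well",
            "replicate",
            "cluster",
            "r_to_centroid",
        ]
        rows = [
            [*label, cluster, self.member_centroid_r[label]]
            for label, cluster in self.memberships.items()
        ]
        return rows, columns


def kmeans_cluster(
    rs: RecordSet, k: int, seed: int = 42, restarts: int = 10
) -> ClusterResult:
    """Cluster z-scored kinetic profiles into *k* groups.

    Curves are resampled to the joint grid, z-score scaled per record
    (zero-variance records are excluded with a warning), then clustered
    by Euclidean k-means with spread-out (k-means++) initial centres,
    keeping the best of ``restarts`` runs by within-cluster sum of
    squares.  Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    grid, mat = resample_set(rs)

    labels = [r.label for r in rs]
    scaled_rows = []
    usable_labels = []
    excluded = []
    for lab, row in zip(labels, mat):
        srow, degenerate = zscore(row)
        if degenerate:
            excluded.append(lab)
            continue
        usable_labels.append(lab)
        scaled_rows.append(srow)
    if excluded:
        log.warning("excluded %d zero-variance record(s) from clustering", len(excluded))
    if len(scaled_rows) < k:
        raise ValueError(
            f"k={k} exceeds the {len(scaled_rows)} usable (non-degenerate) records"
        )
    X = np.vstack(scaled_rows)

    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=300,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)

    # renumber clusters 1..k by first appearance in record order
    remap: dict[int, int] = {}
    for raw in km.labels_:
        if raw not in remap:
            remap[raw] = len(remap) + 1
    assignments = np.array([remap[raw] for raw in km.labels_])

    centroids = np.vstack(
        [X[assignments == c].mean(axis=0) for c in range(1, k + 1)]
        if set(assignments) == set(range(1, k + 1))
        else [
            X[assignments == c].mean(axis=0)
            if np.any(assignments == c)
            else np.full(X.shape[1], np.nan)
            for c in range(1, k + 1)
        ]
    )

    member_r = {}
    for lab, row, c in zip(usable_labels, X, assignments):
        centroid = centroids[c - 1]
        if centroid.std() == 0:
            member_r[lab] = float("nan")
        else:
            member_r[lab] = float(np.corrcoef(row, centroid)[0, 1])

    return ClusterResult(
        k=k,
        grid=grid,
        memberships=dict(zip(usable_labels, (int(a) for a in assignments))),
        centroids=centroids,
        member_centroid_r=member_r,
        scaled_vectors=dict(zip(usable_labels, X)),
        inertia=float(km.inertia_),
        seed=seed,
        excluded=tuple(excluded),
    )
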