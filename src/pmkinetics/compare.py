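"""Heat-map strain comparison: fold changes and Welch's t-tests.

Each test strain is contrasted against a user-selected parent strain,
well by well.  Every replicate curve is first reduced to a scalar growth
summary (area under the curve by default); the ratio of mean test to
mean parent summary becomes a *signed fold change* — the ratio itself
when >= 1, minus its reciprocal when < 1, so |FC| >= 1 always and the
sign encodes direction — and a Welch's (unequal-variance) t-test on the
replicate summaries supplies the p-value.  The classic significance
screen keeps wells with p < 0.05 and FC >= 2 or FC <= -2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .curves import curve_summary
from .model import RecordSet

__all__ = [
    "ComparisonCell",
    "ComparisonResult",
    "welch_t_test",
    "signed_fold_change",
    "heatmap_compare",
    "DEFAULT_P_MAX",
    "DEFAULT_FC_MIN",
]

log = logging.getLogger(__name__)

DEFAULT_P_MAX = 0.05
DEFAULT_FC_MIN = 2.0


def welch_t_test(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's modified t-test (unequal variances).

    Returns ``(t, df, p)`` with ``t = (mean(a) - mean(b)) /
    sqrt(s2a/na + s2b/nb)`` (sample variances) and Welch–Satterthwaite
    degrees of freedom.  Degenerate zero-variance groups are defined:
    equal means give (0, na+nb-2, 1); unequal means give (±inf, nan, 0).
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    na, nb = av.size, bv.size
    if na < 2 or nb < 2:
        raise ValueError(
            f"welch_t_test needs >= 2 samples per group (got {na}, {nb})"
        )
    va = av.var(ddof=1)
    vb = bv.var(ddof=1)
    diff = av.mean() - bv.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0
        log.warning("both groups zero-variance with unequal means; p defined as 0")
        return math.copysign(float("inf"), diff), float("nan"), 0.0
    se2 = va / na + vb / nb
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(df), float(min(1.0, p))


def signed_fold_change(ratio: float) -> float:
    """Signed fold-change convention: r >= 1 -> r, 0 < r < 1 -> -1/r.

    |FC| >= 1 by construction; FC at exactly ratio 1 is +1.
    """
    if not math.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"ratio must be a positive finite number, got {ratio}")
    return ratio if ratio >= 1.0 else -1.0 / ratio


@dataclass(frozen=True)
class ComparisonCell:
    """One well's test-vs-parent contrast."""

    phenotype: str
    plate: str
    well: str
    test_strain: str
    parent_strain: str
    ratio: float  # mean test summary / mean parent summary; NaN if incomputable
    fc: float  # signed fold change; NaN if incomputable
    t: float
    df: float
    p: float  # NaN when unavailable (< 2 replicates)
    n_test: int
    n_parent: int
    incomputable: bool = False  # parent mean summary <= 0
    p_unavailable: bool = False  # too few replicates for the t-test

    @property
    def significant(self) -> bool:
        return (
            not self.incomputable
            and not self.p_unavailable
            and not math.isnan(self.p)
        )


@dataclass(frozen=True)
class ComparisonResult:
    """All test-vs-parent cells, ready for filtering and heat-map layout."""

    parent_strain: str
    summary_method: str
    cells: tuple[ComparisonCell, ...]

    def test_strains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(c.test_strain, None)
        return list(seen)

    def filtered(
        self, p_max: float = DEFAULT_P_MAX, fc_min: float = DEFAULT_FC_MIN
    ) -> tuple[ComparisonCell, ...]:
        """Cells passing the significance screen: p < p_max and |FC| >= fc_min."""
        return tuple(
            c
            for c in self.cells
            if c.significant and c.p < p_max and abs(c.fc) >= fc_min
        )

    def to_table(self, cells: Optional[Sequence[ComparisonCell]] = None):
        columns = [
            "plate",
            "well",
            "phenotype",
            "test_strain",
            "parent_strain",
            "ratio",
            "fold_change",
            "t",
            "df",
            "p_value",
            "n_test",
            "n_parent",
        ]
        use = self.cells if cells is None else cells
        rows = [
            [
                c.plate,
                c.well,
                c.phenotype,
                c.test_strain,
                c.parent_strain,
                c.ratio,
                c.fc,
                c.t,
                c.df,
                c.p,
                c.n_test,
                c.n_parent,
            ]
            for c in use
        ]
        return rows, columns

    def fc_matrix(self, test_strain: str) -> tuple[np.ndarray, list[str], list[str]]:
        """(wells × plates) signed-fold-change matrix for one test strain.

        Rows are well ids A01..H12, columns the plates in sorted order;
        missing or incomputable cells are NaN.
        """
        from .model import WELL_IDS

        cells = [c for c in self.cells if c.test_strain == test_strain]
        if not cells:
            raise ValueError(f"no cells for test strain {test_strain!r}")
        plates = sorted({c.plate for c in cells})
        wells = list(WELL_IDS)
        mat = np.full((len(wells), len(plates)), np.nan)
        widx = {w: i for i, w in enumerate(wells)}
        pidx = {p: j for j, p in enumerate(plates)}
        for c in cells:
            if c.well in widx and not c.incomputable:
                mat[widx[c.well], pidx[c.plate]] = c.fc
        return mat, wells, plates


def heatmap_compare(
    rs: RecordSet,
    parent_strain: str,
    summary_method: str = "auc",
) -> ComparisonResult:
    """Compare every test strain against the parent, well by well.

    For each (strain, plate, well), replicate curves are reduced to
    scalars by :func:`~pmkinetics.curves.curve_summary`; the ratio of the
    mean test summary to the mean parent summary gives the signed fold
    change, and Welch's t-test on the two sets of replicate summaries
    gives the p-value.  Wells whose parent mean summary is <= 0 are
    marked incomputable; wells with fewer than 2 replicates on either
    side keep their fold change but carry no p-value.
    """
    strains = rs.strains()
    if parent_strain not in strains:
        raise ValueError(
            f"parent strain {parent_strain!r} absent from the record set "
            f"(present: {sorted(strains)})"
        )
    if len(strains) < 2:
        raise ValueError("need at least one test strain besides the parent")

    # per strain, per (plate, well): replicate summaries + phenotype label
    summaries: dict[str, dict[tuple[str, str], list[float]]] = {}
    phenotypes: dict[tuple[str, str], str] = {}
    for rec in rs:
        if rec.averaged:
            raise ValueError(
                "heatmap_compare needs raw replicates, not pre-averaged records"
            )
        key = (rec.plate, rec.well)
        summaries.setdefault(rec.strain, {}).setdefault(key, []).append(
            curve_summary(rec.curve, summary_method)
        )
        phenotypes.setdefault(key, rec.phenotype)

    parent = summaries[parent_strain]
    cells: list[ComparisonCell] = []
    for test_strain in (s for s in summaries if s != parent_strain):
        for key in summaries[test_strain]:
            if key not in parent:
                continue
            plate, well = key
            ts = np.asarray(summaries[test_strain][key])
            ps = np.asarray(parent[key])
            parent_mean = float(ps.mean())
            test_mean = float(ts.mean())
            if parent_mean <= 0:
                log.warning(
                    "parent mean summary <= 0 for %s/%s; cell incomputable",
                    plate,
                    well,
                )
                cells.append(
                    ComparisonCell(
                        phenotype=phenotypes[key],
                        plate=plate,
                        well=well,
                        test_strain=test_strain,
                        parent_strain=parent_strain,
                        ratio=float("nan"),
                        fc=float("nan"),
                        t=float("nan"),
                        df=float("nan"),
                        p=float("nan"),
                        n_test=ts.size,
                        n_parent=ps.size,
                        incomputable=True,
                    )
                )
                continue
            ratio = test_mean / parent_mean
            fc = signed_fold_change(ratio) if ratio > 0 else float("nan")
            if ts.size >= 2 and ps.size >= 2:
                t, df, p = welch_t_test(ts, ps)
                p_unavailable = False
            else:
                log.warning(
                    "fewer than 2 replicates for %s/%s; p-value unavailable",
                    plate,
                    well,
                )
                t, df, p = float("nan"), float("nan"), float("nan")
                p_unavailable = True
            cells.append(
                ComparisonCell(
                    phenotype=phenotypes[key],
                    plate=plate,
                    well=well,
                    test_strain=test_strain,
                    parent_strain=parent_strain,
                    ratio=ratio,
                    fc=fc,
                    t=t,
                    df=df,
                    p=p,
                    n_test=ts.size,
                    n_parent=ps.size,
                    p_unavailable=p_unavailable,
                )
            )
    return ComparisonResult(
        parent_strain=parent_strain,
        summary_method=summary_method,
        cells=tuple(cells),
    )
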