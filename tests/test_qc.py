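"""Outlier screening and negative-control quantile calibration."""

import itertools

import numpy as np
import pytest

from pmkinetics import (
    RecordSet,
    generate_negative_controls,
    negative_controls_analysis,
    outlier_analysis,
)
from pmkinetics.synthetic import ControlConfig

from conftest import logistic_curve, make_record


def pearson_oracle(x, y):
    """Textbook covariance-formula Pearson r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


def group_of(curves, strain="S1", phenotype="P1", plate="PM01"):
    t = np.arange(0, len(curves[0]) * 10, 10.0)
    return RecordSet(
        make_record(
            strain=strain,
            phenotype=phenotype,
            plate=plate,
            well="A01",
            replicate=i + 1,
            times=t,
            values=v,
        )
        for i, v in enumerate(curves)
    )


class TestOutlierAnalysis:
    def test_identical_curves_median_one_nothing_flagged(self):
        v = logistic_curve(np.arange(0, 300, 10.0), midpoint=150, rate=0.05)
        rows = outlier_analysis(group_of([v, v, v]), threshold=0.9)
        np.testing.assert_allclose(
            [r.median_correlation for r in rows], 1.0, atol=1e-12
        )
        assert not any(r.flagged for r in rows)

    def test_reversed_ramp_flagged_and_drags_partners_to_zero(self):
        ramp = np.linspace(0, 100, 11)
        rows = outlier_analysis(
            group_of([ramp, ramp, ramp[::-1]]), threshold=0.5
        )
        # pairwise correlations: r12=1, r13=r23=-1; medians by hand:
        # members 1,2 -> median(1, -1) = 0; member 3 -> median(-1, -1) = -1
        meds = [r.median_correlation for r in rows]
        np.testing.assert_allclose(meds, [0.0, 0.0, -1.0], atol=1e-12)
        assert all(r.flagged for r in rows)

    def test_pair_median_equals_single_pairwise_r(self):
        rng = np.random.default_rng(4)
        a = np.clip(logistic_curve(np.arange(0, 300, 10.0), midpoint=150, rate=0.05)
                    + rng.normal(0, 5, 30), 0, None)
        b = np.clip(logistic_curve(np.arange(0, 300, 10.0), midpoint=160, rate=0.04)
                    + rng.normal(0, 5, 30), 0, None)
        rows = outlier_analysis(group_of([a, b]), threshold=0.5)
        expected = pearson_oracle(a, b)
        for row in rows:
            assert row.median_correlation == pytest.approx(expected, abs=1e-12)

    def test_medians_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(9)
        curves = [rng.uniform(0, 100, 25) for _ in range(5)]
        base = {
            (r.well, r.replicate): r.median_correlation
            for r in outlier_analysis(group_of(curves), threshold=0.5)
        }
        perm = [curves[i] for i in (3, 1, 4, 0, 2)]
        rows = outlier_analysis(group_of(perm), threshold=0.5)
        for row in rows:
            orig_idx = (3, 1, 4, 0, 2)[row.replicate - 1]
            assert row.median_correlation == pytest.approx(
                base[("A01", orig_idx + 1)], abs=1e-12
            )
            assert -1.0 <= row.median_correlation <= 1.0

    def test_lowering_threshold_never_flags_more(self):
        rng = np.random.default_rng(2)
        curves = [rng.uniform(0, 100, 25) for _ in range(6)]
        rs = group_of(curves)
        flagged = [
            {(r.well, r.replicate) for r in outlier_analysis(rs, threshold=th) if r.flagged}
            for th in (0.9, 0.5, 0.1, -0.5)
        ]
        for tighter, looser in itertools.pairwise(flagged):
            assert looser <= tighter

    def test_planted_anticorrelated_outlier_recovered(self):
        t = np.arange(0, 4320, 15.0)
        rng = np.random.default_rng(12)
        base = logistic_curve(t)
        concordant = [np.clip(base + rng.normal(0, 2, t.size), 0, None) for _ in range(4)]
        planted = np.clip(base[::-1] + rng.normal(0, 2, t.size), 0, None)
        rows = outlier_analysis(group_of(concordant + [planted]), threshold=0.5)
        flagged = {r.replicate for r in rows if r.flagged}
        assert flagged == {5}

    def test_zero_variance_member_reported_degenerate_and_flagged(self):
        v = logistic_curve(np.arange(0, 300, 10.0), midpoint=150, rate=0.05)
        flat = np.full(v.size, 20.0)
        rows = outlier_analysis(group_of([v, v, flat]), threshold=0.5)
        degen = [r for r in rows if r.degenerate]
        assert len(degen) == 1 and degen[0].replicate == 3
        assert degen[0].flagged and np.isnan(degen[0].median_correlation)
        healthy = [r for r in rows if not r.degenerate]
        np.testing.assert_allclose(
            [r.median_correlation for r in healthy], 1.0, atol=1e-12
        )

    def test_singleton_groups_skipped(self):
        rows = outlier_analysis(RecordSet([make_record()]), threshold=0.5)
        assert rows == []

    def test_empty_recordset_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            outlier_analysis(RecordSet())


def controls_of(values_per_curve):
    t = np.arange(0, len(values_per_curve[0]) * 15, 15.0)
    return RecordSet(
        make_record(
            strain="control",
            phenotype="negative_control",
            well="A01",
            plate=f"NC{i + 1:02d}",
            times=t,
            values=v,
        )
        for i, v in enumerate(values_per_curve)
    )


class TestNegativeControls:
    def test_constant_controls_give_constant_quantiles(self):
        neg = controls_of([np.full(10, 30.0)] * 5)
        q, overlay = negative_controls_analysis(neg)
        assert overlay is None
        np.testing.assert_array_equal(q.curves, 30.0)
        np.testing.assert_array_equal(q.candidate_thresholds, 30.0)

    def test_median_of_five_constant_levels(self):
        neg = controls_of([np.full(10, v) for v in (10, 20, 30, 40, 50)])
        q, _ = negative_controls_analysis(neg, levels=(0.5,))
        np.testing.assert_array_equal(q.curves[0], 30.0)

    def test_quantiles_match_sort_based_oracle(self):
        rng = np.random.default_rng(8)
        mat = rng.uniform(0, 50, size=(12, 20))
        neg = controls_of(list(mat))
        levels = (0.05, 0.25, 0.5, 0.75, 0.95)
        q, _ = negative_controls_analysis(neg, levels=levels)
        for li, level in enumerate(levels):
            for j in range(mat.shape[1]):
                col = np.sort(mat[:, j])
                h = level * (col.size - 1)  # linear interpolation between order stats
                lo = int(np.floor(h))
                hi = min(lo + 1, col.size - 1)
                oracle = col[lo] + (h - lo) * (col[hi] - col[lo])
                assert q.curves[li, j] == pytest.approx(oracle, abs=1e-10)

    def test_quantiles_monotone_in_level(self):
        rng = np.random.default_rng(3)
        neg = controls_of(list(rng.normal(25, 5, size=(9, 30)).clip(0)))
        q, _ = negative_controls_analysis(neg)
        assert np.all(np.diff(q.curves, axis=0) >= -1e-12)

    def test_median_on_odd_set_is_middle_order_statistic(self):
        rng = np.random.default_rng(5)
        mat = rng.uniform(0, 50, size=(7, 15))
        q, _ = negative_controls_analysis(controls_of(list(mat)), levels=(0.5,))
        np.testing.assert_allclose(q.curves[0], np.sort(mat, axis=0)[3], atol=1e-12)

    def test_overlay_shares_the_grid(self):
        neg = controls_of(list(np.full((4, 12), 20.0)))
        t = np.arange(0, 12 * 15, 15.0)
        non_neg = RecordSet(
            [make_record(phenotype="glucose", times=t,
                         values=logistic_curve(t, midpoint=60, rate=0.05))]
        )
        q, overlay = negative_controls_analysis(neg, non_neg)
        np.testing.assert_array_equal(q.grid.times, overlay.grid.times)

    def test_empty_controls_rejected_and_bad_levels(self):
        with pytest.raises(ValueError, match="non-empty"):
            negative_controls_analysis(RecordSet())
        with pytest.raises(ValueError, match="levels"):
            negative_controls_analysis(controls_of([np.full(5, 1.0)] * 2), levels=(0, 0.5))

    def test_generated_controls_noise_sd_recovered(self):
        cfg = ControlConfig(count=1000, baseline=100.0, noise_sd=5.0,
                            duration_min=600.0)
        rs = generate_negative_controls(cfg, seed=17)
        mat = np.vstack([r.curve.values for r in rs])
        sds = mat.std(axis=0, ddof=1)
        assert np.all((sds > 4.5) & (sds < 5.5))
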