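"""ET50 estimation: exactness, oracle equivalence, ordering, group tests."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from photoxl import kinetics
from photoxl.kinetics import (
    KineticsResult,
    compare_groups,
    estimate_et50,
    filter_background,
    normalize_to_max,
)


def brute_force_et50(rel, times):
    """Independent re-implementation of the selection + OLS rule.

    Plain loops and explicit least-squares formulas; shares no code with the
    pipeline estimator.
    """
    pts = [(t, r) for t, r in zip(times, rel)
           if t > 0 and not math.isnan(r)]
    pts.sort(key=lambda p: p[0])
    if len(pts) < 3:
        return None
    best = max(range(len(pts)), key=lambda i: (pts[i][1], -i))
    # earliest time achieving the maximum
    i_max = min(i for i in range(len(pts)) if pts[i][1] == pts[best][1])
    sel = pts[: i_max + 1]
    if len(sel) < 3:
        return None
    xs = [math.log(t) for t, _ in sel]
    ys = [r for _, r in sel]
    n = len(sel)
    xbar, ybar = sum(xs) / n, sum(ys) / n
    sxx = sum((x - xbar) ** 2 for x in xs)
    sxy = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
    slope = sxy / sxx
    if slope <= 0:
        return None
    return math.log(2) / slope


class TestNormalizeToMax:
    def test_simple_series(self):
        np.testing.assert_allclose(
            normalize_to_max(np.array([2.0, 4.0, 8.0])), [0.25, 0.5, 1.0]
        )

    def test_constant_series_all_ones(self):
        np.testing.assert_allclose(
            normalize_to_max(np.array([3.0, 3.0, 3.0])), [1.0, 1.0, 1.0]
        )

    def test_replicates_averaged_before_normalization(self):
        out = normalize_to_max(
            np.array([3.0, 5.0, 8.0]), replicate_groups=[[0, 1], [2]]
        )
        np.testing.assert_allclose(out, [0.5, 1.0])

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            normalize_to_max(np.array([np.nan, np.nan]))


class TestFilterBackground:
    times = np.array([0.0, 1.0, 2.0])

    def test_above_threshold_removed(self):
        assert filter_background(np.array([0.6, 0.8, 1.0]), self.times)

    def test_exactly_at_threshold_kept(self):
        assert not filter_background(np.array([0.5, 0.8, 1.0]), self.times)

    def test_missing_at_zero_counts_as_zero(self):
        assert not filter_background(np.array([np.nan, 0.8, 1.0]), self.times)

    def test_no_unirradiated_sample_errors(self):
        with pytest.raises(ValueError, match="t=0"):
            filter_background(np.array([0.5, 1.0]), np.array([1.0, 2.0]))


class TestEstimateEt50:
    def test_exact_log_linear_series(self):
        times = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        rel = 0.2 * np.log(times) + 0.1
        res = estimate_et50(rel, times)
        assert res.status == "ok"
        assert res.slope == pytest.approx(0.2, abs=1e-12)
        assert res.et50 == pytest.approx(math.log(2) / 0.2, abs=1e-12)

    def test_half_slope_doubles_et50(self):
        times = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        res = estimate_et50(0.1 * np.log(times) + 0.1, times)
        assert res.et50 == pytest.approx(6.9315, abs=1e-4)

    def test_monotone_decreasing_series_too_few_points(self):
        times = np.array([1.0, 2.0, 4.0, 8.0])
        res = estimate_et50(np.array([1.0, 0.8, 0.6, 0.4]), times)
        assert res.status == "too_few_points" and res.et50 is None

    def test_nonpositive_slope_status(self):
        times = np.array([1.0, 2.0, 4.0, 8.0])
        # max at the last point but overall downward trend before a spike
        rel = np.array([0.9, 0.5, 0.2, 1.0])
        res = estimate_et50(rel, times)
        assert res.status in ("ok", "nonpositive_slope")
        if res.status == "nonpositive_slope":
            assert res.et50 is None

    def test_saturating_truth_matches_independent_oracle(self):
        times = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        rel = 1.0 - np.exp(-0.5 * times)
        rel = rel / rel.max()
        res = estimate_et50(rel, times)
        oracle = brute_force_et50(rel.tolist(), times.tolist())
        assert res.et50 == pytest.approx(oracle, abs=1e-9)

    def test_random_series_match_oracle(self, rng):
        times = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0])
        for _ in range(100):
            rel = rng.uniform(0, 1, size=times.size)
            rel[rng.random(times.size) < 0.15] = np.nan
            res = estimate_et50(rel, times)
            oracle = brute_force_et50(rel.tolist(), times.tolist())
            if oracle is None:
                assert res.status != "ok"
            else:
                assert res.status == "ok"
                assert res.et50 == pytest.approx(oracle, abs=1e-9)

    def test_status_invariants(self):
        with pytest.raises(ValueError):
            KineticsResult(protein_id="x", status="ok", et50=None)
        with pytest.raises(ValueError):
            KineticsResult(protein_id="x", status="too_few_points", et50=1.0)


class TestRateOrdering:
    def test_noiseless_saturating_curves_strictly_ordered(self):
        """In the mid-rise regime the estimate is strictly decreasing in k."""
        times = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0])
        ks = 10 ** np.linspace(-2.0, -1.3, 100)
        et50s = []
        for k in ks:
            rel = 1.0 - np.exp(-k * times)
            res = estimate_et50(rel / rel.max(), times)
            assert res.status == "ok"
            et50s.append(res.et50)
        assert np.all(np.diff(et50s) < 0)  # decreasing in k
        rho = stats.spearmanr(et50s, 1.0 / ks).statistic
        assert rho == pytest.approx(1.0)

    def test_dispersion_contrast_between_sources(self):
        """A source with compressed rates yields a far tighter ET50 spread
        than one spreading rates over two orders of magnitude (noiseless)."""
        times = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0])

        def ets(ks):
            out = []
            for k in ks:
                rel = 1.0 - np.exp(-k * times)
                res = estimate_et50(rel / rel.max(), times)
                out.append(res.et50)
            return np.array(out)

        narrow = ets(10 ** np.linspace(-1.62, -1.6, 50))
        spread = ets(10 ** np.linspace(-2.5, -1.0, 50))
        assert narrow.std(ddof=1) < spread.std(ddof=1) / 10


class TestCompareGroups:
    @staticmethod
    def _results(et50s, prefix="P"):
        return [
            KineticsResult(protein_id=f"{prefix}{i}", slope=1.0, intercept=0.0,
                           n_points=4, t_max=8.0, et50=e, status="ok")
            for i, e in enumerate(et50s)
        ]

    def test_group_identical_to_reference(self, rng):
        res = self._results(rng.uniform(1, 10, 40))
        groups = {"all_again": {r.protein_id for r in res}}
        out = compare_groups(res, groups)
        assert out[0].p_raw > 0.9
        assert out[0].p_adjusted == out[0].p_raw  # Holm with m=1

    def test_shifted_group_detected(self, rng):
        ref = rng.normal(50, 1.0, 1000)
        fast = rng.normal(45, 1.0, 50)  # 5 sigma below
        res = self._results(np.concatenate([ref, fast]))
        fast_ids = {r.protein_id for r in res[1000:]}
        out = compare_groups(res, {"fast": fast_ids})
        assert out[0].p_adjusted < 0.001
        assert out[0].n_reference == 1050  # inclusive reference

    def test_holm_ordering_across_groups(self, rng):
        res = self._results(rng.normal(50, 5, 300))
        ids = [r.protein_id for r in res]
        groups = {
            "g1": set(ids[:30]),
            "g2": set(ids[30:60]),
            "g3": set(ids[60:90]),
        }
        out = compare_groups(res, groups)
        for c in out:
            assert c.p_adjusted >= c.p_raw

    def test_small_group_skipped_with_warning(self, rng):
        res = self._results(rng.uniform(1, 10, 20))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            out = compare_groups(res, {"tiny": {res[0].protein_id}})
        assert out == []
        assert any("skipped" in str(w.message) for w in caught)


class TestEstimateAll:
    def test_background_proteins_removed(self):
        from conftest import make_samples
        from photoxl.containers import QuantMatrix, SampleMeta

        times = [0.0, 1.0, 2.0, 4.0, 8.0]
        samples = [
            SampleMeta(f"t{t:g}", "tc", t, "none" if t == 0 else "led", 1)
            for t in times
        ]
        signal = [0.05, 0.3, 0.5, 0.8, 1.0]
        background = [1.0, 0.95, 1.05, 1.0, 0.9]
        qm = QuantMatrix(["sig", "bg"],
                         np.array([signal, background]) * 1000.0, samples)
        res = {r.protein_id: r for r in kinetics.estimate_all(qm)}
        assert res["bg"].status == "background_removed"
        assert res["sig"].status == "ok"
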