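"""Median chronology aggregation and signal-strength statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cellchron as cc
from cellchron.chronology import ChronologyError
from cellchron.detrend import IndexSeries


def idx(sid, first, values, tree=None):
    return IndexSeries(series_id=sid, tree_id=tree or sid, first_year=first,
                       indices=np.asarray(values, dtype=float))


class TestBuildChronology:
    def test_staggered_starts_give_144_year_span(self):
        starts = [1774, 1800, 1825, 1850, 1870, 1875, 1880, 1885, 1889, 1893]
        rng = np.random.default_rng(0)
        series = [idx(f"S{i}", s, 1 + 0.1 * rng.normal(size=2014 - s))
                  for i, s in enumerate(starts)]
        chron = cc.build_chronology(series, min_depth=5)
        assert chron.first_year == 1870
        assert chron.last_year == 2013
        assert len(chron) == 144

    def test_five_identical_series_reproduce_themselves(self):
        vals = np.linspace(0.5, 1.5, 60)
        series = [idx(f"S{i}", 1950, vals) for i in range(5)]
        chron = cc.build_chronology(series)
        np.testing.assert_allclose(chron.values, vals)
        assert (chron.sample_depth == 5).all()

    def test_median_by_hand(self):
        odd = [idx(f"A{i}", 2000, [v]) for i, v in enumerate([0.8, 1.0, 1.2, 1.4, 0.6])]
        assert cc.build_chronology(odd, min_depth=5).values[0] == pytest.approx(1.0)
        even = [idx(f"B{i}", 2000, [v]) for i, v in enumerate([0.8, 1.0, 1.2, 1.4])]
        assert cc.build_chronology(even, min_depth=4).values[0] == pytest.approx(1.1)

    def test_duplicating_all_series_leaves_median_unchanged(self):
        rng = np.random.default_rng(3)
        series = [idx(f"S{i}", 1950, np.exp(0.1 * rng.normal(size=50)))
                  for i in range(6)]
        base = cc.build_chronology(series)
        doubled = cc.build_chronology(
            series + [idx(s.series_id + "X", 1950, s.indices) for s in series]
        )
        np.testing.assert_allclose(doubled.values, base.values)

    def test_no_qualifying_year_raises(self):
        series = [idx("A", 2000, [1.0]), idx("B", 2005, [1.0])]
        with pytest.raises(ChronologyError, match="depth"):
            cc.build_chronology(series, min_depth=2)


class TestRbar:
    def test_identical_series_give_unit_rbar(self):
        vals = np.exp(0.1 * np.random.default_rng(1).normal(size=60))
        series = [idx(f"S{i}", 1950, vals, tree=f"T{i}") for i in range(4)]
        res = cc.rbar_eff(series)
        assert res.rbar_between == pytest.approx(1.0)
        assert res.rbar_eff == pytest.approx(1.0)

    def test_one_core_per_tree_equals_mean_pairwise(self):
        rng = np.random.default_rng(2)
        series = [idx(f"S{i}", 1950, np.exp(0.1 * rng.normal(size=80)),
                      tree=f"T{i}") for i in range(3)]
        res = cc.rbar_eff(series)
        brute = np.mean([
            np.corrcoef(series[a].indices, series[b].indices)[0, 1]
            for a in range(3) for b in range(a + 1, 3)
        ])
        assert res.rbar_eff == pytest.approx(brute, abs=1e-12)

    def test_white_noise_rbar_near_zero(self):
        rng = np.random.default_rng(7)
        reps = []
        for _ in range(20):
            series = [idx(f"S{i}", 1900, np.exp(0.1 * rng.normal(size=100)),
                          tree=f"T{i}") for i in range(6)]
            reps.append(cc.rbar_eff(series).rbar_eff)
        assert abs(np.mean(reps)) < 2 / np.sqrt(100)

    def test_two_core_formula(self):
        """rbar_eff = rbar_bt / (rbar_wt + (1 - rbar_wt)/cbar) with shared cores."""
        rng = np.random.default_rng(4)
        common = rng.normal(size=120)
        series = []
        for t in range(4):
            tree_sig = rng.normal(size=120)
            for c in "AB":
                noise = rng.normal(size=120)
                series.append(idx(f"T{t}{c}", 1894,
                                  np.exp(0.05 * (common + tree_sig + noise)),
                                  tree=f"T{t}"))
        res = cc.rbar_eff(series)
        expected = res.rbar_between / (res.rbar_within + (1 - res.rbar_within) / 2.0)
        assert res.rbar_eff == pytest.approx(expected, abs=1e-12)
        assert res.rbar_within > res.rbar_between

    def test_short_overlap_pairs_skipped(self):
        a = idx("A", 1900, np.ones(40) + 0.01 * np.arange(40))
        b = idx("B", 1935, np.ones(40) + 0.01 * np.arange(40))
        with pytest.raises(ChronologyError, match="between-tree"):
            cc.rbar_eff([a, b])


class TestEpsSnr:
    def test_closed_forms(self):
        eps, snr = cc.eps_snr(0.298, 10)
        assert snr == pytest.approx(10 * 0.298 / 0.702)
        assert eps == pytest.approx(snr / (1 + snr))
        assert cc.eps_snr(0.0, 10) == (0.0, 0.0)

    def test_snr_from_eps_inverts(self):
        for e in [0.0, 0.3, 0.818, 0.905]:
            snr = cc.snr_from_eps(e)
            assert snr / (1 + snr) == pytest.approx(e, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ChronologyError):
            cc.eps_snr(1.0, 10)
        with pytest.raises(ChronologyError):
            cc.snr_from_eps(1.0)


class TestGini:
    def test_constant_series_is_zero(self):
        assert cc.gini(np.full(10, 3.3)) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cc.gini(np.array([1.0, 2.0, 3.0])) == pytest.approx(8 / 36)

    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=200),
           st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_matches_double_loop_and_scale_invariance(self, values, scale):
        x = np.asarray(values)
        brute = sum(abs(a - b) for a in x for b in x) / (2 * len(x) ** 2 * x.mean())
        assert cc.gini(x) == pytest.approx(brute, abs=1e-12)
        assert cc.gini(scale * x) == pytest.approx(cc.gini(x), abs=1e-12)


class TestAr1:
    def test_recovers_generating_phi(self):
        rng = np.random.default_rng(10)
        x = np.zeros(1000)
        for t in range(1, 1000):
            x[t] = 0.5 * x[t - 1] + rng.normal()
        assert cc.ar1(x) == pytest.approx(0.5, abs=0.06)

    def test_alternating_sequence_matches_brute_force(self):
        x = np.tile([1.0, -1.0], 50)
        d = x - x.mean()
        brute = np.sum(d[1:] * d[:-1]) / np.sum(d * d)
        assert cc.ar1(x) == pytest.approx(brute, abs=1e-14)
        assert cc.ar1(x) < -0.9

    def test_iid_null_rejection_rate(self):
        rng = np.random.default_rng(11)
        inside = sum(
            abs(cc.ar1(rng.normal(size=144))) < 2 / np.sqrt(144) for _ in range(200)
        )
        assert inside / 200 > 0.85  # ~95% nominal coverage


class TestSummarize:
    def test_identity_and_full_record(self, default_dataset):
        series, _ = default_dataset
        ld = [cc.detrend(s) for s in series if s.parameter == "LD"]
        chron = cc.build_chronology(ld)
        stats = cc.summarize_chronology(chron, ld)
        assert stats.snr == pytest.approx(stats.eps / (1 - stats.eps), abs=1e-12)
        assert not stats.partial
        assert stats.n_series == 10 and stats.n_trees == 10

    def test_single_series_flagged_partial(self):
        rng = np.random.default_rng(5)
        one = [idx("A", 1950, np.exp(0.1 * rng.normal(size=60)))]
        chron = cc.build_chronology(one, min_depth=1)
        stats = cc.summarize_chronology(chron, one)
        assert stats.partial
        assert np.isnan(stats.rbar_eff) and np.isnan(stats.eps)
        assert np.isfinite(stats.ar1) and np.isfinite(stats.gini)

    def test_eps_n_conventions_ordered(self, default_dataset):
        series, _ = default_dataset
        rw = [cc.detrend(s) for s in series if s.parameter == "ring_width"]
        chron = cc.build_chronology(rw)
        by = {conv: cc.summarize_chronology(chron, rw, eps_n=conv).eps
              for conv in ("mean-trees", "max-trees", "cores")}
        assert by["mean-trees"] <= by["max-trees"] <= by["cores"]
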