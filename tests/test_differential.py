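"""Moderated t, BH adjustment, call thresholds, fine mapping, overlaps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from replitime import (
    GenomeDefinition,
    DifferentialRTModel,
    annotation_enrichment,
    bh_adjust,
    call_windows,
    intersect_windows,
    make_windows,
    moderated_t_test,
    venn_counts,
)
from replitime.differential import map_frame_to_fine


class TestModeratedT:
    def test_equal_means_give_zero_t_unit_p(self):
        a = np.array([[1.0, 2.0, 3.0]])  # mean 2, same as b's
        b = np.array([[3.0, 2.0, 1.0]])
        res = moderated_t_test(np.vstack([a, a + 1]), np.vstack([b, b]))
        assert res.t[0] == pytest.approx(0.0)
        assert res.p[0] == pytest.approx(1.0)

    def test_df_prior_zero_matches_ordinary_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (50, 3))
        b = rng.normal(0, 1, (50, 4))
        res = moderated_t_test(a, b, df_prior=0)
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res.t, t_ref, rtol=1e-10)
        np.testing.assert_allclose(res.p, p_ref, rtol=1e-10)

    def test_df_prior_inf_pools_variances(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (40, 3))
        b = rng.normal(0, 1, (40, 3))
        res = moderated_t_test(a, b, df_prior=np.inf)
        assert len(np.unique(res._res.s2_post)) == 1
        assert np.isinf(res.df_total)

    def test_prior_estimation_recovers_homogeneous_variance(self):
        """With a common true variance the prior df is large and s2_post
        concentrates near the truth."""
        rng = np.random.default_rng(3)
        sigma = 0.3
        a = rng.normal(0, sigma, (2000, 3))
        b = rng.normal(0, sigma, (2000, 3))
        res = moderated_t_test(a, b)
        assert res.df_prior > 4
        assert np.median(res._res.s2_post) == pytest.approx(sigma**2, rel=0.2)

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            moderated_t_test(np.zeros((5, 1)), np.zeros((5, 2)))

    def test_all_zero_variance_fallback(self, caplog):
        a = np.tile([[1.0, 1.0, 1.0]], (10, 1)) + np.arange(10)[:, None]
        b = np.tile([[0.0, 0.0, 0.0]], (10, 1))
        res = moderated_t_test(a, b)
        assert np.isinf(res.df_total)
        assert np.isfinite(res.p).all()

    def test_symmetry_under_condition_swap(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (100, 3))
        b = rng.normal(0.2, 1, (100, 3))
        fwd = moderated_t_test(a, b)
        rev = moderated_t_test(b, a)
        np.testing.assert_allclose(fwd.log_fc, -rev.log_fc)
        np.testing.assert_allclose(fwd.p, rev.p)
        calls_fwd = call_windows(fwd.log_fc, fwd.p_adj, alpha=0.2, lfc=0.05)
        calls_rev = call_windows(rev.log_fc, rev.p_adj, alpha=0.2, lfc=0.05)
        swap = {"advanced": "delayed", "delayed": "advanced", "ns": "ns"}
        assert [swap[c] for c in calls_fwd] == list(calls_rev)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCallWindows:
    @pytest.mark.parametrize(
        "p_adj,lfc,expected",
        [
            (0.009, 0.11, "advanced"),
            (0.009, -0.11, "delayed"),
            (0.01, 0.11, "ns"),     # strict "<" on adjusted p
            (0.009, 0.1, "ns"),     # strict ">" on |log FC|
        ],
    )
    def test_strict_thresholds(self, p_adj, lfc, expected):
        assert call_windows([lfc], [p_adj])[0] == expected


class TestFineMapping:
    def _grid(self):
        genome = GenomeDefinition((("chr1", 300_000),))
        return make_windows(genome, 100_000, 10_000)

    def _frame(self, grid, p_adj, log_fc=0.5):
        f = grid.windows.copy().reset_index(drop=True)
        f["mean_a"] = 1.0
        f["mean_b"] = 0.5
        f["log_fc"] = log_fc
        f["p_adj"] = p_adj
        return f

    def test_interior_fine_window_median_of_ten(self):
        grid = self._grid()
        # coarse p_adj = (window ordinal + 1) / 1000 -> values 0.001 .. 0.021
        frame = self._frame(grid, (np.arange(21) + 1) / 1000.0)
        fine = map_frame_to_fine(frame, grid, alpha=0.05, lfc=0.1)
        row = fine.frame[fine.frame["start"] == 100_000].iloc[0]
        # covered by coarse starts 10k..100k -> ordinals 2..11 -> median 6.5/1000
        assert row["n_coarse"] == 10
        assert row["p_adj"] == pytest.approx(0.0065)

    def test_first_fine_window_inherits_single_coarse(self):
        grid = self._grid()
        frame = self._frame(grid, (np.arange(21) + 1) / 1000.0)
        fine = map_frame_to_fine(frame, grid, alpha=0.05, lfc=0.1)
        row = fine.frame[fine.frame["start"] == 0].iloc[0]
        assert row["n_coarse"] == 1 and row["p_adj"] == pytest.approx(0.001)

    def test_all_significant_coarse_implies_significant_fine(self):
        grid = self._grid()
        fine = map_frame_to_fine(self._frame(grid, 0.001), grid, alpha=0.05, lfc=0.1)
        assert (fine.frame["call"] != "ns").all()

    def test_masked_coarse_windows_excluded(self):
        grid = self._grid()
        frame = self._frame(grid, 0.001).drop(index=range(0, 12)).reset_index(drop=True)
        fine = map_frame_to_fine(frame, grid, alpha=0.05, lfc=0.1)
        # fine window [0,10k) was covered only by dropped coarse windows
        assert (fine.frame["start"] != 0).all()

    def test_end_to_end_from_results(self):
        rng = np.random.default_rng(6)
        grid = self._grid()
        res = DifferentialRTModel(
            rng.normal(0, 0.1, (21, 3)), rng.normal(0, 0.1, (21, 3)), grid=grid
        ).fit()
        fine = res.map_to_fine()
        assert fine.frame["end"].max() <= 300_000
        assert set(fine.frame["call"]) <= {"advanced", "delayed", "ns"}


class TestIntersect:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_half_overlap_boundary_reported(self):
        a = self._df([("chr1", 0, 100_000)])
        b = self._df([("chr1", 50_000, 150_000)])
        assert intersect_windows(a, b, f=0.5)[0]

    def test_forty_percent_not_reported(self):
        a = self._df([("chr1", 0, 100_000)])
        b = self._df([("chr1", 60_000, 160_000)])
        assert not intersect_windows(a, b, f=0.5)[0]

    def test_single_b_window_must_reach_fraction(self):
        # two B windows each cover 30%; no single one reaches 50%
        a = self._df([("chr1", 0, 100_000)])
        b = self._df([("chr1", 0, 30_000), ("chr1", 70_000, 100_000)])
        assert not intersect_windows(a, b, f=0.5)[0]

    def test_oracle_equivalence_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            def rand_set(n):
                starts = rng.integers(0, 900, n)
                lengths = rng.integers(10, 200, n)
                chroms = rng.choice(["c1", "c2"], n)
                return pd.DataFrame(
                    {"chrom": chroms, "start": starts, "end": starts + lengths}
                )
            a, b = rand_set(int(rng.integers(1, 40))), rand_set(int(rng.integers(1, 40)))
            got = intersect_windows(a, b, f=0.5)
            brute = np.zeros(len(a), dtype=bool)
            for i, (ca, sa, ea) in enumerate(zip(a["chrom"], a["start"], a["end"])):
                for cb, sb, eb in zip(b["chrom"], b["start"], b["end"]):
                    if ca == cb and min(ea, eb) - max(sa, sb) >= 0.5 * (ea - sa):
                        brute[i] = True
            np.testing.assert_array_equal(got, brute)

    def test_venn_counts(self):
        a = self._df([("chr1", 0, 100), ("chr1", 1000, 1100)])
        b = self._df([("chr1", 0, 100)])
        v = venn_counts(a, b, f=0.5)
        assert (v["a_only"], v["b_only"], v["a_and_b"]) == (1, 0, 1)


class TestEnrichment:
    def _setup(self):
        genome = GenomeDefinition(
            (("chr1", 500_000),), {"pericentric": [("chr1", 0, 200_000)]}
        )
        grid = make_windows(genome, 100_000, 100_000)
        return genome, grid

    def test_all_calls_inside_annotation(self):
        genome, grid = self._setup()
        called = np.array([True, True, False, False, False])
        e = annotation_enrichment(grid, called, genome, "pericentric")
        assert e["frac_calls_in_annotation"] == 1.0
        assert e["frac_annotated_called"] == 1.0

    def test_no_calls(self):
        genome, grid = self._setup()
        e = annotation_enrichment(grid, np.zeros(5, bool), genome, "pericentric")
        assert e["frac_annotated_called"] == 0.0
        assert e["frac_calls_in_annotation"] == 0.0

    def test_empty_annotation_error(self):
        genome, grid = self._setup()
        with pytest.raises(KeyError):
            annotation_enrichment(grid, np.zeros(5, bool), genome, "nope")


class TestResultsObject:
    def test_summary_text_and_counts(self):
        rng = np.random.default_rng(8)
        genome = GenomeDefinition((("chr1", 2_000_000),))
        grid = make_windows(genome, 100_000, 100_000)
        a = rng.normal(0.5, 0.05, (20, 3))
        b = rng.normal(0.0, 0.05, (20, 3))
        res = DifferentialRTModel(a, b, grid=grid, conditions=("wing", "follicle")).fit()
        text = res.summary()
        assert "wing vs follicle" in text and "prior df" in text
        cs = res.call_summary()
        assert cs["n_advanced"] == 20  # huge planted shift, all called
        assert cs["n_total"] == 20

    def test_adjusted_p_geq_raw(self):
        rng = np.random.default_rng(9)
        res = DifferentialRTModel(rng.normal(size=(50, 3)), rng.normal(size=(50, 3))).fit()
        assert (res.p_adj >= res.p - 1e-12).all()
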