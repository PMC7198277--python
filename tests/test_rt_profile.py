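"""RT values, quantile normalization, LOESS smoothing, correlation matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from replitime import (
    GenomeDefinition,
    RTProgram,
    SimulationConfig,
    CoverageTable,
    correlation_matrix,
    loess_profile,
    make_windows,
    pooled_g1_pairing,
    quantile_normalize,
    rt_values,
    simulate_reads,
)
from replitime.rtprofile import _loess_1d

from conftest import coverage_from_counts


def simple_cov(grid, s_counts, g1_counts, total_s=1000, total_g1=1000):
    return coverage_from_counts(
        grid,
        {"c_S_1": s_counts, "c_G1_1": g1_counts},
        [("c_S_1", "c", "S", 1, total_s), ("c_G1_1", "c", "G1", 1, total_g1)],
    )


class TestRTValues:
    def test_equal_rpm_gives_zero(self, uniform_grid):
        n = len(uniform_grid)
        cov = simple_cov(uniform_grid, np.full(n, 10), np.full(n, 10))
        rt = rt_values(cov, {"c_S_1": "c_G1_1"})
        np.testing.assert_allclose(rt.values["c_S_1"], 0.0)

    def test_double_rpm_gives_one(self, uniform_grid):
        n = len(uniform_grid)
        cov = simple_cov(uniform_grid, np.full(n, 20), np.full(n, 10))
        rt = rt_values(cov, {"c_S_1": "c_G1_1"})
        np.testing.assert_allclose(rt.values["c_S_1"], 1.0)

    def test_missing_pairing_error(self, uniform_grid):
        n = len(uniform_grid)
        cov = simple_cov(uniform_grid, np.full(n, 1), np.full(n, 1))
        with pytest.raises(ValueError, match="pairing"):
            rt_values(cov, {})

    def test_zero_windows_masked_and_logged(self, uniform_grid):
        n = len(uniform_grid)
        g1 = np.full(n, 10)
        g1[3] = 0
        cov = simple_cov(uniform_grid, np.full(n, 10), g1)
        rt = rt_values(cov, {"c_S_1": "c_G1_1"})
        assert rt.n_masked == 1 and len(rt.values) == n - 1
        assert 3 not in rt.values.index
        with pytest.raises(ValueError, match="zero"):
            rt_values(cov, {"c_S_1": "c_G1_1"}, mask_zero=False)

    def test_condition_average_is_exact_column_mean(self, uniform_grid):
        n = len(uniform_grid)
        rng = np.random.default_rng(0)
        cov = coverage_from_counts(
            uniform_grid,
            {"c_S_1": rng.integers(5, 50, n), "c_S_2": rng.integers(5, 50, n),
             "c_G1_1": np.full(n, 20)},
            [("c_S_1", "c", "S", 1, 1000), ("c_S_2", "c", "S", 2, 1000),
             ("c_G1_1", "c", "G1", 1, 1000)],
        )
        rt = rt_values(cov, pooled_g1_pairing(cov))
        np.testing.assert_allclose(
            rt.condition_mean("c"), rt.values.mean(axis=1).to_numpy()
        )

    def test_planted_timing_contrast(self):
        """t=0.5 vs t=1.0 regions differ by log2(1.5) ~ 0.585 at depth."""
        genome = GenomeDefinition((("chr1", 2_000_000),))
        program = RTProgram(
            "wt", (("chr1", 0, 1_000_000, 0.5), ("chr1", 1_000_000, 2_000_000, 1.0))
        )
        cfg = SimulationConfig(library_size=2_000_000, replicates=3, seed=21)
        reads = simulate_reads(genome, program, cfg)
        grid = make_windows(genome, 100_000, 100_000)
        cov = CoverageTable.from_read_sets(reads, grid)
        rt = rt_values(cov, pooled_g1_pairing(cov))
        mean = rt.condition_mean("wt")
        starts = rt.windows["start"].to_numpy()
        contrast = mean[starts < 1_000_000].mean() - mean[starts >= 1_000_000].mean()
        assert contrast == pytest.approx(np.log2(1.5), abs=0.05)


class TestQuantileNormalize:
    def test_hand_computed_case(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_fixed_point(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_ties_get_mean_reference(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2.5, 5.5]
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx(ref[:2].mean())

    @given(
        arrays(np.float64, (10, 3), unique=True,
               elements=st.floats(-50, 50, allow_nan=False, width=32))
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sorted_identical_and_idempotent_tie_free(self, arr):
        # ties are handled by rank-span averaging, which (as in the standard
        # algorithm) breaks the identical-sorted-multiset / idempotence
        # properties for tied columns; continuous RT values are tie-free
        df = pd.DataFrame(arr, columns=list("abc"))
        out = quantile_normalize(df)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 3):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-9)
        again = quantile_normalize(out)
        np.testing.assert_allclose(again.to_numpy(), out.to_numpy(), atol=1e-9)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        out = quantile_normalize(df)
        for c in df:
            np.testing.assert_array_equal(
                np.argsort(df[c].to_numpy()), np.argsort(out[c].to_numpy())
            )

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


def rt_table_from_values(grid, values, condition="c"):
    from replitime import RTTable

    df = pd.DataFrame({f"{condition}_S_1": values})
    return RTTable(grid, df, {f"{condition}_S_1": condition})


class TestLoess:
    def test_constant_reproduced(self, uniform_grid):
        rt = rt_table_from_values(uniform_grid, np.full(len(uniform_grid), 0.7))
        prof = loess_profile(rt, column="c_S_1", bandwidth=150_000)
        np.testing.assert_allclose(prof.data["value"], 0.7)

    def test_linear_reproduced(self, uniform_grid):
        mid = uniform_grid.midpoints.astype(float)
        rt = rt_table_from_values(uniform_grid, mid / 1e6)
        prof = loess_profile(rt, column="c_S_1", bandwidth=150_000)
        chr1 = prof.chrom("chr1")  # chr2 has one window and is skipped
        expect = mid[:len(chr1)] / 1e6
        np.testing.assert_allclose(chr1["value"], expect, rtol=1e-9)

    def test_step_function_against_wls_oracle(self):
        x = np.arange(0.0, 40.0)
        y = np.where(x < 20, 0.0, 1.0)
        bw = 8.0
        got = _loess_1d(x, y, x, bw)

        def wls(x0):
            w = np.clip(1 - (np.abs(x - x0) / bw) ** 3, 0, None) ** 3
            X = np.stack([np.ones_like(x), x - x0], axis=1)
            beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
            return beta[0]

        for x0 in (10.0, 19.0, 21.0):
            assert got[int(x0)] == pytest.approx(wls(x0), abs=1e-12)
        # monotone through the step, bounded by the data range
        assert np.all(np.diff(got[15:25]) >= -1e-12)
        assert got.min() >= 0.0 and got.max() <= 1.0

    def test_bandwidth_below_step_rejected(self, uniform_grid):
        rt = rt_table_from_values(uniform_grid, np.zeros(len(uniform_grid)))
        with pytest.raises(ValueError, match="bandwidth"):
            loess_profile(rt, column="c_S_1", bandwidth=5_000)


class TestCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=30)
        df = pd.DataFrame({"a": v, "b": -v})
        corr = correlation_matrix(df)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_too_few_windows_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="3"):
            correlation_matrix(df)

    def test_exclusion_mask_applied(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=40)
        df = pd.DataFrame({"a": base.copy(), "b": base.copy()})
        df.loc[:4, "b"] *= -1  # disagreement confined to masked rows
        mask = np.ones(40, dtype=bool)
        mask[:5] = False
        corr = correlation_matrix(df, include=mask)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_replicates_at_default_noise_correlate(self):
        """Two S replicates under the default noise model correlate >= 0.9."""
        genome = GenomeDefinition((("chr1", 5_000_000),))
        program = RTProgram.random_blocks(genome, 100_000, seed=7, condition="wt")
        cfg = SimulationConfig(library_size=1_000_000, replicates=2, seed=8)
        reads = simulate_reads(genome, program, cfg)
        grid = make_windows(genome, 100_000, 100_000)
        cov = CoverageTable.from_read_sets(reads, grid)
        rt = rt_values(cov, pooled_g1_pairing(cov))
        corr = correlation_matrix(rt)
        assert corr.loc["wt_S_1", "wt_S_2"] >= 0.9
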