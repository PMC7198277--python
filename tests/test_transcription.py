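"""Transcript simulation truth, differential expression, TPM classes,
window assignment schemes, RT/expression concordance."""

import numpy as np
import pandas as pd
import pytest

from replitime import (
    GenomeDefinition,
    SimulationConfig,
    TranscriptExpressionSpec,
    assign_to_windows,
    classify_expression,
    differential_expression,
    make_windows,
    rt_expression_concordance,
    simulate_transcripts,
    tpm,
)


@pytest.fixture(scope="module")
def genome():
    return GenomeDefinition((("chr1", 2_000_000),))


class TestSimulateTranscripts:
    def test_truth_labels(self, genome):
        spec = TranscriptExpressionSpec(n_transcripts=200)
        tx, counts = simulate_transcripts(
            genome, spec, SimulationConfig(replicates=3, seed=1), conditions=("A", "B")
        )
        a_cols = [c for c in counts.columns if c.startswith("A_")]
        b_cols = [c for c in counts.columns if c.startswith("B_")]
        a_spec = tx["true_class"] == "A_specific"
        assert (counts.loc[a_spec.to_numpy(), b_cols].to_numpy() == 0).all()
        shared = tx["true_class"] == "shared"
        assert np.allclose(tx.loc[shared, "true_log2fc"], 0.0)
        assert np.isposinf(tx.loc[a_spec, "true_log2fc"]).all()

    def test_dispersion_validated(self):
        with pytest.raises(ValueError):
            TranscriptExpressionSpec(dispersion=0.0)

    def test_null_logfc_estimates_unbiased(self, genome):
        """200 null transcripts: mean estimated log FC within 3 SE of 0."""
        spec = TranscriptExpressionSpec(
            n_transcripts=200, frac_a_specific=0, frac_b_specific=0, frac_de=0
        )
        tx, counts = simulate_transcripts(
            genome, spec, SimulationConfig(replicates=3, seed=2)
        )
        a = counts[[c for c in counts.columns if c.startswith("A_")]]
        b = counts[[c for c in counts.columns if c.startswith("B_")]]
        de = differential_expression(a, b)
        se = de["log_fc"].std() / np.sqrt(len(de))
        assert abs(de["log_fc"].mean()) < 3 * se


class TestDifferentialExpression:
    def test_identical_columns_null(self):
        counts = pd.DataFrame({"r1": [10, 200, 3000], "r2": [12, 180, 3100],
                               "r3": [9, 220, 2900]})
        de = differential_expression(counts, counts)
        np.testing.assert_allclose(de["log_fc"], 0.0)
        np.testing.assert_allclose(de["p"], 1.0)

    def test_null_nb_type_i_error(self):
        """200-transcript null NB draws: mean p<0.05 fraction ~ 0.05 +- 0.02."""
        rng = np.random.default_rng(3)
        r, mean = 10.0, 500.0
        p = r / (r + mean)
        fracs = []
        for _ in range(10):
            a = pd.DataFrame(rng.negative_binomial(r, p, (200, 3)))
            b = pd.DataFrame(rng.negative_binomial(r, p, (200, 3)))
            de = differential_expression(a, b)
            fracs.append((de["p"] < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_planted_fourfold_change_recovered(self):
        """A 4-fold planted subset recovers log FC ~ 2 relative to the null
        background (CPM is relative, so the global offset cancels in the
        planted-minus-null contrast)."""
        rng = np.random.default_rng(4)
        r = 20.0
        n, n_de = 500, 25
        mean = np.full(n, 1000.0)
        mean_a = mean.copy()
        mean_a[:n_de] *= 4
        a = pd.DataFrame(rng.negative_binomial(r, r / (r + mean_a), (3, n)).T)
        b = pd.DataFrame(rng.negative_binomial(r, r / (r + mean), (3, n)).T)
        de = differential_expression(a, b)
        contrast = de["log_fc"][:n_de].mean() - de["log_fc"][n_de:].mean()
        assert contrast == pytest.approx(2.0, abs=0.15)

    def test_zero_library_rejected(self):
        z = pd.DataFrame(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="library"):
            differential_expression(z, z)


class TestTPMAndClasses:
    def test_tpm_columns_sum_to_million(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.integers(0, 1000, (50, 4)))
        lengths = rng.integers(200, 5000, 50)
        t = tpm(counts, lengths)
        np.testing.assert_allclose(t.sum(axis=0), 1e6)

    def test_classification_invariant_to_library_scaling(self):
        counts_a = pd.DataFrame({"r1": [10, 0, 5, 0]})
        counts_b = pd.DataFrame({"r1": [10, 3, 0, 0]})
        lengths = [1000, 1000, 1000, 1000]
        c1 = classify_expression(tpm(counts_a, lengths), tpm(counts_b, lengths))
        c2 = classify_expression(tpm(counts_a * 10, lengths), tpm(counts_b * 10, lengths))
        pd.testing.assert_series_equal(c1, c2)

    @pytest.mark.parametrize(
        "a,b,expected",
        [(5.0, 0.0, "A_specific"), (1.0, 1.0, "shared"),
         (0.0, 2.0, "B_specific"), (0.0, 0.0, "silent")],
    )
    def test_classes(self, a, b, expected):
        cls = classify_expression(pd.DataFrame({"r": [a]}), pd.DataFrame({"r": [b]}))
        assert cls.iloc[0] == expected


def tx_frame(rows):
    return pd.DataFrame(
        rows, columns=["transcript_id", "chrom", "start", "end", "log_fc", "p", "p_adj"]
    )


class TestAssignToWindows:
    def _grid(self):
        return make_windows(GenomeDefinition((("chr1", 100_000),)), 10_000, 10_000)

    def test_mean_of_opposite_lfc_is_zero(self):
        tx = tx_frame([("t1", "chr1", 1000, 3000, 1.0, 0.5, 0.6),
                       ("t2", "chr1", 2000, 4000, -1.0, 0.5, 0.6)])
        out = assign_to_windows(tx, self._grid(), scheme="mean_lfc")
        row = out[out["start"] == 0].iloc[0]
        assert row["log_fc"] == pytest.approx(0.0) and row["n_transcripts"] == 2

    def test_max_abs_tie_broken_by_p_then_id(self):
        tx = tx_frame([("t2", "chr1", 1000, 3000, 1.0, 0.3, 0.4),
                       ("t1", "chr1", 2000, 4000, -1.0, 0.3, 0.4),
                       ("t3", "chr1", 2500, 4500, -1.0, 0.2, 0.4)])
        out = assign_to_windows(tx, self._grid(), scheme="max_abs_lfc")
        # |lfc| all equal; t3 has the smallest p
        assert out[out["start"] == 0].iloc[0]["log_fc"] == -1.0
        tx2 = tx_frame([("t2", "chr1", 1000, 3000, 1.0, 0.3, 0.4),
                        ("t1", "chr1", 2000, 4000, -1.0, 0.3, 0.4)])
        out2 = assign_to_windows(tx2, self._grid(), scheme="max_abs_lfc")
        assert out2[out2["start"] == 0].iloc[0]["log_fc"] == -1.0  # id "t1" < "t2"

    def test_lowest_p_matches_bruteforce_argmin(self):
        rng = np.random.default_rng(6)
        rows = []
        for i in range(60):
            start = int(rng.integers(0, 95_000))
            rows.append((f"t{i:03d}", "chr1", start, start + int(rng.integers(500, 8000)),
                         float(rng.normal()), float(rng.uniform()), float(rng.uniform())))
        tx = tx_frame(rows)
        grid = self._grid()
        out = assign_to_windows(tx, grid, scheme="lowest_p").set_index("start")
        for _, w in grid.windows.iterrows():
            hits = tx[(tx["start"] < w["end"]) & (tx["end"] > w["start"])]
            if hits.empty:
                assert w["start"] not in out.index
            else:
                best = hits.sort_values(["p", "transcript_id"]).iloc[0]
                assert out.loc[w["start"], "log_fc"] == best["log_fc"]

    def test_windows_without_transcripts_absent(self):
        tx = tx_frame([("t1", "chr1", 1000, 2000, 1.0, 0.5, 0.5)])
        out = assign_to_windows(tx, self._grid(), scheme="mean_lfc")
        assert set(out["start"]) == {0}

    def test_schemes_agree_on_single_transcript_windows(self):
        tx = tx_frame([("t1", "chr1", 15_000, 16_000, 0.8, 0.1, 0.2)])
        grid = self._grid()
        vals = [
            assign_to_windows(tx, grid, scheme=s).iloc[0]["log_fc"]
            for s in ("mean_lfc", "lowest_p", "max_abs_lfc")
        ]
        assert vals == [0.8, 0.8, 0.8]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            assign_to_windows(tx_frame([]), self._grid(), scheme="median")


class TestConcordance:
    def _fine(self, n, calls, log_fc):
        return pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * 10_000,
             "end": (np.arange(n) + 1) * 10_000, "log_fc": log_fc, "call": calls}
        )

    def _tx(self, n, log_fc, p):
        starts = np.arange(n) * 10_000 + 2_000
        return pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(n)], "chrom": "chr1",
             "start": starts, "end": starts + 1_000, "log_fc": log_fc, "p": p,
             "p_adj": p}
        )

    def test_no_significant_transcripts_all_without(self):
        fine = self._fine(10, ["advanced"] * 5 + ["delayed"] * 5, 0.5)
        tx = self._tx(10, 1.0, 0.9)  # nothing significant
        out = rt_expression_concordance(tx, fine)
        assert out["crosstab"]["advanced"]["frac_without"] == 1.0
        assert out["crosstab"]["delayed"]["frac_without"] == 1.0

    def test_independent_changes_uncorrelated(self):
        rng = np.random.default_rng(7)
        n = 600
        fine = self._fine(n, ["ns"] * n, rng.normal(size=n))
        tx = self._tx(n, rng.normal(size=n), rng.uniform(size=n))
        out = rt_expression_concordance(tx, fine)
        assert abs(out["correlation"]) < 0.1
        assert out["n_windows_with_transcript"] == n

    def test_coupled_changes_positively_correlated(self):
        rng = np.random.default_rng(8)
        n = 300
        rt_lfc = rng.normal(size=n)
        fine = self._fine(n, ["ns"] * n, rt_lfc)
        tx = self._tx(n, 2 * rt_lfc + rng.normal(0, 0.3, n), rng.uniform(size=n))
        out = rt_expression_concordance(tx, fine)
        assert out["correlation"] > 0.8
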