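"""Fingerprint summarization, selection rules and pathway enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metadyn import fingerprint as fp


def _fc_frame(records):
    return pd.DataFrame(
        records,
        columns=["ion", "cell_line", "treatment", "time_h", "log2fc", "pvalue"],
    )


class TestSummarize:
    def test_max_abs_keeps_sign(self):
        fc = _fc_frame(
            [
                ("i", "A", "D", 24.0, 0.5, 0.5),
                ("i", "A", "D", 48.0, -2.0, 0.01),
                ("i", "A", "D", 72.0, 1.0, 0.2),
            ]
        )
        tab = fp.summarize_across_lines(fc, "D")
        assert tab.loc["i", "median_max_fc"] == -2.0
        assert tab.loc["i", "combined_p"] == pytest.approx(0.01)

    def test_median_and_sd_across_lines(self):
        fc = _fc_frame(
            [("i", ln, "D", 24.0, -2.0, 0.5) for ln in ("A", "B", "C")]
        )
        tab = fp.summarize_across_lines(fc, "D")
        assert tab.loc["i", "median_max_fc"] == -2.0
        assert tab.loc["i", "sd_max_fc"] == 0.0
        assert tab.loc["i", "n_lines"] == 3

    def test_combined_p_is_product_of_minima(self):
        fc = _fc_frame(
            [
                ("i", "A", "D", 24.0, 1.0, 1e-4),
                ("i", "B", "D", 24.0, 1.0, 1e-3),
                ("i", "C", "D", 24.0, 1.0, 1e-5),
            ]
        )
        tab = fp.summarize_across_lines(fc, "D")
        assert tab.loc["i", "combined_p"] == pytest.approx(1e-12)

    def test_line_order_invariance(self):
        records = [
            ("i", ln, "D", t, f, p)
            for ln, f, p in (("A", 1.5, 0.01), ("B", -0.5, 0.2), ("C", 2.5, 0.001))
            for t, (f, p) in {24.0: (f, p), 48.0: (f / 2, p * 2)}.items()
        ]
        fc = _fc_frame(records)
        tab1 = fp.summarize_across_lines(fc, "D")
        tab2 = fp.summarize_across_lines(fc.iloc[::-1], "D")
        pd.testing.assert_frame_equal(tab1, tab2)

    def test_absolute_mode(self):
        fc = _fc_frame(
            [
                ("i", "A", "D", 24.0, -2.0, 0.1),
                ("i", "B", "D", 24.0, 2.0, 0.1),
            ]
        )
        signed = fp.summarize_across_lines(fc, "D")
        absolute = fp.summarize_across_lines(fc, "D", absolute=True)
        assert signed.loc["i", "median_max_fc"] == 0.0
        assert absolute.loc["i", "median_max_fc"] == 2.0


class TestSelection:
    @pytest.mark.parametrize(
        "fc_val,p_val,selected",
        [
            (-2.0, 1e-12, True),
            (0.9, 1e-20, False),  # fold-change cut fails
            (1.0, 1e-10, True),  # boundary inclusive
            (2.0, 1e-9, False),  # p cut fails
        ],
    )
    def test_conserved_cuts(self, fc_val, p_val, selected):
        tab = pd.DataFrame(
            {"median_max_fc": [fc_val], "combined_p": [p_val],
             "sd_max_fc": [0.0], "n_lines": [3]},
            index=["i"],
        )
        assert ("i" in fp.select_conserved(tab)) is selected

    def test_conserved_monotone_in_cuts(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(
            {
                "median_max_fc": rng.normal(0, 2, 50),
                "combined_p": 10.0 ** rng.uniform(-20, 0, 50),
                "sd_max_fc": 0.0,
                "n_lines": 3,
            },
            index=[f"i{k}" for k in range(50)],
        )
        tight = set(fp.select_conserved(tab, fc_cut=1.5, p_cut=1e-12))
        loose = set(fp.select_conserved(tab, fc_cut=1.0, p_cut=1e-10))
        assert tight <= loose

    def test_variable_selection(self):
        tab = pd.DataFrame(
            {
                "median_max_fc": [0.0, 1.5, 0.0, 0.5],
                "combined_p": [0.5] * 4,
                "sd_max_fc": [0.0, np.std([0, 3], ddof=1), 1.5, np.nan],
                "n_lines": [3, 2, 3, 1],
            },
            index=list("abcd"),
        )
        got = set(fp.select_variable(tab))
        assert got == {"b", "c"}  # sd 2.12 and the inclusive boundary 1.5
        # a 3-unit response in one of five lines stays below the 1.5 cut
        assert np.std([3, 0, 0, 0, 0], ddof=1) == pytest.approx(1.3416, abs=1e-4)


def _brute_force_hypergeom(k, K, n, N):
    """Exhaustive enumeration over all outcomes of drawing n from N."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return hits / total


class TestEnrichment:
    def test_exact_small_case(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        assert fp.hypergeom_pvalue(4, 5, 4, 10) == pytest.approx(
            5 / 210, abs=1e-12
        )

    def test_k_zero_is_certain(self):
        assert fp.hypergeom_pvalue(0, 5, 4, 10) == 1.0

    def test_degenerate_full_overlap(self):
        assert fp.hypergeom_pvalue(4, 4, 4, 4) == 1.0

    def test_matches_enumeration_everywhere(self):
        """All (N<=12, K, n, k) configurations vs the counting oracle."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert fp.hypergeom_pvalue(k, K, n, N) == pytest.approx(
                            _brute_force_hypergeom(k, K, n, N), abs=1e-12
                        )

    def test_enrich_pathways_table(self):
        universe = {f"m{k}" for k in range(10)}
        selected = {"m0", "m1", "m2", "m3"}
        pws = [
            fp.PathwaySet("p1", "hit set", frozenset({"m0", "m1", "m2", "m3", "m4"})),
            fp.PathwaySet("p2", "miss set", frozenset({"m5", "m6", "m7"})),
            fp.PathwaySet("p3", "outside", frozenset({"zzz"})),
        ]
        res = fp.enrich_pathways(selected, universe, pws, q_cut=0.05)
        assert list(res["pathway"]) == ["p1", "p2"]  # p3 skipped (K=0)
        top = res.iloc[0]
        assert (top["k"], top["K"], top["n"], top["N"]) == (4, 5, 4, 10)
        assert top["p"] == pytest.approx(5 / 210)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            fp.enrich_pathways(set(), set(), [])

    def test_selected_outside_universe_errors(self):
        with pytest.raises(ValueError):
            fp.enrich_pathways({"x"}, {"y"}, [])


class TestAdjustment:
    def test_single_p_unchanged(self):
        assert fp.adjust_pvalues([0.01])[0] == pytest.approx(0.01)

    def test_bh_step_up_arithmetic(self):
        qs = fp.adjust_pvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(qs, [0.04, 0.04, 0.04, 0.04])

    def test_bh_q_monotone_and_geq_p(self):
        rng = np.random.default_rng(8)
        ps = rng.uniform(1e-6, 1, 200)
        qs = fp.adjust_pvalues(ps, method="bh")
        assert (qs >= ps - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(qs[order]) >= -1e-12).all()

    def test_storey_pi0_near_one_under_null(self):
        rng = np.random.default_rng(10)
        ps = rng.uniform(size=1000)
        qs = fp.adjust_pvalues(ps, method="storey")
        # under a uniform null, q ~= p * m / rank, i.e. pi0 ~= 1
        bh = fp.adjust_pvalues(ps, method="bh")
        ratio = np.median(qs / bh)
        assert 0.9 <= ratio <= 1.1

    def test_storey_fallback_below_100_tests(self):
        with pytest.warns(UserWarning, match="fewer than 100"):
            qs = fp.adjust_pvalues([0.01, 0.5], method="storey")
        np.testing.assert_allclose(
            qs, fp.adjust_pvalues([0.01, 0.5], method="bh")
        )

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fp.adjust_pvalues([0.0, 0.5])


def test_null_pipeline_selects_nothing():
    """Under the no-effect null, the conserved cuts select ~0 of 300 ions."""
    rng = np.random.default_rng(77)
    records = []
    for ion in range(300):
        for ln in "ABCDE":
            for t in (24.0, 48.0, 72.0, 96.0):
                x = rng.normal(0, 0.125, 3)
                records.append(
                    (
                        f"i{ion}", ln, "D", t,
                        float(np.mean(x)),
                        float(stats.ttest_1samp(x, 0).pvalue),
                    )
                )
    fc = _fc_frame(records)
    tab = fp.summarize_across_lines(fc, "D")
    assert len(fp.select_conserved(tab)) == 0
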