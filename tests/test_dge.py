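import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from eodkit import dge
from eodkit.dge import (
    CONTRASTS,
    DGEError,
    bh_fdr,
    classify_patterns,
    fc_from_log2fc,
    filter_degs,
    pct_half_up,
    run_contrasts,
    sample_correlation,
    simple_de,
    summarize_contrasts,
    tmm_factors,
    tmm_normalize,
)
from eodkit.synth import ExprSimParams, PlantedDEG, gene_names, simulate_counts


def bh_oracle(p):
    """Definition-based step-up: adjusted p_i = min over j>=i (ranked) of
    p_(j)*n/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    out = np.empty(n)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j]] * n / (j + 1) for j in range(rank_pos - 1, n)
        ]
        out[idx] = min(1.0, min(candidates))
    return out


class TestTMM:
    def test_identical_columns_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, 300)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        np.testing.assert_allclose(tmm_factors(counts), 1.0, atol=1e-12)

    def test_pure_depth_difference_normalizes_away(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(100, 500) + 1
        counts = pd.DataFrame({"a": col, "b": 2 * col, "c": col})
        factors, expr = tmm_normalize(counts)
        np.testing.assert_allclose(factors, 1.0, atol=1e-9)
        # equal up to the prior count (0.5 against a 2x library)
        np.testing.assert_allclose(expr["a"], expr["b"], atol=0.01)

    def test_matches_bruteforce_trimmed_weighted_mean(self):
        # 20-gene toy with one heavily spiked gene in sample b
        rng = np.random.default_rng(2)
        a = rng.poisson(100, 20) + 1
        b = a.copy()
        b[0] *= 40
        counts = pd.DataFrame({"a": a, "b": b})
        factors = tmm_factors(counts, ref_sample="a")

        # brute-force evaluation of the trimmed weighted mean of M
        na, nb = a.sum(), b.sum()
        m = np.log2((b / nb) / (a / na))
        aa = 0.5 * np.log2((b / nb) * (a / na))
        w = (nb - b) / (nb * b) + (na - a) / (na * a)
        lo_m, hi_m = np.quantile(m, [0.3, 0.7])
        lo_a, hi_a = np.quantile(aa, [0.05, 0.95])
        sel = (m >= lo_m) & (m <= hi_m) & (aa >= lo_a) & (aa <= hi_a)
        raw_b = 2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1 / w[sel]))
        expected = pd.Series({"a": 1.0, "b": raw_b})
        expected /= np.exp(np.log(expected).mean())
        np.testing.assert_allclose(factors, expected, rtol=1e-12)
        # the spike inflates b's library, so the other genes look diluted
        # and the composition correction pulls b's factor below 1
        assert factors["b"] < 1.0

    def test_single_sample_rejected(self):
        with pytest.raises(DGEError):
            tmm_factors(pd.DataFrame({"a": [1, 2, 3]}))

    def test_disjoint_sample_warns_factor_one(self):
        counts = pd.DataFrame(
            {"a": [10, 20, 0, 0], "b": [0, 0, 30, 40], "c": [10, 20, 0, 0]}
        )
        with pytest.warns(UserWarning, match="no expressed genes"):
            f = tmm_factors(counts, ref_sample="a")
        assert f["b"] == pytest.approx(f["a"])  # geometric-mean rescaled


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 7), 0.2)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = rng.integers(1, 13)
            p = rng.uniform(0, 1, n)
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DGEError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(DGEError):
            bh_fdr([-0.1])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    @settings(max_examples=100, deadline=None)
    def test_property_matches_oracle(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), bh_oracle(pvals), atol=1e-12)


class TestSimpleDE:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.poisson(60, size=(400, 8)),
            index=gene_names(400),
            columns=[f"control_{i}" for i in range(4)] + [f"T8day_{i}" for i in range(4)],
        )
        table = simple_de(counts, [f"control_{i}" for i in range(4)], [f"T8day_{i}" for i in range(4)])
        assert table["pvalue"].min() > 1e-4  # no real signal
        assert abs(table["log2fc"]).median() < 0.3

    def test_orientation_positive_means_up_in_b(self):
        rng = np.random.default_rng(11)
        flat = rng.poisson(50, size=(200, 4))
        counts = pd.DataFrame(
            np.vstack([[100, 110, 800, 820], flat]),
            index=["up_gene"] + [f"flat{i}" for i in range(200)],
            columns=["control_1", "control_2", "T8day_1", "T8day_2"],
        )
        table = simple_de(counts, ["control_1", "control_2"], ["T8day_1", "T8day_2"])
        assert table.loc["up_gene", "log2fc"] > 2.0
        # and the reverse orientation flips the sign
        rev = simple_de(counts, ["T8day_1", "T8day_2"], ["control_1", "control_2"])
        assert rev.loc["up_gene", "log2fc"] < -2.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.negative_binomial(10, 10 / (10 + 50), size=(3000, 13)),
            index=gene_names(3000),
            columns=[f"control_{i}" for i in range(6)] + [f"T8day_{i}" for i in range(7)],
        )
        table = simple_de(
            counts,
            [f"control_{i}" for i in range(6)],
            [f"T8day_{i}" for i in range(7)],
        )
        # Welch t on discrete counts is approximate; KS at alpha=0.01 with
        # a light tolerance via subsampling independence
        assert sps.kstest(table["pvalue"], "uniform").pvalue > 1e-4

    def test_planted_gene_recovered_across_seeds(self):
        hits = 0
        n_seeds = 15
        gene = gene_names(1500)[3]
        for seed in range(n_seeds):
            params = ExprSimParams(
                n_genes=1500,
                planted_degs={gene: PlantedDEG("broad", "up", 6.0)},
                dispersion=0.1,
                seed=seed,
            )
            sim = simulate_counts(params)
            tables = run_contrasts(sim.counts, sim.treatments)
            calls = filter_degs(tables["control_vs_T8day"])
            hits += calls[gene] == "up"
        assert hits == n_seeds

    def test_too_small_groups_rejected(self):
        counts = pd.DataFrame({"a_1": [1], "a_2": [2], "b_1": [3]})
        with pytest.raises(DGEError):
            simple_de(counts, ["a_1", "a_2"], ["b_1"])


class TestFilterAndClassify:
    def _table(self, rows):
        return pd.DataFrame(
            [
                {"gene": g, "log2fc": lfc, "pvalue": 0.0, "fdr": fdr, "mean_expr": 5.0}
                for g, lfc, fdr in rows
            ]
        ).set_index("gene")

    def test_paper_boundary_cases(self):
        table = self._table(
            [
                ("fc4.12", np.log2(4.12), 1e-5),  # above both bounds -> up
                ("fc3.9", np.log2(3.9), 1e-9),  # below FC bound -> ns
                ("fc4.00", np.log2(4.0), 1e-5),  # FC bound inclusive -> up
                ("fdr_at_bound", np.log2(8.0), 0.001),  # FDR bound strict -> ns
                ("down", -np.log2(6.0), 1e-5),
            ]
        )
        calls = filter_degs(table, min_fc=4, max_fdr=0.001)
        assert calls.to_dict() == {
            "fc4.12": "up",
            "fc3.9": "ns",
            "fc4.00": "up",
            "fdr_at_bound": "ns",
            "down": "down",
        }

    def test_full_boundary_grid_matches_predicate(self):
        fcs = [2.0, 4.0, 8.0, -2.0, -4.0, -8.0, 0.0]
        fdrs = [1e-6, 0.001, 0.5]
        rows = [
            (f"g{i}", np.log2(abs(fc)) * np.sign(fc) if fc else 0.0, fdr)
            for i, (fc, fdr) in enumerate(itertools.product(fcs, fdrs))
        ]
        table = self._table(rows)
        calls = filter_degs(table, min_fc=4, max_fdr=0.001)
        for (fc, fdr), (g, lfc, _) in zip(itertools.product(fcs, fdrs), rows):
            if fdr < 0.001 and lfc >= 2.0:
                expected = "up"
            elif fdr < 0.001 and lfc <= -2.0:
                expected = "down"
            else:
                expected = "ns"
            assert calls[g] == expected, (fc, fdr)

    @given(
        st.floats(min_value=1.0, max_value=8.0),
        st.floats(min_value=1e-6, max_value=0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_filter_monotone_in_thresholds(self, min_fc, max_fdr):
        rng = np.random.default_rng(17)
        table = self._table(
            [(f"g{i}", rng.normal(0, 3), rng.uniform(0, 0.1)) for i in range(40)]
        )
        strict = filter_degs(table, min_fc=min_fc, max_fdr=max_fdr)
        loose = filter_degs(table, min_fc=max(1.0, min_fc / 2), max_fdr=min(1.0, max_fdr * 2))
        for g in table.index:
            if strict[g] != "ns":
                assert loose[g] == strict[g]

    def test_classify_covers_all_27_triples(self):
        states = ["up", "down", "ns"]
        triples = list(itertools.product(states, repeat=3))
        genes = [f"g{i}" for i in range(27)]
        calls = {
            "control_vs_T8day": pd.Series([t[0] for t in triples], index=genes),
            "control_vs_T1day": pd.Series([t[1] for t in triples], index=genes),
            "T1day_vs_T8day": pd.Series([t[2] for t in triples], index=genes),
        }
        out = classify_patterns(calls)
        assert len(out) == 27
        assert out["pattern"].nunique() == 27  # labels are injective
        # conflict iff broad contradicts BOTH granular calls
        for g, (b, e, l) in zip(genes, triples):
            expected = (b == "up" and e == "down" and l == "down") or (
                b == "down" and e == "up" and l == "up"
            )
            assert out.loc[g, "conflict"] == expected

    def test_paper_like_examples(self):
        genes = ["myh6", "xirp1", "acta1b"]
        calls = {
            "control_vs_T8day": pd.Series(["up", "up", "ns"], index=genes),
            "control_vs_T1day": pd.Series(["ns", "up", "down"], index=genes),
            "T1day_vs_T8day": pd.Series(["ns", "ns", "up"], index=genes),
        }
        out = classify_patterns(calls)
        assert out.loc["myh6", "pattern"] == "broad_up"
        assert out.loc["xirp1", "pattern"] == "broad_up+early_up"
        assert out.loc["acta1b", "pattern"] == "early_down+late_up"
        assert not out["conflict"].any()

    def test_missing_contrast_rejected(self):
        with pytest.raises(DGEError, match="missing"):
            classify_patterns({"control_vs_T8day": pd.Series(dtype=object)})


class TestSummaries:
    def test_pct_rounding_half_up(self):
        assert pct_half_up(244, 20887) == 1.17
        assert pct_half_up(98, 20942) == 0.47
        assert pct_half_up(43, 20401) == 0.21
        assert pct_half_up(1, 800) == 0.13  # 0.125 rounds half-up
        assert pct_half_up(0, 100) == 0.0

    def test_side_counts_conserve_totals(self):
        summary = summarize_contrasts(
            side_counts={
                "control_vs_T8day": (96, 148),
                "control_vs_T1day": (34, 64),
                "T1day_vs_T8day": (13, 30),
            },
            n_expressed={
                "control_vs_T8day": 20887,
                "control_vs_T1day": 20942,
                "T1day_vs_T8day": 20401,
            },
        )
        assert summary.loc["control_vs_T8day", "n_deg"] == 244
        assert summary.loc["control_vs_T1day", "n_deg"] == 98
        assert summary.loc["T1day_vs_T8day", "n_deg"] == 43
        assert summary["pct_deg"].tolist() == [1.17, 0.47, 0.21]

    def test_calls_based_summary_conserves(self):
        calls = {
            "control_vs_T8day": pd.Series(
                ["up"] * 5 + ["down"] * 3 + ["ns"] * 12,
                index=[f"g{i}" for i in range(20)],
            )
        }
        summary = summarize_contrasts(calls=calls, n_expressed={"control_vs_T8day": 20})
        row = summary.loc["control_vs_T8day"]
        assert row["n_deg"] == row["n_up_a"] + row["n_up_b"] == 8
        assert row["n_up_b"] == 5  # 'up' = up in the longer-exposure group

    def test_deg_exceeding_expressed_rejected(self):
        with pytest.raises(DGEError, match="exceeds"):
            summarize_contrasts(
                side_counts={"control_vs_T8day": (50, 60)},
                n_expressed={"control_vs_T8day": 100},
            )

    def test_zero_degs(self):
        s = summarize_contrasts(
            side_counts={"control_vs_T8day": (0, 0)},
            n_expressed={"control_vs_T8day": 1000},
        )
        assert s.loc["control_vs_T8day", "pct_deg"] == 0.0


class TestFC:
    def test_signed_linear_fold_change(self):
        assert fc_from_log2fc(2.0) == 4.0
        assert fc_from_log2fc(-2.0) == -4.0
        assert fc_from_log2fc(0.0) == 1.0


class TestSampleCorrelation:
    def test_duplicated_sample_r_one(self):
        rng = np.random.default_rng(8)
        col = rng.poisson(40, 500)
        counts = pd.DataFrame({"a": col, "b": col, "c": rng.poisson(40, 500)})
        r = sample_correlation(counts)
        assert r.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            rng.poisson(30, size=(2000, 5)), columns=list("abcde")
        )
        r = sample_correlation(counts)
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_independent_samples_low_offdiag(self):
        rng = np.random.default_rng(10)
        # independent log-normal expression per sample
        counts = pd.DataFrame(
            rng.poisson(2.0 ** rng.normal(5, 2, size=(2000, 4))),
            columns=list("abcd"),
        )
        r = sample_correlation(counts).to_numpy()
        off = r[~np.eye(4, dtype=bool)]
        assert np.abs(off).mean() < 0.2

    def test_no_passing_genes_errors(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(DGEError, match="pass"):
            sample_correlation(counts, min_count=10)
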