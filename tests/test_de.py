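import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncscreen import de


def _nb_counts(rng, mu, alpha, n):
    mu = np.asarray(mu, dtype=float)[:, None] * np.ones((1, n))
    return rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        c = pd.DataFrame({"s1": [5, 10, 20], "s2": [5, 10, 20]})
        assert np.allclose(de.size_factors_median_of_ratios(c), [1.0, 1.0])

    def test_doubled_sample_closed_form(self):
        # geometric-mean reference splits the factor symmetrically: (1/sqrt2, sqrt2)
        c = pd.DataFrame({"s1": [10, 20, 30, 40], "s2": [20, 40, 60, 80]})
        assert np.allclose(de.size_factors_median_of_ratios(c),
                           [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_sample_unit_factor(self):
        c = pd.DataFrame({"s1": [3, 7, 11]})
        assert np.allclose(de.size_factors_median_of_ratios(c), [1.0])

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(0)
        c = pd.DataFrame(rng.poisson(50, size=(200, 4)) + 1,
                         columns=list("abcd"))
        f = de.size_factors_median_of_ratios(c)
        c2 = c.copy()
        c2["a"] = c2["a"] * 3
        f2 = de.size_factors_median_of_ratios(c2)
        # multiplying one sample's counts by c multiplies its factor by c,
        # relative to the overall rescaling of the geometric reference
        assert np.allclose(f2["a"] / f["a"] / (f2["b"] / f["b"]), 3.0)

    def test_all_zero_gene_everywhere_errors(self):
        c = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError, match="undefined|no gene"):
            de.size_factors_median_of_ratios(c)


class TestDispersion:
    def test_poisson_data_floors_near_zero(self):
        rng = np.random.default_rng(1)
        mu = rng.uniform(20, 500, 2000)
        c = pd.DataFrame(rng.poisson(mu[:, None], size=(2000, 20)),
                         columns=[f"s{i}" for i in range(20)])
        f = pd.Series(1.0, index=c.columns)
        a = de.estimate_dispersion(c, f, [list(c.columns[:10]), list(c.columns[10:])])
        assert np.median(a) <= 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(20, 500, 2000)
        y = _nb_counts(rng, mu, 0.2, 100)
        c = pd.DataFrame(y, columns=[f"s{i}" for i in range(100)])
        f = de.size_factors_median_of_ratios(c)
        a = de.estimate_dispersion(c, f, [list(c.columns[:50]), list(c.columns[50:])])
        assert 0.15 <= np.median(a) <= 0.25

    def test_constant_gene_hits_floor(self):
        c = pd.DataFrame({"s1": [7], "s2": [7], "s3": [7], "s4": [7]})
        f = pd.Series(1.0, index=c.columns)
        a = de.estimate_dispersion(c, f, [["s1", "s2"], ["s3", "s4"]])
        assert a.iloc[0] == de.ALPHA_MIN

    def test_single_sample_group_rejected(self):
        c = pd.DataFrame({"s1": [1], "s2": [2]})
        f = pd.Series(1.0, index=c.columns)
        with pytest.raises(ValueError, match=">= 2 samples"):
            de.estimate_dispersion(c, f, [["s1"], ["s2"]])


class TestWald:
    def test_same_data_both_sides_is_null(self, null_counts):
        counts, ga, _ = null_counts
        both = counts[ga].copy()
        both.columns = [f"{c}_copy" for c in ga]
        merged = pd.concat([counts[ga], both], axis=1)
        f = de.size_factors_median_of_ratios(merged)
        a = de.estimate_dispersion(merged, f, [ga, list(both.columns)])
        res = de.wald_test_two_group(merged, f, a, ga, list(both.columns))
        assert np.allclose(res["log2FoldChange"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_label_swap_negates_lfc_and_stat(self, null_counts):
        counts, ga, gb = null_counts
        f = de.size_factors_median_of_ratios(counts)
        a = de.estimate_dispersion(counts, f, [ga, gb])
        ab = de.wald_test_two_group(counts, f, a, ga, gb)
        ba = de.wald_test_two_group(counts, f, a, gb, ga)
        assert np.allclose(ab["log2FoldChange"], -ba["log2FoldChange"], atol=1e-6)
        assert np.allclose(ab["stat"], -ba["stat"], atol=1e-5)
        assert np.allclose(ab["pvalue"], ba["pvalue"], atol=1e-8)

    def test_planted_lfc_recovered_with_power(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(50, 500, 500)
        lfc = np.zeros(500)
        lfc[:50] = 2.0
        ya = _nb_counts(rng, mu, 0.1, 20)
        yb = _nb_counts(rng, mu * 2.0**lfc, 0.1, 20)
        c = pd.DataFrame(np.hstack([ya, yb]),
                         columns=[f"A{i}" for i in range(20)] + [f"B{i}" for i in range(20)])
        ga, gb = list(c.columns[:20]), list(c.columns[20:])
        f = de.size_factors_median_of_ratios(c)
        a = de.estimate_dispersion(c, f, [ga, gb])
        res = de.wald_test_two_group(c, f, a, ga, gb)
        assert 1.6 <= np.median(res["log2FoldChange"][:50]) <= 2.4
        assert (res["padj"][:50] < 0.15).mean() >= 0.9

    def test_all_zero_gene_gets_na_outside_bh(self, null_counts):
        counts, ga, gb = null_counts
        counts = counts.copy()
        counts.iloc[0] = 0
        f = de.size_factors_median_of_ratios(counts)
        a = de.estimate_dispersion(counts, f, [ga, gb])
        res = de.wald_test_two_group(counts, f, a, ga, gb)
        assert np.isnan(res["pvalue"].iloc[0]) and np.isnan(res["padj"].iloc[0])
        assert res["padj"].iloc[1:].notna().all()

    def test_empty_group_rejected(self, null_counts):
        counts, ga, gb = null_counts
        f = de.size_factors_median_of_ratios(counts)
        a = de.estimate_dispersion(counts, f, [ga, gb])
        with pytest.raises(ValueError, match="non-empty"):
            de.wald_test_two_group(counts, f, a, ga, [])

    def test_sign_consistency_invariant(self, null_counts):
        counts, ga, gb = null_counts
        f = de.size_factors_median_of_ratios(counts)
        a = de.estimate_dispersion(counts, f, [ga, gb])
        res = de.wald_test_two_group(counts, f, a, ga, gb)
        assert np.all(np.sign(res["stat"].fillna(0)) == np.sign(res["log2FoldChange"].fillna(0)))
        assert np.all(res["padj"].fillna(0) >= res["pvalue"].fillna(0) - 1e-12)


def bh_brute_force(p):
    """Literal step-up definition: padj_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [min(1.0, m * p[order[j]] / (j + 1)) for j in range(rank_pos, m)]
        out[idx] = min(candidates)
    return out


class TestBH:
    def test_hand_computed_examples(self):
        assert de.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)
        assert np.allclose(de.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)
        assert np.allclose(de.bh_adjust(np.ones(5)), 1.0)

    def test_na_propagated_and_excluded_from_m(self):
        out = de.bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(out[1])
        # m = 2, not 3
        assert out[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust(np.array([1.2]))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, p):
        assert np.allclose(de.bh_adjust(np.array(p)), bh_brute_force(p), atol=1e-12)


class TestTransforms:
    def test_vst_constant_and_monotone(self):
        c = pd.DataFrame({"s1": [5, 9, 100], "s2": [5, 9, 100]})
        f = pd.Series(1.0, index=c.columns)
        v = de.vst_counts(c, f)
        assert np.allclose(v["s1"], v["s2"])
        assert v["s1"].is_monotonic_increasing

    def test_vst_decouples_sd_from_mean(self):
        rng = np.random.default_rng(4)
        mu = rng.uniform(1, 1000, 3000)
        y = _nb_counts(rng, mu, 0.2, 50)
        c = pd.DataFrame(y, columns=[f"s{i}" for i in range(50)])
        v = de.vst_counts(c, pd.Series(1.0, index=c.columns))
        hi = mu > 20
        slope = np.polyfit(v.mean(axis=1)[hi], v.std(axis=1)[hi], 1)[0]
        assert abs(slope) <= 0.1

    def test_tpm_examples(self):
        c = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        lengths = pd.Series([1000, 1000], index=["a", "b"])
        assert np.allclose(de.tpm_normalize(c, lengths)["s1"], [5e5, 5e5])
        lengths2 = pd.Series([2000, 1000], index=["a", "b"])
        assert np.allclose(de.tpm_normalize(c, lengths2)["s1"], [1e6 / 3, 2e6 / 3])

    def test_tpm_all_zero_sample_stays_zero(self):
        c = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        lengths = pd.Series([1000, 500], index=["a", "b"])
        out = de.tpm_normalize(c, lengths)
        assert np.allclose(out["s1"], 0.0) and not out.isna().any().any()

    def test_tpm_rejects_zero_length(self):
        c = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(ValueError, match="length"):
            de.tpm_normalize(c, pd.Series([0], index=["a"]))


class TestAgainstDESeq2Implementation:
    """Independent cross-checks against pydeseq2 (a DESeq2 reimplementation)."""

    def test_size_factors_match(self, null_counts):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        counts, ga, gb = null_counts
        meta = pd.DataFrame({"condition": ["A"] * 10 + ["B"] * 10},
                            index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        ours = de.size_factors_median_of_ratios(counts)
        assert np.allclose(ours.to_numpy(), dds.obs["size_factors"].to_numpy(), rtol=1e-10)

    def test_lfc_concordance_on_planted_signal(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(7)
        mu = rng.uniform(50, 500, 300)
        lfc = np.where(np.arange(300) < 60, rng.choice([-2.0, 2.0], 300), 0.0)
        ya = _nb_counts(rng, mu, 0.1, 10)
        yb = _nb_counts(rng, mu * 2.0**lfc, 0.1, 10)
        c = pd.DataFrame(np.hstack([ya, yb]), index=[f"g{i}" for i in range(300)],
                         columns=[f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)])
        ga, gb = list(c.columns[:10]), list(c.columns[10:])
        f = de.size_factors_median_of_ratios(c)
        a = de.estimate_dispersion(c, f, [ga, gb])
        ours = de.wald_test_two_group(c, f, a, ga, gb)

        meta = pd.DataFrame({"condition": ["A"] * 10 + ["B"] * 10}, index=c.columns)
        dds = DeseqDataSet(counts=c.T, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        stats.summary()
        theirs = stats.results_df["log2FoldChange"].reindex(ours["gene_id"]).to_numpy()
        r = np.corrcoef(ours["log2FoldChange"], theirs)[0, 1]
        assert r > 0.95
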