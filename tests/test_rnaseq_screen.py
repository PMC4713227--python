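"""Median-of-ratios normalisation, the concordance filter and its calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringcode.rnaseq_screen import (
    CountMatrix,
    concordance_filter,
    de_compare,
    run_screen,
    simulate_counts,
    size_factors,
    venn_partition,
)


def matrix_from_array(arr, genotypes=None, stages=None):
    arr = np.asarray(arr)
    n_samples = arr.shape[1]
    names = [f"s{i}" for i in range(n_samples)]
    samples = pd.DataFrame({
        "genotype": genotypes or ["wt"] * n_samples,
        "stage": stages or ["T1"] * n_samples,
        "replicate": range(1, n_samples + 1),
    }, index=names)
    counts = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                          columns=names)
    return CountMatrix(counts, samples)


class TestSizeFactors:
    def test_proportional_samples_recover_depth_ratio(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, 60)
        cm = matrix_from_array(np.column_stack([base, 2 * base]))
        sf = size_factors(cm)
        assert sf["s1"] / sf["s0"] == pytest.approx(2.0)

    def test_single_sample_factor_one(self):
        cm = matrix_from_array(np.array([[10], [40], [90]]))
        assert size_factors(cm).iloc[0] == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_independent_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 300, size=(50, 6))
        arr[:10] += 1  # guarantee reference genes
        cm = matrix_from_array(arr)
        sf = size_factors(cm).to_numpy()
        # straight-line oracle
        expected = []
        for j in range(6):
            ratios = []
            for i in range(50):
                row = arr[i].astype(float)
                if (row > 0).all():
                    geo = np.exp(np.mean(np.log(row)))
                    ratios.append(row[j] / geo)
            expected.append(np.median(ratios))
        assert np.allclose(sf, expected)

    def test_agrees_with_deseq2_reference_implementation(self):
        # independent cross-check against the established estimator
        import warnings

        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(1)
        arr = rng.integers(1, 400, size=(80, 6))
        cm = matrix_from_array(arr)
        meta = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3},
                            index=cm.counts.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=cm.counts.T, metadata=meta,
                               design="~condition", quiet=True)
            dds.fit_size_factors()
        assert np.allclose(size_factors(cm).to_numpy(),
                           dds.obs["size_factors"].to_numpy(), rtol=1e-3)

    def test_no_reference_gene_rejected(self):
        cm = matrix_from_array(np.array([[0, 5], [3, 0]]))
        with pytest.raises(ValueError, match="size factors"):
            size_factors(cm)


class TestDeCompare:
    def test_identical_groups_ratio_zero_p_one(self):
        arr = np.tile([[100], [50]], (1, 6))
        cm = matrix_from_array(arr)
        sf = size_factors(cm)
        res = de_compare(cm, sf, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_planted_fourfold_gene_detected(self):
        cm, truth = simulate_counts(
            200, planted={0: ({"T1"}, 2.0)}, dispersion=0.01, seed=3)
        sub = cm.of_stage("T1")
        sf = size_factors(sub)
        res = de_compare(sub, sf, sub.samples_of("hom"), sub.samples_of("wt"))
        gene = truth["gene"].iloc[0]
        assert res.loc[gene, "log2fc"] == pytest.approx(2.0, abs=0.4)
        assert res.loc[gene, "p"] < 0.01

    def test_all_zero_gene_ratio_zero_p_one(self):
        arr = np.vstack([np.zeros(4, dtype=int), np.full(4, 100)])
        cm = matrix_from_array(arr)
        sf = size_factors(cm)
        res = de_compare(cm, sf, ["s0", "s1"], ["s2", "s3"])
        assert res.loc["g0", "log2fc"] == 0.0
        assert res.loc["g0", "p"] == 1.0

    def test_empty_group_rejected(self):
        cm = matrix_from_array(np.ones((3, 4), dtype=int))
        with pytest.raises(ValueError, match="non-empty"):
            de_compare(cm, size_factors(cm), [], ["s0"])


@pytest.fixture(scope="module")
def stage_screen():
    planted = {i: ({"T1"}, 2.0 if i % 2 == 0 else -2.0) for i in range(10)}
    cm, truth = simulate_counts(300, planted=planted, dispersion=0.01, seed=8)
    sub = cm.of_stage("T1")
    sf = size_factors(sub)
    res_wt = de_compare(sub, sf, sub.samples_of("hom"), sub.samples_of("wt"))
    res_het = de_compare(sub, sf, sub.samples_of("hom"), sub.samples_of("het"))
    return sub, sf, res_wt, res_het, truth


class TestConcordanceFilter:
    def test_receptor_gene_excluded_first(self, stage_screen):
        sub, sf, res_wt, res_het, truth = stage_screen
        receptor = truth["gene"].iloc[0]  # strongly differential, still excluded
        out = concordance_filter(res_wt, res_het, sub, [receptor], sf=sf)
        row = out.table.loc[receptor]
        assert not row["passed"] and row["reason"] == "receptor_excluded"

    def test_planted_genes_pass_without_exclusion(self, stage_screen):
        sub, sf, res_wt, res_het, truth = stage_screen
        out = concordance_filter(res_wt, res_het, sub, [], sf=sf)
        passing = out.passing()
        assert set(truth["gene"]) <= passing

    def test_discordant_signs_fail_with_reason(self):
        # gene up against wt but down against het, both nominally significant
        arr = np.array([
            [400, 390, 410, 100, 110, 105, 1000, 980, 1020],  # hom between wt and het
            [500, 490, 510, 500, 510, 490, 500, 495, 505],
        ])
        cm = matrix_from_array(
            arr, genotypes=["hom"] * 3 + ["wt"] * 3 + ["het"] * 3)
        sf = pd.Series(1.0, index=cm.counts.columns)
        res_wt = de_compare(cm, sf, cm.samples_of("hom"), cm.samples_of("wt"))
        res_het = de_compare(cm, sf, cm.samples_of("hom"), cm.samples_of("het"))
        out = concordance_filter(res_wt, res_het, cm, [], sf=sf)
        assert out.table.loc["g0", "reason"] == "discordant"

    def test_low_count_uses_max_genotype_mean(self):
        # hom mean is 30 >= 20 although wt/het are low: passes the floor
        arr = np.array([[30, 32, 28, 2, 3, 2, 2, 2, 3]])
        cm = matrix_from_array(arr, genotypes=["hom"] * 3 + ["wt"] * 3 + ["het"] * 3)
        sf = pd.Series(1.0, index=cm.counts.columns)
        res_wt = de_compare(cm, sf, cm.samples_of("hom"), cm.samples_of("wt"))
        res_het = de_compare(cm, sf, cm.samples_of("hom"), cm.samples_of("het"))
        out = concordance_filter(res_wt, res_het, cm, [], sf=sf)
        assert out.table.loc["g0", "reason"] != "low_count"
        # and a uniformly low gene fails the floor
        arr_low = arr // 3
        cm2 = matrix_from_array(arr_low, genotypes=["hom"] * 3 + ["wt"] * 3 + ["het"] * 3)
        res_wt2 = de_compare(cm2, sf, cm2.samples_of("hom"), cm2.samples_of("wt"))
        res_het2 = de_compare(cm2, sf, cm2.samples_of("hom"), cm2.samples_of("het"))
        out2 = concordance_filter(res_wt2, res_het2, cm2, [], sf=sf)
        assert out2.table.loc["g0", "reason"] == "low_count"

    def test_gene_universe_mismatch_rejected(self, stage_screen):
        sub, sf, res_wt, res_het, _ = stage_screen
        with pytest.raises(ValueError, match="gene universe"):
            concordance_filter(res_wt.iloc[:-1], res_het, sub, [], sf=sf)

    def test_gene_order_permutation_invariance(self, stage_screen):
        sub, sf, res_wt, res_het, _ = stage_screen
        out = concordance_filter(res_wt, res_het, sub, [], sf=sf)
        perm = np.random.default_rng(0).permutation(len(res_wt))
        sub_p = CountMatrix(sub.counts.iloc[perm], sub.samples)
        out_p = concordance_filter(res_wt.iloc[perm], res_het.iloc[perm], sub_p, [], sf=sf)
        assert out.passing() == out_p.passing()

    def test_tightening_p_cut_only_removes_genes(self, stage_screen):
        sub, sf, res_wt, res_het, _ = stage_screen
        loose = concordance_filter(res_wt, res_het, sub, [], sf=sf, p_cut=0.1)
        tight = concordance_filter(res_wt, res_het, sub, [], sf=sf, p_cut=0.01)
        assert tight.passing() <= loose.passing()


class TestVenn:
    def test_disjoint_singletons(self):
        out = venn_partition({"T1": {"a"}, "T2": {"b"}, "T3": {"c"}})
        assert out["T1"] == {"a"} and out["T2"] == {"b"} and out["T3"] == {"c"}
        assert out["T1&T2"] == set() and out["T1&T2&T3"] == set()

    def test_identical_sets_fill_triple_intersection(self):
        s = {"a", "b"}
        out = venn_partition({"T1": set(s), "T2": set(s), "T3": set(s)})
        assert out["T1&T2&T3"] == s
        assert all(not v for k, v in out.items() if k != "T1&T2&T3")

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        a=st.sets(st.integers(0, 30)), b=st.sets(st.integers(0, 30)),
        c=st.sets(st.integers(0, 30)),
    )
    def test_regions_partition_the_union(self, a, b, c):
        out = venn_partition({"T1": a, "T2": b, "T3": c})
        regions = list(out.values())
        assert sum(len(r) for r in regions) == len(a | b | c)
        assert set().union(*regions) == a | b | c


class TestCalibration:
    def test_null_simulation_pass_fraction_below_ten_percent(self):
        cm, _ = simulate_counts(2000, seed=11)
        out = run_screen(cm)
        for result in out["results"].values():
            assert len(result.passing()) / 2000 <= 0.10

    def test_planted_fourfold_recall_at_paper_thresholds(self):
        planted = {i: ({"T1", "T2", "T3"}, 2.0) for i in range(100)}
        cm, truth = simulate_counts(1000, planted=planted, dispersion=0.01, seed=5)
        out = run_screen(cm)
        true_set = set(truth["gene"])
        for result in out["results"].values():
            recall = len(result.passing() & true_set) / len(true_set)
            assert recall >= 0.8
            # planted-truth recovery: passing set close to truth overall
            jaccard = len(result.passing() & true_set) / len(result.passing() | true_set)
            assert jaccard >= 0.7

    def test_seed_determinism(self):
        a, _ = simulate_counts(50, seed=4)
        b, _ = simulate_counts(50, seed=4)
        assert a.counts.equals(b.counts)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError, match="invalid design"):
            simulate_counts(0)
        with pytest.raises(ValueError, match="dispersion"):
            simulate_counts(10, dispersion=0.0)
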