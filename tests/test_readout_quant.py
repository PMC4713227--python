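"""qPCR dilution-factor quantification and neuron-count statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ringcode.readout_quant import (
    StandardCurve,
    count_anova,
    genotype_comparison,
    load_default_curves,
    relative_quantity,
    simulate_ct,
)


@pytest.fixture(scope="module")
def curves():
    return load_default_curves()


class TestSimulateCt:
    def test_halving_abundance_raises_ct_one_cycle_at_doubling(self):
        curve = {"g": StandardCurve("g", 1.0, 30.0)}  # fold = 2 exactly
        hi = simulate_ct({"g": 2.0}, curve, 0.0, 1, 0).frame.iloc[0, 0]
        lo = simulate_ct({"g": 1.0}, curve, 0.0, 1, 0).frame.iloc[0, 0]
        assert lo - hi == pytest.approx(1.0)

    def test_zero_sigma_is_deterministic(self, curves):
        ab = {"Or47b": 1.5, "Or67a": 0.8}
        a = simulate_ct(ab, curves, 0.0, 3, 1).frame
        b = simulate_ct(ab, curves, 0.0, 3, 2).frame
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_seeded_noise_reproducible(self, curves):
        ab = {"Or47b": 1.5}
        a = simulate_ct(ab, curves, 0.3, 4, 7).frame
        b = simulate_ct(ab, curves, 0.3, 4, 7).frame
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_nonpositive_abundance_rejected(self, curves):
        with pytest.raises(ValueError, match="positive"):
            simulate_ct({"Or47b": 0.0}, curves, 0.0, 1, 0)

    def test_table_efficiencies_imply_near_doubling(self, curves):
        folds = [c.fold() for c in curves.values()]
        assert all(1.9 < f < 2.1 for f in folds)


class TestRelativeQuantity:
    def test_round_trip_recovers_abundance_ratios(self, curves):
        ab = {"Or47b": 2.0, "Or67a": 0.5, "Gr21a": 1.25, "ACT5C": 7.0}
        ct = simulate_ct(ab, curves, 0.0, 3, 0)
        rq = relative_quantity(ct, curves)
        for g1 in ab:
            for g2 in ab:
                assert rq.of(g1)[0] / rq.of(g2)[0] == pytest.approx(
                    ab[g1] / ab[g2], rel=1e-9)

    def test_panel_mean_is_one_per_replicate(self, curves):
        ab = {"Or47b": 3.0, "Or67a": 0.5, "Gr21a": 1.0, "ACT5C": 9.0}
        rq = relative_quantity(simulate_ct(ab, curves, 0.2, 5, 3), curves)
        panel = [g for g in ab if curves[g].role == "or_panel"]
        means = rq.frame.loc[panel].mean(axis=0).to_numpy()
        assert np.allclose(means, 1.0)

    def test_global_scaling_invariance(self, curves):
        ab = {"Or47b": 2.0, "Or67a": 0.5, "Gr21a": 1.0}
        rq1 = relative_quantity(simulate_ct(ab, curves, 0.0, 2, 0), curves)
        scaled = {g: 37.0 * a for g, a in ab.items()}
        rq2 = relative_quantity(simulate_ct(scaled, curves, 0.0, 2, 0), curves)
        assert np.allclose(rq1.frame.to_numpy(), rq2.frame.to_numpy())

    def test_equal_ct_equal_curves_normalise_to_one(self):
        curve = {g: StandardCurve(g, 1.0, 30.0) for g in ("a", "b")}
        ct = simulate_ct({"a": 1.0, "b": 1.0}, curve, 0.0, 2, 0)
        rq = relative_quantity(ct, curve)
        assert np.allclose(rq.frame.to_numpy(), 1.0)

    def test_one_cycle_lower_doubles_prenormalised_factor(self):
        curve = {g: StandardCurve(g, 1.0, 30.0) for g in ("a", "b")}
        ct = simulate_ct({"a": 2.0, "b": 1.0}, curve, 0.0, 1, 0)
        assert ct.frame.loc["b", "rep1"] - ct.frame.loc["a", "rep1"] == pytest.approx(1.0)
        rq = relative_quantity(ct, curve)
        assert rq.of("a")[0] / rq.of("b")[0] == pytest.approx(2.0)

    def test_rn_null_panel_shifts_match_neuron_pools(self, curves, composition,
                                                     params, wt_reference, fate_map):
        # end-to-end: simulated antennae -> receptor abundances -> Ct ->
        # normalised factors; at4 receptors rise, ab10 receptors fall
        from ringcode.antenna_simulator import class_counts, simulate_antennae
        from ringcode.disc_model import build_perturbation, simulate_disc
        from ringcode.perturbation_predictor import predict_fate_deltas
        from ringcode.ring_segmentation import classify_rings, segment_rings

        state = simulate_disc(params, [build_perturbation("gene=rn mode=null")])
        delta = predict_fate_deltas(
            wt_reference, classify_rings(segment_rings(state), wt_reference), fate_map)

        gene_to_class = {"Or47b": "Or47b", "Or67a": "Or67a",
                         "Or82a": "Or82a", "Gr21a": "Gr21a", "Or13a": "Or13a"}

        def panel(delta_arg, seed):
            samples = simulate_antennae(composition, delta_arg, n=50, seed=seed)
            ab = {g: class_counts(samples, cls).mean() + 0.5
                  for g, cls in gene_to_class.items()}
            return relative_quantity(simulate_ct(ab, curves, 0.1, 3, seed), curves)

        wt_q, rn_q = panel(None, 21), panel(delta, 22)
        assert rn_q.of("Or47b").mean() > wt_q.of("Or47b").mean()  # at4 up
        assert rn_q.of("Or67a").mean() < wt_q.of("Or67a").mean()  # ab10 down
        assert rn_q.of("Or82a").mean() < wt_q.of("Or82a").mean()  # ab5 down

    def test_missing_curve_names_gene(self, curves):
        ct = simulate_ct({"Or47b": 1.0}, curves, 0.0, 1, 0)
        ct.frame.index = ["OrUnknown"]
        with pytest.raises(ValueError, match="OrUnknown"):
            relative_quantity(ct, curves)


class TestGenotypeComparison:
    def make_groups(self, a, b, genes=("g",)):
        import pandas as pd

        from ringcode.readout_quant import RelQuant

        qa = RelQuant(pd.DataFrame([a] * len(genes), index=list(genes)))
        qb = RelQuant(pd.DataFrame([b] * len(genes), index=list(genes)))
        return {"mut": qa, "wt": qb}

    def test_identical_groups_fold_one_p_one(self):
        res = genotype_comparison(self.make_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.loc["g", "fold"] == pytest.approx(1.0)
        assert res.loc["g", "p"] == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        res = genotype_comparison(self.make_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]))
        assert res.loc["g", "t"] == pytest.approx(-3.674, abs=1e-3)
        assert res.loc["g", "p"] == pytest.approx(0.0214, abs=1e-3)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_pooled_t(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 4), rng.normal(0.5, 1, 5)
        res = genotype_comparison(self.make_groups(list(a), list(b)))
        # brute force: pooled-variance two-sample t from first principles
        na, nb = len(a), len(b)
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert res.loc["g", "t"] == pytest.approx(t)
        assert res.loc["g", "p"] == pytest.approx(p)

    def test_type_one_error_calibrated_through_qpcr_pipeline(self, curves):
        genes = {"Or47b": 1.0, "Or67a": 1.0, "Gr21a": 1.0}
        rejections = 0
        repeats = 500
        for i in range(repeats):
            qa = relative_quantity(simulate_ct(genes, curves, 0.3, 3, 2 * i), curves)
            qb = relative_quantity(simulate_ct(genes, curves, 0.3, 3, 2 * i + 1), curves)
            res = genotype_comparison({"a": qa, "b": qb})
            rejections += int(res.loc["Or47b", "p"] < 0.05)
        rate = rejections / repeats
        assert 0.03 < rate < 0.07

    def test_requires_two_replicates(self, curves):
        qa = relative_quantity(simulate_ct({"Or47b": 1.0}, curves, 0.0, 1, 0), curves)
        with pytest.raises(ValueError, match="replicates"):
            genotype_comparison({"a": qa, "b": qa})


class TestCountAnova:
    def test_hand_computed_example(self):
        res = count_anova({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert res["F"] == pytest.approx(3.0)
        assert (res["df_between"], res["df_within"]) == (2, 6)
        assert res["posthoc"].shape[0] == 3

    def test_constant_groups_flagged_degenerate(self):
        res = count_anova({"a": [2, 2], "b": [2, 2], "c": [2, 2]})
        assert res["zero_within_variance"]
        assert res["F"] == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_sums_of_squares(self, seed):
        rng = np.random.default_rng(seed)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, rng.integers(3, 7)) for i in range(3)}
        res = count_anova(groups)
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert res["F"] == pytest.approx(f_ref)
        assert res["p"] == pytest.approx(p_ref)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 groups"):
            count_anova({"a": [1, 2, 3]})

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            count_anova({"a": [1, 2], "b": [5]})
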