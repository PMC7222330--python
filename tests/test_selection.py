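import numpy as np
import pytest

import adaptiphy as ap
from adaptiphy.alignio import NucAlignment
from adaptiphy.phylo import compress_patterns, pruning_loglik
from adaptiphy.selection import (
    MixtureModelParams,
    _null_to_alt,
    estimate_zeta,
    fit_selection_model,
    joint_loglik,
    lrt_pvalue,
)
from adaptiphy.selection import TestConfig as SelectionConfig
from adaptiphy.selection import test_selection as run_selection

from conftest import random_alignment, random_model
from oracles import brute_force_mixture_loglik


class TestLrtPvalue:
    def test_equal_likelihoods_give_p_one(self):
        stat, p = lrt_pvalue(-100.0, -100.0)
        assert stat == 0.0 and p == 1.0

    def test_chi2_five_percent_quantile(self):
        _, p = lrt_pvalue(0.0, 3.841459 / 2)
        assert p == pytest.approx(0.05, abs=5e-6)

    def test_chi2_one_percent_quantile(self):
        _, p = lrt_pvalue(0.0, 6.634897 / 2)
        assert p == pytest.approx(0.01, abs=5e-6)

    def test_negative_difference_clamps_to_zero(self):
        stat, p = lrt_pvalue(-99.9, -100.0)
        assert stat == 0.0 and p == 1.0


class TestEstimateZeta:
    def test_fully_neutral_is_one(self):
        p = MixtureModelParams(b1=0.0, zeta1=0.5, delta2=0.0, zeta3=7.0)
        assert estimate_zeta(p) == pytest.approx(1.0)

    def test_fully_selected_equals_zeta3(self):
        p = MixtureModelParams(b1=0.0, zeta1=0.5, delta2=1.0, zeta3=7.0)
        assert estimate_zeta(p) == pytest.approx(7.0)

    def test_purifying_half_formula(self):
        p = MixtureModelParams(b1=0.5, zeta1=0.5, delta1=0.0, delta2=0.0)
        assert estimate_zeta(p) == pytest.approx(0.75)


class TestMixtureParams:
    @pytest.mark.parametrize("kind", ["null", "alt"])
    def test_category_weights_sum_to_one(self, kind):
        p = MixtureModelParams(
            b1=0.3, zeta1=0.4, delta=0.2, delta1=0.6, delta2=0.1, zeta3=3.0
        )
        weights = [w for w, _, _ in p.categories(kind)]
        assert min(weights) >= 0
        assert sum(weights) == pytest.approx(1.0)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            MixtureModelParams(b1=1.4, zeta1=0.5).validate("null")
        with pytest.raises(ValueError):
            MixtureModelParams(b1=0.5, zeta1=0.5, zeta3=0.5).validate("alt")


@pytest.fixture(scope="module")
def toy_tree():
    return ap.read_newick("((A:0.1,B:0.2):0.05,C:0.3);")


class TestJointLoglik:
    def test_b1_zero_null_equals_neutral_pruning(self, toy_tree, rng):
        model = random_model(rng)
        ref = random_alignment(rng, ["A", "B", "C"], 30, missing_prob=0.05)
        query = random_alignment(rng, ["A", "B", "C"], 10, missing_prob=0.05)
        params = MixtureModelParams(b1=0.0, zeta1=0.5, delta=0.7)
        got = joint_loglik(
            params, "null", compress_patterns(ref), compress_patterns(query),
            toy_tree, model, "A",
        )
        want = pruning_loglik(compress_patterns(ref), toy_tree, model) + (
            pruning_loglik(compress_patterns(query), toy_tree, model)
        )
        assert got == pytest.approx(want, abs=1e-10)

    def test_alt_with_zero_deltas_equals_null(self, toy_tree, rng):
        model = random_model(rng)
        ref = random_alignment(rng, ["A", "B", "C"], 20)
        query = random_alignment(rng, ["A", "B", "C"], 10)
        rpt, qpt = compress_patterns(ref), compress_patterns(query)
        null = MixtureModelParams(b1=0.4, zeta1=0.3, delta=0.0)
        alt = MixtureModelParams(
            b1=0.4, zeta1=0.3, delta1=0.0, delta2=0.0, zeta3=5.0
        )
        assert joint_loglik(null, "null", rpt, qpt, toy_tree, model, "A") == (
            pytest.approx(
                joint_loglik(alt, "alt", rpt, qpt, toy_tree, model, "A"),
                abs=1e-10,
            )
        )

    @pytest.mark.parametrize("kind", ["null", "alt"])
    def test_matches_brute_force_enumeration(self, toy_tree, kind, rng):
        model = random_model(rng)
        ref = random_alignment(rng, ["A", "B", "C"], 4, missing_prob=0.2)
        query = random_alignment(rng, ["A", "B", "C"], 2, missing_prob=0.2)
        params = MixtureModelParams(
            b1=0.35, zeta1=0.2, delta=0.55, delta1=0.25, delta2=0.4, zeta3=4.5
        )
        got = joint_loglik(
            params, kind, compress_patterns(ref), compress_patterns(query),
            toy_tree, model, "B",
        )
        want = brute_force_mixture_loglik(
            params, kind, ref, query, toy_tree, model, "B"
        )
        assert got == pytest.approx(want, abs=1e-8)


@pytest.fixture(scope="module")
def neutral_pair(primate_tree, sim_model):
    rng = np.random.default_rng(81)
    ref = ap.simulate_alignment(primate_tree, sim_model, 3000, rng)
    query = ap.simulate_alignment(primate_tree, sim_model, 300, rng)
    return query, ref


@pytest.fixture(scope="module")
def selected_pair(primate_tree, sim_model):
    rng = np.random.default_rng(82)
    ref = ap.simulate_alignment(primate_tree, sim_model, 3000, rng)
    query = ap.simulate_alignment(primate_tree.scaled("human", 7.0), sim_model, 300, rng)
    return query, ref


TWO_STAGE = dict(n_restarts=5, mode="two_stage")


class TestTestSelection:
    def test_query_copied_from_reference_is_not_significant(self, neutral_pair):
        # a query that IS reference material should look neutral
        _, ref = neutral_pair
        query = NucAlignment(list(ref.species), [s[:300] for s in ref.seqs])
        ps = []
        for seed in range(20):
            res = run_selection(
                query, ref, "human", SelectionConfig(seed=seed, **TWO_STAGE)
            )
            ps.append(res.p)
        assert all(p > 0.2 for p in ps)

    def test_alpha7_query_detected(self, selected_pair):
        query, ref = selected_pair
        res = run_selection(query, ref, "human", SelectionConfig(seed=3, **TWO_STAGE))
        assert res.p < 0.05
        assert res.mle_alt.zeta3 > 1.5
        assert res.mle_alt.delta1 + res.mle_alt.delta2 > 0.1

    def test_identical_query_and_reference_zeta_near_one(self, neutral_pair):
        _, ref = neutral_pair
        res = run_selection(ref, ref, "human", SelectionConfig(seed=4, **TWO_STAGE))
        assert res.zeta == pytest.approx(1.0, abs=0.15)

    def test_alternative_nests_null(self, neutral_pair, selected_pair):
        for query, ref in (neutral_pair, selected_pair):
            res = run_selection(query, ref, "human", SelectionConfig(seed=5, **TWO_STAGE))
            assert res.lnL_alt >= res.lnL_null - 1e-6
            assert res.LRT >= 0
            assert 0 < res.p <= 1

    def test_neutral_query_collapses_toward_null(self, neutral_pair):
        query, ref = neutral_pair
        res = run_selection(query, ref, "human", SelectionConfig(seed=6, **TWO_STAGE))
        collapsed = (
            res.mle_alt.zeta3 < 1.05
            or res.mle_alt.delta1 * res.mle_alt.b1
            + res.mle_alt.delta2 * (1 - res.mle_alt.b1) < 0.2
            or res.p > 0.05
        )
        assert collapsed

    def test_species_mismatch_rejected(self, neutral_pair):
        query, ref = neutral_pair
        bad = NucAlignment(["x", "y"], ["ACGT" * 20, "ACGT" * 20])
        with pytest.raises(ValueError):
            run_selection(bad, ref, "human", SelectionConfig(**TWO_STAGE))

    def test_short_query_rejected(self, neutral_pair):
        query, ref = neutral_pair
        short = NucAlignment(list(query.species), [s[:20] for s in query.seqs])
        with pytest.raises(ValueError):
            run_selection(short, ref, "human", SelectionConfig(**TWO_STAGE))

    def test_same_seed_reproduces_result(self, neutral_pair):
        query, ref = neutral_pair
        cfg = SelectionConfig(seed=9, **TWO_STAGE)
        r1 = run_selection(query, ref, "human", cfg)
        r2 = run_selection(query, ref, "human", cfg)
        assert (r1.lnL_null, r1.lnL_alt, r1.p, r1.zeta) == (
            r2.lnL_null, r2.lnL_alt, r2.p, r2.zeta
        )


class TestFitSelectionModel:
    def test_single_restart_matches_many_on_easy_instance(
        self, neutral_pair, primate_tree
    ):
        # a query drawn from reference material: the alternative collapses
        # onto the null and every restart reaches the same flat optimum
        from adaptiphy.phylo import empirical_base_frequencies, fit_tree_model

        _, ref = neutral_pair
        query = NucAlignment(list(ref.species), [s[:300] for s in ref.seqs])
        stage1 = fit_tree_model(ref, primate_tree, pi=empirical_base_frequencies(ref))
        qpt = compress_patterns(query)
        lnL1, _, _ = fit_selection_model(
            "alt", qpt, stage1.tree, stage1.model, "human",
            n_restarts=1, rng=np.random.default_rng(1),
        )
        lnL20, _, _ = fit_selection_model(
            "alt", qpt, stage1.tree, stage1.model, "human",
            n_restarts=20, rng=np.random.default_rng(2),
        )
        assert lnL1 == pytest.approx(lnL20, abs=1e-4)

    def test_null_start_guarantees_nesting(self, neutral_pair, primate_tree):
        from adaptiphy.phylo import empirical_base_frequencies, fit_tree_model

        query, ref = neutral_pair
        stage1 = fit_tree_model(ref, primate_tree, pi=empirical_base_frequencies(ref))
        qpt = compress_patterns(query)
        lnLn, pn, _ = fit_selection_model(
            "null", qpt, stage1.tree, stage1.model, "human",
            n_restarts=3, rng=np.random.default_rng(5),
        )
        lnLa, _, _ = fit_selection_model(
            "alt", qpt, stage1.tree, stage1.model, "human",
            n_restarts=1, rng=np.random.default_rng(6),
            extra_starts=[_null_to_alt(pn)],
        )
        assert lnLa >= lnLn - 1e-6


def test_joint_mode_agrees_with_two_stage_on_strong_signal(selected_pair):
    query, ref = selected_pair
    r2 = run_selection(query, ref, "human", SelectionConfig(seed=7, **TWO_STAGE))
    rj = run_selection(
        query, ref, "human", SelectionConfig(seed=7, n_restarts=3, mode="joint")
    )
    # joint optimization can only improve both likelihoods; the verdict
    # and effect size should agree
    assert rj.p < 0.05 and r2.p < 0.05
    assert rj.zeta == pytest.approx(r2.zeta, rel=0.5)
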