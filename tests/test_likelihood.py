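"""Transition probabilities and the compound pruning likelihood."""

import numpy as np
import pytest

from mmphylo import (
    Alignment,
    MMMSpec,
    ValidationError,
    build_switching_process,
    compose_compound_generator,
    hky,
    jc,
    read_tree,
    simulate,
    site_pattern_compression,
    transition_matrix,
    tree_log_likelihood,
)
from mmphylo.benchmarks import random_spec
from mmphylo.phylo import random_tree
from oracles import (
    enumeration_loglik,
    expm_series,
    jc_transition_closed_form,
    reference_standard_pruning,
)


def single_model_spec(component, family="custom"):
    return MMMSpec((component,), np.ones(1), build_switching_process([], 1),
                   family=family)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        comp = compose_compound_generator(single_model_spec(jc()))
        assert np.array_equal(transition_matrix(comp, 0.0), np.eye(4))

    def test_jc_closed_form(self):
        comp = compose_compound_generator(single_model_spec(jc()))
        for t in [0.01, 0.1, 0.5, 2.0]:
            assert np.abs(transition_matrix(comp, t)
                          - jc_transition_closed_form(t)).max() < 1e-10

    def test_chapman_kolmogorov_against_series_oracle(self):
        spec = random_spec(np.random.default_rng(5), max_models=2)
        comp = compose_compound_generator(spec)
        p_direct = transition_matrix(comp, 0.3)
        p_chained = transition_matrix(comp, 0.1) @ transition_matrix(comp, 0.2)
        assert np.abs(p_direct - p_chained).max() < 1e-8
        assert np.abs(p_direct - expm_series(comp.generator, 0.3)).max() < 1e-8

    def test_rows_stochastic(self):
        spec = random_spec(np.random.default_rng(6), max_models=3)
        comp = compose_compound_generator(spec)
        p = transition_matrix(comp, 1.7)
        assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-10
        assert p.min() >= 0

    def test_negative_time_rejected(self):
        comp = compose_compound_generator(single_model_spec(jc()))
        with pytest.raises(ValidationError, match="nonnegative"):
            transition_matrix(comp, -0.1)


class TestPruning:
    def test_single_model_equals_standard_pruning(self, four_taxon_tree, small_alignment):
        comp_model = hky(3.0, [0.35, 0.15, 0.2, 0.3])
        spec = single_model_spec(comp_model, family="HKY")
        res = tree_log_likelihood(small_alignment, four_taxon_tree, spec)
        from mmphylo.phylo import match_tree_alignment

        order = match_tree_alignment(four_taxon_tree, small_alignment)
        tp = small_alignment.tip_partials()[order]
        expected = reference_standard_pruning(
            tp, four_taxon_tree, comp_model.generator, comp_model.frequencies
        )
        assert np.abs(res.site_log_likelihoods - expected).max() < 1e-10

    def test_single_model_with_gamma_equals_standard_mixture(self, four_taxon_tree,
                                                             small_alignment):
        comp_model = hky(3.0, [0.35, 0.15, 0.2, 0.3])
        spec = single_model_spec(comp_model, family="HKY").with_asrv(0.4, 4)
        res = tree_log_likelihood(small_alignment, four_taxon_tree, spec)
        from mmphylo.phylo import match_tree_alignment

        order = match_tree_alignment(four_taxon_tree, small_alignment)
        tp = small_alignment.tip_partials()[order]
        expected = reference_standard_pruning(
            tp, four_taxon_tree, comp_model.generator, comp_model.frequencies,
            rates=spec.asrv.category_rates, weights=spec.asrv.category_weights,
        )
        assert np.abs(res.site_log_likelihoods - expected).max() < 1e-10

    def test_star_tree_zero_lengths_all_same_tip(self):
        tree = read_tree("(A:0.0,B:0.0,C:0.0,D:0.0);")
        aln = Alignment(["A", "B", "C", "D"], ["AAA"] * 4)
        spec = MMMSpec((jc(), jc()), np.ones(2),
                       build_switching_process([0.5], 2, "symmetric"))
        res = tree_log_likelihood(aln, tree, spec)
        assert np.allclose(res.site_log_likelihoods, np.log(0.25), atol=1e-12)
        assert abs(res.log_likelihood - 3 * np.log(0.25)) < 1e-12

    def test_four_taxon_asymmetric_matches_enumeration(self, four_taxon_tree):
        rng = np.random.default_rng(17)
        spec = random_spec(rng, max_models=2, families=("HKY",))
        sim = simulate(four_taxon_tree, spec, 6, seed=3)
        res = tree_log_likelihood(sim.alignment, four_taxon_tree, spec)
        expected = enumeration_loglik(sim.alignment, four_taxon_tree, spec)
        assert abs(res.log_likelihood - expected) < 1e-10 * abs(expected)

    def test_identical_components_reduce_to_base_model(self, four_taxon_tree,
                                                       small_alignment):
        base = hky(2.5, [0.3, 0.2, 0.25, 0.25])
        for phi in ([0.01], [5.0]):
            spec = MMMSpec((base, base), np.ones(2),
                           build_switching_process(phi, 2, "symmetric"),
                           family="HKY")
            mmm_ll = tree_log_likelihood(small_alignment, four_taxon_tree, spec)
            base_ll = tree_log_likelihood(small_alignment, four_taxon_tree,
                                          single_model_spec(base, "HKY"))
            assert abs(mmm_ll.log_likelihood - base_ll.log_likelihood) < 1e-10

    def test_vanishing_switching_approaches_mixture_limit(self, four_taxon_tree,
                                                          small_alignment):
        c1 = hky(2.0, [0.4, 0.1, 0.1, 0.4])
        c2 = hky(8.0, [0.1, 0.4, 0.4, 0.1])
        spec = MMMSpec((c1, c2), np.ones(2),
                       build_switching_process([1e-8, 1e-8], 2, "asymmetric"),
                       family="HKY")
        res = tree_log_likelihood(small_alignment, four_taxon_tree, spec)
        per_model = [
            tree_log_likelihood(small_alignment, four_taxon_tree,
                                single_model_spec(c, "HKY")).site_log_likelihoods
            for c in (c1, c2)
        ]
        psi = spec.switching.stationary
        mixture = np.log(psi[0] * np.exp(per_model[0]) + psi[1] * np.exp(per_model[1]))
        assert np.abs(res.site_log_likelihoods - mixture).max() < 1e-5

    def test_deep_caterpillar_tree_no_underflow(self):
        # 220 cascading long branches push raw partials past 1e-100,
        # exercising the rescaling accumulator
        n = 220
        rng = np.random.default_rng(0)
        newick = "t0:1.0"
        for i in range(1, n):
            newick = f"({newick},t{i}:1.0):1.0"
        tree = read_tree(newick + ";")
        spec = MMMSpec((jc(), jc()), np.ones(2),
                       build_switching_process([0.3], 2, "symmetric"))
        sim = simulate(tree, spec, 8, seed=1)
        res = tree_log_likelihood(sim.alignment, tree, spec)
        assert np.isfinite(res.log_likelihood)
        assert res.log_likelihood < 0

    def test_asrv_category_posteriors_sum_to_one(self, four_taxon_tree, small_alignment):
        spec = single_model_spec(hky(2.0, [0.25] * 4), "HKY").with_asrv(0.3, 4)
        res = tree_log_likelihood(small_alignment, four_taxon_tree, spec)
        assert np.abs(res.category_posteriors.sum(axis=1) - 1.0).max() < 1e-10


def test_nexus_tree_block_readable():
    text = (
        "#NEXUS\nBEGIN TREES;\n"
        "TREE t1 = [&R] ((A:0.1,B:0.1):0.05,C:0.2);\nEND;\n"
    )
    tree = read_tree(text)
    assert sorted(tree.tip_labels) == ["A", "B", "C"]


def test_pruning_cost_scales_with_compound_dimension(capsys):
    """Informational: log the empirical scaling of pruning time with the
    compound-state count KS (theory: ~quadratic per site and node once
    the per-branch exponentials are done). The slope is printed, not
    asserted — wall-clock noise on shared machines makes a hard bound
    meaningless."""
    import time

    from mmphylo.benchmarks import random_spec
    from mmphylo.phylo import random_tree as _random_tree

    rng = np.random.default_rng(0)
    tree = _random_tree(8, rng)
    sizes, times = [], []
    for k in (1, 2, 3, 4):
        comps = tuple(jc() for _ in range(k))
        n_rates = k * (k - 1) // 2
        sw = build_switching_process([0.5] * n_rates, k, "symmetric") if k > 1 \
            else build_switching_process([], 1)
        spec = MMMSpec(comps, np.ones(k), sw, family="JC")
        sim = simulate(tree, spec, 400, seed=k)
        ev_t = []
        for _ in range(3):
            t0 = time.perf_counter()
            tree_log_likelihood(sim.alignment, tree, spec)
            ev_t.append(time.perf_counter() - t0)
        sizes.append(4 * k)
        times.append(min(ev_t))
    slope = np.polyfit(np.log(sizes), np.log(times), 1)[0]
    print(f"pruning cost ~ (KS)^{slope:.2f} over KS={sizes}")
    assert np.isfinite(slope)


class TestPatternCompression:
    def test_identical_columns_single_pattern(self):
        aln = Alignment(["a", "b"], ["AAAA", "CCCC"])
        patterns, weights, inverse = site_pattern_compression(aln)
        assert patterns.shape[1] == 1
        assert weights.tolist() == [4.0]
        assert inverse.tolist() == [0, 0, 0, 0]

    def test_compressed_equals_naive_loglik(self, rng):
        tree = random_tree(6, rng)
        spec = random_spec(rng, max_models=2)
        sim = simulate(tree, spec, 200, seed=9)
        fast = tree_log_likelihood(sim.alignment, tree, spec, compress=True)
        slow = tree_log_likelihood(sim.alignment, tree, spec, compress=False)
        assert abs(fast.log_likelihood - slow.log_likelihood) < 1e-12 * abs(slow.log_likelihood)
        assert np.abs(fast.site_log_likelihoods - slow.site_log_likelihoods).max() < 1e-10

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValidationError, match="empty alignment"):
            site_pattern_compression(Alignment(["a", "b"], ["", ""]))
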