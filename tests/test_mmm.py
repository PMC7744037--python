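"""Switching process, compound generator, notation, covarion preset."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmphylo import (
    MMMSpec,
    ModelParseError,
    ValidationError,
    build_switching_process,
    compose_compound_generator,
    compound_stationary,
    covarion_preset,
    hky,
    jc,
    parse_model_notation,
)
from mmphylo.benchmarks import random_spec
from mmphylo.mmm import save_spec, load_spec, spec_to_dict, spec_from_dict
from oracles import compound_generator_entrywise, stationary_nullspace


class TestSwitchingProcess:
    def test_symmetric_two_state_is_uniform(self):
        sw = build_switching_process([0.5], 2, "symmetric")
        assert np.allclose(sw.stationary, [0.5, 0.5])
        assert np.abs(sw.rates.sum(axis=1)).max() < 1e-12

    def test_asymmetric_two_state_matches_nullspace_oracle(self):
        sw = build_switching_process([2.0, 1.0], 2, "asymmetric")
        assert np.allclose(sw.stationary, [1.0 / 3.0, 2.0 / 3.0], atol=1e-12)
        assert np.allclose(sw.stationary, stationary_nullspace(sw.rates), atol=1e-10)

    def test_chain_through_middle_state_still_irreducible(self):
        # phi_13 = phi_31 = 0 but state 2 connects everything
        sw = build_switching_process([1.0, 0.0, 1.0], 3, "symmetric")
        assert np.allclose(sw.stationary, [1 / 3, 1 / 3, 1 / 3], atol=1e-10)
        assert np.allclose(sw.stationary, stationary_nullspace(sw.rates), atol=1e-10)
        assert np.abs(sw.rates.sum(axis=1)).max() < 1e-12

    def test_reducible_chain_rejected(self):
        with pytest.raises(ValidationError, match="not irreducible"):
            build_switching_process([1.0, 0.0, 0.0], 3, "symmetric")

    def test_reducible_allowed_with_explicit_weights(self):
        sw = build_switching_process([0.0], 2, "symmetric",
                                     stationary=[0.3, 0.7], allow_reducible=True)
        assert np.allclose(sw.stationary, [0.3, 0.7])

    def test_wrong_rate_count_rejected(self):
        with pytest.raises(ValidationError, match="expected 2 off-diagonal"):
            build_switching_process([1.0], 2, "asymmetric")


class TestCompoundGenerator:
    def test_single_model_collapses_to_base_generator(self):
        base = hky(2.0, [0.3, 0.2, 0.2, 0.3])
        sw = build_switching_process([], 1)
        spec = MMMSpec((base,), np.ones(1), sw, family="HKY")
        comp = compose_compound_generator(spec)
        assert np.allclose(comp.generator, base.generator, atol=1e-14)

    def test_zero_switching_is_block_diagonal(self):
        sw = build_switching_process([0.0], 2, "symmetric",
                                     stationary=[0.5, 0.5], allow_reducible=True)
        spec = MMMSpec((jc(), jc()), np.ones(2), sw, family="JC")
        lam = compose_compound_generator(spec).generator
        assert np.allclose(lam[:4, 4:], 0)
        assert np.allclose(lam[4:, :4], 0)
        assert np.allclose(lam[:4, :4], jc().generator)

    def test_two_hky_components_match_entrywise_oracle(self):
        c1 = hky(2.0, [0.4, 0.1, 0.1, 0.4])
        c2 = hky(6.0, [0.1, 0.4, 0.4, 0.1])
        sw = build_switching_process([0.3, 0.7], 2, "asymmetric")
        spec = MMMSpec((c1, c2), np.array([0.5, 1.5]), sw, family="HKY")
        comp = compose_compound_generator(spec)
        expected = compound_generator_entrywise(
            [c1, c2], [0.5, 1.5], sw.rates, psi=sw.stationary, normalize=True
        )
        assert np.allclose(comp.generator, expected, atol=1e-12)

    def test_stationary_uniform_for_symmetric_jc(self):
        sw = build_switching_process([0.4], 2, "symmetric")
        spec = MMMSpec((jc(), jc()), np.ones(2), sw, family="JC")
        assert np.allclose(compound_stationary(compose_compound_generator(spec)), 0.125)

    def test_stationary_matches_nullspace_oracle(self):
        c1 = hky(1.0, [0.4, 0.1, 0.1, 0.4])
        c2 = jc()
        sw = build_switching_process([2.0, 1.0], 2, "asymmetric")  # psi = (1/3, 2/3)
        spec = MMMSpec((c1, c2), np.ones(2), sw)
        comp = compose_compound_generator(spec)
        stat = compound_stationary(comp)
        assert np.allclose(stat, stationary_nullspace(comp.generator), atol=1e-9)
        assert np.abs(stat @ comp.generator).max() < 1e-10

    def test_product_form_exact_only_under_shared_frequencies(self):
        from mmphylo.mmm import product_form_stationary

        # shared frequencies: product form is the stationary law
        pi = [0.4, 0.1, 0.1, 0.4]
        shared = MMMSpec((hky(2.0, pi), hky(6.0, pi)), np.ones(2),
                         build_switching_process([2.0, 1.0], 2, "asymmetric"))
        comp = compose_compound_generator(shared)
        assert abs(comp.stationary[0] - 0.4 / 3.0) < 1e-12
        assert np.allclose(comp.stationary, product_form_stationary(shared), atol=1e-12)
        # distinct frequencies: the product form has a nonzero residual
        mixed = MMMSpec((hky(1.0, pi), jc()), np.ones(2),
                        build_switching_process([2.0, 1.0], 2, "asymmetric"))
        comp2 = compose_compound_generator(mixed)
        residual = np.abs(product_form_stationary(mixed) @ comp2.generator).max()
        assert residual > 1e-3
        assert np.abs(comp2.stationary @ comp2.generator).max() < 1e-10

    @pytest.mark.parametrize("seed", range(25))
    def test_random_spec_generator_invariants(self, seed):
        spec = random_spec(np.random.default_rng(seed), allow_asrv=True)
        comp = compose_compound_generator(spec)
        lam = comp.generator
        assert np.abs(lam.sum(axis=1)).max() < 1e-10
        off = lam[~np.eye(lam.shape[0], dtype=bool)]
        assert off.min() >= 0
        assert np.abs(comp.stationary @ lam).max() < 1e-10

    def test_symmetric_equal_frequency_spec_is_reversible_asymmetric_is_not(self):
        pi = np.array([0.4, 0.1, 0.2, 0.3])
        c = hky(3.0, pi)
        sym = MMMSpec((c, c), np.ones(2), build_switching_process([0.5], 2, "symmetric"))
        comp = compose_compound_generator(sym)
        flux = comp.stationary[:, None] * comp.generator
        assert np.abs(flux - flux.T).max() < 1e-12
        # witness: asymmetric switching with unequal frequencies breaks it
        c2 = hky(3.0, np.array([0.1, 0.4, 0.3, 0.2]))
        asym = MMMSpec((c, c2), np.ones(2),
                       build_switching_process([0.9, 0.2], 2, "asymmetric"))
        comp2 = compose_compound_generator(asym)
        flux2 = comp2.stationary[:, None] * comp2.generator
        assert np.abs(flux2 - flux2.T).max() > 1e-3


class TestNotation:
    def test_fully_distinct_symmetric(self):
        t = parse_model_notation("MMM(HKY)_222T")
        assert (t.family, t.n_models, t.n_rate_sets, t.n_freq_sets,
                t.n_multipliers, t.structure) == ("HKY", 2, 2, 2, 2, "symmetric")

    def test_shared_rates_asymmetric(self):
        t = parse_model_notation("MMM(HKY)_122A")
        assert t.n_rate_sets == 1 and t.n_freq_sets == 2 and t.n_multipliers == 2
        assert t.structure == "asymmetric"
        assert t.rate_set_index() == (0, 0)
        assert t.freq_set_index() == (0, 1)

    def test_omitted_multiplier_count_requires_asrv(self):
        t = parse_model_notation("MMM(HKY)_22A")
        assert t.n_multipliers is None and t.asrv_required
        spec = t.instantiate(rate_sets=[[2.0], [3.0]],
                             freq_sets=[[0.4, 0.1, 0.1, 0.4], [0.25] * 4],
                             switch_rates=[0.3, 0.6], alpha=0.5)
        assert np.allclose(spec.multipliers, 1.0)
        assert spec.asrv is not None
        with pytest.raises(ValidationError, match="alpha is required"):
            t.instantiate(rate_sets=[[2.0], [3.0]],
                          freq_sets=[[0.25] * 4, [0.25] * 4],
                          switch_rates=[0.3, 0.6])

    @pytest.mark.parametrize("bad", ["MMM(HKY)_2X", "HKY_22A", "MMM(FOO)_22A",
                                     "MMM(HKY)_23A", "MMM(HKY)_2222A"])
    def test_malformed_strings_rejected_with_position(self, bad):
        with pytest.raises(ModelParseError):
            parse_model_notation(bad)

    @pytest.mark.parametrize("name", ["MMM(HKY)_222T", "MMM(GTR)_122A",
                                      "MMM(JC)_11T", "MMM(GTR)_33A",
                                      "MMM(HKY)_22A", "MMM(GTR)_13A"])
    def test_compose_parse_round_trip(self, name):
        t = parse_model_notation(name)
        rng = np.random.default_rng(1)
        spec = t.instantiate(
            rate_sets=[[2.0 + i] if t.family == "HKY" else 0.5 + rng.random(6)
                       for i in range(t.n_rate_sets)],
            freq_sets=[rng.dirichlet(np.ones(4) * 8) for _ in range(t.n_freq_sets)],
            switch_rates=0.2 + rng.random(max(t.n_switch_rates(), 0)),
            multipliers=None if t.asrv_required else 0.5 + rng.random(t.n_models),
            alpha=0.5 if t.asrv_required else None,
        )
        assert spec.canonical_name() == t.name


class TestCovarionPreset:
    def test_off_block_rows_contain_only_switching(self):
        spec = covarion_preset(hky(2.0, [0.3, 0.2, 0.2, 0.3]), 1.5, 0.5)
        lam = compose_compound_generator(spec).generator
        # off model (rows 4..7): no substitution, only switching back
        off_block = lam[4:, 4:]
        assert np.allclose(off_block, np.diag(np.diag(off_block)))
        assert lam.shape == (8, 8)

    def test_matches_hand_assembled_tuffley_steel_matrix(self):
        base = jc()
        s01, s10 = 1.0, 2.0
        spec = covarion_preset(base, s01, s10)
        lam = compose_compound_generator(spec).generator
        eye = np.eye(4)
        expected = np.block([
            [base.generator - s01 * eye, s01 * eye],
            [s10 * eye, -s10 * eye],
        ])
        assert np.allclose(lam, expected, atol=1e-14)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            covarion_preset(jc(), 0.0, 1.0)


class TestConfigRoundTrip:
    @pytest.mark.parametrize("fmt", ["yaml", "json"])
    def test_save_load_round_trip(self, tmp_path, fmt):
        spec = random_spec(np.random.default_rng(3), allow_asrv=True)
        path = tmp_path / f"model.{fmt}"
        save_spec(spec, path)
        loaded = load_spec(path)
        assert np.allclose(loaded.multipliers, spec.multipliers)
        assert np.allclose(loaded.switching.rates, spec.switching.rates)
        for a, b in zip(loaded.components, spec.components):
            assert np.allclose(a.generator, b.generator)
        if spec.asrv is not None:
            assert loaded.asrv.shape == spec.asrv.shape

    def test_dict_round_trip_preserves_asrv_identifiability(self):
        d = spec_to_dict(covarion_preset(jc(), 1.0, 2.0))
        spec = spec_from_dict(d)
        assert np.allclose(spec.multipliers, [1.0, 0.0])

    def test_asrv_with_free_multipliers_rejected(self):
        sw = build_switching_process([0.5], 2, "symmetric")
        with pytest.raises(ValidationError, match="identifiability"):
            spec = MMMSpec((jc(), jc()), np.array([1.0, 2.0]), sw)
            spec.with_asrv(0.5)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 100_000))
def test_random_specs_stationarity_property(seed):
    spec = random_spec(np.random.default_rng(seed))
    comp = compose_compound_generator(spec)
    assert np.abs(comp.stationary @ comp.generator).max() < 1e-10
    assert abs(comp.stationary.sum() - 1.0) < 1e-12
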