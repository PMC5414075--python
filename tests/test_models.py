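"""Unit and property tests for the model space and its update equations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confrl.models import (
    BETA_FLOOR,
    ModelSpec,
    ParamSet,
    best_model,
    choice_probability,
    classify_outcome,
    enumerate_models,
    modulate_parameters,
    outcome_signal,
    update_confidence,
    update_values,
)


class TestModelSpace:
    def test_enumeration_counts(self):
        specs = enumerate_models()
        assert len(specs) == 27
        assert sum(s.is_hierarchical for s in specs) == 24
        assert len({(s.rl_variant, s.confidence_signal, s.modulation)
                    for s in specs}) == 27

    def test_model_ids_round_trip(self):
        for spec in enumerate_models():
            assert ModelSpec.from_id(spec.model_id) == spec
        assert best_model().model_id == "coupled.optim.bothshared"

    def test_signal_modulation_coupling_enforced(self):
        with pytest.raises(ValueError):
            ModelSpec("money", "none", "alpha")
        with pytest.raises(ValueError):
            ModelSpec("money", "optimality", "none")

    def test_free_params_depend_on_modulation(self):
        assert ModelSpec("money").free_params == ("alpha0", "beta0")
        assert best_model().free_params == (
            "alpha0", "beta0", "C0", "gamma", "kappa"
        )
        sep = ModelSpec("money", "abspe", "both_separate")
        assert sep.free_params[-2:] == ("kappa_alpha", "kappa_beta")

    def test_paramset_validation(self):
        with pytest.raises(ValueError, match="requires parameter"):
            ParamSet(alpha0=0.3, beta0=1.0).validate_for(best_model())
        with pytest.raises(ValueError, match="not licensed"):
            ParamSet(alpha0=0.3, beta0=1.0, kappa=1.0).validate_for(
                ModelSpec("money")
            )
        with pytest.raises(ValueError, match="alpha0"):
            ParamSet(alpha0=1.5, beta0=1.0).validate_for(ModelSpec("money"))


class TestOutcomeSignal:
    @pytest.mark.parametrize(
        "variant, outcome, expected",
        [
            ("money", -0.1, -0.1),
            ("money", 1.0, 1.0),
            ("valence", -0.1, -1.0),
            ("valence", 0.1, 1.0),
            ("coupled", 1.0, 1.0),
            ("coupled", -1.0, -1.0),
        ],
    )
    def test_reinforcer_coding(self, variant, outcome, expected):
        assert outcome_signal(variant, outcome) == expected

    def test_zero_outcome_rejected(self):
        with pytest.raises(ValueError):
            outcome_signal("money", 0.0)


class TestValueUpdate:
    def test_zero_rate_is_identity(self):
        assert update_values("valence", 0.3, -0.2, "A", 1.0, 0.0) == (0.3, -0.2)

    def test_delta_rule_presented_cue_only(self):
        q_a, q_b = update_values("valence", 0.0, 0.25, "A", 1.0, 0.5)
        assert q_a == pytest.approx(0.5)
        assert q_b == pytest.approx(0.25)

    def test_coupled_updates_other_cue_toward_negated_reinforcer(self):
        q_a, q_b = update_values("coupled", 0.0, 0.0, "A", 1.0, 0.5)
        assert (q_a, q_b) == pytest.approx((0.5, -0.5))

    def test_coupled_antisymmetry_is_preserved(self):
        # symmetric start: the two cue values stay exact mirrors forever
        rng = np.random.default_rng(0)
        q_a = q_b = 0.0
        for _ in range(200):
            cue = "A" if rng.random() < 0.5 else "B"
            r = 1.0 if rng.random() < 0.5 else -1.0
            q_a, q_b = update_values("coupled", q_a, q_b, cue, r,
                                     rng.uniform(0.05, 0.95))
            assert q_a == pytest.approx(-q_b, abs=1e-12)


class TestConfidenceUpdate:
    def test_zero_rate_is_identity(self):
        assert update_confidence("optimality", 0.7, 1e-12, optimality=1) == \
            pytest.approx(0.7)

    def test_optimality_delta_rule(self):
        assert update_confidence("optimality", 0.5, 0.2, optimality=1) == \
            pytest.approx(0.6)

    def test_repeated_optimal_outcomes_converge_to_one(self):
        c = 0.1
        prev = c
        for _ in range(200):
            c = update_confidence("optimality", c, 0.3, optimality=1)
            assert c >= prev
            prev = c
        assert c == pytest.approx(1.0, abs=1e-6)

    def test_abspe_normalised_target(self):
        # target is 1 - |pe|/2 so confidence stays a [0, 1] level
        c = update_confidence("abspe", 0.5, 0.5, pe=-1.0)
        assert c == pytest.approx(0.5 * 0.5 + 0.5 * 0.5)
        c = update_confidence("abspe", 0.0, 1 - 1e-9, pe=0.0)
        assert c == pytest.approx(1.0, abs=1e-6)

    @given(st.floats(0, 1), st.floats(0.01, 0.99), st.floats(-2, 2))
    @settings(derandomize=True, max_examples=50)
    def test_confidence_stays_in_unit_interval(self, c, gamma, pe):
        c2 = update_confidence("abspe", c, gamma, pe=pe)
        assert 0.0 <= c2 <= 1.0


class TestModulation:
    def test_zero_confidence_leaves_base_parameters(self):
        for form in ("linear", "exponential"):
            for confirm in (True, False):
                am, bm = modulate_parameters(
                    0.3, 1.2, 0.0, confirm, "both_shared", kappa=2.0,
                    form=form,
                )
                assert (am, bm) == pytest.approx((0.3, 1.2))

    def test_linear_form_saturates_at_unit_weight(self):
        am, bm = modulate_parameters(0.3, 1.2, 0.5, True, "both_shared",
                                     kappa=2.0, form="linear")
        assert am == pytest.approx(1.0)
        assert bm == pytest.approx(BETA_FLOOR)
        am, _ = modulate_parameters(0.3, 1.2, 0.5, False, "both_shared",
                                    kappa=2.0, form="linear")
        assert am == pytest.approx(0.0)

    def test_zero_kappa_reduces_to_plain_rl(self):
        for form in ("linear", "exponential"):
            am, bm = modulate_parameters(0.4, 0.8, 0.9, False, "both_shared",
                                         kappa=0.0, form=form)
            assert (am, bm) == pytest.approx((0.4, 0.8))

    def test_only_licensed_targets_modulated(self):
        am, bm = modulate_parameters(0.4, 0.8, 0.9, True, "alpha", kappa=3.0)
        assert am > 0.4 and bm == 0.8
        am, bm = modulate_parameters(0.4, 0.8, 0.9, True, "beta", kappa=3.0)
        assert am == 0.4 and bm < 0.8

    def test_separate_weights(self):
        am, bm = modulate_parameters(
            0.4, 0.8, 0.5, True, "both_separate",
            kappa_alpha=5.0, kappa_beta=0.0,
        )
        assert am > 0.4 and bm == pytest.approx(0.8)

    @given(
        st.floats(0.05, 0.95), st.floats(0.1, 3.0), st.floats(0.1, 5.0),
        st.floats(0, 1), st.floats(0, 1),
        st.sampled_from(["linear", "exponential"]),
    )
    @settings(derandomize=True, max_examples=80)
    def test_monotone_in_confidence(self, a0, b0, kappa, c1, c2, form):
        # alpha_m increases (confirmatory) / decreases (contradictory) with
        # confidence; beta_m never increases with confidence
        lo, hi = sorted((c1, c2))
        a_lo, b_lo = modulate_parameters(a0, b0, lo, True, "both_shared",
                                         kappa=kappa, form=form)
        a_hi, b_hi = modulate_parameters(a0, b0, hi, True, "both_shared",
                                         kappa=kappa, form=form)
        assert a_hi >= a_lo - 1e-12
        assert b_hi <= b_lo + 1e-12
        a_lo_c, _ = modulate_parameters(a0, b0, lo, False, "both_shared",
                                        kappa=kappa, form=form)
        a_hi_c, _ = modulate_parameters(a0, b0, hi, False, "both_shared",
                                        kappa=kappa, form=form)
        assert a_hi_c <= a_lo_c + 1e-12
        assert 0.0 <= a_hi <= 1.0 and 0.0 <= a_hi_c <= 1.0
        assert b_hi > 0


class TestChoiceProbability:
    def test_indifference_at_zero_value(self):
        for beta in (0.01, 1.0, 50.0):
            assert choice_probability(0.0, beta) == pytest.approx(0.5)

    def test_logistic_value(self):
        assert choice_probability(1.0, 1.0) == pytest.approx(0.7311, abs=1e-4)

    def test_deterministic_limit(self):
        assert choice_probability(0.5, 1e-6) == pytest.approx(1.0)
        assert choice_probability(-0.5, 1e-6) == pytest.approx(0.0)


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "q, val, expected",
        [
            (0.4, 1, "confirmatory"),
            (-0.4, 1, "contradictory"),
            (-0.4, -1, "confirmatory"),
            (0.0, 1, "confirmatory"),
            (0.0, -1, "contradictory"),
        ],
    )
    def test_valence_match_rule(self, q, val, expected):
        assert classify_outcome(q, val) == expected
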