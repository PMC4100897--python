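"""The five stochastic error specifications mapping values to choice probabilities."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from riskmix.choice_models import (
    ERROR_SPECS,
    ErrorFamily,
    ErrorSpec,
    Link,
    NoiseParams,
    choose_b_probability,
    contextual_range,
    latent_index,
)
from riskmix.exceptions import DomainError
from riskmix.preference_models import PreferenceParams, eut_value
from riskmix.task_design import Lottery, LotteryPair

ALL_SPECS = list(ERROR_SPECS.values())


def _pair(x_a, x_b, row=1):
    return LotteryPair(Lottery((1.0,), (x_a,)), Lottery((1.0,), (x_b,)), row_index=row)


class TestErrorSpec:
    def test_exactly_five_admissible_codes(self):
        assert sorted(ERROR_SPECS) == ["CL", "CP", "FL", "FP", "LUCE"]

    def test_luce_rejects_links(self):
        with pytest.raises(DomainError):
            ErrorSpec(ErrorFamily.LUCE_STRICT, Link.PROBIT)

    def test_fechner_requires_link(self):
        with pytest.raises(DomainError):
            ErrorSpec(ErrorFamily.FECHNER, Link.NONE)

    def test_code_round_trip(self):
        for code, spec in ERROR_SPECS.items():
            assert ErrorSpec.from_code(code) == spec


class TestLatentIndex:
    def test_zero_on_identical_values(self):
        pair = _pair(2.0, 2.0)
        assert latent_index(pair, "EUT", PreferenceParams(r=0.3), NoiseParams(0.5)) == 0.0

    def test_division_by_noise_scale(self):
        pair = _pair(2.0, 2.5)  # value difference 0.5 at r = 0
        idx = latent_index(pair, "EUT", PreferenceParams(r=0.0), NoiseParams(0.428))
        assert idx == pytest.approx(0.5 / 0.428)

    def test_antisymmetric_under_option_swap(self, hl_low):
        params, noise = PreferenceParams(r=0.4), NoiseParams(0.3)
        for pair in hl_low.pairs:
            swapped = LotteryPair(pair.option_b, pair.option_a, pair.row_index, pair.scale)
            assert latent_index(pair, "EUT", params, noise) == pytest.approx(
                -latent_index(swapped, "EUT", params, noise)
            )


class TestContextualRange:
    def test_risk_neutral_baseline_range(self, hl_low):
        nu = contextual_range(hl_low.pair(3), PreferenceParams(r=0.0)).nu
        assert nu == pytest.approx(3.85 - 0.10)

    def test_scaled_range(self, hl_high):
        nu = contextual_range(hl_high.pair(3), PreferenceParams(r=0.0)).nu
        assert nu == pytest.approx(19.25 - 0.50)

    @pytest.mark.parametrize("r", [-2.0, -1.0, 0.0, 0.5, 0.99])
    def test_positive_over_design(self, r, hl_low, hl_high):
        for design in (hl_low, hl_high):
            for pair in design.pairs:
                assert contextual_range(pair, PreferenceParams(r=r)).nu > 0

    def test_degenerate_pair_rejected(self):
        with pytest.raises(DomainError, match="degenerate"):
            contextual_range(_pair(2.0, 2.0), PreferenceParams(r=0.0))


class TestChooseBProbability:
    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.code)
    def test_half_on_indifference(self, spec):
        # equal expected values at r = 0 but distinct prizes (so the
        # contextual range is well defined)
        pair = LotteryPair(
            Lottery((0.5, 0.5), (3.0, 1.0)), Lottery((1.0,), (2.0,)), row_index=1
        )
        p = choose_b_probability(pair, "EUT", PreferenceParams(r=0.0), NoiseParams(0.4), spec)
        assert p == pytest.approx(0.5)

    def test_luce_ratio_example(self):
        # EU_A = 1, EU_B = 2, mu = 1 -> 2/(1+2)
        pair = _pair(1.0, 2.0)
        p = choose_b_probability(
            pair, "EUT", PreferenceParams(r=0.0), NoiseParams(1.0), ERROR_SPECS["LUCE"]
        )
        assert p == pytest.approx(2.0 / 3.0)

    def test_probit_tail_point(self):
        # value difference / mu = 1.6449 -> standard normal CDF ~ 0.95
        pair = _pair(2.0, 2.0 + 1.6449)
        p = choose_b_probability(
            pair, "EUT", PreferenceParams(r=0.0), NoiseParams(1.0), ERROR_SPECS["FP"]
        )
        assert p == pytest.approx(0.95, abs=1e-4)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.code)
    def test_complementarity(self, spec, hl_low):
        params, noise = PreferenceParams(r=0.4, gamma=0.7), NoiseParams(0.3)
        functional = "RDU"
        for pair in hl_low.pairs:
            swapped = LotteryPair(pair.option_b, pair.option_a, pair.row_index, pair.scale)
            p_b = choose_b_probability(pair, functional, params, noise, spec)
            p_a = choose_b_probability(swapped, functional, params, noise, spec)
            assert p_b + p_a == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.code)
    def test_noise_limits(self, spec, hl_low):
        pair = hl_low.pair(2)  # B strictly worse at r = 0.3
        params = PreferenceParams(r=0.3)
        huge = choose_b_probability(pair, "EUT", params, NoiseParams(1e8), spec)
        assert huge == pytest.approx(0.5, abs=1e-4)
        tiny = choose_b_probability(pair, "EUT", params, NoiseParams(1e-8), spec)
        assert tiny == pytest.approx(0.0, abs=1e-8)

    def test_strict_utility_equals_logit_of_log_values(self, hl_low, hl_high):
        # the strict-to-strong identity, checked against the literal ratio
        # V_B^(1/mu) / (V_A^(1/mu) + V_B^(1/mu)) computed independently
        worst = 0.0
        for design in (hl_low, hl_high):
            for pair in design.pairs:
                for r in (-1.0, 0.0, 0.5, 0.9):
                    for mu in (0.1, 0.5, 1.0, 2.0):
                        params = PreferenceParams(r=r)
                        p = choose_b_probability(
                            pair, "EUT", params, NoiseParams(mu), ERROR_SPECS["LUCE"]
                        )
                        v_a = float(
                            np.dot(
                                pair.option_a.probabilities,
                                np.asarray(pair.option_a.prizes) ** (1 - r),
                            )
                        )
                        v_b = float(
                            np.dot(
                                pair.option_b.probabilities,
                                np.asarray(pair.option_b.prizes) ** (1 - r),
                            )
                        )
                        ratio = v_b ** (1 / mu) / (v_a ** (1 / mu) + v_b ** (1 / mu))
                        worst = max(worst, abs(p - ratio))
        assert worst < 1e-12

    def test_luce_requires_r_below_one(self, hl_low):
        with pytest.raises(DomainError, match="r < 1"):
            choose_b_probability(
                hl_low.pair(1),
                "EUT",
                PreferenceParams(r=1.2),
                NoiseParams(0.2),
                ERROR_SPECS["LUCE"],
            )

    @pytest.mark.parametrize("r", [-2.0, -0.5, 0.0, 0.5, 0.99])
    def test_contextual_rescaled_index_bounded(self, r, hl_low, hl_high):
        # (V_B - V_A)/nu in [-1, 1]: the moderate-utility motivation
        params = PreferenceParams(r=r, gamma=0.6)
        for design in (hl_low, hl_high):
            for pair in design.pairs:
                nu = contextual_range(pair, params).nu
                diff = eut_value(pair.option_b, params) - eut_value(pair.option_a, params)
                assert abs(diff / nu) <= 1.0 + 1e-12

    def test_probit_vs_logit_link_values(self, hl_low):
        pair = hl_low.pair(7)
        params, noise = PreferenceParams(r=0.2), NoiseParams(0.4)
        idx = latent_index(pair, "EUT", params, noise)
        assert choose_b_probability(pair, "EUT", params, noise, ERROR_SPECS["FP"]) == (
            pytest.approx(norm.cdf(idx))
        )
        assert choose_b_probability(pair, "EUT", params, noise, ERROR_SPECS["FL"]) == (
            pytest.approx(expit(idx))
        )
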