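"""Likelihood construction, MLE, cluster-robust covariance, Wald tests."""

import math

import numpy as np
import pytest

from riskmix.estimation import (
    FitOptions,
    FitResult,
    ModelSpec,
    ParameterVector,
    all_model_specs,
    cluster_sandwich_vcov,
    compile_dataset,
    dataset_loglik,
    fit_mle,
    link_crosscheck,
    record_loglik,
    wald_test,
)
from riskmix.exceptions import DomainError, ValidationError
from riskmix.task_design import ChoiceDataset, ChoiceRecord, build_hl_design


def _stub_fit(names, estimates, vcov, loglik=-700.0, k=None, n_obs=1680):
    estimates = np.asarray(estimates, dtype=float)
    return FitResult(
        spec=ModelSpec.from_code("RDU-FP"),
        params=ParameterVector.for_rdu(0.5, 1.0, 0.3),
        estimates=estimates,
        names=tuple(names),
        loglik=loglik,
        per_obs_loglik=np.full(n_obs, loglik / n_obs),
        theta_internal=estimates.copy(),
        vcov=np.asarray(vcov, dtype=float),
        vcov_internal=None,
        n_obs=n_obs,
        n_clusters=84,
        k_params=k or len(names),
        convergence={},
        flags=[],
        cluster_idx=np.repeat(np.arange(84), n_obs // 84),
    )


class TestModelSpec:
    def test_fifteen_admissible_combinations(self):
        specs = all_model_specs()
        assert len(specs) == 15
        assert len({s.code for s in specs}) == 15

    def test_code_round_trip(self):
        assert ModelSpec.from_code("mix-cp").functional == "MIXTURE"
        assert ModelSpec.from_code("EUT-LUCE").k_params == 2

    def test_unknown_code_rejected(self):
        with pytest.raises(DomainError):
            ModelSpec.from_code("CPT-FP")


class TestRecordLoglik:
    def test_indifference_is_log_half_for_any_parameters(self, hl_low):
        rec = ChoiceRecord("S1", "low", 3, "INDIFFERENT")
        pair = hl_low.pair(3)
        for code in ("EUT-FP", "RDU-CL", "MIX-CP"):
            spec = ModelSpec.from_code(code)
            params = {
                "EUT": ParameterVector.for_eut(0.4, 0.2),
                "RDU": ParameterVector.for_rdu(-0.2, 0.7, 0.3),
                "MIXTURE": ParameterVector.for_mixture(0.4, -0.2, 0.7, 0.3, 0.4),
            }[spec.functional]
            assert record_loglik(rec, pair, spec, params) == pytest.approx(math.log(0.5))

    def test_mixture_gamma_one_is_pi_invariant(self, hl_low):
        spec = ModelSpec.from_code("MIX-FP")
        rec = ChoiceRecord("S1", "low", 6, "B")
        pair = hl_low.pair(6)
        lls = [
            record_loglik(
                rec, pair, spec, ParameterVector.for_mixture(0.5, 0.5, 1.0, 0.3, pi)
            )
            for pi in (0.1, 0.5, 0.9)
        ]
        assert max(lls) - min(lls) < 1e-12


class TestDatasetLoglik:
    def test_kernel_agrees_with_scalar_path(self, mix_cp_data):
        # the aggregated per-pair kernel must reproduce the record-by-record
        # computation through the scalar choice-model route
        cases = [
            ("EUT-FP", ParameterVector.for_eut(0.6, 0.4)),
            ("RDU-CL", ParameterVector.for_rdu(-0.1, 0.7, 0.2)),
            ("RDU-LUCE", ParameterVector.for_rdu(0.3, 1.4, 0.25)),
            ("MIX-CP", ParameterVector.for_mixture(0.409, -0.291, 0.391, 0.106, 0.316)),
        ]
        for code, params in cases:
            spec = ModelSpec.from_code(code)
            total, per_obs = dataset_loglik(mix_cp_data, spec, params)
            scalar = sum(
                record_loglik(r, mix_cp_data.pair_for(r), spec, params)
                for r in mix_cp_data.records
            )
            assert total == pytest.approx(scalar, abs=1e-9)
            assert total == pytest.approx(per_obs.sum(), abs=1e-10)

    def test_additive_over_subject_split(self, eut_fp_data):
        spec = ModelSpec.from_code("EUT-FP")
        params = ParameterVector.for_eut(0.682, 0.428)
        subjects = eut_fp_data.subjects
        left = eut_fp_data.subset(subjects[:40])
        right = eut_fp_data.subset(subjects[40:])
        whole, _ = dataset_loglik(eut_fp_data, spec, params)
        assert whole == pytest.approx(
            dataset_loglik(left, spec, params)[0] + dataset_loglik(right, spec, params)[0]
        )

    def test_collapse_chain(self, mix_cp_data):
        # pi = 1 -> EUT; pi = 0 -> RDU; gamma = 1 -> RDU equals EUT
        for err in ("FP", "CL"):
            eut = ModelSpec.from_code(f"EUT-{err}")
            rdu = ModelSpec.from_code(f"RDU-{err}")
            mix = ModelSpec.from_code(f"MIX-{err}")
            ll_eut, _ = dataset_loglik(mix_cp_data, eut, ParameterVector.for_eut(0.5, 0.3))
            ll_rdu, _ = dataset_loglik(
                mix_cp_data, rdu, ParameterVector.for_rdu(-0.2, 0.7, 0.3)
            )
            ll_mix_pi1, _ = dataset_loglik(
                mix_cp_data, mix, ParameterVector.for_mixture(0.5, -0.2, 0.7, 0.3, 1.0)
            )
            ll_mix_pi0, _ = dataset_loglik(
                mix_cp_data, mix, ParameterVector.for_mixture(0.5, -0.2, 0.7, 0.3, 0.0)
            )
            ll_rdu_g1, _ = dataset_loglik(
                mix_cp_data, rdu, ParameterVector.for_rdu(0.5, 1.0, 0.3)
            )
            assert ll_mix_pi1 == pytest.approx(ll_eut, abs=1e-10)
            assert ll_mix_pi0 == pytest.approx(ll_rdu, abs=1e-10)
            assert ll_rdu_g1 == pytest.approx(ll_eut, abs=1e-10)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            ChoiceDataset(records=[], designs={"low": build_hl_design(1.0)})


class TestFitMle:
    def test_recovers_eut_truth_within_ci(self, eut_fp_fit):
        r_hat, mu_hat = eut_fp_fit.estimate("r"), eut_fp_fit.estimate("mu")
        lo, hi = eut_fp_fit.conf_int()[0]
        assert lo <= 0.682 <= hi
        assert abs(mu_hat - 0.428) < 0.1
        assert eut_fp_fit.loglik == pytest.approx(eut_fp_fit.per_obs_loglik.sum(), abs=1e-8)

    def test_probit_logit_scale_correspondence(self, eut_fp_data):
        fit_fp = fit_mle(eut_fp_data, ModelSpec.from_code("EUT-FP"), FitOptions(starts="fast"))
        fit_fl = fit_mle(eut_fp_data, ModelSpec.from_code("EUT-FL"), FitOptions(starts="fast"))
        assert abs(fit_fp.estimate("r") - fit_fl.estimate("r")) < 0.05
        # probit noise scale exceeds the logit one by the usual link factor
        assert 1.5 <= fit_fp.estimate("mu") / fit_fl.estimate("mu") <= 1.9
        assert link_crosscheck(fit_fp, fit_fl) is None

    def test_record_order_invariance(self, small_eut_data):
        spec = ModelSpec.from_code("EUT-FP")
        options = FitOptions(starts="fast", compute_vcov=False)
        fit1 = fit_mle(small_eut_data, spec, options)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(small_eut_data.records))
        shuffled = ChoiceDataset(
            records=[small_eut_data.records[i] for i in order],
            designs=small_eut_data.designs,
        )
        fit2 = fit_mle(shuffled, spec, options)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)
        assert np.allclose(fit1.estimates, fit2.estimates, atol=1e-8)

    def test_all_same_response_is_flagged(self):
        designs = {"low": build_hl_design(1.0)}
        records = [
            ChoiceRecord(f"S{s}", "low", row, "A")
            for s in range(1, 11)
            for row in range(1, 11)
        ]
        data = ChoiceDataset(records=records, designs=designs)
        fit = fit_mle(data, ModelSpec.from_code("EUT-FP"), FitOptions(starts="fast"))
        assert any("degenerate" in f or "boundary" in f for f in fit.flags)

    def test_single_cluster_rejected(self, hl_low):
        records = [ChoiceRecord("S1", "low", row, "A") for row in range(1, 11)]
        data = ChoiceDataset(records=records, designs={"low": build_hl_design(1.0)})
        with pytest.raises(ValidationError, match="clusters"):
            fit_mle(data, ModelSpec.from_code("EUT-FP"))


class TestClusterSandwich:
    def test_public_recompute_matches_fit(self, eut_fp_fit, eut_fp_data):
        vcov = cluster_sandwich_vcov(eut_fp_fit, eut_fp_data)
        assert np.allclose(vcov, eut_fp_fit.vcov, rtol=1e-8)
        # symmetric positive semidefinite
        assert np.all(np.linalg.eigvalsh(vcov) > -1e-12)

    def test_duplicating_clusters_shrinks_ses(self, small_eut_data):
        spec = ModelSpec.from_code("EUT-FP")
        fit1 = fit_mle(small_eut_data, spec, FitOptions(starts="fast"))
        doubled = ChoiceDataset(
            records=list(small_eut_data.records)
            + [
                ChoiceRecord(r.subject_id + "_copy", r.task_id, r.row_index, r.response)
                for r in small_eut_data.records
            ],
            designs=small_eut_data.designs,
        )
        fit2 = fit_mle(doubled, spec, FitOptions(starts="fast"))
        assert np.allclose(fit1.estimates, fit2.estimates, atol=1e-6)
        ratio = fit2.se / fit1.se
        # doubling independent clusters scales the sandwich by ~ 1/sqrt(2)
        assert np.all((ratio > 0.6) & (ratio < 0.8))

    def test_information_matrix_against_independent_differentiation(self, eut_fp_data):
        # the internal Hessian used by the sandwich, checked against
        # statsmodels' numerical differentiation of the same objective
        from statsmodels.tools.numdiff import approx_hess3

        from riskmix.estimation import _hessian, _negloglik_fn

        spec = ModelSpec.from_code("EUT-FP")
        compiled = compile_dataset(eut_fp_data)
        fit = fit_mle(compiled, spec, FitOptions(starts="fast", compute_vcov=False))
        ours = -_hessian(compiled, spec, fit.theta_internal)
        negll = _negloglik_fn(compiled, spec)
        theirs = approx_hess3(fit.theta_internal, negll)
        assert np.allclose(ours, theirs, rtol=1e-4, atol=1e-6)


class TestWald:
    def test_single_constraint_example(self):
        # gamma-hat 0.908, SE 0.061, H0 gamma = 1
        fit = _stub_fit(("r", "gamma", "mu"), [0.65, 0.908, 0.378],
                        np.diag([0.04**2, 0.061**2, 0.041**2]))
        res = wald_test(fit, {"gamma": 1.0})
        assert res.statistic == pytest.approx(2.27, abs=0.01)
        assert res.p_value == pytest.approx(0.13, abs=0.005)
        assert res.df == 1

    def test_satisfied_constraint_gives_zero(self):
        fit = _stub_fit(("r", "mu"), [0.5, 0.3], np.diag([0.01, 0.01]))
        res = wald_test(fit, {"r": 0.5})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_joint_constraint_degrees_of_freedom(self):
        fit = _stub_fit(("r", "gamma", "mu"), [0.65, 0.9, 0.38], np.diag([0.01, 0.01, 0.01]))
        assert wald_test(fit, {"r": 0.6, "gamma": 1.0}).df == 2

    def test_constraint_on_absent_parameter_rejected(self):
        fit = _stub_fit(("r", "mu"), [0.5, 0.3], np.diag([0.01, 0.01]))
        with pytest.raises(DomainError, match="pi_eut"):
            wald_test(fit, {"pi_eut": 0.5})
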