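"""Shared fixtures: designs and simulated datasets (all generated in-process)."""

import pytest

from riskmix.estimation import FitOptions, fit_mle
from riskmix.synthetic_data import preset_truth, simulate_dataset
from riskmix.task_design import build_hl_design


@pytest.fixture(scope="session")
def hl_low():
    return build_hl_design(1.0)


@pytest.fixture(scope="session")
def hl_high():
    return build_hl_design(5.0)


@pytest.fixture(scope="session")
def eut_fp_data():
    """84 subjects x 20 choices from the EUT Fechner-probit preset."""
    return simulate_dataset(preset_truth("EUT-FP", seed=42))


@pytest.fixture(scope="session")
def mix_cp_data():
    """84 subjects x 20 choices from the mixture contextual-probit preset."""
    return simulate_dataset(preset_truth("MIX-CP", seed=7))


@pytest.fixture(scope="session")
def small_eut_data():
    """A lighter 20-subject EUT dataset for optimizer-heavy tests."""
    return simulate_dataset(preset_truth("EUT-FP", seed=5, n_subjects=20))


@pytest.fixture(scope="session")
def eut_fp_fit(eut_fp_data):
    truth = preset_truth("EUT-FP")
    return fit_mle(eut_fp_data, truth.spec, FitOptions(starts="fast"))
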