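"""Shared fixtures: the calibrated reduced reference spheroids and the four
treatment experiments, built once per session and reused by all tests."""

from __future__ import annotations

import numpy as np
import pytest

from spheroidca.experiments import (
    bystander_experiment,
    intensification_experiment,
    monotherapy_experiment,
    scheduling_experiment,
)
from spheroidca.reference import calibrate_hap_dose, hap_kill_response, reference_pair

#: seed of the reference-spheroid growth; all derived experiments use fixed
#: seeds so the whole suite is bit-reproducible
REFERENCE_SEED = 1


@pytest.fixture(scope="session")
def ref_pair():
    return reference_pair(seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def small(ref_pair):
    return ref_pair[0]


@pytest.fixture(scope="session")
def large(ref_pair):
    return ref_pair[1]


@pytest.fixture(scope="session")
def calibration(large):
    return calibrate_hap_dose(large)


@pytest.fixture(scope="session")
def large_peaks(large):
    """Per-cell peak AHAP exposure of the Large reference at unit dose."""
    return hap_kill_response(large)


@pytest.fixture(scope="session")
def mono_results(small, large, calibration):
    dose = calibration["dose"]
    return {
        "small": monotherapy_experiment(small, dose, seed=7),
        "large": monotherapy_experiment(large, dose, seed=7),
    }


@pytest.fixture(scope="session")
def sched_results(small, large, calibration):
    dose = calibration["dose"]
    return {
        "small": scheduling_experiment(small, dose, seed=3),
        "large": scheduling_experiment(large, dose, seed=3),
    }


@pytest.fixture(scope="session")
def intens_results(large, calibration):
    return intensification_experiment(large, calibration["dose"], seed=5)


@pytest.fixture(scope="session")
def bystander_results(large, calibration):
    return bystander_experiment(large, calibration["dose"], seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
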