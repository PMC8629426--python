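"""Shared fixtures: small virtual cohorts and their fits, computed once."""

from __future__ import annotations

import numpy as np
import pytest

import icikinetics as ik


@pytest.fixture(scope="session")
def example_trajectory() -> ik.TrajectoryModel:
    """Growth regime with k = 0.02, rho_inf = 2 (hand-checkable)."""
    return ik.TrajectoryModel.from_values(0.02, 1.0, 0.01)


@pytest.fixture(scope="session")
def noiseless_cohort() -> ik.SyntheticCohort:
    return ik.generate_cohort(ik.GeneratorConfig(n=30, noise_amplitude=0.0), seed=11)


@pytest.fixture(scope="session")
def noisy_cohort() -> ik.SyntheticCohort:
    """Default study conditions: uniform +/-0.1 noise, 29% responders."""
    return ik.generate_cohort(ik.GeneratorConfig(n=30), seed=12)


def _truth_alpha_map(syn: ik.SyntheticCohort) -> dict[str, float]:
    return dict(zip(syn.truth.patient_id, syn.truth.alpha))


@pytest.fixture(scope="session")
def noiseless_fits(noiseless_cohort) -> list[ik.FitResult]:
    amap = _truth_alpha_map(noiseless_cohort)
    return ik.fit_cohort(noiseless_cohort.cohort, amap)


@pytest.fixture(scope="session")
def noisy_fits(noisy_cohort) -> list[ik.FitResult]:
    amap = _truth_alpha_map(noisy_cohort)
    return ik.fit_cohort(noisy_cohort.cohort, amap)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
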