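"""Shared fixtures: one session-scoped synthetic cohort feeds most tests."""

from __future__ import annotations

import numpy as np
import pytest

from pepmrd import (
    SimConfig,
    simulate_cohort,
    simulate_survival,
    spectra_to_matrix,
)


@pytest.fixture(scope="session")
def cohort():
    """A small mixed cohort run through the full peak pipeline once.

    Returns (spectra, records, truth, matrix); records carry simulated
    survival for the leukemia groups.
    """
    config = SimConfig(
        group_sizes={"healthy": 12, "newly_diagnosed": 12, "HCR": 10, "MR": 10},
        seed=42,
    )
    spectra, records, truth = simulate_cohort(config)
    records = simulate_survival(
        records,
        truth["marker_rel_intensity"],
        coupling=config.survival_coupling,
        censor_rate=config.censor_rate,
        seed=43,
    )
    matrix = spectra_to_matrix(spectra)
    return spectra, records, truth, matrix


@pytest.fixture(scope="session")
def cohort_matrix(cohort):
    return cohort[3]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
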