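"""Shared fixtures: a stabilized default patient and cached scenario runs."""

from __future__ import annotations

import numpy as np
import pytest

from hemoshock import (EngineParams, PatientProfile, ScenarioConfig, run_scenario,
                       stabilize)


@pytest.fixture(scope="session")
def default_patient() -> PatientProfile:
    return PatientProfile()


@pytest.fixture(scope="session")
def stabilized_engine(default_patient):
    """One stabilized engine, shared read-only across fast tests."""
    return stabilize(default_patient)


@pytest.fixture(scope="session")
def severity_runs(default_patient):
    """Scenario records for one patient at three bleed severities."""
    out = {}
    for rate in (100.0, 150.0, 200.0):
        records, recovered = run_scenario(default_patient,
                                          ScenarioConfig(bleed_rate=rate))
        out[rate] = (records, recovered)
    return out


def records_array(records, attr: str) -> np.ndarray:
    return np.array([getattr(r, attr) for r in records])
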