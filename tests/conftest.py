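"""Shared fixtures: synthetic recordings and the balanced recovery cohort."""

import numpy as np
import pytest
from hypothesis import settings

import legagility as lg
from legagility.synthetic import SensorModel, SeverityProfile, simulate_cohort, simulate_recording

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

BALANCED_MIX = {0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25}
RECOVERY_SEED = 7
RECOVERY_SUBJECTS = 48


@pytest.fixture(scope="session")
def sev0_recording():
    return simulate_recording(SeverityProfile.from_severity(0.0), SensorModel(),
                              duration=10.0, seed=1, recording_id="sev0",
                              subject_id="S1", leg="left")


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 10-subject cohort written to disk (manifest + CSV recordings)."""
    out = tmp_path_factory.mktemp("cohort10")
    manifest, truth = simulate_cohort(10, severity_mix=BALANCED_MIX, seed=3,
                                      out_dir=out)
    return manifest, truth, out


@pytest.fixture(scope="session")
def recovery_run():
    """The 48-subject balanced-severity cohort pushed through the full
    pipeline (features -> selection -> LOSO models -> reports), seed 7.

    Session-scoped: this is the package's parameter-recovery workhorse and
    several tests read different aspects of the same run.
    """
    manifest, truth = simulate_cohort(RECOVERY_SUBJECTS, severity_mix=BALANCED_MIX,
                                      seed=RECOVERY_SEED)
    result = lg.pipeline.run_pipeline(manifest, seed=RECOVERY_SEED)
    return {"manifest": manifest, "truth": truth, "result": result}
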