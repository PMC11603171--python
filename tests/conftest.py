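import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from taplearn import cohort, dataio
from taplearn.cohort import CohortSpec, LatentLearnerParams, StimEffectSpec
from taplearn.types import (
    AgeGroup,
    Arm,
    Dataset,
    ParticipantProfile,
    PipelineConfig,
)


@pytest.fixture
def config():
    return PipelineConfig(rng_seed=0)


@pytest.fixture
def profile():
    return ParticipantProfile(
        participant_id="P0001", age_years=68.0, age_group=AgeGroup.OLDER,
        arm=Arm.NONE, dataset=Dataset.SYNTHETIC,
    )


def make_profile(pid="P0001", age=68.0, arm=Arm.NONE):
    from taplearn.types import age_group_for

    return ParticipantProfile(
        participant_id=pid, age_years=age, age_group=age_group_for(age),
        arm=arm, dataset=Dataset.SYNTHETIC,
    )


def noiseless_params(a0=0.5, b=0.1, x_p=30, s0=1.0, speed_gain=0.2):
    return LatentLearnerParams(
        a0=a0, b_true=b, x_p=x_p, s0=s0, speed_gain=speed_gain,
        noise_sd_acc=0.0, noise_sd_speed=0.0,
    )


@pytest.fixture
def small_cohort_frames():
    """A 30-participant unstimulated cohort as (blocks, profiles, truth)
    DataFrames; module-scope cache is deliberate overkill avoidance —
    generation takes well under a second."""
    spec = CohortSpec(n_per_cell=5, arms=(Arm.NONE, Arm.PLACEBO), rng_seed=42)
    profiles, records, truth = cohort.generate_cohort_blocks(spec, None)
    return (
        dataio.blocks_to_frame(records),
        dataio.profiles_to_frame(profiles),
        truth,
    )


@pytest.fixture
def stim_cohort_frames():
    """A mixed-arm cohort (none/placebo/verum) with default injected
    effects."""
    spec = CohortSpec(n_per_cell=5, rng_seed=7)
    profiles, records, truth = cohort.generate_cohort_blocks(spec, StimEffectSpec())
    return (
        dataio.blocks_to_frame(records),
        dataio.profiles_to_frame(profiles),
        truth,
    )
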