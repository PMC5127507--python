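import logging

import pytest

from repcall import (ASSAY_PRESETS, UNDETECTED, Cohort, Group,
                     ReplicateMeasurement, Stage, SubjectRecord)

logging.getLogger("repcall").setLevel(logging.ERROR)


@pytest.fixture
def epi():
    """Triplicate assay preset (cutoff 45, 0.9 mL plasma per well)."""
    return ASSAY_PRESETS["epi_procolon_2"]


@pytest.fixture
def sensi():
    """Single-well assay preset (cutoff 41, 1.8 mL plasma per well)."""
    return ASSAY_PRESETS["sensicolon"]


def make_subject(subject_id, group, target_cts, control_ct=30.0,
                 stage=None):
    """Build a subject from a list of target Cts (None = undetected)."""
    group = Group(group)
    if stage is None:
        stage = Stage.II if group is Group.CRC else Stage.NA
    stage = Stage(stage)
    reps = tuple(
        ReplicateMeasurement(
            target_ct=UNDETECTED if t is None else t,
            control_ct=(UNDETECTED if control_ct is None else control_ct),
            replicate_index=i + 1)
        for i, t in enumerate(target_cts))
    return SubjectRecord(subject_id=subject_id, group=group, stage=stage,
                         replicates=reps)


@pytest.fixture
def toy_cohort(epi):
    """One clearly-positive CRC subject, two clean NED subjects."""
    return Cohort(subjects=[
        make_subject("S1", "CRC", [35.0, 36.0, None]),
        make_subject("S2", "NED", [None, None, None]),
        make_subject("S3", "NED", [None, None, None]),
    ], assay=epi)
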