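"""Shared fixtures: small synthetic records/cohorts and random generators."""

import numpy as np
import pytest

from eiodetect import SampledPoint, SimConfig, WalkRecord, simulate_cohort


def make_record(
    spo2,
    pr=None,
    labels=None,
    subject_id="s1",
    is_valid=None,
    quality=None,
    is_event=None,
):
    """Build a WalkRecord from plain lists (1 Hz timestamps)."""
    n = len(spo2)
    pr = pr if pr is not None else [90.0] * n
    points = []
    for i in range(n):
        points.append(
            SampledPoint(
                timestamp=float(i),
                spo2=float(spo2[i]),
                pr=float(pr[i]),
                is_valid=True if is_valid is None else bool(is_valid[i]),
                quality=True if quality is None else bool(quality[i]),
                is_event=True if is_event is None else bool(is_event[i]),
                is_eiod=None if labels is None else int(labels[i]),
            )
        )
    return WalkRecord(subject_id=subject_id, points=points)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject default-condition cohort used across modules."""
    return simulate_cohort(SimConfig(n_subjects=6, seed=11))
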