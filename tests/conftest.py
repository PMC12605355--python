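"""Shared fixtures: simple crafted masks and a session-scoped graded
synthetic study (generated once, reused by the statistics tests)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import meibomorph as mb
from meibomorph.distribution import compute_indicators

STUDY_SEED = 20260923
N_PER_GRADE = 25


def rect_mask(shape, r0, r1, c0, c1):
    """Axis-aligned filled rectangle on a blank canvas."""
    g = np.zeros(shape, dtype=bool)
    g[r0:r1, c0:c1] = True
    return mb.SegmentationMask(g)


@pytest.fixture(scope="session")
def graded_samples():
    """Seeded grade-stratified dataset at the study's stated size."""
    return mb.generate_graded_dataset(N_PER_GRADE, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def indicator_table(graded_samples):
    """Measured indicator table for the graded dataset (the expensive step)."""
    rows = []
    for s in graded_samples:
        ind = compute_indicators(s.gland_mask, s.tarsus_mask, s.image_id)
        row = ind.as_dict()
        row["grade"] = s.truth.grade
        rows.append(row)
    return pd.DataFrame(rows)
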