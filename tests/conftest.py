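"""Shared fixtures: small synthetic cohorts analysed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from dietfreq import phantom, pipeline
from dietfreq.segmentation import SegmentTable


def make_table(grid, breast_id="B", runs=(23.0,)):
    """SegmentTable from a 4x4 array-like (NaN = missing)."""
    grid = np.asarray(grid, dtype=float)
    counts = np.where(np.isfinite(grid), 10, 0)
    return SegmentTable(breast_id, grid, counts, list(runs))


@pytest.fixture(scope="session")
def small_cohort():
    """4 cancerous + 4 healthy breasts, two runs, segment-scale tumours."""
    recs, manifest = phantom.synth_cohort(
        4,
        4,
        [22.0, 23.0],
        seed=42,
        n_points=300,
        diameter_range=(30.0, 48.0),
        heterogeneity_range=(0.02, 0.08),
    )
    return recs, manifest


@pytest.fixture(scope="session")
def small_cohort_tables(small_cohort):
    recs, manifest = small_cohort
    analyses = pipeline.analyze_cohort(recs)
    labels = dict(zip(manifest["breast_id"], manifest["label"]))
    return analyses, labels
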