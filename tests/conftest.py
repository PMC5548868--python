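"""Shared fixtures: small synthetic cohorts and their FC matrices."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import fcbiomarker as fb


def cohort_fc(spec):
    """Generate a cohort and run the connectivity stage on it."""
    participants, truth = fb.synthetic.generate_cohort(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fc, retention = fb.connectivity.cohort_fc_matrix(
            [
                {"series": p.series, "motion": p.motion, "nuisance": p.nuisance}
                for p in participants
            ]
        )
    attrs = fb.synthetic.cohort_attribute_table(participants)
    return fc, attrs, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """16-participant cohort with a strong planted diagnostic effect."""
    spec = fb.synthetic.SyntheticCohortSpec(
        n_per_group=8,
        n_rois=10,
        n_frames=120,
        planted_edges=[(0, 1), (2, 3), (4, 5)],
        effect_delta=0.5,
        seed=11,
    )
    return cohort_fc(spec)


@pytest.fixture(scope="session")
def trained_pipeline(planted_cohort):
    """Artifacts of the full cascade trained on the planted cohort."""
    fc, attrs, _ = planted_cohort
    config = fb.PipelineConfig(
        scca_fractions_u=[0.2, 0.4, 0.6], scca_fractions_v=[0.2, 0.4]
    )
    return fb.evaluation.train_classifier(fc, attrs, config), fc, attrs
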