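"""Shared fixtures.

The expensive phantom-cohort fixtures are session-scoped and shared
between the module property tests and the acceptance suite: an 8-mouse,
4-pressure cohort at 512 px (the desk-scale stated world) and a
texture-gain sweep at a single pressure used for the accuracy-vs-gain
and misclassification-boundary properties.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lungtex import phantom as ph
from lungtex import pipeline as pl

COHORT_SEED = 11
SWEEP_SEED = 21
SWEEP_GAINS = (0.1, 0.3, 1.0, 3.0)
SWEEP_PRESSURE = 10


@pytest.fixture(scope="session")
def cohort():
    """8 virtual mice x 4 pressures, 512-px frames, fixed master seed."""
    return ph.generate_cohort(8, [6, 8, 10, 12], master_seed=COHORT_SEED,
                              image_side=512)


@pytest.fixture(scope="session")
def cohort_features(cohort) -> pd.DataFrame:
    """Standardized per-window feature table for the full cohort."""
    return pl.cohort_feature_table(cohort)


@pytest.fixture(scope="session")
def gain_sweep():
    """Leave-one-mouse-out segmentation at four texture-gain levels.

    Returns ``{gain: (CVReport, predictions)}`` for 8-mouse cohorts at a
    single pressure whose only difference is the speckle amplitude gain.
    """
    out = {}
    for g in SWEEP_GAINS:
        coh = ph.generate_cohort(
            8, [SWEEP_PRESSURE], master_seed=SWEEP_SEED, image_side=512,
            texture_gain={SWEEP_PRESSURE: g},
        )
        feats = pl.cohort_feature_table(coh)
        reports, preds = pl.segmentation_cv(
            feats, n_trees=128, seed=3, return_predictions=True
        )
        out[g] = (reports[SWEEP_PRESSURE], preds)
    return out


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 mice x 1 pressure at 256 px, for cheap integration tests."""
    return ph.generate_cohort(2, [6], master_seed=1, image_side=256)
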