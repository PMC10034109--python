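"""Shared fixtures: the montage and two small processed cohorts.

The cohort fixtures run the full front end (generation -> preprocessing ->
ICA -> ROI selection -> feature extraction) once per session and are shared
by every test that needs subject-level features, to keep the suite fast.
"""

import warnings

import numpy as np
import pytest

from rtmspredict import (
    PreprocessConfig,
    SyntheticCohortConfig,
    generate_cohort,
    standard_montage_32,
)
from rtmspredict.pipeline import RunConfig, cohort_feature_table

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)

COHORT_DURATION_S = 36.0
COHORT_KEEP_S = 32.0
COHORT_FS = 250.0


@pytest.fixture(scope="session")
def montage():
    return standard_montage_32()


def _processed_cohort(cfg: SyntheticCohortConfig):
    run_cfg = RunConfig(
        cohort=cfg, preprocess=PreprocessConfig(keep_duration_s=COHORT_KEEP_S), seed=cfg.seed
    )
    recordings, truth = generate_cohort(cfg)
    table, reports = cohort_feature_table(recordings, run_cfg)
    return {"recordings": recordings, "truth": truth, "table": table, "reports": reports}


@pytest.fixture(scope="session")
def contrast_cohort():
    """20+20 subjects with the default source-level group contrasts."""
    return _processed_cohort(
        SyntheticCohortConfig(
            n_responders=20, n_nonresponders=20,
            duration_s=COHORT_DURATION_S, fs=COHORT_FS, seed=101,
        )
    )


@pytest.fixture(scope="session")
def null_cohort():
    """20+20 subjects with every group contrast switched off."""
    return _processed_cohort(
        SyntheticCohortConfig.null(
            n_responders=20, n_nonresponders=20,
            duration_s=COHORT_DURATION_S, fs=COHORT_FS, seed=202,
        )
    )
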