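"""Shared fixtures and helpers for the test suite.

Heavy synthetic-cohort computations (full simulate -> detrend -> entropy
paths) are session-scoped so the screening/classification tests and the
acceptance suite share them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

import copbalance as cb
from copbalance import synthetic as syn

# expected sifting-cap warnings would otherwise flood the output
logging.getLogger("copbalance").setLevel(logging.ERROR)


#: Age distribution placing essentially everyone above the 47-year cut,
#: so screening/classification strata are well populated in small cohorts.
ELDERLY_AGES = {label: syn.AgeParams(62.0, 8.0, 50.0, 85.0) for label in cb.DiagnosisLabel}


def pipeline_features(
    config: syn.CohortConfig, detrend: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run simulate -> (detrend) -> ApEn -> pivot in memory.

    Returns (features indexed by patient_id, metadata frame).  ``detrend``
    can be disabled for trend-free configs, where the detrending stage is an
    identity on the structure being measured.
    """
    patients, trials = cb.generate_cohort(config)
    rows = []
    for trial in trials:
        x = trial.samples
        if detrend:
            x = cb.detrend(x, cb.decompose(x))
        rows.append(
            {
                "patient_id": trial.patient_id,
                "condition": trial.condition,
                "axis": trial.axis,
                "apen": cb.apen(x).value,
            }
        )
    features = cb.assemble_features(pd.DataFrame(rows))
    metadata = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "diagnosis": [p.diagnosis.value for p in patients],
            "age": [p.age for p in patients],
        }
    )
    return features, metadata


@pytest.fixture(scope="session")
def planted_screening_cohort():
    """48-patient cohort (12/class, all elderly) with the planted
    NormalBalance-vs-TBI regularity gap, run through the full pipeline."""
    config = syn.CohortConfig(
        class_sizes={label: 12 for label in cb.DiagnosisLabel},
        age_params=ELDERLY_AGES,
        regularity=cb.planted_separation_profile(),
        seed=21,
    )
    return pipeline_features(config, detrend=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
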