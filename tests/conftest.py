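"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fibretmt.io import QuantMatrix
from fibretmt.simulate import (
    CohortParams,
    generate_cohort,
    null_params,
    with_mito_content,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-biology cohort, 8 participants / 32 samples / 2 plexes."""
    params = CohortParams(n_participants_per_group=4, n_proteins=300)
    return generate_cohort(params, seed=11)


@pytest.fixture(scope="session")
def clean_cohort():
    """No technical artefacts, no missingness: biology-only cohort."""
    params = CohortParams(
        n_participants_per_group=4,
        n_proteins=300,
        batch_location_sd=0.0,
        batch_scale_log_sd=0.0,
        loading_log2_sd=0.0,
        missing_intercept=-50.0,
        missing_random_rate=0.0,
    )
    return generate_cohort(params, seed=5)


@pytest.fixture(scope="session")
def content_confound_cohort():
    """2x type-I mitochondrial content, zero per-protein remodelling.

    Technical structure (batches, loading, missingness) stays at study
    defaults; all per-protein biological effects are off, so any
    mitochondrial DE signal is purely the content multiplier.
    """
    params = with_mito_content(
        null_params(
            n_participants_per_group=8,
            n_proteins=1000,
            batch_location_sd=0.30,
            batch_scale_log_sd=0.10,
            loading_log2_sd=0.20,
            missing_intercept=5.0,
            missing_slope=-0.5,
            missing_random_rate=0.005,
        ),
        type_i=2.0,
    )
    return generate_cohort(params, seed=23)


@pytest.fixture()
def toy_matrix():
    """3 proteins x 4 samples log2 matrix with one missing entry."""
    data = pd.DataFrame(
        [[10.0, 11.0, 10.5, 10.2],
         [8.0, np.nan, 8.5, 8.1],
         [12.0, 12.5, 12.2, 12.4]],
        index=["P1", "P2", "P3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return QuantMatrix(data, "log2")
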