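"""Shared fixtures: published-count record frames and small synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from screendx import CohortConfig, generate_population

W_POS = 906 / 287   # design weight, screen-positive stratum
W_NEG = 9057 / 258  # design weight, screen-negative stratum


def _rows(n, stratum, q1, q2, dx_dep, weight):
    return [{"stratum": stratum, "screen_q1": q1, "screen_q2": q2,
             "dx_depression": dx_dep, "design_weight": weight}] * n


@pytest.fixture(scope="session")
def study_frame():
    """Interviewed records reconstructing the study's printed raw counts.

    287 screen-positives (130 depressed; 132 answered yes to both questions,
    80 of them depressed) and 258 screen-negatives (17 depressed), carrying
    the study's design weights 906/287 and 9057/258.  Any-disorder status is
    observed for 285 positives (187 with a disorder) and 251 negatives (55),
    with the remaining modules missing.
    """
    rows = []
    # positive stratum: both-positive block then either-only block
    rows += _rows(80, "positive", 1, 1, 1, W_POS)
    rows += _rows(52, "positive", 1, 1, 0, W_POS)
    rows += _rows(50, "positive", 1, 0, 1, W_POS)
    rows += _rows(105, "positive", 1, 0, 0, W_POS)
    # negative stratum
    rows += _rows(17, "negative", 0, 0, 1, W_NEG)
    rows += _rows(241, "negative", 0, 0, 0, W_NEG)
    df = pd.DataFrame(rows)
    df["id"] = [f"R{i:04d}" for i in range(len(df))]
    df["help_q"] = np.nan
    df["module_observed_depression"] = 1

    # any-disorder: per stratum, first block observed, first sub-block diseased
    pos = df["stratum"] == "positive"
    neg = ~pos
    df["module_observed_any"] = 0
    df.loc[df.index[pos][:285], "module_observed_any"] = 1
    df.loc[df.index[neg][:251], "module_observed_any"] = 1
    df["dx_any"] = 0
    df.loc[df.index[pos][:187], "dx_any"] = 1
    df.loc[df.index[neg][:55], "dx_any"] = 1
    return df


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized population under the default study-structure config."""
    return generate_population(CohortConfig(n_screen=20_000), seed=1)


@pytest.fixture(scope="session")
def large_calibration_cohort():
    """Population under the design-stage screen assumptions, for calibration."""
    config = CohortConfig(
        n_screen=50_000, screen_sens=0.95, screen_spec=0.89,
        prevalence={"depression": 0.09, "anxiety": 0.15, "any_disorder": 0.27})
    return generate_population(config, seed=2), config
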