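"""Shared fixtures.

Expensive artefacts (the survey-preset dataset and its maximum-likelihood
reporting fit) are session-scoped so the unit and acceptance suites share one
computation.
"""

import warnings

import pytest

from misreport import btzip, synthetic


@pytest.fixture(scope="session")
def preset_cfg_8k():
    return synthetic.fecond_like_preset(n_women=8000, seed=42)


@pytest.fixture(scope="session")
def preset_respondents_8k(preset_cfg_8k):
    return synthetic.simulate_respondents(preset_cfg_8k)


@pytest.fixture(scope="session")
def reporting_spec():
    """BT-ZIP specification matching the generator's exclusion restrictions."""
    return btzip.BTZIPSpec(
        count_covariates=["education", "age_group_survey", "parity_survey",
                          "infertility_treatment", "ever_smoked", "bmi_category"],
        zero_covariates=["education"],
        report_covariates=["education", "marital_status", "health", "income"],
    )


@pytest.fixture(scope="session")
def preset_fit_8k(preset_respondents_8k, reporting_spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return btzip.fit(preset_respondents_8k, reporting_spec, seed=0)
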