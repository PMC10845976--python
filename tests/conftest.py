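import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from famsurvey import SurveyConfig, run_survey_pipeline
from famsurvey.synthetic import default_template, make_root_domain_with_mask, make_seed_rows
from famsurvey.profile_scan import profile_from_seed


@pytest.fixture(scope="session")
def template():
    return default_template(0)


@pytest.fixture(scope="session")
def root_and_mask(template):
    return make_root_domain_with_mask(template)


@pytest.fixture(scope="session")
def profile(root_and_mask):
    root, mask = root_and_mask
    ids, rows = make_seed_rows(root, mask, n_rows=20, divergence=0.2, seed=1)
    return profile_from_seed(ids, rows)


@pytest.fixture(scope="session")
def default_config():
    return SurveyConfig(seed=1)


@pytest.fixture(scope="session")
def default_run(default_config):
    """One full pipeline run on the default study conditions, shared broadly."""
    return run_survey_pipeline(default_config)
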