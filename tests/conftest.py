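import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from thermovote import synthetic_data as sd
from thermovote import workflow


@pytest.fixture(scope="session")
def default_campaign():
    """One default-condition synthetic campaign (35 days, 1121 visitors)."""
    return sd.generate_campaign(seed=1)


@pytest.fixture(scope="session")
def default_analysis(default_campaign):
    """Full pipeline run on the default campaign."""
    c = default_campaign
    return workflow.analyze_campaign(c.survey, c.indoor_daily, c.outdoor)


@pytest.fixture(scope="session")
def small_config():
    """Reduced campaign for cheap structural tests."""
    return sd.SyntheticConfig(
        n_days=6,
        n_respondents=120,
        cell_counts=(
            ("male", 30, 40, 15),
            ("female", 30, 40, 15),
            ("male", 65, 75, 20),
            ("female", 65, 75, 30),
        ),
    )
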