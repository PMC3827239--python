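import numpy as np
import pytest

import pondghg as pg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_campaign():
    """A small noisy campaign shared across pipeline tests."""
    return pg.generate_campaign(pg.CampaignConfig(seed=42, n_polygonal=6, n_runnel=8))


@pytest.fixture
def zero_noise_campaign():
    return pg.generate_campaign(
        pg.CampaignConfig(seed=7, n_polygonal=5, n_runnel=5).zero_noise()
    )


def campaign_tables(campaign):
    """Observation tables of a campaign, as run_report expects them."""
    return {
        "ponds": campaign.ponds,
        "wind": campaign.wind,
        "headspace": campaign.headspace,
        "funnels": campaign.funnels,
        "isotopes": campaign.isotopes,
        "radiocarbon": campaign.radiocarbon,
    }
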