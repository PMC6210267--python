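import pytest
from hypothesis import HealthCheck, settings

from pricalib import pipeline, synth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    """Default stated-world generator configuration, seed 1."""
    return synth.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def panel_campaign(config):
    """23-day white-panel campaign: (observations, per-bin truth)."""
    return synth.generate_panel_campaign(config)


@pytest.fixture(scope="session")
def season(config):
    """Full synthetic growing season with ground truth."""
    return synth.generate_season(config)


@pytest.fixture(scope="session")
def pipeline_result(config, panel_campaign, season):
    """The complete analysis run once on the default season."""
    panel, _ = panel_campaign
    return pipeline.run_season_pipeline(
        panel, season.optical, season.broadband, season.wsn, season.flux,
        config.site,
    )
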