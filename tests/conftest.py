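"""Shared fixtures: simulated scenes reused across test modules."""

import pytest

import radarbeat as rb
from radarbeat.experiments import _replicate_scene


@pytest.fixture(scope="session")
def sweep_config() -> rb.SweepConfig:
    """Default experiment configuration with a fixed base seed."""
    return rb.SweepConfig(base_seed=0)


@pytest.fixture(scope="session")
def scene_minus20(sweep_config) -> rb.ChestScene:
    """One -20 dB chest scene with radar baseband (replicate 0)."""
    return _replicate_scene(sweep_config, -20.0, 0)


@pytest.fixture(scope="session")
def scene_heartbeat_only() -> rb.ChestScene:
    """Heartbeat-plus-noise reference scene (no respiration)."""
    return rb.simulate_scene(
        scen=rb.ScenarioParams(seed=42),
        radar=rb.RadarParams(),
        include_respiration=False,
    )
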