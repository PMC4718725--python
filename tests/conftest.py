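"""Shared fixtures: the standard synthetic field trial is built once per
session and reused by most module tests."""

import warnings

import numpy as np
import pytest

from climexp.envparams import DevAnchors, assemble_and_finalize
from climexp.pipeline import (PipelineConfig, averaged_design,
                              build_source_inputs, default_cluster_specs)
from climexp.simulate import (GroundTruth, ScheduleConfig, SoilConfig,
                              WeatherConfig, make_schedule,
                              simulate_expression, simulate_soil_moisture,
                              simulate_weather)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def weather_config():
    return WeatherConfig(seed=7)


@pytest.fixture(scope="session")
def weather(weather_config):
    return simulate_weather(weather_config)


@pytest.fixture(scope="session")
def soil(weather):
    return {f: simulate_soil_moisture(weather, f, SoilConfig())
            for f in ("irrigated", "rainfed")}


@pytest.fixture(scope="session")
def schedule(weather_config):
    return make_schedule(ScheduleConfig(), weather_config)


@pytest.fixture(scope="session")
def design(schedule):
    return averaged_design(schedule)


@pytest.fixture(scope="session")
def anchors():
    return DevAnchors.default_synthetic()


@pytest.fixture(scope="session")
def ed(weather, soil, anchors, design):
    return assemble_and_finalize(weather, soil, anchors, design)


@pytest.fixture(scope="session")
def source_inputs():
    """(weather, soil, schedule, design, ed) for the default pipeline
    configuration at seed 7."""
    return build_source_inputs(PipelineConfig(seed=7))


@pytest.fixture(scope="session")
def global_truth(source_inputs):
    """Ground truth with one global equation per cluster (seed 7)."""
    cfg = PipelineConfig(seed=7)
    *_, ed = source_inputs
    rng = np.random.default_rng(7)
    specs = default_cluster_specs(ed, cfg, rng, segmentations=(("all",),))
    return GroundTruth(clusters=specs, seed=8)


@pytest.fixture(scope="session")
def continuous_expression(source_inputs, global_truth):
    """Noise-free continuous-mode expression for exact checks."""
    weather, soil, schedule, design, ed = source_inputs
    import dataclasses
    clean = [dataclasses.replace(s, gene_noise_sd=0.0, loading_spread=0.0,
                                 shared_noise_sd=0.0, genotype_effect_sd=0.0)
             for s in global_truth.clusters]
    truth = GroundTruth(clusters=clean, n_low_cv_genes=5, n_low_mean_genes=5,
                        n_background_genes=0, seed=9)
    expr = simulate_expression(ed.values, design, schedule, truth,
                               mode="continuous")
    return expr, truth
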