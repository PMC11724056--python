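"""Shared fixtures: small fast synthetic datasets and the cached default runs.

The default full-scale pipeline run is expensive (~40 s), so it is
computed once per session per seed and shared by every test that needs
planted-truth recovery at the study's default conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

from scarscreen import pipeline, synthdata


def small_synth_kwargs(**overrides) -> dict:
    """Desk-scale generator overrides for structural unit tests."""
    kwargs = dict(
        n_genes=300,
        n_cells_per_timepoint=800,
        n_markers_per_cluster=12,
        n_markers_per_subcluster=6,
        grid_shape=(15, 15),
        wound_radius_um=350.0,
    )
    kwargs.update(overrides)
    return kwargs


@pytest.fixture(scope="session")
def small_config() -> synthdata.SynthConfig:
    return synthdata.SynthConfig(seed=11, **small_synth_kwargs())


@pytest.fixture(scope="session")
def small_single_cell(small_config):
    return synthdata.generate_single_cell(small_config)


@pytest.fixture(scope="session")
def default_runs():
    """Lazily computed full-default pipeline runs keyed by seed."""
    cache: dict[int, pipeline.PipelineResult] = {}

    def get(seed: int) -> pipeline.PipelineResult:
        if seed not in cache:
            cache[seed] = pipeline.run_screen_stages(pipeline.PipelineConfig(seed=seed))
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def deconv_bench_config():
    """Six-type benchmark generator for deconvolution recovery tests."""

    def make(seed: int) -> synthdata.SynthConfig:
        return synthdata.SynthConfig(
            seed=seed, n_genes=300, n_cells_per_timepoint=1500,
            major_types={"F": (.2, .3, .35), "M": (.25, .22, .15),
                         "N": (.2, .06, .03), "EpC": (.15, .2, .24),
                         "EC": (.1, .12, .13), "TC": (.1, .1, .1)},
            region_composition={
                "wound": {"F": .45, "M": .3, "N": .1, "EpC": .05, "EC": .06, "TC": .04},
                "intact": {"F": .2, "M": .05, "N": .02, "EpC": .45, "EC": .18, "TC": .1},
                "muscle": {"F": .1, "M": .05, "N": 0., "EpC": .35, "EC": .4, "TC": .1}},
            grid_shape=(20, 20), n_markers_per_cluster=20, n_markers_per_subcluster=6)

    return make


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
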