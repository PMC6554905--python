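"""Shared fixtures: a compact endmember library/scene and one full study run.

The default 185-plant study is expensive enough that the end-to-end and
tissue-classification tests share a single session-scoped run.
"""

from __future__ import annotations

import numpy as np
import pytest

import grassspec as gs


@pytest.fixture(scope="session")
def library() -> gs.EndmemberLibrary:
    return gs.default_library()


@pytest.fixture()
def small_scene() -> gs.SceneConfig:
    return gs.SceneConfig(lines=40, samples=32, plant_fraction=0.4, seed=11)


@pytest.fixture()
def clean_scene() -> gs.SceneConfig:
    """Noise-free, gradient-free small acquisition."""
    return gs.SceneConfig(
        lines=40, samples=32, plant_fraction=0.4, noise_sd=0.0,
        lighting_gradient=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def attribute_names() -> list[str]:
    return [s.name for s in gs.default_attribute_specs()]


@pytest.fixture(scope="session")
def default_study() -> gs.StudyResult:
    """One full default study (185 plants, default noise, gradient on)."""
    return gs.run_study(gs.StudyConfig())


def bl_ps_rows(table, plant_id, names):
    """Ground-truth BL and PS attribute dicts for one plant."""
    bl = table[(table.plant_id == plant_id) & (table.tissue == "BL")].iloc[0]
    ps = table[(table.plant_id == plant_id) & (table.tissue == "PS")].iloc[0]
    return bl[names].to_dict(), ps[names].to_dict()


@pytest.fixture()
def rng() -> np.random.Generator:
    """Fresh deterministic generator per test (order-independent streams)."""
    return np.random.default_rng(20160322)
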