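"""Shared fixtures: acquisition configs, a lossless calibrant material,
small simulated cubes, and (session-scoped) the trained benchmark models.
"""

from __future__ import annotations

import pytest

import thzchem as tz
from thzchem.materials import DEFAULT_MATERIALS, MaterialSpec
from thzchem.simulate import Placement, SceneSpec, simulate_scene


@pytest.fixture(scope="session")
def acq():
    return tz.AcquisitionConfig()


@pytest.fixture(scope="session")
def acq_quiet():
    """Noise-free acquisition."""
    return tz.AcquisitionConfig(noise_dynamic_range_db=None)


@pytest.fixture(scope="session")
def calibrant():
    """Lossless n=1.7 material: P3-P2 separation (14 ps at d=3 mm) clears
    the 13-ps minimum pulse separation, so all four echoes are kept."""
    return MaterialSpec("CAL", 0, 1.7)


@pytest.fixture(scope="session")
def cal_registry(calibrant):
    reg = dict(DEFAULT_MATERIALS)
    reg["CAL"] = calibrant
    return reg


def edge_adjacent_scene(seed: int = 1) -> SceneSpec:
    """Disk placed so pixel (10, 6) has beam overlap ~0.9: all of P1..P4
    exceed the detection threshold there.  Geometry jitter off so echo
    delays are exactly analytic."""
    return SceneSpec(
        placements=(Placement("CAL", (6.0, 5.7), 10.0, 3.0),),
        surface_jitter_mm=0.0, thickness_jitter_mm=0.0, seed=seed)


@pytest.fixture(scope="session")
def cal_scene():
    return edge_adjacent_scene()


@pytest.fixture(scope="session")
def kno3_scene():
    return tz.make_disk_scene("KNO3", seed=301)


@pytest.fixture(scope="session")
def kno3_cube(kno3_scene, acq):
    return simulate_scene(kno3_scene, acq)


@pytest.fixture(scope="session")
def kno3_grid(kno3_cube):
    return tz.extract_cube(kno3_cube)


@pytest.fixture(scope="session")
def bare_metal_cube(acq):
    return simulate_scene(SceneSpec(placements=(), seed=7), acq)


@pytest.fixture(scope="session")
def benchmark_run():
    """Full desk-scale benchmark: simulate, train both networks on the
    uncovered scenes, blind-test on uncovered and covered scenes.  Shared
    across the acceptance tests (this is the expensive fixture)."""
    from thzchem.pipeline import default_run_config, run_benchmark

    metrics, arts = run_benchmark(default_run_config(seed=1))
    return metrics, arts
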