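import numpy as np
import pytest

from myowalk.sequences import default_spec, make_waveform
from myowalk.substrate import (
    CrossSectionSet,
    TissueBlock,
    build_substrate,
    generate_cross_sections,
    morph_ecv,
)
from shapely.geometry import Polygon


@pytest.fixture(scope="session")
def small_packing():
    """36-cell jittered packing morphed to the default healthy ECV."""
    cs = generate_cross_sections(36, mean_diameter=18.0, seed=11)
    return morph_ecv(cs, 0.2469)


@pytest.fixture(scope="session")
def small_substrate(small_packing):
    block = TissueBlock(small_packing, Lz=127.0, icd_depth=2.0)
    return build_substrate(block, voxel=(400.0, 400.0, 800.0), ha_rate=10.0,
                           half_shift=True, buffer=40.0)


@pytest.fixture(scope="session")
def square_cell_substrate():
    """One 20x20 um square cell centred in a 40x40 block: analytic geometry."""
    sq = Polygon([(10.0, 10.0), (30.0, 10.0), (30.0, 30.0), (10.0, 30.0)])
    cs = CrossSectionSet((sq,), (0,), 40.0, 40.0)
    block = TissueBlock(cs, Lz=100.0, icd_depth=2.0)
    return build_substrate(block, voxel=(40.0, 40.0, 100.0), ha_rate=0.0,
                           half_shift=False, buffer=0.0)


@pytest.fixture(scope="session")
def free_substrate():
    """No cells at all: free diffusion at D_ECS everywhere."""
    cs = CrossSectionSet((), (), 100.0, 100.0)
    block = TissueBlock(cs, Lz=100.0, icd_depth=0.0)
    return build_substrate(block, voxel=(2800.0, 2800.0, 8000.0), ha_rate=0.0,
                           half_shift=False, buffer=0.0)


@pytest.fixture(scope="session")
def waveforms():
    return {k: make_waveform(default_spec(k, b=0.6)) for k in ("STEAM", "PGSE", "MCSE")}
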