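"""Shared fixtures: desk-scale source/protocol and cached reconstructions.

Heavy simulate→reconstruct products are session-scoped so multiple tests can
characterize the same volume without re-synthesizing it.
"""

from __future__ import annotations

import numpy as np
import pytest

from pdoct import presets
from pdoct.polarimetry import dopu, estimate_noise, stokes_from_jones
from pdoct.recon import CalibrationMap, reconstruct
from pdoct.simulator import NoiseSpec, synthesize_volume, truth_masks


@pytest.fixture(scope="session")
def desk_src():
    return presets.desk_source()


@pytest.fixture(scope="session")
def desk_src_linear():
    return presets.desk_source(sweep=(1.0,))


@pytest.fixture(scope="session")
def cal_true(desk_src):
    return CalibrationMap.from_source(desk_src)


@pytest.fixture(scope="session")
def slab_recon(desk_src, cal_true):
    """Noise-free polarization-preserving slab: raw, volume, truth mask."""
    protocol = presets.desk_protocol(alines=64, bscans=8)
    phantom = presets.slab_phantom(0.0)
    raw = synthesize_volume(phantom, desk_src, protocol, NoiseSpec(), seed=1)
    vol = reconstruct(raw, cal_true)
    masks = truth_masks(phantom, protocol, vol.depth_axis)
    return {
        "phantom": phantom,
        "protocol": protocol,
        "raw": raw,
        "vol": vol,
        "masks": masks,
        "in_slab": masks.labels == 1,
    }


@pytest.fixture(scope="session")
def slab_dopu(slab_recon):
    vol = slab_recon["vol"]
    stokes = stokes_from_jones(vol, estimate_noise(vol))
    return dopu(stokes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
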