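"""Shared fixtures: synthetic stacks that are expensive to build/analyze."""

from __future__ import annotations

import numpy as np
import pytest

from cardioquant.synthetic import (
    MultichannelSpec,
    VesselSpec,
    gen_multichannel,
)


@pytest.fixture(scope="session")
def cm_stack():
    """100 CM nuclei (4 EdU+) and 50 capillary nuclei (3 EdU+)."""
    spec = MultichannelSpec(
        image_shape=(512, 384),
        n_nuclei=100,
        render_cm_channels=True,
        n_capillary_nuclei=50,
        marker_fractions={"edu": 0.04},
        capillary_marker_fractions={"edu": 0.06},
        seed=3,
    )
    return gen_multichannel(spec)


@pytest.fixture(scope="session")
def scar_band_stack():
    """WGA band covering 40% of the frame, 30 nuclei inside, 10% EdU+."""
    spec = MultichannelSpec(
        image_shape=(512, 200),
        n_nuclei=30,
        scar_band_px=80,
        marker_fractions={"edu": 0.1},
        coverage_fractions={"pdgfrb": 0.30},
        seed=2,
    )
    return gen_multichannel(spec)


@pytest.fixture(scope="session")
def artery_stack():
    """Vessels of 8, 12 and 20 µm diameter inside the scar band."""
    spec = MultichannelSpec(
        image_shape=(512, 320),
        pixel_size=0.5,
        n_nuclei=10,
        scar_band_px=90,
        vessels=(VesselSpec(8.0), VesselSpec(12.0), VesselSpec(20.0)),
        seed=4,
    )
    return gen_multichannel(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
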