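"""Shared fixtures: small deterministic beds and one calibrated load sweep.

Expensive objects (the full-density default bed and its study-design sweep)
are session-scoped so the suite solves them once.
"""

import numpy as np
import pytest

from frictionpad.padmech import FibrilBed, PadGeometry, sweep_loads
from frictionpad.synthgen import STUDY_LOADS, make_fibril_bed


@pytest.fixture(scope="session")
def default_pad() -> PadGeometry:
    return PadGeometry()


@pytest.fixture(scope="session")
def default_bed(default_pad) -> FibrilBed:
    return make_fibril_bed(0.19, default_pad, tip_height_sd=2.5, seed=1)


@pytest.fixture(scope="session")
def default_sweep(default_bed, default_pad):
    """Study-design load sweep of the calibrated default bed."""
    return sweep_loads(default_bed, default_pad, list(STUDY_LOADS))


@pytest.fixture(scope="session")
def tiny_bed_pad():
    """A ≤20-fibril bed small enough for brute-force oracles."""
    rng = np.random.default_rng(7)
    pad = PadGeometry(dome_radius=500.0, footprint_area=300.0)
    n = 15
    r = pad.footprint_radius
    positions = rng.uniform(-r / 1.5, r / 1.5, (n, 2))
    offsets = np.abs(rng.normal(0.0, 1.0, n))
    bed = FibrilBed(positions=positions, tip_offsets=offsets,
                    footprint_area=pad.footprint_area)
    return bed, pad
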