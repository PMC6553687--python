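"""Shared fixtures: synthetic traces built from prescribed series."""

from __future__ import annotations

import numpy as np
import pytest

from phyllosim.geometry import Primordium
from phyllosim.simulate import SimSettings, SimulationTrace


def trace_from_series(divergences, plastochrons=None, theta0=0.0, model_tag="dc1"):
    """Build a trace whose consecutive divergence angles are prescribed.

    ``plastochrons`` defaults to unit spacing; pass explicit birth-time
    gaps (one per divergence) to emulate oscillating plastochrons or
    simultaneous insertions (gap 0 -> same node).
    """
    divergences = np.asarray(divergences, dtype=float)
    if plastochrons is None:
        plastochrons = np.ones_like(divergences)
    plastochrons = np.asarray(plastochrons, dtype=float)
    assert len(plastochrons) == len(divergences)
    thetas = theta0 + np.concatenate(([0.0], np.cumsum(divergences)))
    births = np.concatenate(([0.0], np.cumsum(plastochrons)))
    prims = [
        Primordium(i + 1, th % 360.0, bt)
        for i, (th, bt) in enumerate(zip(thetas, births))
    ]
    return SimulationTrace(prims, model_tag, None, SimSettings(), [])


@pytest.fixture
def make_trace():
    return trace_from_series


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
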