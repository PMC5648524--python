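"""Shared fixtures: small synthetic recordings and stacks.

Everything is generated programmatically with fixed seeds; module-scoped
fixtures are reused across tests to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from caslice.synthetic import (
    gamma_train,
    generate_ihc_stack,
    generate_preset_slice,
    render_dff,
)
from caslice.types import FluorescenceTrace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="module")
def pfrg_control():
    """One pFRG/RTN control preset slice (5 min)."""
    return generate_preset_slice("pFRG/RTN", "control", seed=11)


@pytest.fixture(scope="module")
def prebotc_control():
    """One preBötC control preset slice (5 min)."""
    return generate_preset_slice("preBotC", "control", seed=12)


@pytest.fixture(scope="module")
def small_stack():
    """A small two-channel stack: fast fixture for ROI tests."""
    return generate_ihc_stack(
        n_cells_per_channel=(40, 12), overlap_fraction=0.75,
        penetration_fraction=0.30, stack_depth_um=54.0, seed=5,
        field_px=(128, 128))


def make_trace(peak_times_s, amplitude=0.45, noise_sd=0.0, duration_s=300.0,
               dt=0.5, offset=100.0, seed=0, cell_id="cell"):
    """Raw-intensity trace with transients planted at the given times."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt))
    t = np.asarray(peak_times_s, dtype=float)
    amps = np.full(t.size, amplitude)
    dff = render_dff(t, amps, n, dt)
    if noise_sd > 0:
        dff = dff + rng.normal(0.0, noise_sd, n)
    return FluorescenceTrace(offset * (1.0 + dff), dt, cell_id)


def make_gamma_trace(rate_cpm, cv_pct=33.0, duration_s=300.0, seed=0,
                     noise_sd=0.015, amplitude=0.45):
    """Gamma-renewal transient train rendered as a raw trace."""
    rng = np.random.default_rng(seed)
    dt = 0.5
    n = int(round(duration_s / dt))
    t = gamma_train(rng, rate_cpm, cv_pct, 0.0, duration_s)
    amps = amplitude * rng.uniform(0.85, 1.15, size=t.size)
    dff = render_dff(t, amps, n, dt)
    dff = dff + rng.normal(0.0, noise_sd, n)
    return FluorescenceTrace(100.0 * (1.0 + dff), dt, f"g{seed}"), t
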