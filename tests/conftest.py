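"""Shared fixtures: field solutions are expensive, solve them once."""

from __future__ import annotations

import numpy as np
import pytest

from depcyte.dielectrics import MEDIA
from depcyte.field_solver import ChannelGeometry, ElectrodeLayout, solve_potential
from depcyte.transport import TransportParams


@pytest.fixture(scope="session")
def dep_medium():
    return MEDIA["dep_medium"]


@pytest.fixture(scope="session")
def field_8vpp():
    """Discrimination drive: 8 Vpp at 6 MHz, default geometry."""
    return solve_potential(ElectrodeLayout(applied_voltage_vpp=8.0),
                           ChannelGeometry(), 0.5e-6)


@pytest.fixture(scope="session")
def field_2vpp():
    """Quantitative-mapping drive: 2 Vpp at 6 MHz."""
    return solve_potential(ElectrodeLayout(applied_voltage_vpp=2.0),
                           ChannelGeometry(), 0.5e-6)


@pytest.fixture(scope="session")
def cho_params(dep_medium):
    """Nominal viable-CHO-sized transport parameters (Re{Kcm} overridden
    per test via dataclasses.replace)."""
    return TransportParams(medium=dep_medium, radius=6.25e-6, re_kcm=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20241127)


@pytest.fixture(scope="session")
def mapping_grid(cho_params, field_2vpp):
    """Forward (r, Kcm, vi) -> v_diff grid at the quantitative 2 Vpp drive."""
    from depcyte.kcm_mapping import build_mapping

    return build_mapping(
        cho_params, field_2vpp,
        r_axis=np.array([5.0e-6, 5.65e-6, 6.3e-6, 6.95e-6, 7.6e-6]),
        kcm_axis=np.array([-0.5, -0.35, -0.2, -0.05, 0.1, 0.25, 0.4, 0.55]),
        vi_axis=np.array([1080e-6, 1170e-6, 1260e-6, 1350e-6, 1440e-6]))
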