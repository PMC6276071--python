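"""Shared fixtures and independent oracles.

The oracles here are deliberately separate from the package: the
4-state carrier steady state is re-derived with a hand-assembled rate
matrix, and the rapid-equilibrium closed forms are written out
algebraically, so tests compare two independent routes to the same
quantity."""

from __future__ import annotations

import numpy as np
import pytest

from portersim import (
    CarrierParams,
    build_asymmetric_carrier,
    build_symmetric_carrier,
    calibrate_reference_carrier,
)

SMALL_GRID = tuple(np.geomspace(0.03, 300.0, 12))


@pytest.fixture
def sym_model():
    return build_symmetric_carrier()


@pytest.fixture
def asym_model():
    return build_asymmetric_carrier()


@pytest.fixture(scope="session")
def reference_calibration():
    """The reference-carrier calibration is expensive enough to share."""
    return calibrate_reference_carrier(seed=0)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_carrier_occupancies(p: CarrierParams, s_out: float, s_in: float):
    """Steady state of the 4-state carrier from a hand-built rate matrix
    (states ordered C_out, GC_out, GC_in, C_in), independent of the
    package's network machinery."""
    p = p.resolve()
    a = np.zeros((4, 4))

    def add(i, j, r):
        a[j, i] += r
        a[i, i] -= r

    add(0, 1, p.k_on * s_out)
    add(1, 0, p.k_on * p.kd_out)
    add(1, 2, p.f_out_in)
    add(2, 1, p.f_in_out)
    add(2, 3, p.k_on * p.kd_in)
    add(3, 2, p.k_on * s_in)
    add(3, 0, p.b_in_out)
    add(0, 3, p.b_out_in)
    m = a.copy()
    m[0, :] = 1.0
    rhs = np.zeros(4)
    rhs[0] = p.total_carrier
    return np.linalg.solve(m, rhs)


def oracle_net_influx(p: CarrierParams, s_out: float, s_in: float) -> float:
    p = p.resolve()
    x = oracle_carrier_occupancies(p, s_out, s_in)
    return p.k_on * p.kd_in * x[2] - p.k_on * s_in * x[3]


def rapid_equilibrium_forms(p: CarrierParams) -> dict[str, float]:
    """Closed-form kinetic parameters in the rapid-binding limit
    (association/dissociation much faster than carrier transit)."""
    p = p.resolve()
    fo, fi = p.f_out_in, p.f_in_out
    boi, bio = p.b_out_in, p.b_in_out
    return {
        "vm_influx": fo * bio / (fo + bio),
        "km_influx": p.kd_out * (bio + boi) / (bio + fo),
        "vm_efflux": fi * boi / (fi + boi),
        "vm_exchange": fo * fi / (fo + fi),
    }
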