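"""Thermodynamic calculators and equilibrium audits.

These implement the free-energy bookkeeping used to scrutinise
asymmetric carrier schemes: the Gibbs energy gap between binding sites
of unequal affinity, the vacant-carrier distribution it forces at
equilibrium, the energy equivalent of an asymmetric empty-carrier rate
pair, and the chemical-potential/activity-coefficient relations showing
that any equilibrium asymmetry in a mobile component's concentration
must be offset by a reciprocal asymmetry in activity coefficients
(Gibbs' phase rule), leaving no free energy to drive transport.

Energies are in kJ/mol with natural logarithms; the default temperature
is 303.15 K (30 degrees C).  The simulator itself is an ideal mixture:
the equilibrium audit checks concentrations, while activity-coefficient
handling is confined to the calculators here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import GAS_CONSTANT
from .network import (
    CLAMPED,
    ConfigurationError,
    NetworkModel,
    SteadyStateResult,
    solve_steady_state,
)

__all__ = [
    "EnergyContext",
    "ThermoState",
    "EnergyReport",
    "EquilibriumAudit",
    "site_energy_gap",
    "vacant_ratio_from_kd",
    "empty_rate_ratio_from_vacant_ratio",
    "rate_asymmetry_energy",
    "chemical_potential",
    "activity_coefficient_ratio",
    "partition_ratio",
    "equilibrium_audit",
    "energy_report",
]


@dataclass(frozen=True)
class EnergyContext:
    """Temperature context; R in J/(mol K), T in K."""

    temperature: float = 303.15
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive kelvin")

    @property
    def rt(self) -> float:
        """R*T in kJ/mol."""
        return self.gas_constant * self.temperature / 1000.0


@dataclass(frozen=True)
class ThermoState:
    """Chemical-potential inputs for one component in one phase:
    mu0 (kJ/mol), mole fraction x and activity coefficient gamma;
    the activity is a = x * gamma."""

    mu0: float
    mole_fraction: float
    activity_coefficient: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.mole_fraction <= 1.0):
            raise ValueError("mole fraction must lie in [0, 1]")
        if self.activity_coefficient <= 0:
            raise ValueError("activity coefficient must be positive")

    @property
    def activity(self) -> float:
        return self.mole_fraction * self.activity_coefficient


def site_energy_gap(kd_in: float, kd_out: float,
                    ctx: EnergyContext = EnergyContext()) -> float:
    """Gibbs free-energy difference (kJ/mol) of ligand bound at sites of
    unequal affinity: RT ln(kd_in/kd_out).  Positive when the inside
    site is the weaker binder."""
    if kd_in <= 0 or kd_out <= 0:
        raise ValueError("dissociation constants must be positive")
    return ctx.rt * math.log(kd_in / kd_out)


def vacant_ratio_from_kd(kd_in: float, kd_out: float) -> float:
    """Equilibrium vacant-site distribution C_in/C_out forced by the
    affinity asymmetry of a single-cycle carrier: kd_in/kd_out."""
    if kd_in <= 0 or kd_out <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_in / kd_out


def empty_rate_ratio_from_vacant_ratio(ratio: float) -> float:
    """Empty-carrier unidirectional rate ratio k_out-in / k_in-out
    required to sustain a vacant-site ratio C_in/C_out at equilibrium
    (flux balance C_out * k_oi = C_in * k_io): equal to the ratio."""
    if ratio <= 0:
        raise ValueError("vacant-site ratio must be positive")
    return ratio


def rate_asymmetry_energy(k_oi: float, k_io: float,
                          ctx: EnergyContext = EnergyContext()) -> float:
    """Free-energy equivalent (kJ/mol) of an asymmetric empty-carrier
    rate pair: -RT ln(k_oi/k_io); negative when the inward rate is the
    faster (about -5.8 kJ/mol for a tenfold ratio at 30 degrees C)."""
    if k_oi <= 0 or k_io <= 0:
        raise ValueError("rates must be positive")
    return -ctx.rt * math.log(k_oi / k_io)


def chemical_potential(state: ThermoState,
                       ctx: EnergyContext = EnergyContext()) -> float:
    """mu = mu0 + RT ln(a); undefined (raises) at zero activity."""
    a = state.activity
    if a <= 0:
        raise ValueError("chemical potential undefined at zero activity")
    return state.mu0 + ctx.rt * math.log(a)


def activity_coefficient_ratio(x_i: float, x_j: float) -> float:
    """gamma_j / gamma_i required for phases i and j to share one
    activity when their mole fractions differ: x_i / x_j.  A tenfold
    concentration asymmetry therefore demands a reciprocal tenfold
    activity-coefficient asymmetry -- no free energy is stored."""
    if x_i <= 0 or x_j <= 0:
        raise ValueError("mole fractions must be positive")
    return x_i / x_j


@dataclass(frozen=True)
class EnergyReport:
    """Site-affinity energy gap and empty-rate asymmetry energy for one
    carrier parameterisation, with inputs echoed.  For a detailed-
    balanced carrier the two cancel -- the bookkeeping by which the
    alternating-access scheme claims a free transport cycle."""

    kd_in: float
    kd_out: float
    k_oi: float
    k_io: float
    temperature: float
    site_gap: float
    rate_asymmetry: float

    @property
    def total(self) -> float:
        return self.site_gap + self.rate_asymmetry


def energy_report(kd_in: float, kd_out: float, k_oi: float, k_io: float,
                  ctx: EnergyContext = EnergyContext()) -> EnergyReport:
    return EnergyReport(kd_in, kd_out, k_oi, k_io, ctx.temperature,
                        site_energy_gap(kd_in, kd_out, ctx),
                        rate_asymmetry_energy(k_oi, k_io, ctx))


def partition_ratio(ss: SteadyStateResult) -> float:
    """(C_out + GC_out) / (C_in + GC_in): the ratio of total
    outward-facing to total inward-facing carrier, as a function of the
    ligand concentrations behind ``ss``."""
    out_total = in_total = 0.0
    for state in ss.model.states.values():
        if state.location == "outward":
            out_total += ss.occupancy[state.id]
        elif state.location == "inward":
            in_total += ss.occupancy[state.id]
    if out_total == 0.0 and in_total == 0.0:
        raise ConfigurationError(
            "partition ratio needs a carrier model with outward/inward states")
    return out_total / in_total


@dataclass
class EquilibriumAudit:
    """Uniformity check at equal bath concentrations: every free pool
    must sit at the bath concentration and every elementary step must
    carry zero net flux."""

    bath_conc: float
    pool_conc: dict[str, float]
    net_fluxes: dict[str, float]
    max_conc_deviation: float
    max_flux_imbalance: float
    tolerance: float
    uniform: bool


def equilibrium_audit(model: NetworkModel, bath_conc: float,
                      tolerance: float = 1e-8) -> EquilibriumAudit:
    """Clamp both baths at ``bath_conc``, solve the steady state, and
    verify the Gibbs-phase-rule expectation for a passive network: all
    intermediate pools equilibrate to the bath concentration and every
    transition pair is in detailed balance (zero net flux)."""
    if bath_conc < 0:
        raise ValueError("bath concentration must be non-negative")
    clamps = {c.name: bath_conc for c in model.compartments.values()
              if c.kind == CLAMPED}
    ss = solve_steady_state(model, clamps)
    pool_conc: dict[str, float] = {}
    max_dev = 0.0
    for comp, per_species in ss.conc.items():
        total = sum(per_species.values())
        pool_conc[comp] = total
        max_dev = max(max_dev, abs(total - bath_conc))
    scale = max(bath_conc, 1.0)
    net = {}
    max_imb = 0.0
    for fwd, rev in ss.model.reversible_pairs():
        n = ss.flux[fwd.name] - ss.flux[rev.name]
        net[fwd.name] = n
        one_way = max(ss.flux[fwd.name], ss.flux[rev.name], 1e-300)
        if one_way > 1e-12:
            max_imb = max(max_imb, abs(n) / one_way)
    uniform = max_dev <= tolerance * scale and max_imb <= max(tolerance, 1e-7)
    return EquilibriumAudit(bath_conc, pool_conc, net, max_dev, max_imb,
                            tolerance, uniform)
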