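"""Builders for the transporter model families.

Two families are covered:

* **Alternating carrier** (4-state single cycle): an empty binding site
  that faces either bath and translocates bound ligand during carrier
  inversion.  Symmetric and asymmetric variants; the asymmetric builder
  can close the cycle automatically so the rate products satisfy
  detailed balance.
* **Fixed-site (staged diffusion)**: a chain of fixed-affinity binding
  sites separated by diffusive voids; ligand hops bath -> void -> site ->
  void -> ... with no translocating conformational step.  Variants add a
  dual-occupancy exchange site at the chain midpoint and parallel
  low-affinity portal sites at the external mouth (two tunnels, one of
  which can be blocked to emulate the GLUT1-deficiency T295M lesion).

Rate and affinity defaults follow the package's reference
parameterisation of erythrocyte glucose transport: outside site
K_D = 3 mmol/L, inside site K_D = 30 mmol/L (tenfold affinity
asymmetry), liganded carrier transit 10x the fast empty-carrier rate,
association 1000x the fast empty rate per mmol/L.  The fast empty rate
sets the time scale (1 s^-1) and the total carrier is 1, so fluxes are
reported per carrier per second; comparisons against experiment are made
on Km values (mmol/L) and flux ratios, which are independent of the
carrier amount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import (
    CLAMPED,
    FINITE,
    VOID,
    ConfigurationError,
    NetworkModel,
    StructuralError,
)

__all__ = [
    "SPECIES",
    "GAS_CONSTANT",
    "CarrierParams",
    "MultisiteParams",
    "build_symmetric_carrier",
    "build_asymmetric_carrier",
    "build_multisite_chain",
    "build_branched_multisite",
    "arrhenius_scale",
    "random_balanced_carrier",
]

SPECIES = "glucose"

#: J/(mol K)
GAS_CONSTANT = 8.314462618


@dataclass
class CarrierParams:
    """Rate constants of the 4-state alternating carrier.

    ``kd_out`` / ``kd_in``: site dissociation constants (mmol/L) on the
    two faces; dissociation rates are ``k_on * kd``.
    ``b_out_in`` / ``b_in_out``: empty-carrier transit rates (s^-1).
    ``f_out_in`` / ``f_in_out``: liganded-carrier transit rates (s^-1).
    ``k_on``: association rate, both faces ((mmol/L)^-1 s^-1).

    With ``auto_close=True``, ``b_in_out`` is derived from the
    cycle-closure identity

        f_out_in * kd_in * b_in_out = b_out_in * f_in_out * kd_out

    so that the forward and reverse rate products around the cycle are
    equal (detailed balance); supplying ``b_in_out`` as well is then a
    conflicting over-determination and raises.
    """

    kd_out: float = 3.0
    kd_in: float = 3.0
    b_out_in: float = 1.0
    b_in_out: float | None = 1.0
    f_out_in: float = 10.0
    f_in_out: float = 10.0
    k_on: float = 1000.0
    auto_close: bool = False
    total_carrier: float = 1.0

    def closed_b_in_out(self) -> float:
        return self.b_out_in * self.f_in_out * self.kd_out / (self.f_out_in * self.kd_in)

    def resolve(self) -> "CarrierParams":
        """Return a copy with ``b_in_out`` filled in (auto-closure)."""
        for name in ("kd_out", "kd_in", "b_out_in", "f_out_in", "f_in_out", "k_on"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"carrier parameter {name} must be positive")
        b = self.b_in_out
        if self.auto_close:
            closed = self.closed_b_in_out()
            if b is not None and not math.isclose(b, closed, rel_tol=1e-9):
                raise ConfigurationError(
                    "auto_close conflicts with the supplied b_in_out: cycle closure "
                    f"requires b_in_out = b_out_in*f_in_out*kd_out/(f_out_in*kd_in) "
                    f"= {closed:g}, got {b:g}")
            b = closed
        if b is None:
            raise ValueError("b_in_out is required unless auto_close is set")
        if not b > 0:
            raise ValueError("b_in_out must be positive")
        out = CarrierParams(**{**self.__dict__})
        out.b_in_out = b
        return out


def _carrier_model(p: CarrierParams) -> NetworkModel:
    m = NetworkModel()
    m.add_species(SPECIES)
    m.add_compartment("out", CLAMPED, conc={SPECIES: 0.0})
    m.add_compartment("in", CLAMPED, conc={SPECIES: 0.0})
    m.add_state("C_out", location="outward", group="carrier")
    m.add_state("GC_out", location="outward", occupants=(SPECIES,), group="carrier")
    m.add_state("GC_in", location="inward", occupants=(SPECIES,), group="carrier")
    m.add_state("C_in", location="inward", group="carrier")
    m.groups["carrier"] = p.total_carrier
    m.add_binding("C_out", "GC_out", "out", SPECIES, p.k_on, p.k_on * p.kd_out,
                  name="bind_out")
    m.add_binding("C_in", "GC_in", "in", SPECIES, p.k_on, p.k_on * p.kd_in,
                  name="bind_in")
    m.add_conformational("GC_out", "GC_in", p.f_out_in, p.f_in_out, name="loaded")
    m.add_conformational("C_out", "C_in", p.b_out_in, p.b_in_out, name="empty")
    m.validate()
    return m


def build_symmetric_carrier(params: CarrierParams | None = None) -> NetworkModel:
    """Symmetric 4-state carrier: equal affinities (K_D = 3 mmol/L) and
    equal transit rates on the two faces; liganded transit 10x and
    association 1000x (per mmol/L) the empty-carrier rate of 1 s^-1."""
    p = (params or CarrierParams()).resolve()
    return _carrier_model(p)


def build_asymmetric_carrier(params: CarrierParams | None = None) -> NetworkModel:
    """Asymmetric 4-state carrier.  Defaults: outside K_D = 3 mmol/L,
    inside K_D = 30 mmol/L, symmetric liganded transit, with the slow
    empty return rate derived by cycle closure (detailed balance), which
    makes the equal-bath vacant-site ratio C_in/C_out equal kd_in/kd_out.
    """
    if params is None:
        params = CarrierParams(kd_out=3.0, kd_in=30.0, b_out_in=1.0, b_in_out=None,
                               auto_close=True)
    p = params.resolve()
    return _carrier_model(p)


@dataclass
class MultisiteParams:
    """Parameters of the fixed-site (staged diffusion) chain.

    ``site_kds``: ordered dissociation constants, outside first (mmol/L).
    ``k_on_site``: association rate at every site face.
    ``conductance``: bath<->vestibule and void diffusion conductance
    (amount per s per mmol/L).
    ``void_capacity``: amount held by a void per mmol/L; voids are small
    relative to the baths.
    ``exchange_site``: insert a dual-occupancy site (with an occupant
    swap transition) at the chain midpoint, enabling isotope exchange
    without net transport.
    ``branch_k_on`` / ``branch_kd`` / ``n_branches``: low-affinity portal
    sites forming the parallel tunnels between the outside bath and the
    external vestibule (branched builder only); a branch rate of 0 marks
    a blocked tunnel.
    """

    site_kds: tuple[float, ...] = (3.0, 30.0)
    k_on_site: float = 100.0
    conductance: float = 100.0
    void_capacity: float = 0.01
    exchange_site: bool = False
    exchange_kd: float = 10.0
    exchange_k_on: float | None = None
    swap_rate: float = 1000.0
    n_branches: int = 2
    branch_k_on: float = 0.5
    branch_kd: float = 20.0
    branch_k_on_inner: float | None = 20.0
    total_per_site: float = 1.0

    def validate(self) -> None:
        if len(self.site_kds) < 2:
            raise ValueError("a fixed-site chain needs at least 2 sites")
        if any(k <= 0 for k in self.site_kds):
            raise ValueError("site dissociation constants must be positive")
        for name in ("k_on_site", "conductance", "void_capacity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.branch_k_on < 0:
            raise ValueError("branch rates must be >= 0 (0 = blocked)")


def _add_site(m: NetworkModel, tag: str, kd: float, k_on: float,
              left: str, right: str, total: float,
              k_on_right: float | None = None) -> None:
    """Single-occupancy fixed site between two ligand pools.

    The two faces share the dissociation constant (detailed balance) but
    may have different access rates: ``k_on`` serves the left face and
    ``k_on_right`` (default equal) the right face; the face dissociation
    rates are ``k_on_face * kd``."""
    empty, bound = f"{tag}_empty", f"{tag}_bound"
    m.add_state(empty, location=tag, group=tag)
    m.add_state(bound, location=tag, occupants=(SPECIES,), group=tag)
    m.groups[tag] = total
    k_on_r = k_on if k_on_right is None else k_on_right
    m.add_binding(empty, bound, left, SPECIES, k_on, k_on * kd, name=f"{tag}.L")
    m.add_binding(empty, bound, right, SPECIES, k_on_r, k_on_r * kd, name=f"{tag}.R")


def _add_exchange_site(m: NetworkModel, tag: str, kd: float, k_on: float,
                       swap_rate: float, left: str, right: str, total: float) -> None:
    """Dual-occupancy exchange site with positional (outer/inner) slots.

    Ligand from the outer void binds only the outer slot and releases
    only to the outer void (likewise inner); crossing the site requires a
    swap transition that exchanges the two slots.  When both slots are
    full the swap performs a strict one-for-one exchange, so under a
    trans-side flood the site behaves as an antiporter: tracer entering
    the outer slot is carried inward while the resident ligand makes the
    opposite journey.  A lone occupant may also swap slots, which lets
    net flux traverse the site when it is not saturated."""
    empty = f"{tag}_empty"
    s_out, s_in, double = f"{tag}_outer", f"{tag}_inner", f"{tag}_double"
    m.add_state(empty, location=tag, group=tag)
    m.add_state(s_out, location=tag, occupants=(SPECIES,), group=tag)
    m.add_state(s_in, location=tag, occupants=(SPECIES,), group=tag)
    m.add_state(double, location=tag, occupants=(SPECIES, SPECIES), group=tag)
    m.groups[tag] = total
    k_off = k_on * kd
    # slot 0 = outer position, slot 1 = inner position (on the double)
    m.add_binding(empty, s_out, left, SPECIES, k_on, k_off, name=f"{tag}.L")
    m.add_binding(empty, s_in, right, SPECIES, k_on, k_off, name=f"{tag}.R")
    m.add_binding(s_in, double, left, SPECIES, k_on, k_off, slot=0, name=f"{tag}.L2")
    m.add_binding(s_out, double, right, SPECIES, k_on, k_off, slot=1, name=f"{tag}.R2")
    m.add_conformational(s_out, s_in, swap_rate, swap_rate, name=f"{tag}.hop")
    m.add_swap(double, double, swap_rate, name=f"{tag}.swap")


def build_multisite_chain(params: MultisiteParams | None = None) -> NetworkModel:
    """Fixed-site chain: out bath = v_ext = site1 = ... = v_int = in bath.

    Ligand moves only by association/dissociation at the fixed sites and
    diffusion through the voids; there is no carrier translocation step,
    so at equal bath concentrations every void equilibrates to the bath
    concentration whatever the site affinities (the chain is detailed
    balanced by construction)."""
    p = params or MultisiteParams()
    p.validate()
    m = NetworkModel()
    m.add_species(SPECIES)
    m.add_compartment("out", CLAMPED, conc={SPECIES: 0.0})
    m.add_compartment("in", CLAMPED, conc={SPECIES: 0.0})

    site_specs: list[tuple[str, dict]] = []
    for i, kd in enumerate(p.site_kds):
        site_specs.append((f"site{i + 1}", {"kd": kd}))
    if p.exchange_site:
        mid = len(site_specs) // 2
        site_specs.insert(mid, ("xsite", {"kd": p.exchange_kd, "exchange": True}))

    voids = []
    for i in range(len(site_specs) + 1):
        name = "v_ext" if i == 0 else ("v_int" if i == len(site_specs) else f"v_mid{i}")
        m.add_compartment(name, VOID, capacity=p.void_capacity, conc={SPECIES: 0.0})
        voids.append(name)

    m.add_diffusion("out", voids[0], SPECIES, p.conductance, name="mouth_out")
    m.add_diffusion(voids[-1], "in", SPECIES, p.conductance, name="mouth_in")
    for i, (tag, spec) in enumerate(site_specs):
        left, right = voids[i], voids[i + 1]
        if spec.get("exchange"):
            k_on = p.exchange_k_on if p.exchange_k_on is not None else p.k_on_site
            _add_exchange_site(m, tag, spec["kd"], k_on, p.swap_rate, left, right,
                               p.total_per_site)
        else:
            _add_site(m, tag, spec["kd"], p.k_on_site, left, right, p.total_per_site)
    m.validate()
    return m


def build_branched_multisite(block_right_branch: bool = False,
                             params: MultisiteParams | None = None) -> NetworkModel:
    """Fixed-site chain whose outside mouth is a pair of parallel
    low-affinity portal sites (the two tunnels between the outside
    solution and the external vestibule).  ``block_right_branch`` removes
    one tunnel, emulating the GLUT1-deficiency T295M lesion.

    The portal's bath-facing rim is its narrow face (T295 sits at the
    outer rim of the vestibule), so by default the portal exchanges much
    faster with the vestibule than with the bulk solution
    (``branch_k_on_inner`` >> ``branch_k_on`` at a shared dissociation
    constant).  Losing a tunnel then halves the saturable exit capacity:
    efflux Vmax collapses and, through the vestibule tailback, the
    efflux Km falls, while influx -- rate-limited deeper in the chain --
    loses much less, driving the fitted Haldane ratio below 1."""
    p = params or MultisiteParams(k_on_site=30.0)
    p.validate()
    m = NetworkModel()
    m.add_species(SPECIES)
    m.add_compartment("out", CLAMPED, conc={SPECIES: 0.0})
    m.add_compartment("in", CLAMPED, conc={SPECIES: 0.0})
    m.add_compartment("v_ext", VOID, capacity=p.void_capacity, conc={SPECIES: 0.0})
    n_branches = 1 if block_right_branch else p.n_branches
    if n_branches < 1:
        raise ConfigurationError("at least one open branch is required")
    if p.branch_k_on <= 0:
        raise ConfigurationError("open branches need a positive rate")
    for b in range(n_branches):
        _add_site(m, f"portal_{chr(ord('a') + b)}", p.branch_kd, p.branch_k_on,
                  "out", "v_ext", p.total_per_site,
                  k_on_right=p.branch_k_on_inner)

    prev = "v_ext"
    for i, kd in enumerate(p.site_kds):
        nxt = "v_int" if i == len(p.site_kds) - 1 else f"v_mid{i + 1}"
        m.add_compartment(nxt, VOID, capacity=p.void_capacity, conc={SPECIES: 0.0})
        _add_site(m, f"site{i + 1}", kd, p.k_on_site, prev, nxt, p.total_per_site)
        prev = nxt
    m.add_diffusion("v_int", "in", SPECIES, p.conductance, name="mouth_in")
    m.validate()
    return m


def arrhenius_scale(rate: float, ea: float, t: float, t_ref: float) -> float:
    """Rescale a rate constant from ``t_ref`` to ``t`` (kelvin) for an
    activation energy ``ea`` in kJ/mol:
    rate * exp(-Ea/R * (1/T - 1/T_ref)).

    Assigning a lower activation energy to exchange-path steps than to
    net-flux (dissociation) steps makes the exchange/net flux ratio grow
    as the temperature drops."""
    if t <= 0 or t_ref <= 0:
        raise ValueError("temperatures must be positive kelvin")
    r = GAS_CONSTANT / 1000.0  # kJ/(mol K)
    return rate * math.exp(-ea / r * (1.0 / t - 1.0 / t_ref))


def random_balanced_carrier(rng: np.random.Generator) -> tuple[CarrierParams, NetworkModel]:
    """Draw a random detailed-balance-closed asymmetric carrier; used by
    the property suites (Haldane ratio, cycle checks)."""
    p = CarrierParams(
        kd_out=float(10 ** rng.uniform(-0.5, 1.5)),
        kd_in=float(10 ** rng.uniform(-0.5, 1.5)),
        b_out_in=float(10 ** rng.uniform(-0.5, 0.5)),
        b_in_out=None,
        f_out_in=float(10 ** rng.uniform(-0.5, 1.5)),
        f_in_out=float(10 ** rng.uniform(-0.5, 1.5)),
        k_on=float(10 ** rng.uniform(2.0, 3.5)),
        auto_close=True,
    )
    return p, build_asymmetric_carrier(p)
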