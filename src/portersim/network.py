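"""Mass-action transport networks and their solvers.

A :class:`NetworkModel` couples a set of carrier states (dimensionless
occupancies that obey conservation within named groups) to a set of
compartments holding ligand (concentrations in mmol/L).  Transitions are
elementary mass-action steps -- conformational changes of the carrier,
ligand binding/release against a compartment, diffusive exchange of ligand
between compartments, and occupant swaps on dual-occupancy sites -- and
every transition declares a reverse partner, so the network is
microscopically reversible by construction.

Units, fixed package-wide: concentrations mmol/L, time s, energies kJ/mol.
Carrier amounts are dimensionless (total carrier defaults to 1), so fluxes
are in units of carrier turnovers per second; first-order rate constants
are s^-1 and second-order (binding, diffusion conductance) constants are
(mmol/L)^-1 s^-1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "NetworkError",
    "StructuralError",
    "ConvergenceError",
    "ConfigurationError",
    "LigandSpecies",
    "Compartment",
    "CarrierState",
    "Transition",
    "TracerInfo",
    "NetworkModel",
    "SteadyStateResult",
    "Cycle",
    "CycleReport",
    "TimeCourse",
    "solve_steady_state",
    "enumerate_cycles",
    "check_detailed_balance",
    "expand_tracer",
    "unidirectional_flux",
    "integrate_time_course",
]

CLAMPED = "clamped_bath"
FINITE = "finite_bath"
VOID = "internal_void"

_KINDS = {"conformational", "binding", "release", "void_diffusion", "swap"}


class NetworkError(Exception):
    """Base class for transport-network errors."""


class StructuralError(NetworkError):
    """The network topology or bookkeeping is inconsistent."""


class ConvergenceError(NetworkError):
    """A solver failed to reach the requested tolerance."""


class ConfigurationError(NetworkError):
    """A protocol or solve was requested on an unsuitable model."""


@dataclass(frozen=True)
class LigandSpecies:
    """A transportable ligand.  Members of one ``isotope_class`` are
    kinetically identical (labelled vs unlabelled sugar)."""

    name: str
    isotope_class: str = "sugar"


@dataclass
class Compartment:
    """A ligand pool.

    ``clamped_bath`` concentrations are held fixed during any solve;
    ``finite_bath`` and ``internal_void`` concentrations are state
    variables.  ``capacity`` converts carrier-amount flux into
    concentration change (d conc/dt = net amount flux / capacity); it is
    the compartment volume expressed in the package's dimensionless
    carrier-amount units per (mmol/L).
    """

    name: str
    kind: str = CLAMPED
    capacity: float = 1.0
    conc: dict[str, float] = field(default_factory=dict)

    def concentration(self, species: str) -> float:
        return self.conc.get(species, 0.0)


@dataclass
class CarrierState:
    """A carrier (or fixed-site) state.  ``occupants`` names the bound
    ligand species, one entry per occupied slot; empty tuple = vacant."""

    id: str
    location: str = ""
    occupants: tuple[str, ...] = ()
    group: str = "carrier"


@dataclass
class Transition:
    """A directed elementary step.  ``reverse`` names the partner
    transition; builders always create the two directions together.

    kind-specific fields:

    * ``binding``: ``source`` empty(-er) state, ``target`` bound state,
      ``compartment`` the pool supplying the ligand, ``species`` what is
      bound, ``slot`` the occupant index filled on the target.  ``rate``
      is second order, (mmol/L)^-1 s^-1.
    * ``release``: mirror image of binding (first order).
    * ``void_diffusion``: ``compartment`` -> ``compartment2`` transfer of
      ``species``; ``rate`` is a conductance, (mmol/L)^-1 s^-1 in amount
      units (flux = rate * source concentration).
    * ``conformational`` / ``swap``: first-order state-to-state steps;
      ``swap`` permutes the two occupant slots of a dual-occupancy site.
    """

    name: str
    kind: str
    source: str | None
    target: str | None
    rate: float
    compartment: str | None = None
    compartment2: str | None = None
    species: str | None = None
    slot: int | None = None
    reverse: str | None = None


@dataclass(frozen=True)
class TracerInfo:
    labelled: str
    unlabelled: str
    fraction: float
    cis: str


@dataclass
class NetworkModel:
    """A mass-action transport network.

    ``groups`` maps each conservation group to its total carrier amount;
    the sum of occupancies over the member states is conserved exactly by
    the dynamics.  ``total_carrier`` is the sum over groups.
    """

    species: dict[str, LigandSpecies] = field(default_factory=dict)
    compartments: dict[str, Compartment] = field(default_factory=dict)
    states: dict[str, CarrierState] = field(default_factory=dict)
    transitions: dict[str, Transition] = field(default_factory=dict)
    groups: dict[str, float] = field(default_factory=dict)
    tracer: TracerInfo | None = None

    # -- construction helpers -------------------------------------------------

    def add_species(self, name: str, isotope_class: str = "sugar") -> LigandSpecies:
        sp = LigandSpecies(name, isotope_class)
        self.species[name] = sp
        return sp

    def add_compartment(self, name: str, kind: str = CLAMPED, capacity: float = 1.0,
                        conc: dict[str, float] | None = None) -> Compartment:
        comp = Compartment(name, kind, capacity, dict(conc or {}))
        self.compartments[name] = comp
        return comp

    def add_state(self, id: str, location: str = "", occupants: tuple[str, ...] = (),
                  group: str = "carrier") -> CarrierState:
        if id in self.states:
            raise StructuralError(f"duplicate state id {id!r}")
        st = CarrierState(id, location, tuple(occupants), group)
        self.states[id] = st
        self.groups.setdefault(group, 1.0)
        return st

    def _add_pair(self, fwd: Transition, rev: Transition) -> tuple[Transition, Transition]:
        for t in (fwd, rev):
            if t.name in self.transitions:
                raise StructuralError(f"duplicate transition name {t.name!r}")
        fwd.reverse, rev.reverse = rev.name, fwd.name
        self.transitions[fwd.name] = fwd
        self.transitions[rev.name] = rev
        return fwd, rev

    def add_conformational(self, source: str, target: str, k_fwd: float, k_rev: float,
                           name: str | None = None) -> tuple[Transition, Transition]:
        name = name or f"{source}->{target}"
        return self._add_pair(
            Transition(name, "conformational", source, target, k_fwd),
            Transition(name + ".rev", "conformational", target, source, k_rev))

    def add_binding(self, empty: str, bound: str, compartment: str, species: str,
                    k_on: float, k_off: float, slot: int = 0,
                    name: str | None = None) -> tuple[Transition, Transition]:
        name = name or f"{empty}+{compartment}->{bound}"
        return self._add_pair(
            Transition(name, "binding", empty, bound, k_on,
                       compartment=compartment, species=species, slot=slot),
            Transition(name + ".rev", "release", bound, empty, k_off,
                       compartment=compartment, species=species, slot=slot))

    def add_diffusion(self, comp_a: str, comp_b: str, species: str, conductance: float,
                      name: str | None = None) -> tuple[Transition, Transition]:
        name = name or f"{comp_a}<->{comp_b}"
        return self._add_pair(
            Transition(name, "void_diffusion", None, None, conductance,
                       compartment=comp_a, compartment2=comp_b, species=species),
            Transition(name + ".rev", "void_diffusion", None, None, conductance,
                       compartment=comp_b, compartment2=comp_a, species=species))

    def add_swap(self, source: str, target: str, rate: float,
                 name: str | None = None) -> tuple[Transition, Transition]:
        """Occupant-slot swap on a dual-occupancy site.  ``source`` and
        ``target`` may coincide (single-species model); tracer expansion
        then splits the self-loop into real mixed-label transitions."""
        name = name or f"swap:{source}"
        fwd = Transition(name, "swap", source, target, rate)
        rev = Transition(name + ".rev", "swap", target, source, rate)
        return self._add_pair(fwd, rev)

    # -- basic queries --------------------------------------------------------

    @property
    def total_carrier(self) -> float:
        return float(sum(self.groups.values()))

    def group_states(self, group: str) -> list[str]:
        return [s.id for s in self.states.values() if s.group == group]

    def reversible_pairs(self) -> list[tuple[Transition, Transition]]:
        """One (forward, reverse) tuple per reversible pair, each pair once."""
        pairs, seen = [], set()
        for t in self.transitions.values():
            if t.name in seen:
                continue
            if t.reverse is None or t.reverse not in self.transitions:
                raise StructuralError(f"transition {t.name!r} lacks a reverse partner")
            rev = self.transitions[t.reverse]
            seen.add(t.name)
            seen.add(rev.name)
            pairs.append((t, rev))
        return pairs

    def copy(self) -> "NetworkModel":
        m = NetworkModel(
            species=dict(self.species),
            compartments={k: replace(v, conc=dict(v.conc)) for k, v in self.compartments.items()},
            states={k: replace(v) for k, v in self.states.items()},
            transitions={k: replace(v) for k, v in self.transitions.items()},
            groups=dict(self.groups),
            tracer=self.tracer,
        )
        m._validated = getattr(self, "_validated", False)
        return m

    def with_compartment(self, name: str, kind: str | None = None,
                         capacity: float | None = None) -> "NetworkModel":
        m = self.copy()
        comp = m.compartments[name]
        if kind is not None:
            comp.kind = kind
        if capacity is not None:
            comp.capacity = capacity
        return m

    # -- validation -----------------------------------------------------------

    def validate(self, force: bool = False) -> None:
        """Structural validation; cached, since solves re-validate and
        clamping only changes concentrations (checked separately)."""
        if getattr(self, "_validated", False) and not force:
            return
        for st in self.states.values():
            for sp in st.occupants:
                if sp not in self.species:
                    raise StructuralError(f"state {st.id!r} occupant {sp!r} unknown")
        for comp in self.compartments.values():
            if comp.kind not in (CLAMPED, FINITE, VOID):
                raise StructuralError(f"compartment {comp.name!r} has kind {comp.kind!r}")
            if any(c < 0 for c in comp.conc.values()):
                raise StructuralError(f"negative concentration in {comp.name!r}")
            if comp.kind != CLAMPED and comp.capacity <= 0:
                raise StructuralError(f"compartment {comp.name!r} needs a positive capacity")
        for t in self.transitions.values():
            if t.kind not in _KINDS:
                raise StructuralError(f"transition {t.name!r} has kind {t.kind!r}")
            if not (t.rate > 0):
                raise StructuralError(f"transition {t.name!r} has non-positive rate")
            if t.reverse not in self.transitions:
                raise StructuralError(f"transition {t.name!r} lacks reverse partner")
            for ref in (t.source, t.target):
                if ref is not None and ref not in self.states:
                    raise StructuralError(f"transition {t.name!r} references state {ref!r}")
            for ref in (t.compartment, t.compartment2):
                if ref is not None and ref not in self.compartments:
                    raise StructuralError(f"transition {t.name!r} references compartment {ref!r}")
            if t.species is not None and t.species not in self.species:
                raise StructuralError(f"transition {t.name!r} references species {t.species!r}")
        # each conservation group's state graph must be connected
        for group in self.groups:
            members = self.group_states(group)
            if not members:
                raise StructuralError(f"conservation group {group!r} has no states")
            g = nx.Graph()
            g.add_nodes_from(members)
            for t in self.transitions.values():
                if t.source in g and t.target in g and t.source != t.target:
                    g.add_edge(t.source, t.target)
            if not nx.is_connected(g):
                raise StructuralError(f"carrier graph of group {group!r} is not connected")
        self._validated = True


# ---------------------------------------------------------------------------
# state-vector layout and dynamics
# ---------------------------------------------------------------------------


class _Layout:
    """Index bookkeeping: carrier occupancies first, then the (compartment,
    species) concentration variables of every non-clamped compartment."""

    def __init__(self, model: NetworkModel):
        self.model = model
        self.state_ids = list(model.states)
        self.state_index = {s: i for i, s in enumerate(self.state_ids)}
        self.pools: list[tuple[str, str]] = []
        for comp in model.compartments.values():
            if comp.kind != CLAMPED:
                for sp in model.species:
                    self.pools.append((comp.name, sp))
        self.pool_index = {p: len(self.state_ids) + i for i, p in enumerate(self.pools)}
        self.n = len(self.state_ids) + len(self.pools)
        self._compile()

    def _compile(self) -> None:
        """Precompute index arrays so the mass-action right-hand side is a
        handful of vectorised operations."""
        model = self.model
        trans = list(model.transitions.values())
        m = len(trans)
        self._trans = trans
        rate = np.empty(m)
        src = np.full(m, -1, dtype=int)
        tgt = np.full(m, -1, dtype=int)
        mult = np.full(m, -1, dtype=int)      # concentration multiplier index
        fixed = np.ones(m)                    # clamped multiplier value
        pool_a = np.full(m, -1, dtype=int)    # ligand pool losing at flux/cap
        coef_a = np.zeros(m)
        pool_b = np.full(m, -1, dtype=int)
        coef_b = np.zeros(m)
        for i, t in enumerate(trans):
            rate[i] = t.rate
            if t.source is not None:
                src[i] = self.state_index[t.source]
                tgt[i] = self.state_index[t.target]
            if t.kind == "binding" or t.kind == "void_diffusion":
                key = (t.compartment, t.species)
                if key in self.pool_index:
                    mult[i] = self.pool_index[key]
                else:
                    fixed[i] = model.compartments[t.compartment].concentration(t.species)
            if t.kind == "binding":
                key = (t.compartment, t.species)
                if key in self.pool_index:
                    pool_a[i] = self.pool_index[key]
                    coef_a[i] = -1.0 / model.compartments[t.compartment].capacity
            elif t.kind == "release":
                key = (t.compartment, t.species)
                if key in self.pool_index:
                    pool_a[i] = self.pool_index[key]
                    coef_a[i] = 1.0 / model.compartments[t.compartment].capacity
            elif t.kind == "void_diffusion":
                key_a = (t.compartment, t.species)
                key_b = (t.compartment2, t.species)
                if key_a in self.pool_index:
                    pool_a[i] = self.pool_index[key_a]
                    coef_a[i] = -1.0 / model.compartments[t.compartment].capacity
                if key_b in self.pool_index:
                    pool_b[i] = self.pool_index[key_b]
                    coef_b[i] = 1.0 / model.compartments[t.compartment2].capacity
        self._rate, self._src, self._tgt = rate, src, tgt
        self._mult, self._fixed = mult, fixed
        self._pool_a, self._coef_a = pool_a, coef_a
        self._pool_b, self._coef_b = pool_b, coef_b
        self._has_src = src >= 0
        self._has_mult = mult >= 0
        self._has_pa = pool_a >= 0
        self._has_pb = pool_b >= 0
        # conservation rows
        self._groups = []
        for group, total in model.groups.items():
            idx = np.array([self.state_index[s] for s in model.group_states(group)])
            self._groups.append((idx, total))

    def _fluxes(self, y: np.ndarray) -> np.ndarray:
        f = self._rate.copy()
        f[self._has_src] *= y[self._src[self._has_src]]
        f *= self._fixed
        f[self._has_mult] *= y[self._mult[self._has_mult]]
        return f

    def pack(self, occupancy: dict[str, float] | None = None,
             conc: dict[str, dict[str, float]] | None = None) -> np.ndarray:
        y = np.zeros(self.n)
        model = self.model
        if occupancy is None:
            for group, total in model.groups.items():
                members = model.group_states(group)
                for s in members:
                    y[self.state_index[s]] = total / len(members)
        else:
            for s, v in occupancy.items():
                y[self.state_index[s]] = v
        for comp, sp in self.pools:
            c = model.compartments[comp].concentration(sp)
            if conc is not None and comp in conc and sp in conc[comp]:
                c = conc[comp][sp]
            y[self.pool_index[(comp, sp)]] = c
        return y

    def concentration(self, y: np.ndarray, comp: str, sp: str) -> float:
        key = (comp, sp)
        if key in self.pool_index:
            return float(y[self.pool_index[key]])
        return self.model.compartments[comp].concentration(sp)

    def flux(self, t: Transition, y: np.ndarray) -> float:
        if t.kind == "binding":
            return t.rate * self.concentration(y, t.compartment, t.species) \
                * y[self.state_index[t.source]]
        if t.kind == "void_diffusion":
            return t.rate * self.concentration(y, t.compartment, t.species)
        return t.rate * y[self.state_index[t.source]]

    def rhs(self, y: np.ndarray) -> np.ndarray:
        f = self._fluxes(y)
        dy = np.zeros_like(y)
        np.add.at(dy, self._src[self._has_src], -f[self._has_src])
        np.add.at(dy, self._tgt[self._has_src], f[self._has_src])
        np.add.at(dy, self._pool_a[self._has_pa],
                  (self._coef_a * f)[self._has_pa])
        np.add.at(dy, self._pool_b[self._has_pb],
                  (self._coef_b * f)[self._has_pb])
        return dy

    def residual(self, y: np.ndarray) -> np.ndarray:
        """Steady-state residual: rhs with one state equation per
        conservation group replaced by the conservation constraint."""
        r = self.rhs(y)
        for idx, total in self._groups:
            r[idx[0]] = y[idx].sum() - total
        return r


def _apply_clamps(model: NetworkModel, clamps: dict | None) -> NetworkModel:
    m = model.copy()
    if clamps:
        if len(m.species) != 1 and any(not isinstance(v, dict) for v in clamps.values()):
            raise ConfigurationError("scalar clamps require a single-species model")
        for comp, val in clamps.items():
            if comp not in m.compartments:
                raise ConfigurationError(f"unknown compartment {comp!r} in clamps")
            if isinstance(val, dict):
                m.compartments[comp].conc = dict(val)
            else:
                if val < 0:
                    raise ConfigurationError(f"negative clamp for {comp!r}")
                (sp,) = m.species
                m.compartments[comp].conc = {sp: float(val)}
    return m


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class SteadyStateResult:
    """Converged steady state: occupancies, free-pool concentrations and
    per-transition one-way fluxes (amount/s)."""

    model: NetworkModel
    occupancy: dict[str, float]
    conc: dict[str, dict[str, float]]
    flux: dict[str, float]
    converged: bool
    residual_norm: float
    method: str

    def net_flux(self, name: str) -> float:
        t = self.model.transitions[name]
        return self.flux[name] - self.flux[t.reverse]

    def net_delivery(self, bath: str, species: str | None = None) -> float:
        """Net rate (amount/s) at which ligand (optionally one species)
        is delivered into ``bath`` by the network."""
        total = 0.0
        for t in self.model.transitions.values():
            if species is not None and t.species != species:
                continue
            if t.kind == "release" and t.compartment == bath:
                total += self.flux[t.name]
            elif t.kind == "binding" and t.compartment == bath:
                total -= self.flux[t.name]
            elif t.kind == "void_diffusion":
                if t.compartment2 == bath:
                    total += self.flux[t.name]
                elif t.compartment == bath:
                    total -= self.flux[t.name]
        return total

    def group_totals(self) -> dict[str, float]:
        out = {}
        for group in self.model.groups:
            out[group] = sum(self.occupancy[s] for s in self.model.group_states(group))
        return out


@dataclass
class Cycle:
    """A closed walk of reversible pairs with its directed rate products.

    Second-order (binding / diffusion) rate constants enter the products
    multiplied by a reference concentration, so the ratio is
    concentration-free for cycles that bind and release in the same
    compartments and refers to the equal-bath equilibrium otherwise.
    """

    transitions: list[str]
    forward_product: float
    reverse_product: float

    @property
    def ratio(self) -> float:
        return self.forward_product / self.reverse_product

    def __len__(self) -> int:
        return len(self.transitions)


@dataclass
class CycleReport:
    cycles: list[Cycle]
    tolerance: float
    passed: bool


@dataclass
class TimeCourse:
    model: NetworkModel
    t: np.ndarray
    occupancy: dict[str, np.ndarray]
    conc: dict[str, dict[str, np.ndarray]]

    def concentration(self, comp: str, species: str) -> np.ndarray:
        c = self.model.compartments[comp]
        if c.kind == CLAMPED or comp not in self.conc:
            return np.full_like(self.t, c.concentration(species), dtype=float)
        return self.conc[comp][species]


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------


def _linear_matrix(model: NetworkModel, layout: _Layout) -> np.ndarray:
    """Rate matrix A with dx/dt = A x for bath-only (all-clamped) models."""
    n = len(layout.state_ids)
    A = np.zeros((n, n))
    for t in model.transitions.values():
        if t.source is None:
            continue
        i = layout.state_index[t.source]
        j = layout.state_index[t.target]
        r = t.rate
        if t.kind == "binding":
            r *= model.compartments[t.compartment].concentration(t.species)
        A[j, i] += r
        A[i, i] -= r
    return A


def _linear_steady_state(model: NetworkModel, layout: _Layout) -> np.ndarray:
    A = _linear_matrix(model, layout)
    M = A.copy()
    b = np.zeros(len(layout.state_ids))
    for group, total in model.groups.items():
        members = model.group_states(group)
        row = layout.state_index[members[0]]
        M[row, :] = 0.0
        for s in members:
            M[row, layout.state_index[s]] = 1.0
        b[row] = total
    try:
        x = np.linalg.solve(M, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ConvergenceError(f"singular steady-state system: {exc}") from exc
    return x


def _ode_relax(layout: _Layout, y0: np.ndarray, rtol: float = 1e-10,
               max_time: float = 1e7) -> np.ndarray:
    """Integrate towards steady state until ||dy/dt|| <= rtol * scale."""
    y = y0.copy()
    scale = max(np.linalg.norm(y), 1.0)
    t_end = 1.0
    rhs = lambda t, v: layout.rhs(v)
    while t_end <= max_time:
        sol = solve_ivp(rhs, (0.0, t_end), y, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise ConvergenceError(f"ODE relaxation failed: {sol.message}")
        y = sol.y[:, -1]
        if np.linalg.norm(layout.rhs(y)) <= rtol * max(np.linalg.norm(y), scale):
            return y
        t_end *= 10.0
    return y


def _newton_polish(layout: _Layout, y0: np.ndarray, tol: float = 1e-12,
                   max_iter: int = 60) -> tuple[np.ndarray, float]:
    """Damped Newton on the steady-state residual, seeded near a solution."""
    y = y0.copy()
    fscale = max(abs(t.rate) for t in layout.model.transitions.values())
    r = layout.residual(y)
    for _ in range(max_iter):
        norm = np.linalg.norm(r)
        if norm <= tol * max(fscale, 1.0):
            break
        J = _fd_jacobian(layout.residual, y, r)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        lam = 1.0
        for _ in range(40):
            y_try = y + lam * step
            r_try = layout.residual(y_try)
            if np.linalg.norm(r_try) < norm:
                y, r = y_try, r_try
                break
            lam *= 0.5
        else:  # no improving step; accept current point
            break
    return y, float(np.linalg.norm(r))


def _heuristic_seed(layout: _Layout) -> np.ndarray:
    """Uniform occupancies; free pools start at the mean clamped-bath
    concentration of their species (a good basin for damped Newton)."""
    y = layout.pack()
    model = layout.model
    for comp, sp in layout.pools:
        clamped = [c.concentration(sp) for c in model.compartments.values()
                   if c.kind == CLAMPED]
        if clamped:
            y[layout.pool_index[(comp, sp)]] = float(np.mean(clamped))
    return y


def _admissible(layout: _Layout, y: np.ndarray) -> bool:
    """Occupancies and concentrations must be non-negative (tiny negative
    round-off is tolerated and cleaned up downstream)."""
    return bool(np.all(y >= -1e-9 * max(1.0, np.max(np.abs(y)))))


def _fd_jacobian(fun, y, f0):
    n = len(y)
    J = np.empty((n, n))
    for i in range(n):
        h = 1e-7 * max(abs(y[i]), 1e-3)
        yp = y.copy()
        yp[i] += h
        J[:, i] = (fun(yp) - f0) / h
    return J


def _result_from_vector(model: NetworkModel, layout: _Layout, y: np.ndarray,
                        residual_norm: float, method: str) -> SteadyStateResult:
    occupancy = {s: float(y[layout.state_index[s]]) for s in layout.state_ids}
    conc: dict[str, dict[str, float]] = {}
    for comp, sp in layout.pools:
        conc.setdefault(comp, {})[sp] = float(y[layout.pool_index[(comp, sp)]])
    flux = {t.name: float(layout.flux(t, y)) for t in model.transitions.values()}
    return SteadyStateResult(model, occupancy, conc, flux, True, residual_norm, method)


def solve_steady_state(model: NetworkModel, clamps: dict | None = None, *,
                       cross_check: bool = False, tol: float = 1e-12,
                       rtol_cross: float = 1e-8,
                       guess: SteadyStateResult | None = None) -> SteadyStateResult:
    """Solve for the steady state of ``model`` with bath concentrations
    optionally overridden by ``clamps`` ({compartment: conc} for
    single-species models, or {compartment: {species: conc}}).

    Bath-only models (every compartment clamped) are solved by a direct
    linear solve of the master equation under the conservation
    constraints; with ``cross_check=True`` the result is verified against
    ODE relaxation to ``rtol_cross``.  Models with free void or
    finite-bath concentrations are solved by damped Newton seeded from
    ODE relaxation.
    """
    work = _apply_clamps(model, clamps)
    work.validate()
    layout = _Layout(work)
    if not layout.pools:
        x = _linear_steady_state(work, layout)
        res = float(np.linalg.norm(layout.rhs(x)))
        if cross_check:
            y = _ode_relax(layout, layout.pack(), rtol=1e-11)
            scale = max(np.max(np.abs(x)), 1e-30)
            dev = np.max(np.abs(x - y)) / scale
            if dev > rtol_cross:
                raise ConvergenceError(
                    f"linear and ODE steady states disagree (relative {dev:.2e})")
        result = _result_from_vector(work, layout, x, res, "linear")
    else:
        fscale = max(abs(t.rate) for t in work.transitions.values())
        ok = lambda r: r <= 1e-9 * max(fscale, 1.0)
        seeds = []
        if guess is not None:
            seeds.append(layout.pack(
                {s: guess.occupancy[s] for s in layout.state_ids if s in guess.occupancy},
                guess.conc))
        seeds.append(_heuristic_seed(layout))
        y = res = None
        method = "newton"
        for y0 in seeds:
            y_try, r_try = _newton_polish(layout, y0, tol=tol)
            if _admissible(layout, y_try) and ok(r_try):
                y, res = y_try, r_try
                break
        if y is None:  # fall back to ODE relaxation seeding
            y0 = _ode_relax(layout, _heuristic_seed(layout), rtol=1e-8)
            y, res = _newton_polish(layout, y0, tol=tol)
            method = "ode+newton"
            if not ok(res):
                raise ConvergenceError(
                    f"steady-state solve did not converge (residual {res:.3e})")
        result = _result_from_vector(work, layout, y, res, method)
    _check_conservation(result)
    return result


def _check_conservation(result: SteadyStateResult) -> None:
    for group, total in result.model.groups.items():
        got = sum(result.occupancy[s] for s in result.model.group_states(group))
        if abs(got - total) > 1e-9 * max(total, 1.0):
            raise ConvergenceError(
                f"carrier conservation violated in group {group!r}: {got} vs {total}")


# ---------------------------------------------------------------------------
# cycles and detailed balance
# ---------------------------------------------------------------------------


def _edge_endpoints(t: Transition) -> tuple[str, str]:
    if t.kind == "void_diffusion":
        return ("comp:" + t.compartment, "comp:" + t.compartment2)
    return ("state:" + t.source, "state:" + t.target)


def enumerate_cycles(model: NetworkModel) -> list[Cycle]:
    """Independent cycle basis of the network's reversible-pair multigraph.

    Nodes are carrier states plus the compartments joined by diffusion
    edges; each reversible pair is one undirected edge.  The basis is the
    set of fundamental cycles of a spanning forest, so its size is
    E - V + (number of connected components).
    """
    pairs = model.reversible_pairs()
    adj: dict[str, list[tuple[str, int]]] = {}
    for k, (fwd, _) in enumerate(pairs):
        a, b = _edge_endpoints(fwd)
        adj.setdefault(a, []).append((b, k))
        adj.setdefault(b, []).append((a, k))

    parent: dict[str, tuple[str, int] | None] = {}
    tree_edges: set[int] = set()
    for root in adj:
        if root in parent:
            continue
        parent[root] = None
        queue = [root]
        while queue:
            u = queue.pop()
            for v, k in adj[u]:
                if v not in parent:
                    parent[v] = (u, k)
                    tree_edges.add(k)
                    queue.append(v)

    def root_path(u: str) -> tuple[list[str], list[int]]:
        nodes, edges = [u], []
        while parent[u] is not None:
            p, k = parent[u]
            edges.append(k)
            nodes.append(p)
            u = p
        return nodes, edges

    cycles = []
    for k, (fwd, rev) in enumerate(pairs):
        if k in tree_edges:
            continue
        a, b = _edge_endpoints(fwd)
        if a == b:  # self-loop (single-species swap)
            cycles.append(_cycle_from_walk(model, [fwd.name]))
            continue
        na, ea = root_path(a)
        nb, eb = root_path(b)
        # strip the common suffix above the lowest common ancestor
        while ea and eb and ea[-1] == eb[-1]:
            ea.pop(), eb.pop(), na.pop(), nb.pop()
        # closed walk: a --(non-tree edge)--> b --up--> lca --down--> a
        walk = [_directed_name(model, pairs[k], a, b)]
        for i, k_ in enumerate(eb):  # b upwards: nb[i] -> nb[i+1]
            walk.append(_directed_name(model, pairs[k_], nb[i], nb[i + 1]))
        for i in reversed(range(len(ea))):  # lca downwards: na[i+1] -> na[i]
            walk.append(_directed_name(model, pairs[ea[i]], na[i + 1], na[i]))
        cycles.append(_cycle_from_walk(model, walk))
    return cycles


def _other_end(t: Transition, node: str) -> str:
    a, b = _edge_endpoints(t)
    return b if node == a else a


def _directed_name(model: NetworkModel, pair: tuple[Transition, Transition],
                   frm: str, to: str) -> str:
    fwd, rev = pair
    a, b = _edge_endpoints(fwd)
    if (frm, to) == (a, b):
        return fwd.name
    return rev.name


def _effective_rate(t: Transition, reference_conc: float) -> float:
    if t.kind in ("binding", "void_diffusion"):
        return t.rate * reference_conc
    return t.rate


def _cycle_from_walk(model: NetworkModel, walk: list[str],
                     reference_conc: float = 1.0) -> Cycle:
    fwd = 1.0
    rev = 1.0
    for name in walk:
        t = model.transitions[name]
        fwd *= _effective_rate(t, reference_conc)
        rev *= _effective_rate(model.transitions[t.reverse], reference_conc)
    return Cycle(list(walk), fwd, rev)


def check_detailed_balance(model: NetworkModel, tolerance: float = 1e-9,
                           reference_conc: float = 1.0) -> CycleReport:
    """Thermodynamic consistency check: around every basis cycle the
    product of forward rate constants must equal the product of reverse
    rate constants (second-order rates taken at ``reference_conc``,
    i.e. at the equal-bath equilibrium)."""
    for t in model.transitions.values():
        if t.reverse not in model.transitions:
            raise StructuralError(f"transition {t.name!r} lacks a reverse partner")
    cycles = [
        _cycle_from_walk(model, c.transitions, reference_conc)
        for c in enumerate_cycles(model)
    ]
    passed = all(abs(c.ratio - 1.0) <= tolerance for c in cycles)
    return CycleReport(cycles, tolerance, passed)


# ---------------------------------------------------------------------------
# tracer expansion
# ---------------------------------------------------------------------------


def expand_tracer(model: NetworkModel, labelled_fraction: float = 1e-6,
                  cis: str = "out") -> NetworkModel:
    """Split the single ligand species into an isotopically labelled /
    unlabelled pair sharing every rate constant, placing
    ``labelled_fraction`` of the ``cis`` bath's ligand in the labelled
    pool.  Every occupied state and every ligand-coupled transition is
    duplicated over label assignments; totals are unchanged."""
    if not (0.0 < labelled_fraction <= 1.0):
        raise ValueError("labelled_fraction must lie in (0, 1]")
    if len(model.species) != 1:
        raise ConfigurationError("tracer expansion requires a single-species model")
    if cis not in model.compartments:
        raise ConfigurationError(f"unknown cis compartment {cis!r}")
    (base_name,) = model.species
    base = model.species[base_name]
    lab_name = base_name + "*"

    new = NetworkModel(groups=dict(model.groups))
    new.species[base_name] = base
    new.species[lab_name] = LigandSpecies(lab_name, base.isotope_class)
    for comp in model.compartments.values():
        c = comp.concentration(base_name)
        if comp.name == cis:
            conc = {base_name: (1.0 - labelled_fraction) * c,
                    lab_name: labelled_fraction * c}
        else:
            conc = {base_name: c, lab_name: 0.0}
        new.add_compartment(comp.name, comp.kind, comp.capacity, conc)

    def variant_id(state_id: str, pattern: tuple[int, ...]) -> str:
        if not any(pattern):
            return state_id
        return state_id + "~" + "".join("L" if p else "U" for p in pattern)

    def occupants_for(pattern: tuple[int, ...]) -> tuple[str, ...]:
        return tuple(lab_name if p else base_name for p in pattern)

    for st in model.states.values():
        n = len(st.occupants)
        for pattern in itertools.product((0, 1), repeat=n):
            new.add_state(variant_id(st.id, pattern), st.location,
                          occupants_for(pattern), st.group)
    # re-seed groups with original totals (add_state defaults to 1.0)
    new.groups = dict(model.groups)

    def suffix(pattern: tuple[int, ...]) -> str:
        return "" if not any(pattern) else "~" + "".join("L" if p else "U" for p in pattern)

    for fwd, rev in model.reversible_pairs():
        if fwd.kind == "void_diffusion":
            for sp in (base_name, lab_name):
                sfx = "" if sp == base_name else "~L"
                new._add_pair(
                    replace(fwd, name=fwd.name + sfx, species=sp, reverse=None),
                    replace(rev, name=rev.name + sfx, species=sp, reverse=None))
            continue
        if fwd.kind == "conformational":
            n = len(model.states[fwd.source].occupants)
            for pattern in itertools.product((0, 1), repeat=n):
                sfx = suffix(pattern)
                new._add_pair(
                    replace(fwd, name=fwd.name + sfx, reverse=None,
                            source=variant_id(fwd.source, pattern),
                            target=variant_id(fwd.target, pattern)),
                    replace(rev, name=rev.name + sfx, reverse=None,
                            source=variant_id(rev.source, pattern),
                            target=variant_id(rev.target, pattern)))
            continue
        if fwd.kind == "swap":
            n = len(model.states[fwd.source].occupants)
            if n != 2:
                raise StructuralError("swap transitions require dual-occupancy states")
            seen = set()
            for pattern in itertools.product((0, 1), repeat=2):
                swapped = (pattern[1], pattern[0])
                key = frozenset([pattern, swapped])
                if pattern == swapped or key in seen:
                    if pattern == swapped:
                        # identical-label swap is a physical no-op; keep it
                        # so the expanded network mirrors the original, but
                        # only as a self-loop pair
                        sfx = suffix(pattern)
                        new._add_pair(
                            replace(fwd, name=fwd.name + sfx, reverse=None,
                                    source=variant_id(fwd.source, pattern),
                                    target=variant_id(fwd.target, pattern)),
                            replace(rev, name=rev.name + sfx, reverse=None,
                                    source=variant_id(rev.source, pattern),
                                    target=variant_id(rev.target, pattern)))
                    continue
                seen.add(key)
                sfx = suffix(pattern)
                new._add_pair(
                    replace(fwd, name=fwd.name + sfx, reverse=None,
                            source=variant_id(fwd.source, pattern),
                            target=variant_id(fwd.target, swapped)),
                    replace(rev, name=rev.name + sfx, reverse=None,
                            source=variant_id(fwd.target, swapped),
                            target=variant_id(fwd.source, pattern)))
            continue
        # binding / release pair: expand over the bound state's patterns
        bound = fwd.target if fwd.kind == "binding" else fwd.source
        b_on = fwd if fwd.kind == "binding" else rev
        b_off = rev if fwd.kind == "binding" else fwd
        n = len(model.states[bound].occupants)
        slot = b_on.slot or 0
        for pattern in itertools.product((0, 1), repeat=n):
            sfx = suffix(pattern)
            src_pattern = pattern[:slot] + pattern[slot + 1:]
            sp = lab_name if pattern[slot] else base_name
            on = replace(b_on, name=b_on.name + sfx, reverse=None, species=sp,
                         source=variant_id(b_on.source, src_pattern),
                         target=variant_id(bound, pattern))
            off = replace(b_off, name=b_off.name + sfx, reverse=None, species=sp,
                          source=variant_id(bound, pattern),
                          target=variant_id(b_on.source, src_pattern))
            if fwd.kind == "binding":
                new._add_pair(on, off)
            else:
                new._add_pair(off, on)

    new.tracer = TracerInfo(lab_name, base_name, labelled_fraction, cis)
    new.validate()
    return new


def unidirectional_flux(ss: SteadyStateResult, trans_bath: str,
                        labelled_fraction: float | None = None) -> float:
    """Unidirectional (tracer) ligand flux into ``trans_bath``: the
    labelled delivery rate divided by the labelled fraction of the cis
    pool.  Equals the net flux under zero-trans conditions."""
    if not ss.converged:
        raise ConvergenceError("unidirectional flux requires a converged steady state")
    info = ss.model.tracer
    if info is None:
        raise ConfigurationError("model is not tracer-expanded")
    lf = labelled_fraction if labelled_fraction is not None else info.fraction
    return ss.net_delivery(trans_bath, species=info.labelled) / lf


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------


def integrate_time_course(model: NetworkModel, t_grid,
                          initial_occupancy: dict[str, float] | None = None,
                          initial_conc: dict[str, dict[str, float]] | None = None,
                          rtol: float = 1e-9, atol: float = 1e-12) -> TimeCourse:
    """Integrate the mass-action ODEs over ``t_grid`` (strictly
    increasing, starting at its first element)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing with at least two points")
    work = model.copy()
    work.validate()
    layout = _Layout(work)
    y0 = layout.pack(initial_occupancy, initial_conc)
    sol = solve_ivp(lambda t, y: layout.rhs(y), (t_grid[0], t_grid[-1]), y0,
                    t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise ConvergenceError(f"time-course integration failed: {sol.message}")
    occupancy = {s: sol.y[layout.state_index[s]] for s in layout.state_ids}
    conc: dict[str, dict[str, np.ndarray]] = {}
    for comp, sp in layout.pools:
        conc.setdefault(comp, {})[sp] = sol.y[layout.pool_index[(comp, sp)]]
    # carrier conservation along the trajectory
    for group, total in work.groups.items():
        tot = sum(occupancy[s] for s in work.group_states(group))
        if np.max(np.abs(tot - total)) > 1e-8 * max(total, 1.0):
            raise ConvergenceError(f"carrier conservation drifted in group {group!r}")
    return TimeCourse(work, t_grid, occupancy, conc)
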