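# Methods

## The network model

A transporter is a mass-action network coupling **carrier states**
(dimensionless occupancies) to **compartments** (ligand pools in mmol/L).
Four elementary step kinds exist, each declared together with its reverse:

* *conformational* — first-order state-to-state steps (carrier inversion,
  slot hops), rate in s⁻¹;
* *binding/release* — second-order association of a ligand from a
  compartment onto an empty slot ((mmol/L)⁻¹ s⁻¹) and its first-order
  dissociation; the bound-state slot index and species are recorded so
  isotope expansion is mechanical;
* *void_diffusion* — conductive transfer between two compartments,
  flux = conductance × source concentration;
* *swap* — permutation of the two occupant slots of a dual-occupancy site.

Compartments are `clamped_bath` (fixed concentration — the default,
realising initial-rate protocols as steady states), `finite_bath`, or
`internal_void`. Non-clamped pools carry a *capacity* κ (amount per mmol/L):
d(conc)/dt = net amount flux / κ. Because the total carrier is dimensionless
(C_T = 1) the capacity is the compartment volume expressed in those units;
steady states are independent of κ, only time courses feel it. Units are
fixed package-wide: mmol/L, seconds, kJ/mol, R = 8.314462618 J/(mol·K).

Occupancies are conserved within named groups (one group for the 4-state
carrier; one per site in fixed-site chains, so "Σ occupancies = total" holds
group-wise). Validation checks positivity, reverse partners, reference
integrity and per-group connectivity.

### Solvers

Bath-only models are linear: the steady state is a direct solve of the
master equation with one row per group replaced by its conservation
constraint. With free voids the problem is bilinear (binding flux =
k_on·[void]·occupancy); it is solved by damped Newton (finite-difference
Jacobian, step-halving line search, residual tolerance 1e-12 relative to the
fastest rate) seeded from a heuristic start — uniform occupancies, voids at
the mean clamped concentration — with warm starts along protocol grids and a
fallback seeding by ODE relaxation (LSODA until ‖dX/dt‖ ≤ 1e-8‖X‖). The
linear and ODE routes are cross-checked against each other to 1e-8 relative
in the test suite. Time courses use LSODA with rtol 1e-9/atol 1e-12 and are
checked for carrier (and, with finite baths, total-ligand) conservation.

### Cycles and detailed balance

The reversible pairs form a multigraph over carrier states (binding edges
join the empty and bound states) and compartments (diffusion edges). A
spanning forest yields a fundamental cycle basis of size E − V + C, with
parallel edges (two tunnels; the two faces of a site) handled natively. For
each basis cycle the directed products of rate constants are compared,
second-order constants entering at a reference concentration of 1 mmol/L —
the equal-bath equilibrium — which makes the ratio concentration-free for
cycles that bind and release in the same compartments. Ratios within
tolerance of 1 on the basis imply balance of every closed walk (ratios are
multiplicative over the cycle space; spot-checked exhaustively on the chain
model).

### Tracer expansion

`expand_tracer` splits the single ligand species into labelled/unlabelled
twins in one isotope class, duplicating every occupied state over label
assignments and every ligand-coupled transition with *identical* rate
constants, and splitting the cis bath's concentration. Unidirectional flux
is the labelled delivery rate into the trans bath divided by the labelled
fraction (default 1e-6 — deep in the linear-tracer regime yet well
conditioned); it equals the net flux under zero-trans conditions and is
invariant to the labelled fraction to 1e-8, both asserted in tests.

## Model families and their defaults

**Symmetric carrier** (reference parameterisation): K_D = 3 mmol/L on both
faces, empty transit 1 s⁻¹ (the package time base), liganded transit 10×
faster, association 1000× faster per mmol/L (k_off = 3000 s⁻¹). The fast
empty rate is the out→in one; absolute fluxes are per carrier per second, so
all comparisons with experiment use Km values and flux ratios, which do not
depend on the (unknown) carrier amount.

**Asymmetric carrier**: K_D^out = 3, K_D^in = 30 mmol/L. With `auto_close`
the slow empty return is derived from cycle closure
(f_oi·K_D^in·b_io = b_oi·f_io·K_D^out), which at symmetric liganded transit
forces the empty-rate ratio k_oi/k_io = K_D^in/K_D^out = 10 and hence the
equal-bath vacant-site distribution C_in/C_out = 10. Supplying a conflicting
rate with `auto_close` raises.

**Fixed-site chain**: outside bath = vestibule void = site (K_D 3) = central
void = site (K_D 30) = inner void = inside bath. Sites are single-occupancy;
the two faces of a site share its dissociation constant (detailed balance is
then automatic for any positive rates, a property-tested invariant) but may
have different access rates. Defaults: site association 100 (mmol/L)⁻¹s⁻¹,
void/mouth conductance 100 per mmol/L, void capacity 0.01 — voids much
smaller than baths, all configurable since no canonical values exist. The
optional mid-chain **exchange site** holds up to two ligands in positional
outer/inner slots: outer-void ligand enters only the outer slot, crossing
requires a slot swap (rate 1000 s⁻¹), and when both slots are full the swap
is a strict one-for-one exchange. Under a trans-side flood the doubly
occupied antiport path dominates and the site pumps tracer against its
gradient — the counterflow mechanism of a fixed-site transporter — while a
lone occupant may still swap slots so net flux can traverse.

**Branched model**: the chain's outside mouth is two parallel low-affinity
portal sites (the tunnels to the external vestibule), K_D 20 mmol/L, with a
deliberately asymmetric access geometry: the bath-facing rim is the narrow
face (association 0.5 (mmol/L)⁻¹s⁻¹) while exchange with the vestibule is
fast (20 (mmol/L)⁻¹s⁻¹ — same K_D, so thermodynamics is untouched). This
encodes the structural observation that the disease-linked residue sits at
the outer rim of the vestibule. Blocking one tunnel then halves the
saturable exit capacity: efflux Vmax falls ≈ 2-fold and its Km drops
(tailback), influx Vmax — limited deeper in the chain — barely moves, and
the fitted Haldane ratio falls below 1. The inner-chain association is 30
(mmol/L)⁻¹s⁻¹ here so portal and chain share rate control. A purely
conductive (linear) tunnel can never limit Vmax against a clamped bath, and
a rim-symmetric portal is hit equally in both directions; the rim-asymmetric
saturable portal is the minimal in-family mechanism that reproduces the
observed direction-specific lesion, which is why it is the default.

`arrhenius_scale` moves any rate constant between temperatures for a given
activation energy; giving the exchange path (liganded transit) a lower E_a
than dissociation and empty return makes the exchange/net-flux ratio grow as
temperature falls (5.5× at 303 K → 31× at 277 K with E_a 10 vs 60 kJ/mol),
the cold-amplified asymmetry characteristic of red-cell glucose transport.

## Protocols and fitting

Zero-trans and equilibrium-exchange protocols run over a 24-point log grid,
0.03–300 mmol/L (≥ 30× beyond every Km of interest) as clamped steady
states; counterflow is a time course with a finite inside bath. Km and Vmax
come from nonlinear least squares on J = Vmax·S/(Km+S) — linearisations bias
Km, so Hanes–Woolf supplies only starting values. Fits report standard
errors, residual sum of squares and a convergence flag; non-positive
estimates are flagged failures, not exceptions. Synthetic-data studies use
mean-one multiplicative lognormal noise (fluxes are positive; CV
parameterised on the natural scale) with 50 replicates by default; at 5% CV
the median Km bias is below 2%.

## Carrier calibration and the dependent-observable constraint

`calibrate_carrier` minimises the relative error between model observables —
computed by actually running the protocols and refitting — and target values,
over log-parameters with detailed balance always enforced and the fast empty
rate fixed at 1 (all targets are scale-free). Multistart (default 32
log-normal perturbations around the physiological defaults) with early stop.

A structural fact shapes the reference calibration: for **any** 4-state
carrier, zero-trans influx, zero-trans efflux and equilibrium exchange have
exactly hyperbolic flux curves sharing one Vmax/Km slope. (At vanishing
concentration the empty-carrier distribution and the tagged ligand's
crossing probability are protocol-independent, so all initial slopes
coincide; hyperbolicity does the rest. The suite verifies the identity to
1e-13.) Consequently Vm(influx)/Vm(exchange) ≡ Km(influx)/Km(exchange):
the classical quintet's "33%" Vmax ratio and "20%" Km ratio cannot both be
produced by this model class, with or without detailed balance and whatever
the affinity ratio. The reference calibration therefore fits the
structurally independent subset — the two Km values and the efflux/influx
Vmax ratio, reached exactly (residual ~1e-13) — pins the affinity ratio at
the physiological tenfold, and reports the dependent ratios as regenerated:
both come out at 20%. Spreading least-squares weight over the inconsistent
pair would instead push every observable 6–30% off target without making
the pair attainable.

## Numerical choices and degenerate inputs

Newton admissibility requires non-negative solutions (tiny round-off
tolerated); inadmissible or non-convergent seeds fall back to ODE
relaxation, and failure raises with the residual. Zero clamp concentrations
are legal (zero-trans); zero labelled fraction is not. Cycle enumeration
returns an empty list for acyclic networks and treats the identical-label
swap self-loop as a trivial balanced cycle. Blocked branches are omitted
from the network rather than carried as zero rates, so every stored rate
stays positive.

## What the synthetic conditions do and do not show

All inputs are generated: clamped-bath steady states stand in for
initial-rate measurements (exact in the limit the experiments approximate),
noise is i.i.d. multiplicative lognormal, and the fixed-site rate constants
beyond the two printed affinities are round defaults chosen for regime, not
fitted to data. Passing tests therefore demonstrate internal consistency of
the models and pipelines — conservation, detailed balance, tracer linearity,
closed-form limits, recovery of known parameters — not agreement with any
particular experimental record; absolute Vmax values are per carrier and
deliberately not compared with published nmol/(L·s) figures, which depend on
an unprinted carrier amount. The branched-model lesion results are a
qualitative mechanism demonstration whose magnitudes are
parameter-dependent.

## Known limitations

Stochastic (Gillespie) simulation and spatial diffusion are out of scope;
solutions are ideal mixtures (activity coefficients appear only in the
thermodynamic calculators); tracer expansion supports one isotope pair; the
exchange site holds at most two ligands; and fixed-site Vmax in a
single-file chain is inherently direction-symmetric unless site faces are
given asymmetric access rates, which bounds how much of the observed efflux
asymmetry the plain chain can express.
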