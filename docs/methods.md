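# Methods

## Scope and structure

`bbbsim` couples three components: (i) a four-compartment ordinary
differential equation (ODE) model of free and nanoparticle-encapsulated
delphinidin exchange between a capillary lumen, the endothelial
cytoplasm, and a constant brain-tissue bath, with saturable
p-glycoprotein (p-gp) efflux; (ii) a linear two-pool release/uptake
cascade whose released-pool time course is the Bateman function; and
(iii) a categorical expression overlay that paints tumor-versus-cortex
protein expression onto pathway graphs.  The two ODE systems are solved
separately; the release cascade is not coupled back into the transport
equations (a coupled mode would be future work).

## Geometry and units

The whole brain capillary bed is treated as one right circular cylinder:
lumen radius r_L = 1.2 µm, endothelial outer radius r_E = 3.9 µm,
aggregate length l = 600 km.  Volumes and exchange areas use the
cylinder closed forms V_L = π·r_L²·l, V_E = π·(r_E² − r_L²)·l,
A_LE = 2π·r_L·l, A_EM = 2π·r_E·l.  Every derived quantity is linear in
l, so concentrations are identical whether the compartments are read as
totals over l (the implementation) or per unit length.

All computation happens in a canonical unit system — µm, min, amol, with
concentrations kept in µM — chosen because the permeabilities are
published directly in µm/min.  The single point where an amount flux
meets a concentration (dividing the pump term by a compartment volume)
uses the exact factor 1 amol/µm³ = 10³ µM.  `UnitSystem` supports
alternative base units; a property test verifies that the right-hand
side is invariant under a change of canonical system (mm/h/fmol/mM),
which guards the one nontrivial conversion in the model.

## Transport model

Membrane transport is linear in the concentration difference with
permeability coefficients in velocity units (flux = area × permeability
× ΔC): D_LE = 0.5 µm/min for free compound (an order-of-magnitude
estimate, flagged "reasonable prediction" in the schema) or 34.8 µm/min
encapsulated, and D_EM = 1.89 µm/min across the abluminal membrane.
These are *not* Fickian diffusivities (which would carry length²/time).

The p-gp pump returns compound from endothelium to lumen at the
saturable rate J_pgp = J_max·C_E/(K_M + C_E) with K_M = 1.5 µM.  J_max =
2.42 pmol/(min·dm) carries units amount/(time·length): it is a capacity
per unit capillary length, so the pump's total rate is J_pgp·l.  This
per-length reading is the only dimensionally consistent one and fixes
where l enters the equations.  The pump term adds to the lumen equation
and subtracts from the endothelial one.

The brain bath C_M = 1 µM is held constant — the brain is an infinite
sink/source and no mass balance is enforced across the outer membrane.
Both mode-indexed bath concentrations collapse to the single published
value unless overridden.  The schema also carries k = 0.21 µmol/min (a
maximum pumping rate) that appears in none of the model equations; it is
stored for completeness and unused.

### Dynamical structure worth knowing

Summing the volume-weighted equations cancels the exchange and pump
terms, leaving d(V_L·C_L + V_E·C_E)/dt = A_EM·D_EM·(C_M − C_E).  Two
consequences:

* With the pump off and the outer membrane closed, total amount is
  conserved exactly (tested to 1e-6 relative).
* The mathematical fixed point of the full system has C_E = C_M
  *exactly*, with the lumen elevated by the pump offset
  C_L = C_M + J_pgp(C_M)·l/(A_LE·D_LE) — about 2.6 mM in free mode.
  Because the lumen must accumulate that offset through the pump, the
  fixed point is approached on a multi-hour timescale; over the default
  20-min window (and any practical horizon) the pump holds C_E far
  below C_M (≈ 0.05 µM at 20 min in free mode).  "Steady-state
  depletion of the endothelium" in the package's tests therefore refers
  to the terminal state of the default window, not the asymptotic fixed
  point.

With the pump off, the unique steady state is C_L = C_E = C_M and it is
globally attracting (verified from five initial conditions).

### Initial conditions

The published model does not state initial conditions (the figure axis
ranges suggest order-1 µM normalisation).  The default is a lumen bolus
normalised to the bath: C_L(0) = 1 µM, C_E(0) = 0, fully configurable
via the CLI.  Exact published trajectories are therefore not a
reproduction target; the qualitative contrast (encapsulated trajectories
equilibrate faster with a several-fold tighter excursion than free) is.

## Release cascade

The typeset one-line release equation references two states in a single
derivative and is exponentially unstable read literally.  The package
implements the standard two-compartment cascade

    dCu*/dt = −k₂·Cu*,   dC*/dt = k₂·Cu* − k₁·C*

(uptaken pool feeds released pool at the p-gp uptake rate k₂ = 0.035/min;
released pool clears at the release rate k₁ = 0.01/min).  The released
pool is the Bateman function with peak time ln(k₂/k₁)/(k₂ − k₁) =
50.11 min at the defaults — matching the published ~50.1 min result,
which is what confirms this reading.  Which pool represents "brain
concentration" is likewise not stated in the source; only the released
pool of the cascade reading is consistent with the 50.1 min figure, so
that is what the package reports.

Near k₁ = k₂ the closed forms switch to the degenerate branch
(C* ∝ k·t·e^{−kt}, peak 1/k) when |k₂ − k₁| < 1e-9·max(k₁, k₂), avoiding
catastrophic cancellation; continuity at the switch is tested at a
relative rate gap of 1e-8.  k₂ = 0 (closed uptake pool) is accepted by
the parameter container — the released pool then decays purely
exponentially — but the peak-time formula requires k₂ > 0.

The release horizon defaults to 200 min (≈ 4× the default peak time),
deliberately overriding the transport window of 20 min, because the
documented peak lies outside it.

## Numerics

Both systems are integrated with `scipy.integrate.solve_ivp` (LSODA,
rtol 1e-8, atol 1e-10 µM); the encapsulated transport mode mixes fast
exchange with slow pump-driven accumulation and benefits from a
stiff-capable method.  Output is dense interpolation onto a uniform grid
(500 points default), decoupled from internal steps.  Halving the
tolerances changes reported concentrations by < 1e-6 relative; metrics
at 200 vs 400 grid points agree to < 0.1 %.

Solver undershoot below zero is tolerated to −1e-9 µM, clamped to 0 in
output, and counted (`clamped_points`); anything worse raises an
integration error.

Metrics: peaks are located by quadratic interpolation through the grid
argmax and its neighbours (boundary or constant trajectories are flagged
instead of interpolated); AUC uses the trapezoid rule; the
lumen–endothelium gap-closure time interpolates the first crossing of
50 % of the initial gap.

The *equilibration time* reported by sweeps is a settling time: the
first grid time after which **both** compartments stay within 5 % of the
largest initial gap to C_M.  The one-sided alternative (time for C_E
alone to reach the bath band) is not monotone in the luminal
permeability when the lumen starts at C_M — fast membranes transiently
drag C_E toward the diluted lumen — whereas the settling definition
decreases monotonically with D_LE, which is the behaviour a design sweep
should rank by.  The 5 % band is a package convention.

Verifying the integrator against the Bateman closed form across rate
pairs up to 1/min uses rtol 1e-12 / atol 1e-14 and holds every point
above a 1e-7 µM floor to 1e-6 relative agreement; below that floor the
trajectory (e.g. e^{−200} ≈ 10⁻⁸⁷ at the window end for the fastest
pair) is beneath any fixed-absolute-tolerance integrator's resolution
and relative comparison is meaningless.

Nothing in the package is stochastic; repeated runs produce
bit-identical trajectories and byte-identical CSV/JSON/GraphML files,
which is tested end-to-end through the CLI.

## Expression overlay

The shipped table transcribes a published screen of 73 proteins:
categorical expression in four healthy cerebral-cortex contexts
(endothelial cells, glial cells, neuronal cells, neuropil) and
per-category sample counts in glioma (denominators 9–12 samples).  Rows
where the source table gives a single cortex value spanning all four
contexts are transcribed with the value replicated; "?" cells map to
Uncertain, "N/A" (including the cortex-only annotation on an otherwise
scored row) to N/A — both excluded from ordinal comparison.

The modal tumor category maximises the count with ties broken toward the
*higher* expression category — conservative when screening for
over-expressed targets, and configurable in principle by reordering the
category scan.  Differential flags compare the modal tumor category to
each cortex category on the scale Not Detected < Low < Medium < High.

Node annotation follows the published colour legend (olive = not
available, deep sky blue = not detected, green = low, medium orchid =
medium, deep pink = high).  The two source figure captions disagree on
quarter orientation (counterclockwise vs clockwise); the package follows
the clockwise caption order endothelial → neuropil → neuronal → glial
and records both the choice and the conflict here.  The shipped pathway
graph is synthetic — Table-derived proteins with illustrative edges —
and makes no biological claim; the overlay runs on any GraphML or SIF
graph whose nodes carry a `symbol` attribute.

## What the defaults do and do not represent

The default parameter set is the published configuration: measured or
literature-derived permeabilities, pump kinetics and geometry, plus one
explicitly estimated permeability (free-compound D_LE) and nominal
start/stop times.  Simulations with these defaults reproduce the
structural predictions (peak timing, mode contrast, pump depletion) of
an idealised single-tube BBB; they do not capture branching vasculature,
spatial gradients along the capillary, saturable influx carriers,
blood–CSF or blood–tumor barriers, nanoparticle size/charge physics, or
EPR effects — all outside the model's scope.  Passing tests certify the
mathematics and the implementation, not clinical transferability.

## Problem sizes

Default runs integrate 2-state ODE systems over 20–200 min windows on
500-point output grids; sweeps re-run one simulation per grid value.
The full test suite and the acceptance script each complete in seconds
on a single CPU.
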