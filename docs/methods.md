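# Methods

## Model

One calcium release unit is described by three compartments — dyadic
cleft (`c_d`), sarcoplasmic reticulum (`c_sr`, with total content
`c_sr_tot`) and bulk cytosol (`c_i`) — exchanging calcium through RyR
release, dyadic diffusion and SERCA uptake. Two modelling commitments
shape everything else:

1. **Conserved total calcium.** Membrane fluxes (LCC, NCX) are absent, so
   the volume-weighted total load `c̄_T` is an exact invariant and the
   natural bifurcation parameter. `c_i` is recovered algebraically from
   the conservation law at every evaluation rather than integrated; with
   a single saturable cytosolic buffer (`B_b`, `K_b`) this is a quadratic
   with a unique nonnegative root. Conservation therefore holds to
   round-off on every trajectory of the three-variable and fast-RyR
   models — the drift check in the test suite asserts ≤ 1e-8 relative.
2. **Rapid calsequestrin buffering.** SR buffering is equilibrated
   instantaneously: `c_sr_tot = c_sr + B_SQ·c_sr/(K_SQ + c_sr)`, inverted
   in closed form. This formulation conserves mass exactly (the free ↔
   total maps are algebraic inverses); no finite-rate CSQ ODE is
   implemented.

The SERCA term `g_up·c_i²/(K_s²+c_i²)` has no reversal/leak, so
`c_i = c_d = 0` with a loaded SR is an equilibrium at every load — the
"closed RyR" rest state. This is a deliberate simplification: the real
diastolic `c_i` of ~0.1 μM is collapsed to zero, which changes nothing
about the regime structure at SR concentrations of ~1 mM.

Model variants: the full three-variable model; a **fast-RyR** reduction
(`P_o` slaved to `c_d²/(K_o²+c_d²)`), the baseline for all deterministic
and stochastic analysis; a **fast-dyadic** reduction (`c_d` slaved,
restricted to `B_SQ = 0`) used as a robustness check. The slaving
relations are exactly the fixed-point conditions, so all variants share
their equilibria; only stability and transients differ.

### Known artifact of the fast-dyadic reduction

At spike take-off with a full SR the slaved dyad demands more calcium
than the cell holds (`v_d·c_d + v_sr·c_sr_tot > v·c̄_T` while `c_i`
clamps at zero). The violation is bounded by O(`v_d/v_sr`) of the load —
measured below 1e-3 relative — and transient; the exact-closure variants
do not have it. Mass-conservation guarantees are therefore stated for
the three-variable and fast-RyR models only.

## Parameters and calibration

Units are fixed package-wide: μM, ms, and volumes as fractions of
`v = v_i + v_sr + v_d`. The control values shipped in
`src/caosc/data/control.toml` come in two classes, tagged there:

* **PAPER-class** (fixed from the literature on minimal CaRU models):
  `K_o = 15 μM`, `B_b = 80 μM`, `K_b = 0.5 μM`, `K_SQ = 650 μM`, and the
  CSQ range `B_SQ ∈ [0, 20 mM]` with 0 as the no-CSQ baseline.
* **DERIVED-class** (calibrated once, then frozen). The calibration uses
  the model's own closed forms and target regime map:
  - `v/v_sr = 45.6` pins the resting SR concentration at onset
    (2.28 mM for an onset load of 50 μM);
  - `g̃ = g·τ_i/K_o² = 2/2240 ≈ 8.93e-4 μM⁻²` pins the diastolic SR level
    at onset (0.86 mM) through the onset closed form;
  - `v_d/v = 0.001` — a dyadic cleft three orders of magnitude smaller
    than the cytosol, the physiological order;
  - `A′ = τ_i·g_up·v_i/v_d = 2.0` and `K_s = 0.187 μM` solved jointly so
    the fold of fixed points sits at 39 μM and the Hopf at 66 μM;
  - `τ_i = 0.008 ms` sets the absolute clock (see below);
  - `k_m = 0.086 ms⁻¹` (with `k_p = k_m/K_o²`) places the upper-branch
    stabilisation of the slow-gating variants at 54 μM.

A structural fact makes this calibration well-posed: rescaling `τ_i`
while holding `g·τ_i` and `τ_i·g_up` fixed rescales the entire vector
field in time. The deterministic phase portrait — every locus in load —
is therefore independent of the `τ_i` split, and `τ_i` is a pure
time-unit knob. It is anchored to the one time-dimensional observable in
the target map, the ~1 s noise-driven period at `c̄_T = 35 μM` with
`σ = 2e-3` at the default step (below). A consequence worth knowing: the
deterministic cycle periods come out at tens of milliseconds (36 ms at
54 μM), so the noise-driven low-load rhythm is over an order of magnitude
slower than the deterministic one, which is the qualitative signature
being modelled.

## Stochastic gating

Noise enters as `P_o = c_d²/(K_o²+c_d²) + σ·(U − ½)`, `U ~ Uniform(0,1)`
redrawn every step, result clamped to [0,1]. Bounded per-step noise has
**no step-size-independent continuum limit**: the firing rate at loads
below the fold is a streak-probability effect and depends on `dt/τ_i`.
The step is therefore part of the model definition, recorded in trace
metadata; the default is `dt = 0.01 ms`, with `dt ≲ 1.7·τ_i` required for
stability of the explicit update of the dyadic relaxation. Fixed-step
Euler is used for stochastic runs (σ = 0 reproduces the deterministic
fixed-step run sample-for-sample); deterministic runs use adaptive LSODA
(`rtol 1e-8`, `atol 1e-10`, max step 5 ms).

## Fixed points, stability, loci

Equilibria reduce to one scalar equation `f(c_i; c̄_T) = 0` via
`c_d = c_i + (v_i/v_d)·τ_i·J_up(c_i)` and conservation. Roots are
bracketed on a 2000-point log grid over the feasible `c_i` interval
(upper end where the SR would be empty), polished with Brent's method to
machine tolerance, and merged below 1e-6 μM — enough to resolve the
five-fixed-point window that opens at high CSQ. Jacobians are central
finite differences in the variant's own coordinates (relative step 1e-6,
one-sided at the feasibility boundary); classes follow the eigenvalues
(node/spiral × stable/unstable, saddle).

* **Fold**: bisection on the nontrivial root count (tolerance 0.05 μM).
* **Hopf**: bisection on the sign of the upper branch's leading
  eigenvalue real part; reported absent when the branch is born stable
  (the high-CSQ saddle-node regime).
* **Homoclinic**: downward sweep plus bisection (default tolerance
  0.1 μM, matching the ~1 μM precision of the target loci) on a
  sustained-oscillation classifier applied to trajectories launched just
  off the upper fixed point. Direct integration replaces periodic-orbit
  continuation; the unstable cycle segment near any fold of cycles is
  out of scope.

The **sustained-oscillation classifier** requires peak-to-peak `c_i`
amplitude above `max(0.02 μM, 5%·max c_i of the trace)` and ≥ 5 cycles
with inter-peak CV < 0.2 (deterministic) or < 0.6 (stochastic; cycles
near the noisy onset are slow and irregular). The amplitude reference is
per-trace, not per-sweep: a sweep-wide reference would veto genuine
small-amplitude cycles near the Hopf once the grid extends into the
high-load region whose stable state sits at several μM. Default
transient discard is 2 s of model time for deterministic classification
and 20 s for stochastic (both ≫ the observed relaxation times at the
calibrated clock).

The period estimator is the mean inter-peak interval of `c_i` after the
transient (`scipy.signal.find_peaks`, prominence 0.3 × amplitude),
returning "no oscillation" below the amplitude rule.

## Nullclines and the geometric onset criterion

In the (c_d, c_sr) plane of the fast-RyR variant the `ċ_d = 0` curve is
S-shaped: one or three roots in `c_d` per `c_sr` line (the
release-dominated high-`c_d` root always exists, because `α > 0` at
`c_d = 0` whenever `c_i > 0`). The **pinch-off** is detected as an
interior band of `c_sr` lines carrying a single root (the low-`c_d` pair
lost), flanked by three-root bands — scanned on a 400-line `c_sr` grid
with 600 log-spaced `c_d` points per line, and refined in load by
bisection. The analogous construction in the (c_sr, P_o) plane of the
fast-dyadic variant uses a log grid in `P_o` (its low roots sit at
~1e-3) and pinches off at the same load, as the slaving algebra
dictates.

Scope of the criterion: the pinch-off coincides with the oscillation
onset (the homoclinic) — that is the geometric claim, and the package
verifies onset-side equivalence plus "oscillation ⇒ split" at every
load. It is *not* an equivalence across the whole load axis: above the
Hopf the upper state restabilises while the split closes slightly
later, so a narrow split-but-no-oscillation band exists there.

The onset closed form (see README) assumes `c_d ≪ K_o`, `c_d ≪ c_sr`,
`B_SQ = 0` and bound-buffer dominance; its independent check in the test
suite verifies that the reported `c̄_T*` zeroes the discriminant of the
critical-SR quadratic and that `c_sr*` is the double root. Because the
`ċ_d = 0` curve contains no uptake term, both the closed form and the
numeric pinch-off are exactly independent of `g_up`. One direction worth
stating precisely: the closed form is monotone increasing in `B_b`
(more cytosolic buffer delays onset) but **non-monotone in `K_b`**, with
a maximum near `K_b ≈ v_sr/(4·g̃·v_i·B_b) ≈ 0.08 μM`; at the control
`K_b = 0.5 μM` the onset load *falls* as `K_b` grows. Claims that higher
buffer affinity always lowers the onset hold only below that turning
point.

## Lattice surrogate

The 1-D lattice couples fast-RyR units by pairwise antisymmetric
exchange of cytosolic (optionally SR) calcium; each unit's `c_i` stays
slaved to its *local* load, which evolves only through exchange, so the
lattice total is conserved exactly and unit mathematics is untouched.
No-flux boundaries; explicit steps refused beyond the diffusive
stability bound. Default coupling `D_i = 4 ms⁻¹`, `D_sr = 0`.

What it emulates: the three qualitative regimes of a spatially resolved
cell (quiescent with rare sparks at low load; recurring, partially
propagated multi-unit release events at intermediate load; a persistent
high-`c_i` state at high load) and a measurable event rate via a
line-scan event detector (8-connected supra-threshold components, front
fitted for a speed). What it does not: quantitative wave speeds, regime
boundaries of any detailed subcellular model, RyR state schemes beyond
the two-state gating, or spatial microstructure. A caveat discovered in
its construction: under instantaneous cytosolic buffering a
*deterministically* firing unit cannot raise a resting neighbour's free
`c_i` over the CICR threshold for any coupling strength (buffer and
SERCA absorb the transferred load), so propagation in the surrogate is
noise-assisted — consistent with its role as a stochastic-regime
illustration, not a wave solver.

## Synthetic fixtures

The fixture generator produces mass-consistent traces with embedded
ground truth for validating the estimators: a sinusoid and a
relaxation-spike train (known period), a constant trace (no
oscillation), and a seeded jittered spike train (known mean period,
CV 10%). They validate the period estimator and classifier, not the
model; passing them says nothing about dynamics.

## Limitations

* The derived parameter set is one consistent solution of the
  calibration constraints, not a measured set; all regime-map statements
  are conditional on it (the loci are, by construction, insensitive to
  the `τ_i` clock split).
* No pseudo-arclength continuation or Floquet analysis: cycle extents
  come from direct integration, so unstable cycles are invisible and
  loci carry the stated bisection tolerances.
* The stochastic model's firing statistics are tied to the recorded step
  `dt`; comparisons across steps are comparisons across models.
* No membrane electrophysiology, pacing, or calcium exchange with the
  exterior — by design, to isolate the load-driven instability.
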