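# Methods

## Scattering model

A solute is a set of point scatterers with per-particle form factors
f_j(q) in electrons.  Three form-factor modes are provided:

* **atomic** — Cromer–Mann 4-Gaussian parameterisations for C, N, O, P,
  Mg, K, Cl (and H), so f_j(0) equals the electron count;
* **solvent-corrected** — the atomic factor minus a displaced-solvent
  Gaussian ρ_s·V_j·exp(−q²·V_j^{2/3}/4π) with ρ_s = 0.334 e/Å³ and
  approximate per-element displaced volumes.  This is a reduced,
  per-particle treatment of excluded-volume contrast: it preserves the
  buffer-subtraction API (`excess_intensity`) for users who supply
  measured buffer curves, but it does not model an explicit hydration
  shell or ion atmosphere;
* **constant** — q-independent bead factors (plus optional Gaussian
  beads of finite radius) for coarse-grained models.

Two intensity routes are implemented and tested against each other and
against an independent spherical product quadrature: the exact Debye
sum (with sinc(0) = 1 for coincident pairs) and the discrete
direction-set average over a Fibonacci-sphere layout.  The Fibonacci
layout is deterministic; a seed-keyed random rotation decorrelates
direction sets between runs while keeping each set reproducible.  Both
routes are exact at q = 0.  For the coarse-grained systems this package
targets (tens of beads) the Debye route with analytic gradients is
cheap enough to use on the fly, so it is the default inside the
dynamics engine; the sampled route (e.g. 1,500 directions) exists for
fidelity to on-the-fly protocols at atomic scale and converges to the
Debye result as the direction count grows.

Internal q units are 1/Å; readers accept 1/nm with a unit flag (q/10).
The X-ray wavelength never enters computations — all inputs are in
q-space.

## Coupling energy and forces

The restraint energy per evaluation is

E_SAXS = α(t)·k_c·kT/n_q · Σ_i (I_com(q_i) − I_exp(q_i))²/σ²(q_i)

with σ² = σ_exp² + σ_com² + σ_buffer² at each restrained point.
Defaults: σ_com = 0 (pluggable — how to estimate the statistical error
of a computed curve is left open), σ_buffer = 0.005·I_exp (a 0.5%
relative solvent-density uncertainty).  The restrained grid is n_q
points equally spaced over the target's q range capped at `q_max`, with
target intensity and σ linearly interpolated onto it; n_q = 50 by
default, and `shannon_nq` (ceil(q_max·D_max/π)) documents the
information-theoretic floor.

Design choices where the procedure is genuinely open:

* **Switch function.** α(t) = min(t/t_switch, 1) — the simplest
  monotone ramp satisfying "gradual introduction".
* **Memory average.** Discrete normalized exponential weights
  w_k ∝ exp(−age_k/τ).  The stored average is a convex combination of
  all submitted curves; the newest submission carries normalized weight
  1/W, and the restraint force is the exact gradient of the penalty
  through the memory, i.e. the instantaneous-curve gradient scaled by
  that weight.  The config default is τ = 2.0 time units (100 default
  time steps); the HJH driven protocol uses τ = 0.05, a quarter of the
  force-refresh interval, so the restraint responds at the
  conformational fluctuation timescale of the toy (see "Driven
  protocol" below).
* **Scale matching.** Before the penalty is evaluated the computed
  curve is scaled by the least-squares factor c = Σ(I·I_exp/σ²) /
  Σ(I²/σ²) onto the target (standard SAXS practice; exposed as a flag,
  on by default).  Because c is optimal at evaluation time, its
  implicit coordinate dependence drops out of the gradient (envelope
  theorem), keeping the force expression simple and exact — verified
  against central finite differences at rel. 1e−4.
* **Replica forces.** The replica-averaged energy (prefactor k_c·N^Ω,
  Ω = 1) is differentiated exactly: the force on replica β is
  −∂E/∂r_β through the mean curve, i.e. the shared residual weight
  times (1/N)·∂I_β/∂r_β.  With Ω = 1 the per-replica force magnitude
  matches the single-replica case.

Restraint forces from either intensity route sum to zero exactly
(pairwise model); the Debye route additionally has exactly zero torque
about the centroid, one more reason it is the engine default.

## Coarse-grained toy and integrator

The HJH toy is a bead-per-base-pair chain: two arms of 12 beads at
2.8 Å rise joined by a 5-bead linker.  Harmonic bonds
(E = ½k(r−r₀)², k = 100 ε/Å²), harmonic angles at θ₀ = π (arms
k = 50 ε/rad², linker triples k = 5 ε/rad², a 10:1 stiffness and hence
persistence-length contrast) and a WCA repulsion truncated at 4 Å
between beads ≥ 2 bonds apart.  These constants are qualitative — they
make the arms rod-like and the junction flexible; they are not fits to
any RNA.

Units are reduced: k_B = 1, so `temperature` is the thermal energy in
units of ε directly (a physical k_B can be configured), lengths in Å,
masses 1.  The integrator is the BAOAB splitting of Langevin dynamics —
chosen for its configurational-sampling accuracy at large steps and
because engine-level details of production SD integrators are not
portable.  A stability guard rejects dt·ω > 0.6 for the stiffest bond.
Determinism: one `numpy` Generator seeded per run (per replica:
seed + replica index), so identical seeds give bitwise-identical
trajectories.  Equipartition of the integrator is verified to 5% on
independent harmonic beads (300 degrees of freedom × 23k retained
steps, the vectorised equivalent of one long 1-D run).

## Driven protocol

The reference experiments (`saxsdrive.protocols`) fix the study
conditions: synthetic targets carry 2% relative Gaussian noise with a
matching σ column; the single-replica run uses k_c = 0.5 and the
four-replica run k_c = 1.0, both with n_q = 50; pool admission is
χ² ≤ 2.0 and ensemble convergence χ² ≤ 1.5; four replicas start from
bend angles 0/30/60/90° to cover the conformational range.

Protocol constants chosen once for the toy (and why):

* dt = 0.02, friction = 0.5 — stable for the stiffest spring and
  diffusive enough to equilibrate in tens of thousands of steps;
* temperature = 0.5 ε — arms behave as stiff rods (per-joint angular
  σ ≈ 6°) while the junction bends freely by tens of degrees, the
  regime the motif is meant to represent;
* SAXS force refresh every 10 steps with forces held in between (cost
  control; the curve changes negligibly over 10 steps);
* τ = 0.05 (¼ of the refresh interval), t_switch = 60 time units.  A
  memory long compared with the refresh interval down-weights the
  newest curve and, through the exact gradient, scales the effective
  coupling by that same factor; for a toy whose conformational
  free-energy scale is only a few ε the restraint must act at nearly
  full instantaneous weight to overcome the entropic preference for
  bent states.
* Problem sizes: 80,000 steps for the single-replica experiment and
  60,000 per replica for the four-replica one (the package's choice of
  a converged-but-economical budget; the test suite uses 40,000/30,000
  variants of the same protocols).

χ² is recorded every 100 steps from the scale-matched memory curve
against the target's experimental σ (the metric's definition), and
convergence statistics are taken over the final 20% of records.

## Synthetic targets

`make_synthetic_target` builds I_target = Σ_s w_s I_s(q) from exact
Debye curves of known conformers, adds noise N(0, (ν·I)²) with a fixed
seed and writes σ = ν·I (floored at 1e−6 of the peak so error weighting
never divides by zero).  The generator reproduces the statistical
structure assumed by the χ² metric — E[χ²(truth, target)] = 1, asserted
to 20% over 50 replicates — but none of the systematic features of real
measurements: no buffer mismatch, no inter-point error correlation, no
q-dependent beam effects.  Passing tests therefore demonstrate the
correctness of the machinery and the recoverability of known ensembles
under well-specified noise, not performance on real detector data.

## Reweighting and clustering

Maximum-entropy reweighting minimises χ²(weighted-mean curve)/2 +
θ·D_KL(w‖w₀) over the simplex (softmax parameterisation, L-BFGS with
analytic gradients; reference weights uniform by default).  θ → 0 fits
the curve alone, θ → ∞ returns the reference; the sweep traces a
monotone χ²-vs-D_KL trade-off and `theta_lcurve` picks the knee by the
maximum-distance-to-chord rule.  The objective is this package's
concretisation — the maximum-entropy principle itself prescribes the
divergence, not the estimator.

Clustering uses minimal RMSD after Kabsch superposition (all beads,
uniform weights, proper rotations).  GROMOS: greedily take the frame
with the most neighbours within the cutoff as a center (ties → lowest
frame index), remove its neighbourhood, repeat.  Single linkage:
connected components of the ≤-cutoff graph, centers = medoids.  Labels
are canonicalised (descending cluster size, then lowest member index)
so they are invariant under frame reordering.  Typical cutoffs: 4.0 Å
(GROMOS on heterogeneous pools) and 1.0 Å (single linkage on tight
pools); which distance definition underlies a given published cutoff is
not always stated, so both method and cutoff are parameters.

## Analysis conventions

* R_g is the weighted RMS distance from the weighted centroid; the
  pair-sum identity is asserted as a property test.
* RMSF superposes every frame onto a reference before accumulating
  deviations about the weighted mean; a rigid-body fit absorbs ~1/N of
  a single particle's fluctuation variance, which is why closed-form
  checks use many anchor particles.
* Contact maps use the minimum inter-residue particle distance with a
  6 Å default cutoff; the diagonal and |i−j| ≤ 1 neighbours are flagged
  and set to NaN.
* RDFs normalise by shell volume and bulk density (explicit, or
  estimated from the outer 20% of the range); the local cation
  concentration is g_max·c_bulk, with the reference site per residue a
  selectable particle (one designated bead per residue in toy models;
  whether a published peak refers to phosphorus or phosphate-oxygen
  RDFs can be ambiguous, so the site selection is a parameter).
* FRET efficiency averages E(r) = (1+(r/R₀)⁶)⁻¹ over the label-distance
  distribution (R₀ = 60 Å default).  Dyes are not modelled: distances
  are measured between user-selected label sites and the orientation
  factor is the isotropic assumption built into E(r).
* Bend/twist of a two-arm construct: arm axes are index-order-oriented
  principal axes; bend is the inter-axis angle; twist is the azimuth of
  arm b's axis about arm a's axis measured from a lab-fixed
  Gram–Schmidt reference, so twist differences are meaningful between
  frames sharing the arm-a alignment.  A degenerate (zero-extent) arm
  falls back to the end-to-end vector with a warning.  This is one
  consistent choice among several possible constructions.

## Degenerate inputs and numerical guards

sinc(0) = 1 for coincident scatterer pairs; angle forces use a clamped
sin θ ≥ 1e−8 (the collinear minimum has a genuinely zero gradient);
beads at exactly zero distance in the WCA term raise an integrity
error rather than evaluate the singularity; NaN anywhere in the
integrator state aborts with the last valid recorded frame index;
σ ≤ 0 at any restrained point is a configuration error; profile
writers/readers round-trip at printed precision.

## Known limitations

No explicit solvent or ion scattering from trajectories; no 3-D
density-envelope construction (the distance-shell selection and the
solvent-corrected form factors are the reduced stand-ins); no WAXS; no
coupling to external MD engines; the toy force field is qualitative.
Conclusions from the bundled experiments transfer to real systems only
insofar as the restraint machinery — not the force field or the noise
model — is the object under test.
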