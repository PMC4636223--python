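# Methods

## Single-barrier landscape and escape rates

The bound (autoinhibited) state is modelled as a one-dimensional
diffusive coordinate in a single-barrier free-energy profile with three
parameters: barrier height `ΔG` (in units of k_BT), barrier distance
`x_b` (nm) and effective diffusivity `D` (nm²/s). Temperature defaults
to 300 K (k_BT = 4.142 pN·nm) and is overridable. Two profile shapes are
implemented:

* **harmonic cusp** — parabolic well of curvature `2ΔG·k_BT/x_b²` with an
  absorbing cusp at `x_b` (used by the `bsk` model kind);
* **linear-cubic** — smooth cubic with equal well/barrier curvatures
  `6ΔG·k_BT/x_b²` (default for the `hs` kind; the cusp is available as an
  option).

The zero-force rate is the overdamped high-barrier Kramers rate with the
prefactor built from `D` and those curvatures:

    cusp:          k0 = 2 D ΔG^{3/2} / (x_b² √π) · e^{−ΔG}
    linear-cubic:  k0 = 3 ΔG D / (π x_b²)        · e^{−ΔG}

Verified against the exact mean-first-passage double integral, these
expressions are accurate to 7% (linear-cubic) and 14% (cusp) even at a
low barrier of 5 k_BT, and to <2% at 28.5 k_BT; the test suite also
checks them against a brute-force Euler–Maruyama first-passage
simulation.

Under force the rate follows the standard one-parameter closed form with
`ν = 1/2` (cusp) or `ν = 2/3` (linear-cubic); the Bell model
`k(F) = k0·e^{βFx_b}` is kept as the phenomenological limit. The barrier
vanishes at `F_c = ΔG·k_BT/(ν x_b)`; evaluation at or beyond `F_c`
raises an explicit out-of-regime error rather than extrapolating. The
closed form is monotone in force only while a barrier of at least ~1 k_BT
remains (the prefactor turns over as `F → F_c`); monotonicity is asserted
on that region.

## Rupture-force statistics and their regime of validity

A constant-velocity harmonic transducer loads the bond at
`Ḟ = stiffness_factor · κ_s · v` (the stiffness factor, default 1, is
the only compliance correction — no explicit two-spring dynamics). The
rupture-force density is the quasi-adiabatic first-passage expression
`p(F) = k(F)/Ḟ · exp(−(1/Ḟ)∫₀^F k)`, evaluated by composite Simpson
quadrature on a ≥4000-point grid that stops 1% below `F_c`. The
probability of surviving past the grid is reported as a *survival
deficit*; means and standard deviations are conditional on rupture
within the admissible range, and the synthetic sampler draws from the
same conditional law by inverse transform, so analytic moments, sampler
and likelihood are mutually consistent by construction.

This construction is exact in the slow-pulling (activated) regime but
cannot describe drift-dominated rupture beyond `F_c`. At the fast end of
the default campaign (κ_s = 415 pN/nm, v up to 1 nm/ns) the deficit
reaches ~0.98: most first passages physically occur beyond the barrier-
vanishing force, where the conditional mean saturates (~229 pN for the
default fit) instead of continuing to rise. Consequences for inference
are discussed under *Known limitations*.

## Spectrum fitting

* **Least squares**: RMSD between the model's conditional mean-force
  curve and the per-loading-rate group means, minimized over
  `(log ΔG, log x_b, log D)` by 16-start SLSQP from a Latin hypercube
  (fixed seed 20151106; bounds ΔG ∈ [5, 60] k_BT, x_b ∈ [0.1, 2] nm,
  D ∈ [10⁴, 10⁹] nm²/s). The thermal-stability constraint
  `k0 ≤ k0_max` enters as a nonlinear inequality. Because the objective
  has a flat degeneracy ridge, candidates pinned to the search-box
  boundary are artifacts of where the box ends; among candidates whose
  RMSD ties within the statistical resolution of the objective
  (propagated from the per-rate standard errors, hence exactly zero for
  noiseless data) interior or constraint-boundary solutions are
  preferred.
* **Error surface**: per-(ΔG, x_b) cell, RMSD minimized over a log-spaced
  `D` grid. Since `k ∝ D`, one rate evaluation per cell serves all `D`
  values, and the `k(50 pN)/k0` contour values are `D`-independent.
* **Posterior**: the likelihood is the product over events of the
  conditional first-passage density at each event's loading rate (events
  beyond a candidate's critical force have zero likelihood there);
  optionally Gaussian per-rate residuals, under which the uniform-prior
  MAP coincides with the least-squares optimum. Priors: logarithmic
  `∝ 1/(ΔG·x_b·D)` or uniform, both including local cell volume so
  linear and log grids are treated consistently. Default grids:
  111 × 96 × 51 over the bounds above. Credible regions are
  highest-mass cell sets (50%/95%, nested by construction); >5% mass on
  the grid boundary raises a warning flag on the result.

## Event detection and observables

Rupture = global maximum of the force channel after a centered moving
average (default window 1% of trace duration, exposed as a flag). A
maximum at the trailing edge means the force was still rising — returned
as "no event" data rather than an exception, since a minority of pulling
runs end in conformational damage instead of dissociation. With an
interface-area channel present, the event is flagged consistent if it
falls within one window of the first area drop. Area channels are
segmented by recursive binary change-point splits minimizing
within-segment variance, keeping splits whose level change is ≥ 1 nm²
(default). Trace-derived loading rates use the Theil–Sen slope of the
10–90% pre-rupture ramp.

Contacts use a strict `< 0.6 nm` cutoff ("closer than"), counted
directionally (group-A atoms near group B) with an explicit symmetric
variant. Buried interface area is
`(SASA(A) + SASA(B) − SASA(A∪B))/2` by Shrake–Rupley sampling (probe
0.14 nm, 960 golden-spiral points per atom, per-element van der Waals
radii, 1-based residue indexing). The deterministic point set makes the
estimate quasi- (not exactly) rotation invariant: a rigid motion moves
the value by well under 2%, while contacts and minimum distances are
invariant to 10⁻⁹ nm. Since the area convention of the reference pulling
analysis is unstated, absolute area levels are comparable only
qualitatively. Stress-drop assignment compares leading/trailing window
means (default 5% of the duration) per residue; the largest drop must
remove ≥ 50% of the pre-drop level and fall within a tolerance window of
a rupture step to be labelled step1/step2.

## Force-gated network

Force enters the biochemistry in exactly one reaction, FAK_closed →
FAK_open at rate `k(F)` (re-closing at a slow fixed rate). The default
scheme chains sequential bimolecular assembly — FAK_open + Src, SHC
phosphorylation by FAK_Src, SHC_p + Grb2 + SOS — into the exchange
enzyme E, which processes Ras_GDP through an explicit
E + S ⇌ ES → E + P Michaelis–Menten mechanism. All species, rate
constants (order-of-magnitude values from the receptor→Ras network
modelling literature) and the three built-in landscape parameter sets
live in `data/default_network.yaml`; an alternative scheme can be
supplied through the same format. Declared moiety totals (FAK, Src, SHC,
Grb2, SOS, Ras) are conserved by the stoichiometry, checked at build
time and verified to 10⁻⁶ relative on every trajectory.

Integration uses BDF with reltol 10⁻⁸, abstol 10⁻¹² nM and dense output;
`t₅₀` readouts are refined by root finding on the dense solution, so
they are insensitive to output sampling. Force sweeps default to 25
log-spaced forces over 1–100 pN, extending the horizon until both
readouts cross (or a 10⁹ s cap marks "not reached"). The
rate-vs-substrate curve clamps Ras_GDP and reports the turnover flux
after a fixed 10³ s settling time: the exchange step itself is then in
quasi-steady state while the slow force-gated opening still carries the
force signal — evaluating at infinite time would let even rare
spontaneous openings assemble the full enzyme pool and erase the force
dependence that the transient, physiologically relevant window shows.

## Synthetic data

The default campaign mirrors the pulling study conditions: 13
log-spaced velocities from 6×10⁻³ to 1 nm/ns, 83 runs total (six per
velocity, the five slowest getting a seventh — slow pulls carry the most
barrier information), transducer 250 kJ mol⁻¹ nm⁻² (= 415.13 pN/nm).
Rupture forces are inverse-transform draws from the conditional
first-passage law; traces add Gaussian force noise (default 5 pN) to the
ramp, relax exponentially after rupture, and carry a two-step area
collapse (initial plateau uniform in 3–4.5 nm², intermediate in
1.5–2.8 nm², then zero) plus an end-to-end channel with jumps at both
steps. Stress matrices implant 90% drops at the designated step times.
Every generator is a pure function of its seed.

What the generators do **not** emulate: drift-dominated rupture beyond
the barrier-vanishing force (see above), correlated noise and drift in
real force traces, partial unfolding events, heterogeneous per-run
stiffness, and any membrane physics. Passing tests therefore demonstrate
the internal consistency and statistical calibration of the analysis
chain on data obeying the model's own law, not agreement with real
trajectories.

## Known limitations

* The quasi-adiabatic construction caps the mean-force curve below
  `F_c`. On synthetic campaigns this leaves near-iso-fitting landscape
  families whose mean curves differ by less than the per-rate noise at
  n = 83, so the *least-squares* barrier distance is not reliably
  identified — the fit can run along the degeneracy ridge to the search
  bounds. The per-event Bayesian posterior, which sees the density shape
  rather than only means, does localize `(ΔG, x_b)` and is the
  recommended route for parameter uncertainty.
* Rate expressions use high-barrier prefactors; absolute rates at
  barriers below ~5 k_BT carry order-10% prefactor error (the
  exponential dominates everywhere the package is used).
* The reaction scheme is a minimal representative of the published
  network family; absolute `t₅₀` values depend on the order-of-magnitude
  constants and only the qualitative force-response shapes (monotone FAK
  acceleration, saturating Ras turnover) are asserted.
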