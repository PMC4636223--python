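# mechanofak

Focal adhesion kinase (FAK) is held inactive by its FERM domain docking
onto the kinase domain. Tensile force across the molecule — transmitted
from the membrane through the FERM basic patch and from the cytoskeleton
through the kinase C-terminus — can peel that autoinhibitory interface
open and expose the Tyr576/577 activation loop. `mechanofak` implements
the desk-side analysis that turns force-probe pulling data into a
quantitative model of this mechanosensor, entirely on synthetic inputs:

1. **Rupture-force spectroscopy models** (`dfs_models`): a single-barrier
   free-energy landscape `(ΔG, x_b, D)` evaluated with the harmonic-cusp
   or linear-cubic profile. The zero-force Kramers rate is
   `k₀ = A(ΔG, x_b) · D · e^(−ΔG/k_BT)`, the force-dependent rate follows
   the one-parameter family
   `k(F) = k₀ (1 − νF x_b/ΔG)^{1/ν−1} exp{βΔG[1 − (1 − νF x_b/ΔG)^{1/ν}]}`
   (ν = 1/2 cusp, 2/3 linear-cubic; Bell model as the exponential limit),
   and rupture-force statistics under a loading ramp `Ḟ = κ_s v` come from
   the first-passage construction
   `p(F) = k(F)/Ḟ · exp(−(1/Ḟ)∫₀^F k)`.
2. **Spectrum fitting** (`dfs_fitting`): constrained least squares of the
   mean-force curve (optionally subject to the thermal-stability bound
   `k₀ ≤ 10⁻³ s⁻¹`), the RMSD error surface over `(ΔG, x_b)` with `D`
   profiled out, and a Bayesian grid posterior built from the per-event
   first-passage density under logarithmic or uniform priors.
3. **Rupture events** (`rupture_events`): CSV/XVG pulling-trace parsing,
   rupture detection (highest smoothed force peak, cross-validated
   against the first interface-area drop), loading-rate extraction,
   cumulative dissociation curves, and two-step area-collapse
   segmentation.
4. **Structural observables** (`structural_observables`): 0.6-nm contact
   counts, minimum inter-lobe distance, buried solvent-accessible
   interface area (Shrake–Rupley), inactive/active × bound/unbound state
   labels, and per-residue stress-drop assignment to the two rupture
   steps.
5. **Force-gated signalling** (`mechano_network`): a mass-action
   FAK→Src/SHC/Grb2/SOS→Ras network whose single force-dependent step is
   FAK opening at rate `k(F)`; reports `t₅₀` readouts versus force and
   Michaelis–Menten-like exchange-rate curves in which force sets the
   enzyme concentration.
6. **Synthetic data** (`synthetic_data`): seeded generators for every
   input — rupture spectra drawn from the first-passage law at the
   13-velocity / 83-run pulling campaign, force traces with two-step area
   collapse, stress matrices, and labelled two-domain atom clouds.

## Worked example

```python
import numpy as np
import mechanofak as mf

params = mf.LandscapeParams(deltaG=28.5, x_b=0.86, D=6.6e6)  # kT, nm, nm²/s
print(f"{mf.intrinsic_rate(params, 'bsk'):.2e}")   # 6.43e-04  (1/s)

proto = mf.PullingProtocol.from_kjmol(250.0, 0.05)  # 415 pN/nm at 0.05 nm/ns
mean, sd = mf.mean_rupture_force(params, "bsk", proto)
print(f"{mean:.1f} {sd:.1f}")                       # 226.5 24.1  (pN)

data = mf.sample_rupture_forces(params, "bsk", mf.ProtocolSpec(seed=11))
fit = mf.fit_least_squares(data, "bsk", k0_max=1e-3)
print(f"{fit.rmsd_force:.2f} {fit.params.x_b:.3f} {fit.k0:.2e}")
# 8.48 0.859 1.00e-03
```

The spontaneous opening rate of the fitted landscape sits at the
physiological bound (10⁻³ s⁻¹), the mean rupture force at this pulling
velocity is ~226 pN with a ~24 pN spread, and refitting a synthetic
83-run campaign recovers the curve to ~8.5 pN RMSD with the constraint
active — the barrier distance is then pinned near 0.86 nm. Note the fit
objective has a long degeneracy ridge: many `(ΔG, D)` combinations fit a
mean-force curve equally well (see `error_surface` and the posterior for
the honest uncertainty picture).

Downstream, the force-gated network turns `k(F)` into signalling
kinetics:

```python
curve = mf.force_sweep(params, "bsk", forces=np.array([1.0, 10.0, 100.0]))
# t50(FAK_closed):  883 s   146 s   7.2e-05 s   (accelerates with force)
# t50(Ras_GDP):    1040 s   568 s   405 s       (saturates: enzyme-limited)
```

FAK opening accelerates roughly exponentially with force, while Ras
activation flattens once the assembled exchange enzyme, not FAK opening,
limits the flux — the mechano-enzymatic cap on the cell's force response.

A `mechanofak` command-line interface wraps the same functions
(`mechanofak dfs eval/fit/posterior`, `events detect/collect`,
`obs contacts`, `net sweep`, `synth ...`).

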