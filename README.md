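# eeguq

Uncertainty quantification for EEG single-dipole source localization under
head-tissue conductivity uncertainty.

The conductivities of skin, skull, CSF, gray matter and white matter are the
least certain inputs of any EEG forward model: published measurements span
roughly ±50% for soft tissues and more than a factor of 20 for the skull.
`eeguq` propagates these uncertainties through a complete single-dipole
analysis — forward solutions, goal-function-scan reconstructions, and
sensitivity summaries — so that users can ask: *how much do the reconstructed
position, depth, orientation and strength of a focal source (e.g. the
somatosensory P20/N20 component) move when the conductivities move within
their literature intervals?*  It is aimed at EEG/MEG methods researchers who
want a desk-scale, fully synthetic, reproducible testbed for these questions.

## What it computes

**Forward model.** A concentric multilayer-sphere volume conductor (default
five shells: white matter, gray matter, CSF, skull, skin). The quasi-static
dipole potential is expanded in spherical harmonics; per-degree interface
systems are solved batched over degrees and source positions with adaptive
truncation. The forward model sits behind a pluggable leadfield-provider
contract: anything that maps a conductivity set to a leadfield can replace it.

**Inverse method.** Goal-function scans (GFS). For a measured, average-
referenced topography `u` and the n×3 leadfield block `L(x_i)` of candidate
position `x_i`,

    GoF(x_i) = 1 − (‖u − L(x_i) L(x_i)⁺ u‖₂ / ‖u‖₂)²,

with `L⁺` the Moore–Penrose pseudoinverse. Three variants free successively
more degrees of freedom: *fixed* (strength only), *rotating* (orientation and
strength at a fixed position) and *moving* (the argmax over a source grid).
The source space follows a two-step scheme: a coarse whole-brain scan fixes an
initial estimate, then a fine cubic grid centred on it is masked to the brain
shells with a safety margin below the brain/CSF interface.

**Surrogate.** Re-solving the forward problem for every conductivity draw is
wasteful, so the leadfield is expanded in a generalized polynomial chaos
(gPC): orthonormal Legendre polynomials of total degree ≤ 4 in the rescaled
conductivities ξ ∈ [−1, 1]^d, fitted by pseudo-spectral projection on a
Smolyak sparse Gauss–Legendre grid. The whole experiment plan — five
univariate expansions plus one four-variate expansion (skin, skull, gray
matter, white matter; CSF's interval is too narrow to matter) — needs only
410 exact leadfield computations, after which 10,000-sample Monte Carlo
experiments cost almost nothing.

**Sensitivity.** Because the basis is orthonormal under the uniform prior,
the variance of any output is `Σ_{α≠0} c_α²` and the Sobol index of a
conductivity subset is the normalised sum of squared coefficients whose
multi-index support equals that subset:

    S(i,…,j) = 𝕍(i,…,j) / 𝕍.

Surrogate fidelity is checked with the topography error RDM ∈ [0, 2] and the
magnitude error lnMAG = ln(‖u₁‖/‖u₂‖) against exact forward solutions.

## Worked example

```python
import eeguq as q

# Default synthetic scenario: 5-shell head, 70-electrode cap, ground-truth
# dipole 8 mm below the inner skull, noisy topography at SNR 7.5.
sc = q.prepare_scenario(seed=1)

ref = q.scan_moving(sc.measurement.u_meas, sc.leadfield_standard, sc.shells)
print(ref.gof, ref.depth * 1e3, ref.strength * 1e9)
# 0.8762  8.4  9.5   -> GoF, depth (mm), strength (nAm) at standard conductivities

# Four-variate degree-4 chaos surrogate of the fine-grid leadfield
model = q.build_surrogate(sc, ("skin", "skull", "gm", "wm"), degree=4)
val = q.validate_surrogate(model, sc.exact_gain, sc.prior, n_test=10, seed=17)
print(val.max_rdm, val.max_abs_lnmag)
# 0.0166  0.0183  -> surrogate vs exact forward, 10 random prior draws

# Univariate skull experiment: 2,000 sampled leadfields, three scans each
tab = q.run_univariate("skull", sc, n=2000, seed=100)
print(tab["mov_depth_mm"].min(), tab["mov_depth_mm"].max())
# 4.2  19.1  -> skull conductivity alone moves the source over ~15 mm of depth

rep = q.sensitivity_report(model, sc)
print(rep.iloc[0][["electrode", "voltage_uV", "S_skull", "S_skin"]].to_dict())
# {'electrode': 'E17', 'voltage_uV': 1.421, 'S_skull': 0.639, 'S_skin': 0.236}
```

The numbers mean: with standard literature conductivities the noisy synthetic
topography is explained to GoF 0.88 by a dipole at 8.4 mm depth; varying only
the skull conductivity over its literature interval [1.6, 33] mS/m moves the
reconstructed source between 4 and 19 mm depth (deeper for higher skull
conductivity); and at the most strongly responding electrode, skull
conductivity uncertainty accounts for ~64% of the potential variance, skin
for ~24%.

The same pipeline is scriptable from the shell:

```bash
euq simulate --seed 1 --out out/
euq pce-build --tissues skin,skull,gm,wm --degree 4 --out out/
euq validate --n-test 10 --out out/
euq run --mode univariate:skull --n 10000 --seed 1 --out out/
euq report --out out/
```

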