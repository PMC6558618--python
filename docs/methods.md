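# Methods

## Volume conductor and forward solution

The head is modelled as `K` concentric spherical shells of homogeneous
isotropic conductivity. Default geometry (a conventional adult-head-scale
choice, not derived from any subject): boundaries at 70, 78, 80, 86 and
92 mm for white matter, gray matter, CSF, skull and skin. Standard
conductivities and uniform prior intervals (mS/m):

| tissue | min | max | standard |
|--------|-----|-----|----------|
| skin   | 280.0 | 870.0 | 430.0 |
| skull  | 1.6   | 33.0  | 10.0  |
| CSF    | 1769.6| 1810.4| 1790.0|
| gray matter  | 220.0 | 670.0 | 330.0 |
| white matter | 90.0  | 290.0 | 140.0 |

Soft-tissue intervals are roughly ±50% around the standard value, the skull
interval spans the published measurement extremes, and the CSF interval is a
narrow confidence band around well-replicated measurements — which is why CSF
is retained in the univariate experiments but dropped from the multivariate
one.

The quasi-static potential of a current dipole at radius `b` in shell `s` is
expanded in spherical harmonics. After rotating so the dipole position is the
polar axis, the moment splits into a radial scalar and a tangential vector,
and the two angular channels (`P_n`, `P_n'`) decouple. In each shell the
per-degree radial profile is `a_k (r/r_k)^n + b_k (r_{k-1}/r)^{n+1}`, plus
the free-space dipole field in the source shell. Continuity of potential and
radial current at each interface and zero radial current at the scalp
(insulating air) give a `(2K−1)`-unknown linear system per degree, assembled
with per-shell-normalised basis functions (every entry ≤ 1 in magnitude, so
powers underflow gracefully at high degree) and solved batched over degrees,
source positions and both moment channels.

Truncation: the scalar path adds degree blocks until the latest block
contributes less than `rtol` (default 1e-8) of the accumulated potential
scale, with `N_max = 200`; failure raises an error carrying the achieved
residual. The batched leadfield path fixes the degree from the geometric tail
bound `(b_max/r_scalp)^n` at the most superficial source, plus a safety
margin. Verification: the solver matches the classical homogeneous-sphere
series and the central-dipole closed form to ~1e-15 relative error, and
equal-conductivity multi-shell models collapse onto the homogeneous solution
at the same precision.

All internal quantities are SI (m, S/m, V, A·m); file interfaces use mm (and
tables report mS/m and nAm). Average reference is canonical for all stored
leadfields and measurements, since the goal function is reference-invariant
only when both sides share one reference.

## Source spaces

Grids are cubic lattices with endpoint-inclusive span `extent` per axis
(count `(extent/spacing + 1)³`). Masking retains positions whose radius lies
in an allowed tissue shell (gray or white matter by default) at least
`min_csf_distance` below the brain/CSF boundary; boundary radii belong to the
inner shell so tissue assignment is deterministic. `min_csf_distance`
defaults to 2 mm — motivated by the floor effect that appears when moving
scans pile sources onto the brain/CSF interface — and is configurable.

The analysis uses a two-step construction: a coarse whole-brain lattice
(default 8 mm) scanned with standard conductivities fixes the initial
position, then a fine grid centred there is used for all per-sample scans.
The default fine grid is 12 mm extent at 3 mm spacing (125 lattice nodes,
~119 retained after masking) — a desk-scale choice that keeps the full test
suite in minutes; the finer 30 mm / 1.5 mm configuration (9,261 nodes) is
available by argument.

## Goal-function scans

`GoF = ‖P u‖²/‖u‖²` with `P` the orthogonal projector onto the gain columns;
the pseudoinverse uses an SVD with relative singular-value cutoff 1e-10, so
rank-deficient (near-silent) blocks degrade gracefully instead of crashing a
scan. The vectorised scan path works on the 3×3 Gram matrices via
eigendecomposition with the squared cutoff; a unit test pins it to the SVD
path. Ties in the moving scan (ΔGoF < 1e-12) resolve to the lowest grid
index and are logged. By construction `GoF(fixed) ≤ GoF(rotating) ≤
GoF(moving)` whenever the moving grid contains the fixed position.

Orientation changes are reported in a Gram–Schmidt frame anchored at the
reference reconstruction: e1 = reference orientation, e2 = outward radial
(toward the inner skull — the sphere-model reading of "toward the inner skull
surface"), e3 = toward a configured interhemispheric-fissure direction
(default +y; the sphere has no anatomy, so this must be explicit).
ϑ = arcsin(m̂·e2) > 0 means a more radial dipole; φ = atan2(m̂·e3, m̂·e1) > 0
a tangential rotation toward the fissure. Both angles and the full moment are
reported; no single scalar "orientation change" is defined. Source depth is
the distance to the inner skull surface (the CSF shell's outer radius);
positions exactly on that boundary report depth 0, positions outside raise.

## Chaos surrogate

Uncertain conductivities are independent and uniform on their intervals,
affinely rescaled to ξ ∈ [−1, 1]^d. The surrogate basis is the *orthonormal*
Legendre family `Ψ_α(ξ) = Π_i √(2α_i+1) P_{α_i}(ξ_i)` over all multi-indices
with total degree ≤ 4 (orthonormality makes the variance bookkeeping — and
hence Sobol extraction — a plain sum of squared coefficients). Coefficients
come from pseudo-spectral projection, `c_α = Σ_k w_k f(ξ_k) Ψ_α(ξ_k)`, on a
Smolyak sparse Gauss–Legendre grid with linear growth (level *l* → *l*+1
points) at Smolyak level 4. This rule integrates every monomial of total
degree ≤ 9 exactly (verified by test), which covers all products `Ψ_α Ψ_β`
with `|α|,|β| ≤ 4` — the aliasing-free requirement for degree-4 projection —
so the regularized-regression fallback documented for under-resolved rules is
not needed. Node budget: 5 nodes per univariate expansion, 385 for the
four-variate one; 410 distinct conductivity sets for the whole plan (the
level-5 grid, 953 nodes, would exceed the ≤500 exact-forward budget the
design is built around).

All flattened leadfield entries (electrodes × sources × 3) are fitted
against one shared node set in a single pass. Sampling experiments evaluate
the surrogate in chunks of 500 samples (~100 MB per chunk at the default
geometry) to bound memory.

Surrogate fidelity is validated against the exact solver at random prior
draws using RDM and lnMAG, compared per source position with the three
unit-moment columns stacked into one topography vector. Per-column scoring
is deliberately not used: the near-silent radial-moment columns of deeper
sources turn a tiny absolute discrepancy into a large relative one and say
nothing about reconstructions, which always fit all three columns jointly.
On the default scenario the degree-4 four-variate surrogate reaches max RDM
≈ 0.017 and max |lnMAG| ≈ 0.018 over 10 draws; the error concentrates at the
extreme low end of the skull interval, where the leadfield is most nonlinear
(the degree-4 truncation floor measured along the skull axis alone is
≈ 0.008).

## Sobol indices

From the coefficients: `𝕍 = Σ_{α≠0} c_α²` per output, the conditional
variance of a subset sums `c_α²` over multi-indices whose support equals
exactly that subset, and indices over *all* non-empty subsets sum to 1 for
every output with non-zero variance. Outputs whose variance is pure
quadrature round-off (relative threshold 1e-24) are flagged rather than
divided by. The coefficient route is cross-checked in the tests against an
independent Saltelli pick-freeze Monte Carlo estimator (block-wise standard
errors, 3-SE agreement) both on analytic functions and on the scenario's
electrode potentials.

The per-electrode sensitivity report contracts the leadfield expansion with
the reference source (grid position and fitted moment), yielding a chaos
expansion of each electrode potential; it lists first- and second-order
indices, their residual to 1, and the per-electrode standard deviation
estimated from prior samples of the contracted expansion.

## Synthetic scenario

The generator produces every input the analysis needs:

- **Head**: the default five-shell model with standard conductivities.
- **Electrodes**: 70 channels (a 74-channel cap minus four excluded noisy
  channels) on a Fibonacci spiral over the upper 55% of the sphere; the seed
  only rotates the spiral azimuthally.
- **Truth dipole**: in the gray-matter shell at 8 mm depth below the inner
  skull, oriented 15° off tangential (predominantly tangential with a small
  radial component), 10 nAm — a generic superficial somatosensory-like
  configuration chosen as a scenario default, not a measured fact.
- **Measurement**: average-referenced forward of the truth plus i.i.d.
  Gaussian channel noise. The study SNR of 7.5 is defined as a temporal
  power ratio (component peak over prestimulus power); a single topography
  has no time axis, so the noise variance is set to `mean(signal²)/7.5`
  across channels, preserving the one number the analysis conditions on.
  `snr=inf` returns the noiseless forward bit-exactly.

What the generator does *not* emulate: correlated (spatially structured)
sensor noise, temporal dynamics and filtering artefacts, realistic head
geometry (sulci, skull thickness variation, compact/spongy bone), tissue
anisotropy, and co-registration error. Passing tests therefore demonstrate
the correctness and internal consistency of the uncertainty-propagation
machinery and the *direction* of the conductivity effects in a spherical
conductor — not subject-specific effect magnitudes on real anatomy.

## Experiments and reproducibility

Each experiment draws i.i.d. conductivity samples (10,000 by default; the
acceptance checks use 2,000 to stay desk-scale), evaluates surrogate
leadfields, and runs all three scan variants per sample; one master seed
spawns per-stage child seeds, and identical configuration + seed reproduces
tables bit-identically. Degenerate (zero-width) priors are handled by
fixing the tissue at its standard value and excluding it from the expansion;
a fully degenerate prior reduces to a single exact forward evaluation
replicated across samples (zero-variance tables by construction).

On the default scenario the directional findings are: higher skull
conductivity → deeper sources (Spearman ρ ≈ 0.96, depth range ≈ 4–19 mm over
the skull interval); higher skin conductivity → more superficial sources
(ρ ≈ −0.9); CSF → no depth change at the default grid resolution; fixed-scan
strength rises with skin and falls with skull conductivity; and skull
uncertainty dominates the electrode-potential variance (S_skull ≈ 0.6 at the
most affected electrode), with first- plus second-order indices explaining
>99.9% of it.

## Known limitations

- The sphere model cannot reproduce subject-specific magnitudes; only signs
  and orders of magnitude transfer.
- Degree-4 truncation leaves ~2% worst-case topography error near the lower
  skull-conductivity bound; a higher degree or level would exceed the
  ≤500-forward-evaluation design budget.
- The moving scan is restricted to the fine grid around the initial fit; a
  truth far from it (or reconstructions pushed to the grid boundary by
  extreme conductivities) would clip, as the depth floor/ceiling effects in
  the experiment tables show.
- Uniform independent priors only; no correlated or non-uniform priors, no
  adaptive/anisotropic sparse grids, no MEG.
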