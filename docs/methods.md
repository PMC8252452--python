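# Methods

This note documents the physical and numerical models implemented in
neuropetsim, the defaults that matter, and the boundaries of what the
synthetic studies can and cannot show.

## Geometry and data model

World coordinates are millimetres; voxel indices are 0-based; a volume's
origin is the world position of the center of voxel (0,0,0) and defaults to
centering the grid on the scanner isocenter. Volumes carry a semantic role
(activity, attenuation in cm⁻¹ at 511 keV, Hounsfield units, PET intensity,
label, mask) and operations reject physically meaningless inputs.

A sinogram bin (p, a, r) is the LOR in plane p with azimuth
φ_a = (a + ½)·π/n_angles and signed radial offset s_r, uniform in s (no arc
correction). Planes coincide one-to-one with the z slices of the scanner's
reconstruction grid; 3D ring-pair data can be collapsed onto this grid by
single-slice rebinning (`ssrb`, plane i+j, counts conserved exactly). FORE
rebinning is not implemented; SSRB is the documented stand-in.

## Scanner models

Three tomographs ship as YAML: GE Discovery ST and GE Advance NXi (BGO,
15% energy resolution, 375–650 keV window) and Siemens Biograph mCT (LSO,
12%, 435–650 keV). Their reconstruction grids and voxel sizes follow the
clinical brain protocols (128×128×47 @ 1.95×1.95×3.27 mm, 128×128×35 @
2.05×2.05×4.3 mm, 400×400×148 @ 1.02×1.02×1.50 mm); ring radii, crystal
counts, energy response and sinogram sampling are implementer-chosen
defaults from vendor literature, stored transparently in the YAML files and
user-overridable — they are calibration surfaces, not measured facts.
`rescale_scanner` derives coarser variants preserving the physical FOV
(and keeps the subsets-divide-angles invariant via a gcd).

## Phantoms and initial maps

`generate_brain_phantom` builds a nested-ellipsoid head: scalp soft tissue
⊃ skull bone ⊃ CSF ⊃ gray-matter shell ⊃ white-matter core, with a
sinusoidally modulated gray/white boundary and a central CSF ventricle.
Defaults: gray:white:CSF activity 4:1:0 (the Hoffman-phantom convention),
soft tissue 0.25; attenuation 0.096 cm⁻¹ for water-like tissue and
0.151 cm⁻¹ for bone at 511 keV. Physiological variability is a smoothed
Gaussian random field (FWHM 12 mm default) applied multiplicatively;
spherical lesions multiply activity by a factor. Activity is forced to zero
in air and bone. Everything is deterministic for a fixed seed.

`build_initial_maps` mirrors the refinement loop's initialisation: activity
piecewise-uniform per segmented tissue (CSF zero by default — see the
refinement section for why this matters), attenuation = bone coefficient on
the CT bone mask (HU ≥ 600, inclusive threshold), soft tissue elsewhere
inside the head, zero in air.

## Monte Carlo transport

Decay positions are sampled proportional to activity (inverse-CDF over the
voxel grid, uniform within a voxel). Pair emission is **in-plane**: the
azimuth is uniform in [0, π) and the initial axial direction component is
zero. This 2.5D model matches the direct-plane sinogram the package
reconstructs (the situation after rebinning) and makes the analytic
expectation exact; its cost is that axial sensitivity profiles and oblique
scatter geometry are only approximate. Scattered photons do acquire full 3D
directions.

Free paths use Woodcock (delta) tracking against the grid majorant. The
attenuation map stores 511 keV values; at other energies the map is scaled
by the total Klein-Nishina cross-section ratio plus a photoelectric term
`2·10⁻⁴ · (511/E)³` (water-like branching; bone's higher photoelectric
fraction is not distinguished). Compton angles are sampled from
Klein-Nishina by Kahn's composition-rejection method (validated in-suite
against the differential cross section). Photons below 30 keV are treated
as locally absorbed. Coherent scattering, randoms, TOF, detector blocks,
dead time and crystal discretisation are not modeled; the detector is a
continuous cylinder at the ring radius with a Gaussian energy response
whose variance scales linearly with energy. Non-collinearity is an optional
in-plane Gaussian jitter (0.25° FWHM, on by default); positron range an
optional 3D Gaussian (0.54 mm FWHM, off by default — sub-voxel at ≥ 2 mm
voxels).

Each decay is classified into exactly one of detected / absorbed / escaped
/ window-rejected, so the accounting sums to the decay count. With
`noise='poisson'` the tracked decay count is itself Poisson, which makes
every sinogram bin exactly Poisson (verified by a χ² dispersion test across
seed replicates).

The decay count is `(D₀/λ)(1 − e^{−λT})·branching` (defaults 245 MBq,
1200 s, F-18: half-life 6586.2 s, branching 0.967 → ≈ 2.67·10¹¹ positrons)
times a dimensionless `sensitivity_scale` (default 2·10⁻⁵, i.e. ~5·10⁶
tracked decays), because absolute detector efficiency is not part of the
model; all outputs are in relative units. `n_decays` overrides directly.

`noise_free_projection` is the closed-form expectation of the trues
sinogram: `N · Δφ/π · Δs · FP(A)/(ΣA·vx·vy) · w² / ACF` with w the
single-photon window acceptance at 511 keV. MC trues agree with it bin-wise
within Poisson errors and in total to ~0.1% (in-suite check).

## Projection and reconstruction

The projector is an exact 2D Amanatides–Woo/Siddon traversal per plane
(numba kernels); forward and back projection are exactly adjoint (the
inner-product identity holds to float accuracy and is asserted at 10⁻⁶).
ACFs are `exp(∫ mu dl)` along each LOR with dl in cm.

OSEM uses angle-interleaved subsets, per-subset sensitivity images
BP_S(1/ACF), an optional additive scatter estimate in the denominator, a
nonnegativity-preserving multiplicative update, and an optional Gaussian
post-filter (default 5 mm for the GE models, 3 mm for the mCT) modeling
unresolved detector effects. Defaults are 2 iterations × 21 subsets
(28 for the Advance NXi, whose 336 angles are not divisible by 21);
iteration/subset counts per clinical protocol are not public, so these are
package defaults, overridable everywhere. The exact invariant of the EM
update is the sensitivity-weighted total: Σ_j s_j x_j = Σ_i y_i with
s = BP(1) — the unweighted voxel sum is only preserved when s is constant,
which no real geometry satisfies; the suite asserts the weighted identity
at 10⁻⁶. A reconstruction from an exactly consistent sinogram is a fixed
point of the update (asserted at 10⁻⁸).

## The refinement loop

Starting from `build_initial_maps`, each iteration simulates the current
activity map (analytic noise-free by default — the stable choice; MC
optional), reconstructs with the fixed attenuation map's ACFs, and computes
the whole-head-mask Pearson correlation r with the target. If r ≥ 0.99 the
loop stops; otherwise the activity is multiplied, inside the head mask, by
`clamp(smooth((T + ε)/(R' + ε)))` with 4 mm FWHM smoothing, clamp
[0.2, 5], and ε = 1% of the masked target mean. Two implementation details
beyond the bare multiplicative scheme:

* R' is the reconstruction rescaled to the target's masked mean — the
  loop's relative units otherwise saturate the clamp;
* activity values inside the head are floored at ε-fraction of the mean
  positive activity before multiplying, because zeros are absorbing under a
  multiplicative update and the default initial maps set CSF to zero while
  real targets have nonzero intensity there (spill-in and scatter).

The best-r snapshot is returned, so the reported best-so-far sequence is
non-decreasing. The attenuation map is never updated. The correlation is
Pearson over the whole head support; brain-only or region-weighted variants
are easy to pass as masks but are not the default.

Two properties of the criterion are worth knowing. First, whole-head
r ≥ 0.99 is weak: for a self-consistent noise-free target, the uniform-fill
initial maps already reach r ≈ 0.998 after reconstruction blur, so the loop
can converge without refining; recovery experiments therefore tighten the
threshold to 0.9995. Second, with a noisy low-count target (5·10⁶ decays ≈
2 counts/bin here) OSEM's nonlinear bias lifts cold regions of the target,
and the fitted map's gray/white contrast converges to a compressed value
(≈ 3.4 vs 4.0) even as r crosses 0.99 — consistent with regional
differences surviving image-level convergence. With high-count targets,
gray/white contrast and a 30% hypometabolic lesion's lesion/contralateral
ratio are recovered well within 10% (asserted in-suite). Targets should be
scatter-corrected (as clinical images are); the reproduction study
reconstructs its target with the simulation's own smoothed scatter sinogram
as the additive estimate.

## Comparison statistics

Smoothing is a separable Gaussian in mm (σ = FWHM/√(8 ln 2); 8 mm default).
The voxel-difference statistic e = 2(V_real − V_sim)/(V_real + V_sim) is
bounded in [−2, 2]; results report an 81-bin histogram on [−2, 2] and the
fractions of masked voxels with |e| < 5% and 10%. The default analysis
mask is the brain support (mean image > 10% of its maximum); voxels where
the two images sum to zero are excluded.

Voxel-wise tests are one-sided t maps (paired: df = n−1; two-sample pooled
variance: df = n_A+n_B−2), thresholded at p < 0.01 (Student reference) with
26-connected clusters ≥ k = 300 retained (SPM conventions; both
configurable). Zero-variance voxels get t = 0 and are excluded. FWE
correction is by max-cluster-size permutation (sign flips for paired,
relabelings for two-sample; corrected p = (1+#{null ≥ size})/(1+n_perm)) —
the same error-rate contract as random-field theory without its smoothness
assumptions. The suite calibrates the voxel-wise type-I error at nominal
0.01 over 500 null replicates and the family-wise rate over 200 null
replicates, and verifies that an injected 15% regional effect is detected
as a cluster covering ≥ 80% of the region.

## Problem sizes and limits of the synthetic evidence

The default test/reproduction sizes are chosen as desk-scale study
conditions: a 64×64×31 refinement study at 5·10⁶ tracked decays (the
full-grid scanners are exercised for grid fidelity with 10⁵-decay
simulations and single-iteration reconstructions), 10⁶-decay MC-vs-analytic
comparisons, 20-replicate dispersion checks and 200–500-replicate
statistical calibrations.

The synthetic phantom shares the tissue-class structure, contrast and
attenuation magnitudes of patient-derived maps but not cortical anatomy,
and the simulator omits randoms, detector blocks and inter-crystal effects.
Passing tests therefore demonstrate the internal consistency and calibration
of the pipeline (projector ↔ MC ↔ reconstruction ↔ statistics), and the
refinement loop's behaviour under a correctly specified forward model —
not agreement with any particular scanner's measured data.
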