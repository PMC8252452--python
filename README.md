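# neuropetsim

A self-contained toolkit for generating realistic synthetic brain PET data:
digital head phantoms, Monte Carlo simulation of coincidence acquisitions on
parameterised tomographs, OSEM reconstruction, Brain-VISET-style iterative
refinement of an activity map against a target PET image, and the voxel-wise
statistics used to compare simulated with measured images.

## Who this is for

Quantitative brain-PET methods (SUVR pipelines, dementia/epilepsy
classifiers, harmonisation procedures) need ground-truth images to be
validated against, and physical phantoms are inflexible. The alternative is
simulation: start from a patient-like activity map A(x) and attenuation map
mu(x), simulate the acquisition physics, and reconstruct — the original map
is then an exact ground truth for whatever is measured downstream. This
package implements that workflow end to end in pure scientific Python, at
desk scale, with three commercial scanner models (GE Discovery ST, GE
Advance NXi, Siemens Biograph mCT) shipped as editable YAML.

## The models in brief

* **Acquisition.** Decays are sampled proportional to A(x); annihilation
  photon pairs are tracked through mu(x) by Woodcock delta tracking with
  Klein-Nishina Compton sampling and an E^-3 photoelectric term; photons
  reaching the detector ring receive a Gaussian energy blur and must pass
  the scanner's energy window. Coincidences are histogrammed on a
  (plane, angle φ ∈ [0, π), signed radial offset s) sinogram and tagged
  trues or scatter. Randoms and TOF are not modeled. A closed-form
  noise-free mode returns the exact expectation of the trues sinogram,
  `N · Δφ/π · Δs · FP(A)/(ΣA·vx·vy) · w² / ACF`, where FP is the
  ray-driven line integral, ACF = exp(∫ mu dl) the attenuation factor and
  w the 511 keV window acceptance.
* **Reconstruction.** Standard OSEM over angle-interleaved subsets,
  `x ← x / BP_S(A·1) · BP_S(y / (A·FP_S(x) + s + ε))`, with attenuation
  factors A = 1/ACF, optional additive scatter estimate s, and a Gaussian
  post-filter; one subset reduces to MLEM. The forward/back projector pair
  is exactly adjoint.
* **Refinement (Brain-VISET).** From piecewise-uniform maps filled from a
  tissue segmentation (gray:white:CSF = 4:1:0 by default) and a CT bone
  mask (HU ≥ 600), iterate: simulate → reconstruct → compare to the target
  by whole-head Pearson r → multiply the activity map by a smoothed,
  clamped target/reconstruction ratio — until r ≥ 0.99.
* **Validation statistics.** Voxel-wise relative differences
  `e = 2(V_real − V_sim)/(V_real + V_sim)` ∈ [−2, 2] with threshold
  fractions and histograms, and one-sided voxel-wise t maps (paired or
  two-sample) with 26-connected cluster-extent thresholding (defaults
  p < 0.01, k = 300) and max-statistic permutation FWE correction.

## Worked example

The canned self-consistency study builds a 64×64×31 head phantom with 10%
physiological variability, simulates it on a reduced-grid Discovery ST
model at 5×10⁶ tracked decays, reconstructs the target with attenuation and
scatter correction, and then runs the refinement loop from uniform-fill
initial maps:

```python
import numpy as np
from neuropetsim.workflows import self_consistency_study

study = self_consistency_study(seed=1, n_decays=5_000_000)
h = study.history
print("converged:", h.converged)
print("iterations:", h.n_iterations)
print("r history:", [round(r, 4) for r in h.r_values])
seg = study.segmentation
fa = np.asarray(h.final_activity.data)
gm, wm = seg.mask_for("gray_matter"), seg.mask_for("white_matter")
print(f"refined GM/WM activity ratio: {fa[gm].mean()/fa[wm].mean():.2f}")
```

prints

```
converged: True
iterations: 4
r history: [0.9134, 0.9707, 0.9849, 0.9904]
refined GM/WM activity ratio: 3.45
```

The correlation between the target image and the simulated reconstruction
crosses the 0.99 threshold at the fourth iteration. The refined map's
gray/white ratio (3.45 against the generating 4.03) illustrates a real
property of the method at these counts: low-count OSEM bias in the noisy
target compresses recovered contrast even after the image-space correlation
has converged — with a high-count target the ratio is recovered to within a
few percent (see `tests/test_brainviset.py`).

The same stages are available from the shell
(`neuropetsim phantom|simulate|reconstruct|brainviset|compare|run`), each
with `--seed`, `--log-level` and `--help`.

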