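# Methods

## Problem and model

The package segments co-registered dual-echo neonatal brain MRI — a
PD-weighted and a T2-weighted channel on the same grid — into CSF, gray
matter (GM), white matter (WM) and white matter signal abnormality (WMSA),
and merges in a manually produced map of nine subcortical / posterior-fossa
structures. Each voxel is a point y ∈ ℝ² in (PD, T2) intensity space; the
method is a two-stage classifier in that plane plus spatial regularization:

* **Nonparametric stage (Parzen window).** Per-class kernel density
  p̂_c(x) = (1/n_c) Σᵢ (2π h_c²)⁻¹ exp(−‖x−ξᵢ‖²/2h_c²) over labeled training
  points ξᵢ, tabulated on a regular grid ("feature map"); initial label =
  argmax over {CSF, GM, WM}. A nonparametric start matters because CSF and
  WMSA intensity distributions in newborns are skewed; no Gaussian shape is
  assumed at this stage.
* **Parametric stage (HMRF-EM).** Hidden Markov random field with Gaussian
  class emissions N(y; μ_c, Σ_c) and a Potts pairwise prior: the local
  energy of class c at voxel i is U_i(c) = −log N(y_i; μ_c, Σ_c) +
  β·#{j ∈ N_i : x_j ≠ c}. EM alternates posterior computation (emission ×
  Potts factor from the current labels), closed-form weighted
  mean/covariance/proportion updates, an optional bias-field update, and
  ICM label sweeps. This optimizes the boundaries the Parzen stage drew.

WMSA is *not* classified automatically: its intensity overlaps CSF, so
automated maps consistently call periventricular WMSA "CSF". The pipeline
preserves the human-in-the-loop semantics — a rater-approved correction mask
turns those CSF voxels into WMSA, and `suggest_wmsa_candidates` proposes
interior CSF components near the ventricles for review (a CSF component is
"interior" when it does not touch the brain-mask surface shell).

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| Parzen bandwidth h_c | pooled per-class SD × n^(−1/6) | intensity | 2-D Silverman-type shrinkage; scale-equivariant; overridable per class |
| feature-map grid | 256² bins, samples ± 4·h | intensity² | grid-vs-direct agreement ≥ 99.9%; mass within 1e-3 of 1 enforced |
| tie-break | CSF > GM > WM | — | fixed priority; ties are measure-zero on real data |
| Potts coupling β | 1.0 | — | single-voxel noise removal without eroding the thin cortical ribbon; β = 0 degenerates to an independent Gaussian mixture |
| neighborhood | 8 in-plane neighbors | — | slices are ~5.5× thicker than in-plane voxels, so axial-plane coupling; 3-D 6-neighborhood by config |
| EM stopping | label-change < 1e-4 or 20 iterations; ≤ 5 ICM sweeps/step | — | labels stabilize in a handful of iterations on separable data |
| diffusion | 10 iterations, λ = 0.25, κ = 2 × median abs gradient | intensity | Perona–Malik with exponential conductance; λ at the 2-D stability bound; κ tracks the noise floor |
| normalization landmarks | p1, p10…p90, p99 → [0, 100] | percentile | decile landmarks plus extremes, averaged over training scans; piecewise-linear, monotone |
| surface relabel depth | 2 (configurable 3) | voxels | partial-volume WM at the brain surface relabeled CSF; 2 is the conservative end of the 2–3 voxel range |
| bias smoothing | 25 | mm | Gaussian scale separating anatomy from coil inhomogeneity |
| cov_floor | 0 (off) | intensity² | optional eigenvalue floor; see "Numerical choices" |

## Statistics

Accuracy per class from voxel confusion counts: SI = 2TP/(2TP+FP+FN),
CEI = TP/Ref, OEI = FP/Ref, UEI = FN/Ref with Ref = TP+FN (so CEI+UEI = 1
identically, and SI = 2CEI/(2CEI+OEI+UEI)). Reliability of repeated volume
measurements: within-subject SD is the square root of the one-way ANOVA
residual mean square (equal to sqrt(Σd²/2n) for duplicates); repeatability
is 2.77 × SD, the 95% limit for the difference of two repeats; ICC defaults
to one-way random ICC(1,1) for intra-rater repeats and two-way random
single-measure absolute-agreement ICC(2,1) for inter-rater designs
(McGraw–Wong), both with F-based 95% CIs — the choice is configurable
because ANOVA-based ICC is a family, not a single statistic, and reports
always name the model used. Undefined statistics (empty reference, zero
variance everywhere) are reported as NaN with an explicit marker, never as
0, to avoid silently deflating means.

## The phantom generator

`synthetic.generate_phantom` emulates the axial dual-echo neonatal
acquisition (0.36 × 0.36 mm in-plane, 1.98 mm slices, default 128×128×24
grid) as nested ellipsoids: dark background, extrameningeal "skull" shell,
bright subarachnoid CSF, cortical GM ribbon, WM core with two lateral
ventricles, nine structural blobs at GM-like intensity, and periventricular
WMSA lesions with intensity between WM and CSF (the contrast that makes
WMSA mimic CSF). Default class means in (PD, T2): CSF (180, 200), GM
(130, 120), WM (100, 80), WMSA (150, 170); the closest pair (GM–WM) is 50
units apart, 6.25 × the default additive noise SD of 8 — comfortably inside
the ≥ 5 SD separation regime the recovery checks assume. Partial volume is
modeled by mixing class means with weights from Gaussian-smoothed class
indicators at σ = 0.5 in-plane voxels, i.e. a point-spread function of
≈ 1.2 voxels FWHM — about what a voxel-sized box PSF produces; larger σ
would fabricate a multi-voxel transition band no scanner has. Bias is a
smooth multiplicative field, exp(amplitude × smoothed noise) at 30 mm scale
(or a linear ramp for controlled recovery experiments), amplitude 0.05.
The generator's seed is mandatory and is the only stochastic source in the
package; every downstream stage is deterministic.

What the phantoms do **not** emulate: cortical folding, age-dependent
myelination gradients, Rician noise statistics, motion/k-space artifacts,
and anatomically realistic structure shapes. Passing the recovery checks
therefore demonstrates the correctness of the machinery (classifier,
EM/ICM, post-processing algebra, statistics) under known truth — not
clinical-grade accuracy on real newborn scans, where contrast is poorer and
the manual steps carry real weight.

## Numerical choices

* **ICM** sweeps in raster order (sequential, updates visible within the
  sweep; numba-compiled), so a sweep at a local energy minimum is exactly
  idempotent. Ties in local energy go to the class earliest in the
  CSF > GM > WM priority. The complete-data energy is non-increasing across
  sweeps at fixed parameters.
* **E-step posterior** uses the emission and Potts factors only (no mixing
  proportions): with β = 0 this reduces to Gaussian maximum-likelihood
  classification, the documented degenerate case.
* **Covariance handling**: a class covariance that is singular or has
  condition number > 1e8 gets 1e-6 × max(trace, 1) added to its diagonal
  (with a warning). `cov_floor` optionally floors the eigenvalues: on
  heavily denoised synthetic data a large homogeneous class can collapse to
  near-zero variance, which drags the ML decision boundary onto that class
  and misassigns the whole partial-volume band; the floor is off by default
  so the standard HMRF-EM behaviour (and its GMM equivalence) is untouched.
* **Bias field** is estimated from the smoothed log-residual
  (log intensity − log fitted class mean) per channel, mask-normalized
  smoothing, gauge-fixed to mean gain 1 over the mask. It requires strictly
  positive intensities and is therefore off by default in the pipeline,
  where landmark normalization maps the scale to [0, 100] (values below the
  1st percentile extrapolate below 0). Enable it on raw scanner-scale
  intensities.
* **Degenerate inputs**: a phantom with zero noise yields zero sample
  covariance — handled by the regularization above; a class that empties
  during EM raises `ClassCollapseError` rather than silently reseeding;
  empty brain-mask slices are skipped with a warning during surface relabel.
* **Region growing** is per-axial-slice with 4-connectivity, the threshold
  band propagated to the next slice using the previous slice's grown region
  as seeds, then per-slice hole-filling. On phantoms the apex slices, where
  the CSF ring is entirely partial-volume-mixed with skull, may grow empty —
  the analogue of the occasional manual mask edit on real data, supported as
  a user-supplied mask override.

## Design choices where the design was open

* The Parzen bandwidth rule and the exact Potts potential are this package's
  documented choices (pooled SD × n^(−1/6); β × disagreement count): the
  method family fixes their role but not their form.
* Label codes (0 background, 1 CSF, 2 GM, 3 WM, 4 WMSA, 10–18 structures)
  are this package's convention; left/right structures share one code.
* Structural merging is strictly paste-on (structural codes overwrite
  tissue codes), and the three post-edits are monotone: surface relabel
  only WM→CSF, merge only writes structural codes, WMSA relabel only
  CSF→WMSA — so the edit chain is auditable and conserves in-mask voxel
  count.
* Training samples come from labeled phantoms (or any user-supplied labeled
  scans) rather than a clinical training set; `sample_training_set` draws
  balanced samples from interior (eroded) class regions to avoid teaching
  the classifier partial-volume mixtures.
* Problem sizes in tests and the acceptance script: default 128×128×24
  phantoms (five seeds for the end-to-end check), 300 training samples per
  class — large enough that class statistics are stable, small enough that
  the whole suite runs in well under a minute of compute per check.

## Known limitations

Tissue classification is purely intensity-plus-smoothness; no atlas priors,
so it cannot separate structures with identical intensity (hence the manual
structural map). The WMSA step needs a human-approved mask by design.
Bias correction and normalization interact (see above); applying both
requires care with the intensity scale. ICM finds local energy minima only;
graph-cut or mean-field solvers are out of scope.
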