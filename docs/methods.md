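# Methods

`napvc` simulates and corrects partial volume effects (PVE) in quantitative
sodium (²³Na) MRI of the Achilles tendon. This note records the models, the
numerical choices, and what the synthetic experiments do and do not show.

## The physical problem

Sodium MRI of the Achilles tendon operates at coarse resolution (≈2 mm) and
low SNR because of the low tissue sodium concentration and the fast
biexponential transverse relaxation of the spin-3/2 ²³Na nucleus. Two
distinct partial volume effects corrupt quantification:

* **tissue-fraction effect** — a coarse voxel averages several tissues;
* **spill-over effect** — the point spread function (PSF) of the
  centre-out radial acquisition redistributes signal between voxels. For a
  density-adapted 3D radial (DA-3D-RAD) readout the T2* decay during the
  5 ms readout attenuates high spatial frequencies, so short-T2* tissues
  have long-tailed PSFs with FWHM well above the nominal resolution.

Apparent tissue sodium content (aTSC, mM) is obtained by calibrating the
(sensitivity- and relaxation-corrected) signal against agarose reference
phantoms of known concentration. Because the reference cylinders sit in
air, their *own* uncorrected PVE deficit shrinks the calibration slope and
systematically inflates every tissue concentration — the dominant error
mode of the uncorrected pipeline, and the reason each correction method is
also applied to the references here.

## PSF model (`napvc.psf`)

The k-space trajectory is isotropic, so the PSF is the inverse Fourier
transform of a radial weighting `w(k)` on the sampled ball
`|k| ≤ 1/(2·nominal resolution)`:

```
w(k) = [f_s·exp(−(TE+t(k))/T2s*) + (1−f_s)·exp(−(TE+t(k))/T2l*)] · a(k)
```

with `a(k)` either 1 or the Hanning window `0.5(1+cos πk)` (all corrected
images are reconstructed with a Hanning filter, so the corrections use the
apodized PSF). The time map `t(k)` models a linear-gradient ramp
(`k ∝ t²`) up to `k₀ = ramp_fraction` followed by the density-adapted
regime of constant sampling density (`k ∝ t^(1/3)`); the junction time
`t₀ = 6k₀³T/(1+5k₀³)` makes `t(k)` C1-continuous. This is an explicit
approximation of the gradient design of the real sequence; only the
qualitative long-tail behaviour of the PSF is claimed.

Numerics: the weighting is evaluated on a Cartesian `fft_size³` grid
(default 96³) with a half-voxel linear coverage taper at the ball surface
to suppress surface discretisation noise; the inverse FFT is cropped to a
`(2h+1)³` window (default halfwidth `h = 10` voxels) and renormalised to
unit sum. If the window captures less than 99% of the absolute kernel
mass a `low_coverage` flag is set (this is normal for short-T2* tissues at
halfwidth 10 — roughly 4% of mass lives in the far tails). A finer
`voxel_size` than the nominal resolution yields oversampled kernels for
use on zerofilled grids.

The biexponential amplitude split `f_s` is not part of the tissue table;
the canonical 60/40 split (`f_s = 0.6`) is the package default and is
configurable on `RelaxationTimes`. Fluids (synovial fluid) are
monoexponential: `t2s_star=None` collapses the short component onto
`T2l*`. Mixed voxels use the arithmetic mean of T1, T2l*, T2s* over the
tissue combination, with `T2l*` standing in for the missing short
component of monoexponential tissues.

A genuine non-monotonicity worth knowing about: FWHM as a function of
T2s* *peaks* near 0.7–0.8 ms (at 5 ms readout). Below that, the short
component decays before the readout reaches mid-k-space, so it only adds
a broad low pedestal that no longer widens the main lobe at half maximum.
"Shorter T2s* ⇒ broader PSF" therefore holds for T2s* ≳ 0.8 ms, which
covers all tabulated tissues.

## Synthetic phantom (`napvc.phantom`)

The geometry is parametric (no real segmentation is shipped): the tendon
is an elliptical tube (14 × 6 mm cross-section) running subcutaneously,
in contact with a 3 mm posterior skin shell — as in real anatomy, where
the Achilles tendon lies directly under the skin; the soleus/
gastrocnemius compartment sits anteriorly, the calcaneus (zero sodium)
and the fluid-filled retrocalcaneal bursa at the insertion, two blood
vessels in the deep compartment, fat everywhere else inside the leg.
The tendon is split into three 30 mm sections (INS, MID, MTJ); an
elevated tip (30 mM, first 6 mm of INS) and one hyper- and one
hypo-intense 3 mm spot model regional inhomogeneities that the
segmentation does not know about. Four agarose reference cylinders
(10 mm ⌀, 35 mm, 50/75/100/125 mM) sit behind the coil plane. Default
grid 96³ at 1 mm; a `large` preset recentres the same geometry on 160³.
All shape parameters live in `GeometryConfig`.

The forward corruption chain follows the physical acquisition order:

1. relaxation weighting `(1−exp(−TR/T1))·(f_s·exp(−TE/T2s*)+(1−f_s)·exp(−TE/T2l*))`
   per tissue (90° excitation, TR/TE = 15/0.1 ms);
2. block-mean downsampling to the acquisition grid (tissue-fraction
   effect; 2 mm by default);
3. surface-coil sensitivity `exp(−d/60 mm)` with `d` the distance from
   the coil plane (an analytic stand-in for a measured homogeneous-phantom
   image; results are known to be sensitivity-model dependent);
4. per-voxel-combination PSF convolution (spill-over): voxels are grouped
   by the set of tissues they contain and each group is convolved with the
   PSF of the combination's mean relaxation times (zero-padded
   boundaries — the object is surrounded by air);
5. Rician noise: `sigma = mean(MID signal)/SNR`, magnitude of two
   Gaussian channels; SNR is defined on the MID section because that is
   where the acquisition targets ≈10 (and 5) in vivo;
6. Fourier zerofilling back to the 1 mm grid for the spill-over methods.

## The five corrections

* **PSSR** (`pssr_correct`): region-level tissue-fraction correction,
  `C = S_m − S_sur·(1−v_PS)/v_PS`, with `v_PS` the volume ratio of the
  high-resolution segmentation to its downsized version and `S_sur` the
  mean of the one-voxel 26-connected shell. Downsized ROIs are the voxels
  at least half inside the segmentation, which keeps `v_PS ≤ 1` (values
  above 1 are clamped with a warning). Negative corrected values are
  reported, never clamped.
* **3D-mLTS** (`mlts_correct`): voxel-level least-trimmed-squares
  regression of the 3×3×3 kernel samples on the per-tissue fraction
  vectors; `h = round(0.6·n)` samples with the smallest residuals are
  retained and the fit repeated until the subset is stable (ties broken
  by kernel sample order — deterministic). Kernels are clipped at the
  grid boundary. If the trimmed design cannot resolve its tissues
  (collinear fraction rows), the subset is grown in residual order until
  it can, so gross outliers re-enter last; unresolvable voxels are marked
  invalid. Tissues without samples in the fitting subset get NaN (no
  estimate), not zero.
* **GTM** (`gtm_correct`): `W_ij = mean over mask_i of RSF_j` with
  full-field RSFs (mask convolved with that compartment's PSF); region
  means are recovered by solving `W·T = m`. Exact for piecewise-constant
  images blurred with the compartments' own PSFs. Condition numbers above
  1e8 raise an error suggesting compartment merging.
* **STC** (`stc_correct`): two-compartment iterative correction;
  each step subtracts the cross-spilled signal (current estimate masked,
  convolved, masked to the receiver) and divides by the recovery factor
  `R = Σ m_i·(m_i * PSF_i)`. Negative voxels take their nearest positive
  neighbour's value. Convergence: max over compartment voxels of
  `|Δv|/(|v|+ε)` < 1e-4 with `ε = 1e-6·mean|image|` (a pure machine-eps
  guard never converges on exact-zero bone voxels). The iteration is not
  a contraction near thin-structure edges where `R` is small: on the
  default phantom it settles into a localized period-2 limit cycle — the
  method's known failure mode at coarse resolution. This is detected (a
  state matching the state two iterations back), both states are
  returned, and their mean is used as a labelled convenience value.
* **eSTC** (`estc_correct`): single-sweep variant. Compartment signals
  are first *estimated* by RSF division of the masked image, with the
  overestimated edge voxels repaired by an erode-and-refill operator
  (6-connected erosion, refill from the nearest surviving voxel by
  Euclidean distance); if erosion would empty a small compartment the
  uneroded values are kept and flagged. Each compartment is then
  corrected once, largest to smallest, subtracting all estimated
  spill-in contributions and dividing by its RSF, updating the estimate
  after each correction. Divisions use the mask-restricted RSF with a
  floor of 0.05 (flagged voxels are refilled from the valid interior).
  Negative voxels take their nearest non-negative neighbour. Note the
  operator is one-pass by design but not idempotent: its input model is
  the blurred image, so feeding its output back re-divides by the RSF.

Nearest-neighbour replacements use the scipy Euclidean distance
transform's feature transform; among exactly equidistant candidates its
deterministic scan-order choice decides (not the minimum value).

## Quantification chain (`napvc.quantify`)

The processing order is fixed and pinned by a regression test: partial
volume correction first (PVEs act on the measurable, sensitivity-weighted
signal), then division by the normalised coil sensitivity (voxels below a
0.05 sensitivity floor flagged invalid), then calibration. Reference
means are measured on the full segmentation masks by default — an
uncorrected reference *should* show its PVE deficit; an `erosion` option
measures interiors instead. Reference signals are relaxation-corrected
with the agarose times and fitted by ordinary least squares
(`signal = slope·concentration + intercept`); tissue signals are
relaxation-corrected per tendon section and inverted through the fit.
The combined whole-tendon value uses the average signal and the
voxel-weighted average relaxation times of the entire tendon — this is
deliberately *not* the mean of the three section values. Maps for
region-level methods (PSSR, GTM) scale every ROI voxel by the
corrected/uncorrected mean ratio.

Each method corrects the reference phantoms with its own machinery:
PSSR applies its formula to the downsized reference ROI (nearly a no-op
in air), mLTS uses its fitted reference intensity, GTM carries the four
cylinders as additional compartments, and STC/eSTC use pure recovery
division `r(m·S/RSF)` — their exact zero-signal-surround limit.

## Evaluation (`napvc.evaluate`)

The Monte Carlo harness subtracts the ground truth voxel-wise from each
method's aTSC map (positive = overestimation) over the three sections
and the whole tendon, runs once noise-free (SD across voxels = how well
regional patterns survive) and over seeded noise realisations (SD across
iterations), and reports the RMSE over all tendon voxels. Native-grid
methods (none, PSSR, mLTS) are evaluated by nearest-neighbour upsampling
of their corrected signal to the 1 mm grid; spill-over methods operate
on the zerofilled image directly. Per-iteration seeds derive
deterministically from the base seed; single-method failures are
recorded, not fatal.

Default study conditions: 96³ phantom, 2 mm acquisition, SNR 10 and 5 in
the MID, 20 noise iterations. The full-size historical protocol (100
iterations) is a configuration change, not a code change; 20 iterations
already give across-iteration SDs an order of magnitude below the method
differences being compared. `scripts/acceptance.py` runs the noise-free
pass plus 10 iterations at SNR 10.

## What the synthetic experiments show — and what they do not

The phantom reproduces the *mechanisms*: tissue-fraction mixing,
relaxation-dependent long-tail spill-over, coil-sensitivity gradients,
Rician noise, and reference-phantom self-PVE. On these conditions the
method hierarchy emerges as expected: uncorrected worst (calibration
inflation plus spill), tissue-fraction corrections partial (they cannot
see spill-over, which dominates radial acquisitions), GTM good on means
but biased by the within-region sensitivity gradient and blind to
intra-tendinous inhomogeneity, STC/eSTC best on both means and regional
pattern. The phantom does not reproduce: real anatomy (parametric
shapes), a measured coil profile, B0/B1 effects, motion, or k-space-level
noise; absolute error magnitudes therefore transfer only qualitatively
to in vivo data.

## Known limitations

* STC may not converge (limit cycles) on thin, high-contrast structures;
  the oscillation diagnostics should be inspected.
* eSTC accuracy degrades for compartments so small that erosion empties
  them (the uneroded fallback is used) and for structures thinner than
  the eroded zone.
* The GTM assumes piecewise-constant regions; sensitivity gradients and
  intra-region inhomogeneity violate this and bias its means.
* The trajectory and coil models are deliberate approximations; both are
  isolated behind `SequenceParams`/`GeometryConfig` so they can be
  replaced.
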