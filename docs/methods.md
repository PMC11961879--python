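# Methods

This note documents the models, conventions and numerical choices behind
`mdoseqa`, and what the synthetic-data experiments do and do not show.

## 1. Synthetic phantom cohort

Real prePSQA cohorts pair a planning CT and a TPS dose with a
measurement-reconstructed dose on the same grid; such data is not publicly
available.  The generator (`mdoseqa.phantom_sim`) emulates the *structure*
of that data, not its anatomy:

- **CT.**  An ellipsoidal body (air −1000 HU outside; soft tissue 28–55 HU
  inside with a smooth seeded texture; a 2.5 mm denser skin shell; one
  +700 HU bone cylinder posterior to the target).  Structures are BODY,
  an ellipsoidal PTV strictly inside the body, and small lateral OAR
  ellipsoids.
- **Planned dose (RTDose).**  Deterministic: the prescription inside the
  PTV, a Gaussian falloff `Rx · exp(−d²/2σ²)` with distance `d` to the
  nearest target voxel, plus a low-dose bath (`bath_fraction · Rx`) inside
  the body, zero outside.  With the default bath of 5% the maximum dose is
  1.05 × prescription.
- **Measured dose (MDose).**  The plan transformed by the deviation modes a
  detector-array reconstruction exhibits:

  `MDose = smooth(RTDose) ⊙ (1 + a·G) + A·S + ε`,

  where `smooth` is a Gaussian of width `smooth_sigma` (detector
  resolution / reconstruction blur), `G` is a seeded smooth random field
  with unit maximum amplitude and correlation length `calib_length_scale`
  (low-frequency calibration drift), `S` marks the tissue shell within
  `boundary_shell` of the body surface (the skin/immobilization-mask region
  where reconstructed doses are least trustworthy), and `ε` is voxel noise
  truncated at ±3σ.  The result is clipped at 0 Gy.

Defaults (chosen once as a plausible clinical deviation scale, in Gy/mm):
`smooth_sigma = 3`, `calib_amplitude = 0.02`, `calib_length_scale = 30`,
`boundary_amplitude = 3`, `boundary_shell = 6`, `noise_sigma = 0.5`.
A 2% drift of a 70 Gy prescription and a 3 Gy boundary artifact keep
plan-to-measurement deviations within a few Gy except near the skin, which
matches the qualitative behavior of measurement-guided reconstructions.
The default grid is 64×64×32 at 3 mm isotropic so that cohorts are
CPU-tractable; clinical-resolution grids (e.g. 512×512×150) are a
configuration choice, not a code change.

Cohorts jitter body/target geometry per case (relative half-ranges in
`CohortRanges`) and derive per-case seeds from one cohort seed via
`SeedSequence.spawn`, so every generator output is a pure function of
`(spec, seed)`.

**What passing tests on this cohort show** — that the pipeline is correct
(geometry, resampling, gamma/DVH arithmetic) and that the network can learn
a systematic, anatomy-linked plan→measurement mapping from volumetric
inputs.  **What they do not show** — performance on real patients: the
phantoms have no realistic anatomy, no MLC/arc delivery physics, and a
deviation model far simpler than a real detector chain.

## 2. Network family

All variants share a 3D SE-residual encoder-decoder backbone
(`mdoseqa.fusion_net`):

- building block `x + SE(Conv(ReLU(InstanceNorm(Conv(x)))))` with
  squeeze-and-excitation channel gating (reduction 4, sigmoid gate);
- downsampling by stride-2 convolution, upsampling by voxel-center-aligned
  trilinear interpolation (×2); kernels 3×3×3; channel widths
  `base_channels · 2^level`;
- instance normalization, because training runs at batch size one where
  batch statistics are degenerate.

The **baseline** concatenates CT and RTDose as a 2-channel input to one
encoder (3D ResUNet).  The fusion variants give each modality its own
encoder and couple them at every level:

- **CPF/CCF (concatenation):** `f̃ = Conv(Concat(f_CT, f_RT))`, per-branch
  transforms `f̃_b = Conv_b(f̃)`, added back to the same branch (parallel)
  or the opposite one (cross).  These convolutions are deliberately plain
  (no norm/activation), so zeroed parameters give an exact identity — the
  algebraic anchor used throughout the tests.
- **SPF/SCF (squeezed):** the concatenated features are pooled to a channel
  descriptor, two independent FC heads produce sigmoid gates
  `w_b ∈ (0,1)^C`, and `w_b ⊗ f_b` is added back parallel or crossed.
  Zeroed FC parameters give the closed-form 0.5-gate maps.

One fusion family is used at every level.  The shared decoder follows
`F_i = Conv(Concat(Up(F_{i+1}), Conv(Concat(f̄_CT, f̄_RT))))`, with a
norm/ReLU/SE-residual refinement per level (the refinement carries the
decoder's nonlinearity; the fusion equation itself stays linear and
hand-checkable).

**Normalization.**  CT is clipped to [−1000, 1500] HU and mapped to [0,1];
doses are divided by the per-case prescription (a fixed divisor is a config
option).  Predictions are de-normalized and clipped at 0 Gy.  Inputs with
dims not divisible by `2^(levels−1)` are zero-padded (in normalized space)
and cropped back.

**Residual head.**  The final 1×1×1 convolution predicts a *correction to
the plan* (`output = RTDose + head(F_1)`), with the head weights initialized
to zero so the untrained network is exactly the identity on the plan.  A
desk-scale model trained for a handful of epochs cannot reach sub-percent
absolute-dose accuracy from a cold start, but the plan is already an
excellent first approximation of the measurement; learning the deviation
instead makes the training signal purely the systematic plan→measurement
structure.  `ModelConfig(residual_head=False)` restores absolute-dose
prediction.

**Training** (`mdoseqa.estimator.MDoseRegressor`): L1 (mean absolute voxel
error) loss, RMSprop (α 0.99, ε 1e-8), batch size one, early stopping on
validation L1 with best-weights restore; the pre-training validation loss
anchors the early stopping so the fitted model never ends worse on
validation than its initial state.  The clinical-scale recipe (lr 5e-5, up
to 200 epochs) is the `TrainConfig` default; desk-scale runs (tiny models,
tiny cohorts) use lr 1e-3 and a few epochs, which the loss curves show is
enough for the deviation structure the phantoms contain.  Cohorts are split
60/20/20 with `round(n·f)` for validation/test and the remainder to train
(310 → 186/62/62); the shuffle is seeded.

The network runs on `mdoseqa.nn`, a minimal numpy reverse-mode autodiff
core purpose-built for this architecture (conv3d via im2col + BLAS,
instance norm, trilinear up/down adjoint pair, FC/gating ops).  Every
operation's gradient is verified against central finite differences in the
test suite; training is single-threaded-deterministic for a fixed seed.

## 3. Gamma analysis

`γ(r) = min_{r'} sqrt(‖r−r'‖²/Δd² + (D_eval(r') − D_ref(r))²/ΔD²)` with
defaults 3%/3 mm, global normalization (ΔD = 3% of the reference maximum;
local mode available), 10% low-dose threshold computed on the reference
volume only, and pass at GPR ≥ 90%.  Implementation choices:

- search radius 3×Δd; candidate points on a `1/subdivision` voxel grid
  (default 3) with trilinear dose interpolation; offsets are visited
  nearest-first with early termination once the pure distance term exceeds
  every running minimum;
- candidates outside the evaluated grid are skipped; γ at sub-threshold
  voxels is NaN and excluded from the GPR;
- γ = 1 exactly counts as a pass (boundary inclusive) — a convention, made
  explicit because the definition does not fix it.

At subdivision 1 the engine is exact (≤1e-9) against an exhaustive
brute-force search, which the tests and the acceptance script verify on
random dose pairs.

## 4. DVH conventions

Whole-voxel membership ("in or out" by voxel center).  Dx is computed
bin-free on raw voxel doses with the nearest-rank convention — the largest
dose d such that at least x% of voxels receive ≥ d — so D100 is the
minimum voxel dose and Dx→0⁺ the maximum; Vx uses an inclusive threshold
at x% of the prescription.  Curves default to 0.05 Gy bins; curve reads
agree with bin-free values to within one bin.  Reports give targets
(names starting `PTV`) the full metric set (Dmean, Dmax, D2, D50, D98,
V95, V100) and OARs Dmean/Dmax/D50; structure names are matched
case-insensitively.

## 5. Similarity metrics

MAE and RMSE in Gy over the full volume (masked variants are a caller-side
mask away).  PSNR uses the reference maximum as peak (dose has no canonical
dynamic range) and reports `inf` on a perfect match.  SSIM uses 7×7×7
uniform windows with stabilizers `(0.01·L)²`, `(0.03·L)²`,
`L = max(gt) − min(gt)`, averaged over full (interior) windows; UQI is the
zero-stabilizer case on 8×8×8 windows, with degenerate (zero-denominator)
windows dropped from the average.  Note that UQI's product form gives
`Q(x, −x) = +1` — anti-correlation only drives UQI negative about a shared
non-zero mean; the tests assert the covariance-sign behavior in that form.
MAE ≤ RMSE always (Jensen); SSIM/UQI/PSNR are reference-directional, MAE
and RMSE symmetric.

## 6. Volume I/O

Internal convention: `(z, y, x)` arrays, spacing/origin in mm,
voxel-center origins, axis-aligned geometry only (oblique volumes are
rejected — axial CT with identity direction cosines is the norm for this
application and keeps resampling exactly testable).  DICOM CT series are
sorted by z with slope/intercept applied and gaps/mixed series rejected;
RTDOSE honors DoseGridScaling and GridFrameOffsetVector; RTSTRUCT contours
are rasterized by point-in-polygon tests on voxel centers, unioning
multiple contours per slice and assigning off-plane contours to the
nearest slice with a warning.  Dose-to-CT resampling is trilinear with
zero padding outside the source extent (monotone, no overshoot).  NRRD is
the portable format for synthetic data.

## 7. Problem sizes

The test suite and the acceptance script run desk-scale configurations:
phantoms of 16×32×32 (unit tests) and 64×64×32 (end-to-end study), cohorts
of 6–30 cases, SPF models with `levels=3, base_channels=4` (~90k
parameters) trained ≤5 epochs, and gamma at subdivision 1 for cohort-level
evaluation.  These sizes were chosen so the full study reruns in minutes
on one CPU while still exercising every code path at realistic geometry
ratios; all of them scale up by configuration only.

## 8. Known limitations

- The phantom deviation model is stationary and additive; real
  measurement-guided reconstructions have angle-dependent and
  plan-complexity-dependent errors the generator does not emulate.
- The calibration drift field `G` is unpredictable from the inputs by
  construction, so it bounds the achievable prediction error from below
  (together with the noise floor).
- Only axis-aligned geometry; no RTPLAN parsing, no deformable
  registration, no biological indices (EUD/NTCP/TCP).
- The gamma engine interpolates the evaluated dose on a fixed refinement
  grid rather than solving the exact point-to-surface distance; at
  subdivision 3 the residual discretization error is well below the
  criterion scale for dose grids at 2–3 mm spacing.
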