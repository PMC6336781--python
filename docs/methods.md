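# Methods

This note documents the models and procedures implemented in `restmvpa`,
the parameters that matter, the numerical conventions, and the design
choices made where the design was genuinely open. Nothing stated here is an
empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## 1. Synthetic cohort model

The generator (`synthgen`) emulates a two-group resting-state study: two
groups of `n_per_group` subjects (default 20; 54 restores the emulated
study's scale), each with a 4D BOLD run of `n_volumes` = 200 volumes at
TR = 2 s on a 24^3 grid of 3-mm isotropic voxels.

**Head phantom.** The brain is an ellipsoid (semi-axes 0.45x each grid
dimension) partitioned by normalized ellipsoidal radius rho into CSF
(rho <= 0.20), white matter (0.20 < rho <= 0.55) and a gray-matter rind
(0.55 < rho <= 1). The three compartments tile the brain exactly, which the
nuisance-regression and FCS stages rely on.

**Baseline signal.** Voxel noise is white or AR(1) Gaussian
(default rho = 0.3 — mild temporal autocorrelation typical of BOLD without
dominating the 0.01–0.08 Hz band; innovations are scaled so the stationary
SD equals `global_noise_sd`, default 1). Two shared nuisance sources
(band-limited 0.005–0.05 Hz, unit SD) are injected at full strength into
CSF and WM respectively and at 0.3x into gray matter, giving the CSF/WM
mean-signal regressors something real to remove.

**Group effects.** All regional signals are built by ideal-filtering white
noise to 0.01–0.08 Hz in the frequency domain and rescaling to unit sample
SD; this makes injected amplitude ratios exact by construction, so
recovery properties have analytic targets. Three families:

- *amplitude*: every sphere voxel receives an independent in-band signal
  of SD `base_amplitude` x noise SD (default 1x); the target group's SD is
  multiplied by `effect_size`. `effect_size` = 1 is an exact null.
- *coherence*: one shared in-band signal is added to all sphere voxels of
  the target group, with coefficient sigma*sqrt(s/(1-s)) so it carries a
  fraction `s = effect_size` of voxel variance; the expected pairwise
  correlation inside the sphere is then ~s. `effect_size` = 0 is a null.
- *hub*: as coherence, but the shared signal also drives partner spheres
  (default: the point-reflection of the center through the grid midpoint
  and an axis mirror), raising suprathreshold degree centrality.

**Motion.** Traces are a smooth random drift, globally rescaled so no
drift-only transition reaches the 0.2 mm framewise-displacement threshold,
plus a Poisson number (`motion_spike_rate`, default 1 per run) of sustained
repositioning steps of 0.25–0.6 mm on one translation axis. A sustained
step produces exactly one supra-threshold FD transition, hence ~4 flagged
volumes per spike (one back, the spike, two forward) before overlap and
boundary clipping. Motion is bookkeeping only — the images are generated
aligned; realignment estimation is out of scope.

**Covariates.** Age, illness duration and symptom scores are truncated
normals matched to the emulated study's group means/SDs; sex follows its
34/20 male/female split deterministically. These support the
correlation arm without claiming clinical realism.

**What the generator does not model** — hemodynamic response convolution,
cardiac/respiratory physiological noise, scanner drift/spike artifacts,
spatial inhomogeneity of noise, and between-subject anatomical
variability. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration on signals with known structure, not
performance on real BOLD data.

## 2. Denoising chain

Per subject, in order (`preproc`):

1. discard the first 10 volumes (jointly from BOLD and motion);
2. FD(t) = sum |delta translations| + 50 mm x sum |delta rotations|, FD(0) = 0;
3. flag FD > 0.2 mm volumes plus 1 back / 2 forward neighbors (clipped at
   run boundaries), one 0/1 indicator regressor per flagged volume;
4. regress ONE combined design: Friston-24 motion block (6 parameters,
   their one-back copies with a zero-padded first row, and the 12 squares),
   the spike block, CSF and WM mean signals, a linear trend, and an
   intercept;
5. ideal (brick-wall) FFT band-pass, 0.01 <= f <= 0.08 Hz inclusive, DC
   removed.

Choices worth recording:

- *Single pre-filter regression.* Running motion/spike regression and
  tissue regression as one design before filtering avoids double-regression
  artifacts and reintroduction of removed variance; it nests the
  alternative orderings a serial narrative might suggest.
- *No global-signal regression* — FCS rests on signed correlations that
  global-signal removal would recenter.
- *Ideal FFT filter* — bounds inclusive on discrete bins k/(N*TR); bit-exact
  reproducible contract, no filter-design parameters; idempotent.
- *Design conditioning* — columns are scaled to unit norm before the rank
  check and solve (mm, rad and squared-rad regressors differ by orders of
  magnitude; the projection is unchanged). Exact-duplicate and all-zero
  columns are pruned; a genuinely rank-deficient design is an error naming
  the collinear columns. Spike indicators force residuals at flagged
  volumes to exactly zero (an OLS identity the tests assert).

## 3. Parameter maps

- **ALFF / fALFF** consume the *regressed but unfiltered* residuals, with
  the band applied inside the spectral sums. Computing them after
  band-passing would be circular: every out-of-band bin would already be
  zero and the fALFF denominator ("total power across all frequencies")
  degenerate. Amplitude(k) = sqrt(|X(k)|^2 * 2/N), DC excluded; ALFF is the
  *mean* in-band amplitude (the within-brain-mean normalization cancels the
  mean-vs-sum constant, recorded for bit-exactness); fALFF is the in-band /
  all-bin amplitude ratio, 0 where the denominator vanishes.
- **ReHo** consumes the band-passed series. Kendall's W of each voxel with
  its in-mask, in-grid neighbors (up to 26; edge and mask-boundary voxels
  use whatever neighbors exist, keeping map support equal to the mask;
  fewer than 2 usable series gives 0). W uses no tie-correction factor;
  the vectorized map ranks by double argsort (ordinal), since exact ties
  are measure-zero for continuous filtered data, while the scalar
  `kendalls_w` uses average ranks per its contract.
- **FCS** consumes the band-passed series over gray-matter voxels:
  FCS(i) = sum of atanh(r_ij) over j != i with r_ij > 0.2 (positive tail
  only; r clipped at 1 - 1e-7 to keep the Fisher transform finite;
  zero-variance voxels get 0 and never count as partners). The z-scoring is
  within the GM mask (the correlation matrix is GM-only).
- **Normalization chains**: alff/falff/reho are divided by their in-mask
  mean then smoothed; fcs is smoothed then z-scored (population-SD
  convention). Smoothing is a separable Gaussian,
  sigma = FWHM/(2 sqrt(2 ln 2)) (8 mm FWHM / 3 mm voxels -> sigma ~ 1.133
  voxels), applied to the full grid with zero padding then re-masked —
  the common SPM-style dialect rather than mask-constrained smoothing.

## 4. Univariate arm

Voxelwise pooled-variance two-sample t (df = n1 + n2 - 2), two-sided p,
Benjamini–Hochberg step-up at q = 0.05 applied separately per map kind
(four families, matching per-parameter reporting). Voxels with zero pooled
variance get t = 0, p = 1. FDR is controlled at the voxel level; cluster-
extent inference is out of scope. Demographic tables use summary-statistic
t-tests (Welch default; pooled gives the same rounded p on the reference
age row) and Pearson chi-square without continuity correction. Symptom
correlations are partial Pearson correlations (both variables residualized
on covariates + intercept; t-based p with df = n - k - 2; sex encoded 0/1),
Bonferroni-corrected over all tested region x score pairs by default.

## 5. MVPA arm

Features are the smoothed, normalized maps of one kind, one row per
subject, labels +1 patient / -1 control. The Gram matrix is plain inner
products — no centering or kernel normalization — computed once and
sub-indexed per fold. The SVM is the soft-margin dual on the precomputed
kernel (scikit-learn's SVC; C = 1 by default, exposed in config). The
"feature selection on the training set" step is the identity: the
classifier is whole-brain by design, with no dimensionality reduction.

- *Leave-one-pair-out CV*: the i-th patient is paired with the i-th
  control in table order (results are invariant to pairing under
  exchangeability; an explicit pairing can be supplied). Each fold trains
  on 2(n-1) subjects and predicts the held-out pair, so every subject is
  predicted exactly once.
- *Metrics*: sensitivity = correct fraction among patients, specificity
  among controls; accuracy satisfies
  acc = (sens * n_pat + spec * n_ctrl)/(n_pat + n_ctrl), asserted on every
  report. AUC is Mann–Whitney over pooled held-out decision values (ties
  count 1/2) and is invariant under strictly increasing transforms of the
  decision values.
- *Permutation test*: the full LOOCV is rerun per permuted labeling;
  p = (1 + b)/(1 + m) (add-one estimator, never exactly 0). The default
  statistic is accuracy; `statistic="joint"` counts permutations with both
  sensitivity and specificity >= observed. Seeded, bit-reproducible.
- *Discrimination map*: w = sum alpha_i y_i x_i from the model trained on
  ALL subjects (a single "most discriminating pattern"; fold-averaged maps
  would dilute it), positive = patient-direction; the display threshold
  retains |w| strictly greater than 0.30 x max |w|.

## 6. Orchestration and reproducibility

`run_all` executes simulate -> preprocess -> maps -> univariate -> mvpa
from one config whose defaults are the pipeline's canonical constants
(0.01–0.08 Hz, 0.2 mm FD, 8 mm FWHM, r = 0.2, C = 1, 1000 permutations,
30% threshold, q = 0.05). A single run seed fans out to per-stage
substreams keyed by stage name (`stage_seed`), so toggling one stage never
perturbs another's draws; identical config + seed reproduces every numeric
output byte-for-byte (wall-clock timings go to a separate log). The report
records a config hash and SHA-256 digests of the per-kind feature matrices
and weight maps, sufficient to audit any reported number.

## 7. Problem sizes used in the checks

The automated checks run at desk scale, chosen so the full suite completes
in minutes while keeping every statistical band meaningful: unit tests use
10–12^3 grids with 40–80 volumes; the calibration and recovery suites use
the default 20+20-subject cohorts on 24^3 grids with 200 volumes (50
replicates for the null-classification band, 200 true-null replicates at
99 permutations for the permutation-p calibration, 500 replicates of
5000-voxel uniform-null maps for FDR control); `scripts/acceptance.py`
uses one 20+20 effect cohort, one matching null cohort, and 199
permutations. The emulated study's 54+54 scale remains a config choice.

## 8. Known limitations

- The generator's spatial structure (nested ellipsoids, spherical effects)
  is deliberately schematic; anatomical realism is a non-goal.
- Amplitude effects interact with mean normalization: scaling a sphere up
  shifts the within-brain mean, inducing a small opposite-signed global
  offset elsewhere in normalized maps. This is a real property of
  mean-scaled ALFF analysis, and the recovery checks therefore score the
  *patient-direction* significant cluster against the injected sphere.
- With strong injected effects several map kinds can saturate at 100%
  held-out accuracy, so the four-kind ranking is only meaningfully ordered
  near the discrimination boundary.
- Permutation p-values at m permutations are bounded below by 1/(m+1).
- ReHo's ordinal-rank shortcut differs from average ranks only on exact
  ties (measure-zero for continuous data, but relevant if integer-quantized
  data were fed in).
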