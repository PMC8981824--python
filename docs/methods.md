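# Methods

This note documents the generative model, the analysis conventions, the
numerical choices that were genuinely open, and what the validation
experiments do and do not establish.

## 1. The synthetic world

### Signal model

A recording is `v(t) = a(t)·T_L(t) + ε(t)`, channels × samples, in µV
(an arbitrary 10 µV scale; every analysis stage is scale-free).

* **Templates `T_k`** (classes A–D): each is the difference of two
  isotropic Gaussian bumps (σ = 0.6 head radii) evaluated at the
  electrode positions, then average-referenced and unit-normed. A is a
  left-posterior/right-frontal diagonal dipole, B its mirror image, C an
  occipital–frontal dipole, D a fronto-central maximum whose negative
  bump sits far behind the head rim so it reads as a faint posterior
  ring. The D construction matters: placing D's counter-pole on the
  scalp makes D nearly the sign-flip of C (|spatial correlation| ≈ 0.9),
  and a polarity-invariant analysis then cannot separate the two classes.
  With the final geometry the largest pairwise |correlation| is 0.57
  (C–A/B), comparable to real canonical maps.
* **Montage**: an idealized 64-channel extended 10-20 layout generated
  from the standard ring/arc construction on the unit disk. Only the
  left/right symmetry and rough geometry matter (they shape the
  templates); no claim is made about real cap coordinates.
* **Label process `L(t)`**: a semi-Markov chain. Segment classes follow
  an embedded zero-diagonal row-stochastic matrix; the first segment is
  drawn from its stationary distribution; segment lengths are gamma with
  shape 2 and the class's planted mean (rounded to ≥ 1 sample). Shape 2
  (CV = 0.71) gives a realistic 20–150 ms spread around 60–120 ms means
  while keeping the mean planted exactly; the true run-length law of
  human microstates is unknown, so this is a modeling choice, not an
  empirical claim.
* **Carrier `a(t)`**: a signed 10 Hz sinusoid, phase-continuous across
  segments, scaled so the GFP waveform `|a(t)|` has unit mean; GFP peaks
  therefore recur every 50 ms, as in eyes-closed alpha-dominated EEG.
  A *rectified* carrier would have identical GFP and identical labels
  under the polarity-invariant analysis, but its spectral energy sits at
  DC/20/40 Hz, and the 2 Hz high-pass edge of the analysis band then
  smears each segment's quasi-DC topography across its neighbours
  (measured: noise-free backfit agreement collapses from 1.0 to 0.56).
  The signed carrier keeps the signal inside the analysis band; this is
  the package's deliberate deviation from the more obvious "rectified
  envelope" construction.
* **Noise**: spatially white Gaussian, average-referenced, scaled so
  mean signal GFP / mean noise GFP = `snr` (default 5). White noise is
  the simplest null; real EEG background is spatially and temporally
  correlated and would change the error structure at GFP troughs, but
  not the identities and recovery logic the tests exercise.

### Planted group parameters

The generator is parameterized from the published MwoA/HC group tables:
per-class mean durations, and an embedded chain equal to the published
12-cell transition table row-normalized, with segment weights fixed at
its stationary distribution. Coverage and occurrence are then *emergent*:
`coverage_k ∝ w_k·d_k` and `occurrence_k = w_k / Σ_j w_j d_j`. These
land within ~3% of the published per-class values, which is an internal
consistency check of the published tables rather than a fit. One wrinkle
is documented: the published 12 transition cells sum to ≈ 96, not 100,
so the stationary flow of the row-normalized chain predicts a D→B cell
of ≈ 9.50 rather than the printed 9.14; the pipeline's recovered value
(≈ 9.3) sits between the two because residual label noise pulls cells
toward uniformity. Nothing was rescaled toward the printed cells.

### Clinical model

Patients receive a per-subject class-C mean duration jittered by
N(0, 8.70² ms²) around the group value, and a HIT-6 score from the
conditional Gaussian giving population correlation ρ = −0.27 with that
jitter (mean 65.85, SD 6.91). Controls get independent scores. Sex and
age are filled from the published demographics.

## 2. Analysis conventions

* **Preprocessing**: zero-phase IIR filters (4th-order Butterworth
  band-pass; 2nd-order notch, Q = 30). The acquisition chain
  (0.5–70 Hz + 50 Hz notch, downsample to 500 Hz) is applied only to
  recordings above the 500 Hz target rate. Epochs are the first N
  contiguous 2 s windows (N = 60), common-average referenced per sample.
  Artifact handling is a pass-through hook (synthetic data are clean);
  an amplitude-threshold epoch flag exists but is disabled by default.
* **Segmentation**: GFP peaks are strict local maxima per epoch with a
  10 ms minimum separation (higher peak wins, earlier on ties). The
  modified K-means uses squared spatial correlation for assignment and
  the dominant eigenvector of the members' outer-product sum for the
  update — computed on the *unnormalized* mean-removed topographies, so
  each iteration is monotone in GEV; 50 restarts seeded from distinct
  peak topographies, tolerance 1e-8 on the relative GEV change.
* **Group aggregation** maximizes common variance across subjects
  (permutation + polarity search per subject, eigenvector slot maps),
  restarted from every subject's own maps because a single
  initialization can stall in a local alignment optimum. Maps are then
  labeled A–D by the best of the 4! assignments against the canonical
  templates (total |correlation|, lexicographic tie-break) and
  sign-aligned to them.
* **Back-fitting** assigns every sample of the **broadband**
  average-referenced epochs to `argmax_k |r(v(t), m_k)|`. The 2–20 Hz
  band is used only to select clean topographies for clustering; it is
  *not* in the back-fitting path, because an 18 Hz-wide filter has an
  impulse response (≳ 55 ms) commensurate with a microstate segment, and
  filtering the back-fitting input measurably fragments the label series
  at GFP troughs (occurrence triples; no absorption threshold repairs it
  without absorbing a quarter of the true segments). This is a
  time-bandwidth constraint of the segment model, not an implementation
  artifact.
* **Resolvability floor**: single-sample runs are absorbed into the
  better-correlated flanking class inside `backfit`. One-sample
  microstates are below the temporal resolution of the analysis (the
  generator itself refuses dynamics finer than two samples) and arise
  only at GFP troughs, where the instantaneous field is noise-dominated
  and polarity-invariant correlation is unidentifiable. The ms-scale
  `smooth_labels` operation (plugin-style short-segment rejection) is
  separate and **off by default**: with gamma-shape-2 segment lengths a
  30 ms rejection would absorb ~26% of true segments and bias durations
  upward by ~20%.
* **Parameters**: runs never span epoch boundaries; boundary-truncated
  runs are *included* by default, which keeps the identity
  `occurrence × duration = coverage` exact (an exclusion flag exists).
  Transitions are counted between consecutive runs within epochs and all
  12 ordered cells are normalized jointly to 100 (the convention
  consistent with the published tables).
* **Statistics**: mixed ANOVA F/p via pingouin's standard decomposition;
  the Greenhouse–Geisser ε is recomputed from the pooled (group-
  centered) within-subject covariance and the GG-corrected p is always
  reported alongside a Mauchly gate at α = 0.05. All t-tests are
  pooled-variance and two-sided (the published df = N−2 identifies the
  pooled test); the 2×2 chi-square uses Yates correction (identified by
  reproducing the published 0.41; the uncorrected value would be 0.73).
  TANOVA L2-normalizes each subject's maps; the group statistic is the
  GFP of the difference of group grand-mean (class-averaged) maps, the
  interaction statistic the class-mean GFP of class-wise group
  differences after removing the group effect; the null permutes
  subjects between groups, `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`.

## 3. Known biases and what green tests establish

On planted cohorts at snr 5 the pipeline recovers mean durations with a
systematic −2 to −4% bias (two sources: boundary-truncated runs, −1.6%;
residual trough mislabels splitting occasional runs) and occurrence with
the mirror-image +2 to +4% bias; coverage and syntax are nearly unbiased.
The validation therefore establishes that the machinery is correct and
calibrated to a few percent under the stated world — clean, stationary,
four-class data with a single coherent carrier. It does not establish
performance on real EEG (artifacts, non-stationarity, violated k = 4,
broadband background activity), nor does it validate the published
between-group *differences*, which would require the original recordings.

Two further properties of the synthetic cohort show up in the full-size
analysis drivers and should not be over-read:

* **Inflated F statistics.** The generator plants between-subject
  variability only in the patients' class-C duration (plus estimation
  noise elsewhere), so group contrasts in the driver output are far more
  significant than any real cohort's — the drivers demonstrate the
  statistical battery, they do not reproduce printed F values.
* **TANOVA sensitivity to planted dynamics.** Both groups share the same
  four templates, yet the between-group TANOVA reaches its permutation
  floor at n = 61 + 66: the groups' different class prevalences leak
  microscopically into per-subject map *estimates* (difference-map GFP
  < 1% of map norm), and a randomization test with 127 subjects detects
  it. The type-I calibration test (iid null maps) confirms the test
  itself is exact; the rejection reflects a real, tiny property of the
  stated world.

## 4. Degenerate inputs and edge rules

Zero-variance samples inherit the previous label (leading ones take
class A). An absent class reports NaN duration and zero occurrence/
coverage. Monotone GFP (no peaks) raises. Empty clusters during K-means
are reseeded with the worst-explained topography. Permutation p-values
are floored at `1/(n_perm+1)`. Gamma segment draws are floored at one
sample; sampling rates that cannot resolve the shortest planted class
raise at generation time.
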