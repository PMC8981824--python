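# microstates

Resting-state EEG **microstate** analysis for two-group (patient vs.
control) studies, with a synthetic-EEG generator that plants known
microstate dynamics so every stage of the pipeline can be validated by
parameter recovery.

The package grew out of the question whether interictal migraine without
aura (MwoA) leaves a signature in the sub-second switching of scalp-field
topographies: published cohorts report a shorter mean duration, lower
occurrence and lower coverage of microstate class C in patients, more
class B/D presence, altered transition syntax (e.g. more D→B), and a
negative correlation between class-C duration and headache-related
disability (HIT-6). Because such raw recordings are generally not
deposited, this package treats the published group-level numbers as a
*stated world*: they parameterize a generative model, and the analysis
chain is judged by how well it recovers them.

## The model

At each instant the scalp potential is approximated by one of four
quasi-stable template maps (classes **A–D**, each persisting ~60–120 ms):

```
v(t) = a(t) · T_L(t) + ε(t)
```

with `a(t)` a global waveform, `L(t)` a semi-Markov label process (gamma
segment lengths with planted per-class means, an embedded zero-diagonal
transition matrix between segments) and `ε` sensor noise.

The analysis chain implements the standard microstate machinery:

* **GFP** — global field power, the spatial SD across channels:
  `GFP(t) = sqrt( (1/C) Σ_c (v_c(t) − v̄(t))² )`.
* **GFP-peak clustering** — topographies at GFP maxima are clustered by
  the polarity-invariant **modified K-means** (similarity = squared
  spatial correlation, centroid = dominant eigenvector of Σ v vᵀ), k = 4.
* **GEV** — global explained variance,
  `GEV = Σ_p (GFP_p · r(v_p, m_{l_p}))² / Σ_p GFP_p²`, the objective the
  clustering maximizes.
* **Group maps** — per-subject maps aligned across subjects by
  permutation/polarity search maximizing common variance, then labeled
  A–D against canonical templates.
* **Back-fitting** — every sample labeled by `argmax_k |r(v(t), m_k)|`,
  giving per-class mean **duration** (ms), **occurrence** (/s), time
  **coverage** (%) and the 12 jointly-normalized ordered **transition
  percentages** (syntax).
* **Statistics** — 2×4 mixed ANOVAs with Greenhouse–Geisser correction,
  per-class simple effects, Bonferroni-corrected transition t-tests,
  Yates chi-square, pooled t-tests from summary statistics, Pearson
  correlations, and **TANOVA** (randomization test on topographies).

## Worked example

Generate five 4-minute synthetic subjects whose dynamics plant the
published MwoA group values, then run the full pipeline:

```python
from microstates.montage import standard_64_montage
from microstates.templates import make_canonical_templates
from microstates.reference import MWOA, semimarkov_from_group
from microstates.synth import sample_state_sequence, render_eeg
from microstates.pipeline import PipelineConfig, analyze_group

montage = standard_64_montage()
templates = make_canonical_templates(montage)
spec = semimarkov_from_group(MWOA)       # plants the published MwoA dynamics

recordings = []
for i in range(5):
    labels = sample_state_sequence(spec, length_s=240.0, fs=500.0, seed=2 * i)
    recordings.append(render_eeg(labels, templates, fs=500.0, snr=5.0,
                                 seed=2 * i + 1, montage=montage))

res = analyze_group(recordings, templates, PipelineConfig(), seed=0)
print("mean GEV:", res["gev"].mean().round(4))
print(res["parameters"]
      .groupby("class")[["duration_ms", "occurrence_hz", "coverage_pct"]]
      .mean().round(2))
```

prints

```
mean GEV: 0.9701
       duration_ms  occurrence_hz  coverage_pct
class
A            63.23           3.89         24.62
B            63.99           3.97         25.39
C            58.99           3.77         22.22
D            64.27           4.32         27.77
```

The four cluster maps explain 97% of the GFP-weighted topographic
variance, and the recovered temporal parameters sit within a few percent
of the planted group values (durations 65.13 / 64.99 / 61.44 / 63.61 ms
for A–D) — the small downward duration bias comes from runs truncated at
epoch boundaries and residual label noise at GFP troughs (see
`docs/methods.md`).

## Analysis project

The numbered drivers under `analysis/` reproduce a full study-sized
experiment end to end, writing tables to `results/`:

1. `01_simulate_cohort.py` — freeze a 61 + 66 subject cohort (clinical
   table, montage, master seed; raw EEG is regenerated on demand, never
   stored).
2. `02_segment_backfit.py` — per-group segmentation, A–D labeling,
   back-fitting, TANOVA; writes `parameters.tsv`, `transitions.tsv`,
   `maps_*.csv`, `segmentation_report.json`.
3. `03_group_stats.py` — mixed ANOVAs, simple effects, transition
   t-tests, demographics, HIT-6 correlation; writes `stats_*.tsv/json`.
4. `04_figures.py` — map topographies, violin plots, correlation scatter.

## Acceptance script

`scripts/acceptance.py` recomputes the headline parameter-recovery
quantities from scratch: it generates a 20-subject synthetic cohort
(4 min, 500 Hz, 64 channels, snr 5) planting the published MwoA durations
and row-normalized transition table, runs the complete pipeline
(2–20 Hz filter → 60×2 s epochs → GFP peaks → modified K-means →
labeling → back-fitting, smoothing off), and writes the recovered class-C
duration, class-D occurrence, class-C coverage and D→B transition
percentage as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
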