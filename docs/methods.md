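# Methods

This note documents the models, algorithms, parameter choices and
limitations of peakforge in one place.

## Peak-quality model

A detected peak is represented by an apex-centred window of raw intensities:
10 m/z channels × 41 time points spanning 8 s (the channels are the peak's
fragment traces ordered by descending apex height, zero-padded when fewer
than 10).  The 8 s span is twice the ~4 s full base width of a typical GC
peak on the emulated acquisition, wide enough that the geometry of all seven
classes — including the narrow-peak class E and the border-truncated class F
— is expressible inside the window.  Windows are preprocessed by

1. per-channel linear baseline subtraction anchored at the means of the
   first and last 10% of columns, clipped at zero;
2. division of the whole window by its global maximum (an all-zero window
   stays all-zero);
3. row-major flattening to a 410-dimensional vector.

This makes classification invariant to per-channel additive offsets and to
global scaling, so the classifier sees shape, not abundance.

The classifier is a multi-class (one-vs-one) RBF-kernel SVM selected by
5-fold stratified cross-validation over C ∈ {0.1, 1, 10, 100} and
γ ∈ {10⁻⁴ … 1} (log grid).  One classifier is trained per picker algorithm,
because pickers report different peak populations; labels learned on one
picker's output are never silently reused for another.  Windows with
identical content (same content hash) are counted once before
cross-validation — duplicates would leak across folds and distort
hyper-parameter selection.  The chosen pair, per-fold accuracies and class
counts are recorded in `cv_report`; the preprocessing recipe is embedded in
the persisted classifier so that classification is reproducible.

Exactly seven classes are hard-coded: A/C (apex shifted left/right),
B (centred), D (noise), E (narrow, wide margins), F (border-truncated),
G (merged/shoulder).  Quality tiers: high = {A, B, C}, noise = {D},
review = {E, F, G}.

## Pickers

Both built-in pickers operate on extracted ion chromatograms obtained by
binning every (m/z, intensity) point into fixed-width m/z bins (each point
contributes to exactly one bin; the per-scan sum over bins equals the TIC).

**Matched filter.** Each EIC is convolved with a Ricker (negative Gaussian
second derivative) kernel of the requested FWHM.  Local maxima of the
response above `snthresh · σ̂` are reported, where σ̂ = 1.4826 · MAD of the
response — robust and parameter-free.  Peak boundaries are the nearest
response zero-crossings.  A relative floor of 10⁻⁶ of the response maximum
guards against FFT round-off and profile tails being promoted to peaks on
otherwise silent traces, where the MAD collapses to zero; candidates within
half a kernel of the trace ends are discarded (convolution edge artifacts).
`max_per_eic` (default 10) caps pathological EICs.

**CWT picker.** Mexican-hat CWT over 10 log-spaced scales spanning the
requested peak-width range, with centWave-style parameters
(`peakwidth_min/max`, `snthresh`, `prefilter_k`, `prefilter_i`).  With
1/a-normalised kernels the response of a Gaussian peak of width σ_p is
maximal at scale a = √2·σ_p, so a requested full base width w (≈ 4σ_p) maps
to scale √2·w/4; peaks whose widths lie inside the requested range then
peak at interior scales.  A ridge whose response is maximal at the extreme
smallest (largest) scale and falls off by more than 5% at the neighbouring
scale indicates a peak narrower (wider) than the requested range and is
rejected as a scale mismatch.  EICs without `prefilter_k` consecutive points
above `prefilter_i` are skipped.  Reported width comes from the best scale;
boundaries are apex ± 1.5 scale.

**Pseudospectrum grouping.** Electron ionisation fragments one compound into
many co-eluting traces, so single-m/z hits are grouped by apex proximity
(single-linkage in 1-D, default tolerance 1 s) into compound-level features
before classification — the classifier consumes full compound spectra.  The
merged apex is the height-weighted mean; bounds are the envelope union.
Grouping is idempotent.  The 1 s default is a configurable choice, not an
inferred constant.

Additional pickers register as callables `(RawRun, PickerParams) →
[DetectedPeak]` with a declared parameter schema; built-ins never shell out.

## Scoring and grid search

Classified counts are scored linearly, S = Σ_c w_c·n_c, with defaults
w_A = w_B = w_C = +1, w_D = −1, w_E = w_F = w_G = −0.5.  The linear form
implements "reward high quality, penalise noise hardest, discount
intermediate classes"; all weights are configuration-exposed so users can
shift the balance (e.g. discovery vs diagnostic studies).  Optimisation is
plain exhaustive grid search: score minima are empirically shallow and
broad, so descent or annealing methods buy nothing and risk local optima.
Counts are summed (not averaged) over the optimisation runs — equivalent
for the argmax on equally sized run sets.  Ties are broken by the fewest
class-D peaks, then by lexicographic parameter order, making selection
deterministic.  Optimisation samples should be disjoint from training
samples; an overlap by sample id triggers a warning.

## Integration

Two peaks are duplicates only if their apexes lie within an RT tolerance
(default 2 s) *and* their fragment spectra agree (cosine ≥ 0.8).  Requiring
both avoids collapsing co-eluting but chemically distinct compounds.
Duplicate groups are connected components of that graph; the representative
is chosen by class priority B > A = C > G > E > F > D (a centred apex
quantifies most reliably), ties by larger summed apex intensity, then
earlier RT.  Deduplication within each picker is followed by a cross-picker
merge under the same criterion; merged features carry full provenance
(contributing algorithms and source peak ids).  Features with fewer than 3
fragment m/z are rejected first (configurable).  Nothing is silently lost:
per sample, input = dropped-by-min-m/z + collapsed-as-duplicate + high +
review + noise, and the audit asserting this identity is written alongside
the outputs.

Cross-sample alignment is greedy clustering seeded from the most intense
feature (same RT + cosine criterion against the seed).  Table cells hold
apex height summed over the feature's m/z list; an integrated-area variant
is emitted alongside, and missing values are 0 with a separate mask.  Height
is the default exported intensity because apex heights are more robust than
areas when boundaries are uncertain; both are always computed.

Group statistics are Welch's t-test on log2(intensity + 1) — a transparent
default, configurable — with the fold change reported as the ratio of raw
group means r, displayed as r when r ≥ 1 and −1/r otherwise, so negative
values denote a decrease in the first condition.  Features with an all-zero
group are flagged and not tested.  Raw p-values are reported by default;
Benjamini–Hochberg correction is available behind a flag.

## Annotation

Retention indices are computed by linear interpolation between n-alkane
anchors, RI = 100·(n + (rt − rt_n)/(rt_{n+1} − rt_n)) — appropriate for
temperature-programmed GC; the logarithmic (Kovats, isothermal) form is
available behind a flag.  Values outside the anchor range are extrapolated
and flagged.

Library matching is reverse matching: the similarity is computed over the
library spectrum's m/z positions only, so extra query ions (co-elution
contamination) are ignored.  The score is a weighted cosine with weights
mz² · √intensity on both sides — the common choice for electron-ionisation
spectra, where high-mass fragments are the diagnostic ones; the exponents
are configuration-exposed.  The m/z match tolerance defaults to ±0.5 Th
(nominal-mass EI).  A candidate must lie within ±1.5 RI of the feature;
the best in-window candidate by similarity is reported at high confidence
if its similarity exceeds 0.9, otherwise at low confidence.  By
construction, reverse_match(x, x) = 1 and the score is invariant to
rescaling either spectrum.

## Synthetic data

The generator emulates a 25-minute electron-ionisation GC-MS acquisition
sampled at 5 Hz (60–1560 s).  Compounds elute as Gaussian or
exponentially-modified-Gaussian peaks with a default FWHM of 2.35 s
(σ = 1 s, full base width ≈ 4 s) mirrored on 4–8 nominal-mass fragment
channels with descending relative abundances.  Noise comprises a constant
baseline (200 counts) with linear drift (0.2 counts/s), a monotone
column-bleed ramp on the classic polysiloxane ions 207/281/355 Th starting
at 1200 s (the last quarter of the run, matching where bleed appears on
real instruments), zero-truncated Gaussian shot noise (sd 20 counts), and
Poisson-rate single-scan spikes (0.5/min).  Ground truth records every
injected apex, its 1%-height bounds and an injected label — G when another
apex falls within the summed base half-widths (a shoulder pair), B
otherwise.  The demo panel places 30 compounds across the run, including
two deliberately co-eluting shoulder pairs.

Class-window templates share geometry constants with an *independent*
rule-based checker (`verify_window_label`) that re-derives the label from
the intensity matrix alone: presence (amplitude ≥ 8× the high-frequency
residual noise and lag-1 autocorrelation of the smoothed trace > 0.85, else
D), two significant maxima with a valley-to-apex ratio in (0.45, 0.97) → G,
border intensity > 40% of apex with the apex within 8% of a border → F,
base width < 27% of the window for a near-centred peak → E, then apex
position (within 10% of centre → B, left → A, right → C).  Templates carry
random exponential tailing (τ up to 0.7 σ) so the classifier learns shapes
rather than perfect symmetry, matching the EMG peaks of the simulated runs.
The A/C displacement band is 25–40% of the window; the B band is ±5% — the
boundary between "shifted" and "centred" is a design choice made once for
class separability.  Class G uses a single template family whose valley
ratio is sampled in (0.55, 0.90) and realised by bisection on the peak
separation.

What the generator does **not** emulate: isotope patterns, real EI
fragmentation chemistry, retention-time drift between samples beyond a
configurable constant offset, detector saturation, and m/z-dependent noise.
Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline machinery under realistic peak geometry and
noise, not instrument-grade performance on real data; on real runs the
classifier must be trained on manually labelled windows from the same
instrument and sample type (the `export-sheets`/`train --source labels`
path).

## Workflow and determinism

The CLI executes the pipeline as nine idempotent steps (simulate,
sample-training, export-sheets, train, optimize, pick, integrate, annotate,
stats) with one global seed fanned out per step by hashing `seed:step` —
recorded, along with a configuration hash and input paths, in a per-step
manifest.  CSV artifacts are byte-identical across re-runs with unchanged
inputs and seed.  Per-sample picking tasks are independent and keyed by
sample id, so execution order never affects results.  For synthetic
projects, classifier training defaults to the template corpus
(`source: corpus`, 100 windows per class = 700 total, matching the
recommended minimum for manual labelling); `source: labels` consumes a
filled-in annotation sheet, and `source: auto` bootstraps labels from the
rule-based checker (synthetic data only).

Problem sizes used by the test suite and the acceptance script — a
700-window corpus, 30-compound panels, two optimisation runs, 27-point
grids per picker — were chosen as the smallest sizes at which the studied
effects (class separability, the noise-penalty structure of the score
landscape, merge gains) are stable across seeds.

## Numerical choices

- Robust noise scale: 1.4826·MAD throughout.
- EMG profiles are evaluated with the erfcx/erfc split form, which is
  overflow-safe on both flanks.
- Relative response floor 10⁻⁶ in the pickers (see above); intensities are
  64-bit floats regardless of on-disk encoding.
- MSP output follows the NIST dialect (intensities scaled to max 999,
  integer-rounded, floor 1); any positive scale is accepted on read and
  max-normalised.
- All-zero windows preprocess to all-zero vectors; degenerate duplicate
  groups fall back deterministically via the priority/intensity/RT
  tie-break chain.
- mzData input is intentionally unsupported (legacy format superseded by
  mzML); requesting it raises a clear error.

## Known limitations

- The score is linear in class counts; non-linear trade-offs (e.g.
  saturating rewards) are not modelled.
- Cross-sample alignment is greedy nearest-seed clustering without RT
  warping; large inter-sample RT drift would need alignment upstream.
- The CWT picker's scale-mismatch rejection errs on the side of precision:
  peaks exactly at the edge of the requested width range with steep response
  fall-off can be dropped.
- Compound identification is out of scope: annotation is library matching
  only, and its quality is bounded by the library and the RI calibration.
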