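# Methods

`epiquant` re-implements, as reusable and tested code, the quantitative
analysis stages of a chronic kainic-acid temporal-lobe-epilepsy (TLE)
workflow: EEG seizure-burden evaluation, myelin ultrastructure morphometry,
gap-junction plaque colocalization, and single-cell oligodendrocyte
composition and gene-set scoring. Raw recordings, micrographs and
sequencing runs of such studies are typically unavailable, so a
synthetic-data module plants known ground truth for every stage; truth-label
recovery — not biological fidelity — is what the test suite establishes.

## EEG seizure burden

**Model.** A recording is a single-channel trace x(t) in microvolts sampled
at 1 kHz. Preprocessing is a 0.5 Hz high-pass (4th-order Butterworth applied
forward-backward, so onsets are not delayed). The published screening rules
are:

* baseline: the amplitude level of a 10-min seizure-free stretch;
* seizure: amplitude above 2x baseline lasting strictly more than 15 s;
* spike: a 200-5000 uV transient lasting 5-70 ms (inclusive bounds,
  excursions above 5000 uV rejected as artifacts);
* spike train: >= 3 spikes with consecutive inter-onset intervals in
  [50 ms, 1 s] spanning strictly less than 5 s.

**Operationalisation choices** (the protocol names quantities without
defining their estimators):

* *Amplitude* is the centred 1-s moving max of |x| (`envelope_window_s`);
  edges use truncated windows.
* *Baseline level* is the median over non-overlapping 1-s windows of
  max |x| — robust to isolated artifacts in the baseline stretch.
* Seizure candidate regions come from thresholding the envelope (gaps under
  `seizure_merge_gap_s` = 1 s merged), but each region's onset/offset is
  refined to the first/last raw |x| threshold crossing. Without refinement
  the centred envelope pads every onset by window/2, which would misplace
  onsets by ~0.5 s.
* Sub-threshold gaps shorter than `spike_min_ms` are merged before the
  spike duration test, so a biphasic discharge that crosses the threshold
  twice is one event.
* Train grouping is greedy left-to-right; a run closes as soon as adding
  the next spike would push its span to >= 5 s, and the closed run becomes a
  train if it has >= 3 members (longest-valid-prefix rule). Intervals are
  measured onset-to-onset, the only reading under which the printed 50 ms /
  1 s bounds are coherent.
* Spikes inside detected seizures are counted in `n_spikes` but flagged
  `in_seizure` and excluded from train grouping (configurable); the
  original protocol does not state its overlap policy. Recovery evaluation
  compares interictal spikes only, because a sustained seizure waveform
  intrinsically contains spike-like transients that no interictal truth
  list contains.
* Event intervals are half-open [onset, offset); events touching at a
  boundary are distinct.

A note on a tempting invariant: "raising the spike floor never increases
the spike count" is false for this detector family — inside dense seizure
oscillation, a higher floor can split one over-long (hence rejected) run
into several valid shorter runs. The property holds for isolated
transients and is tested in that scope.

## Synthetic EEG

Background is 1/f-amplitude ("pink") noise with a soft spectral fade-in
below 1 Hz, so the 0.5 Hz preprocessing high-pass leaves the amplitude
statistic essentially unchanged; the trace is rescaled so the baseline
estimator applied to the pure-noise trace returns `baseline_amp_uV`
exactly (tested to within 10% across seeds after filtering). Spikes are a
positive half-sine lobe (2/3 of the stated width) followed by a smaller
negative lobe. The negative lobe is half the peak but clipped just below
the 200 uV detection floor: a literal 2:1 ratio would give large spikes a
second threshold excursion near the 5 ms merge boundary, defeating the
design goal that one discharge is one excursion. Seizures multiply the
noise by `amplitude_multiplier` and superimpose a 5 Hz rhythm of amplitude
multiplier x baseline, which exceeds the 2x screen quickly (first crossing
within ~20 ms of onset for multiplier 4). Defaults: 80 uV baseline, 300-700
uV spikes of 20-40 ms, multiplier 4 seizures of 20 s — mid-range values of
the detector's own bounds, since the protocol publishes no amplitude
statistics for real discharges.

What the generator does *not* emulate: electrode drift, movement artifacts,
state-dependent background (sleep/wake), multi-channel structure, or
realistic interictal morphology. A green recovery test therefore
establishes that the detectors implement their stated rules exactly, not
that they would match a human scorer on real recordings.

## Myelin morphometry

Fibers in cross-section are dark (osmium-stained) annuli around a lighter
axoplasm on a light background. Segmentation thresholds the image (Otsu
refined to the midpoint of the two class means — plain Otsu drifts into the
sheath class when most of the field is background), fills holes, discards
border-touching and sub-minimum components, and splits components containing
several substantial lumens by a lumen-seeded watershed. Holes smaller than
`min_lumen_frac` (10%) of their fiber are treated as intrasheath vacuoles,
not lumens.

Diameters are equivalent-circle diameters d = 2 sqrt(area/pi) — the
rotation-invariant convention standard for G-ratio work; G = d_inner /
d_outer, thickness = (d_outer - d_inner)/2. The G-ratio and pathological
percentage are pixel-size invariant by construction.

Pathology scoring is a package invention (the source protocol names the
categories — sheath loosening, lamellar disruption, vesicle formation — but
no criteria): decompaction = coefficient of variation of ring intensity
(threshold 0.10); disruption = 1 - contour solidity (0.10); vesicles =
count of bright blobs in the sheath zone brighter than the midpoint between
ring median and background (flag at >= 1 blob of >= 3 px). Thresholds were
fixed against the generator's clean fibers (CV < 0.05, zero blobs) before
the recovery suites were run; on noisy real micrographs they would need
re-tuning.

The generator plants non-overlapping annuli (rejection sampling, 500
retries per fiber, reproducible failure naming `n_fibers`), G-ratios
~N(0.7, 0.06) clipped to (0.45, 0.92), outer diameters 1.2-3.0 um at
0.02 um/px. Pathological fibers receive azimuthal ring-intensity modulation
(amplitude 0.30 — kept well inside the dark intensity class so the annulus
never shatters at thresholding) and/or 2-4 bright vesicles capped at half
the lumen radius so vacuoles can never be confused with the lumen.

LFB metrics: OD = log10(mean background / mean ROI) over user-supplied
disjoint masks (the stain protocol does not state its blank reference, so
an explicit background mask is required); corpus-callosum thickness is the
length of the in-mask run of a straight line through a given point, at
0.25 px sampling, raising on degenerate directions that exit the image
while still inside the structure.

## Plaque colocalization

Channels are binarised (Otsu by default; fixed level for determinism),
colocalization is the logical AND, and plaques are 8-connected components
of at least `min_area_px` = 4 px (sub-resolution specks are not plaques;
8-connectivity is stated because it changes counts). Per-plaque area is
emitted both in px^2 and um^2 (the reporting unit in published figures is
ambiguous). Mean plaque intensity is read from the red (connexin) channel.
Line scans sample both channels along a segment with bilinear
interpolation (exact for affine images) and report the Pearson correlation
of the profiles; a constant profile yields NaN with a warning. The
generator plants an irregular diffuse green territory and disk-shaped red
plaques, a stated fraction strictly inside the territory and the rest
strictly outside, so colocalized counts are exactly recoverable.

## Single-cell composition and scoring

* QC keeps cells with detected genes > 250, UMIs > 1000 and mitochondrial
  UMI percentage < 25 — all strict, exactly as the thresholds are printed;
  mitochondrial genes are recognised by the mouse `mt-` prefix.
* Normalisation: y = ln(1 + 10^4 x / column total).
* Module scores follow the bin-matched control scheme: genes are cut into
  24 equal-size bins by mean expression; each set member draws 100 control
  genes with replacement from its bin; score = mean member expression minus
  mean control expression per cell. Defaults (24 bins, 100 controls) are
  the upstream convention; the seed fixes the control draw.
* Rank-AUC pathway scores rank each cell's genes by decreasing expression
  (ties broken by one seed-fixed permutation shared across cells) and
  normalise the area under the set-member recovery curve over the top 5% of
  ranks by its maximum, giving a [0, 1] score invariant to any strictly
  monotone per-cell transform.
* Differential expression is a two-sided two-group Wilcoxon rank-sum test:
  exact by full enumeration of group assignments when C(n, n1) <= 20000
  (ties handled naturally), else the tie-corrected normal approximation
  with continuity correction — the same exact/approximate switch R's
  `wilcox.test` uses. The unconditional normal approximation cannot match
  an exact enumeration within 0.01 at n = 10, which the test suite
  requires. avg_log2FC = log2(mean(expm1 y) + 1) difference, the de-facto
  convention for log-normalised data (stated because it changes which genes
  pass |lfc| > 1); BH adjustment runs across the tested genes; genes
  detected in < 3 cells are skipped and reported.
* The DEG selection rule is strict: |avg_log2FC| > 1 and adjusted p < 0.05.
* Composition percentages are 100 x type / group total, reported to one
  decimal — the convention in which "45.2% (5292/11,707)" is stated.

The count generator samples per-cell library sizes log-normally around
5000, gene counts negative-binomially (dispersion 0.1) around per-class
relative abundances, and shifts planted set members by a log2-fold in the
stated (type, group) cells, renormalising abundances per cell. Baseline
gene abundances are log-normal with sd `gene_logmean_sd` (default 1.0);
the module-score *null* calibration uses sd 0 **and no mitochondrial
genes**, because the null statement "members equal their own controls'
distribution" fails when a member shares an expression bin with the
deliberately ~10x-brighter mito population (which would bias its controls).
The generator emulates neither ambient RNA, doublets, batch structure nor
realistic gene-gene correlation; scoring calibration holds for the stated
sampling model only.

## Numerical and degenerate-input conventions

* Envelope windows are rounded to an odd sample count (exactly centred).
* Detector comparisons: spikes use |x| >= floor (the floor is the printed
  threshold), seizures use envelope > multiplier x baseline (strict), and
  both duration rules follow the printed strictness (spike bounds
  inclusive, seizure "> 15 s" strict).
* Empty inputs raise (`summarize_morphometry`, `composition`,
  `log_normalize` on zero-total cells) rather than returning silent NaNs;
  `qc_filter` reports per-rule removal counts when nothing survives.
* All generators are pure functions of their config, including the seed;
  class iteration orders are fixed so results do not depend on
  `PYTHONHASHSEED`.

## Known limitations

* EEG "amplitude" has no unique definition; a different envelope (RMS,
  Hilbert) would shift seizure boundaries by up to the window length.
* Pathology thresholds are generator-tuned; they are a reproducible rule,
  not a validated classifier for real TEM data.
* The Wilcoxon exact/approximate switch makes p-values of tiny and large
  groups come from different (both standard) computations.
* EDF input is not supported (no EDF reader in the supported dependency
  set); EEG I/O is two-column CSV.
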