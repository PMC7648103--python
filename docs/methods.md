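# Methods

This note documents the models and numerical choices behind `pulsedims`: what
the pipeline computes, what the synthetic generator emulates (and does not),
and where the design was genuinely open.

## The measurement model

A pulsed nanoelectrospray source emits discrete spray events at roughly
0.8 Hz. Each pulse delivers ions for ~0.6–0.9 s, so with a 0.1 s scan period
the mass analyzer records 6–7 scans across a pulse, separated by baseline
gaps. The total ion chronogram (TIC) therefore looks like a pulse train, and
the natural unit of quantitation is the *pulse*: the integral of a species'
extracted-ion chronogram (EIC) over one spray event.

Spray efficiency varies pulse to pulse, but it varies *common-mode*: a weak
pulse is weak for every m/z simultaneously. This is what makes two design
elements of the protocol work:

* **IS-based pulse QC.** A stable-isotope-labelled internal standard (IS) is
  spiked at fixed concentration, so its per-pulse EIC area is a pure readout
  of spray efficiency. Pulses whose IS area falls outside
  [0.8·median, 1.2·median] are discarded. The median is computed once over
  all detected pulses (no iteration) and the bounds are inclusive — the
  written rule specifies the interval but not the boundary handling, so the
  simplest single-pass inclusive reading is implemented.
* **IS normalization.** Dividing every feature by the same-run IS value
  cancels the common-mode amplitude, which is why representative spectra
  from different pulses, runs, and emitters become comparable.

## Pulse processing

Pulses are found by threshold segmentation: maximal contiguous runs of scans
with TIC ≥ `min_height` (default 5% of the TIC maximum) at least
`min_scans` = 3 long. Pulsed sources produce well-separated unimodal pulses,
so derivative-based peak picking would add machinery without benefit. Areas
are trapezoidal with a zero baseline — chemical background is handled
downstream by the blank filter, not by baseline subtraction.

IS areas for the QC window are integrated over the pulse bounds *padded by
two scans* on each side (clipped at the midpoint to the neighbouring pulse).
Threshold-crossing bounds truncate the pulse tails at scan-grid resolution,
which alone contributes ~2% pulse-to-pulse area scatter; padding recovers
the tail mass and makes the area a faithful measure of pulse intensity.

The representative spectrum averages all scans inside the k randomly
selected surviving pulses (k = 5 for the Q-TOF profile, 3 for the Orbitrap
profile; uniform selection without replacement, seeded). Peaks are pooled,
clustered by single-linkage in m/z at 10 ppm, each cluster's m/z is the
intensity-weighted mean, and its intensity is the mean over all pooled scans
with absent peaks counted as zero. Averaging (rather than summing) matches
the "averaged spectrum" convention; the two differ only by a constant factor
that IS normalization removes anyway. Peaks below the instrument abundance
threshold (2×10³ counts Q-TOF, 1.5×10⁴ Orbitrap) are removed at this stage.

## The filter cascade

After alignment (single-linkage, 10 ppm) and IS normalization, the quality
filters run in a canonical order chosen for reproducibility:

blank → prevalence → QC-missingness + sample-outlier → QC-RSD → imputation.

Boundary semantics follow the written rules literally: prevalence ≥ 80% is
inclusive, sample missingness > 20% and RSD^QC > 30% are strict. The blank
rule removes a feature when the mean over non-missing biological samples is
below 3× the mean over blanks (a per-sample variant — keep the feature if
*any* sample exceeds 3× blank — is available behind a flag); features absent
from every blank are kept. RSD^QC uses the n−1 sample standard deviation,
the small-sample convention for triplicate QCs.

Two deliberate choices deserve emphasis:

* **The QC-RSD filter runs on observed (non-imputed) QC values, before
  imputation.** Imputing first hands every QC-missing feature an artificial
  near-zero replicate, exploding its RSD and removing about a quarter of
  genuinely stable features in simulation. The protocol's own statement that
  the four quality filters are order-interchangeable only holds when each
  filter uses missing-aware statistics, which is the reading adopted here;
  `features.filter_order_report` runs all 24 orders and reports retained-set
  divergences rather than hiding them (on tables without missing values the
  24 orders agree exactly, and the test suite asserts this).
* **Half-minimum imputation is global**: every missing value becomes half
  the table's minimum positive value, the standard "below detection limit"
  convention.

## Statistics

Fold changes are computed on untransformed IS-normalized abundances
(mean of group 2 / mean of group 1); p-values, loadings, and correlations on
the glog-transformed, autoscaled matrix. The two scales answer different
questions (effect magnitude vs. evidence) and conflating them is a common
volcano-plot error.

* glog: `x ↦ log2((x + √(x² + λ²))/2)`, λ = table minimum positive value by
  default (both λ and the base are configurable). Monotone, smooth through
  small values, and → log2 as λ → 0.
* Welch's two-tailed unequal-variance t-test per feature (scipy).
* PLS-DA: PLS1 NIPALS against a ±1 class code, deterministic (no random
  initialization), 2 components by default — the standard choice for
  two-group score plots. VIP uses the y-variance-weighted formula;
  mean(VIP²) = 1 holds to 1e-8 and is asserted.
* Discriminant set: volcano (p < 0.05 strict, FC > 2 or < 0.5 strict) ∩
  VIP > 1.8 (strict). No multiple-testing correction is applied by default —
  the protocol selects jointly on p, FC and VIP, which is already far more
  conservative than p alone; BH-FDR can be enabled by thresholding the
  volcano table externally.
* O-PLS-DA: one orthogonal (Trygg–Wold) component by default, then a
  1-component PLS on the filtered matrix; prediction thresholds the
  continuous ŷ at the class-code midpoint. With no y-orthogonal structure
  the predictive component equals plain PLS component 1 (tested).
* Leave-one-out CV re-estimates autoscaling inside every training fold and
  applies the fold's means/sds to the held-out sample; the positive class
  for sensitivity is the second group label (the challenged/stimulated
  group). The glog λ is estimated once on the full table — it is a single
  scalar with negligible leakage potential, re-estimated scaling is the part
  that matters.
* PCA by SVD of the centred matrix; sign convention: each component's
  largest-magnitude loading is positive.

## Annotation

Monoisotopic masses come from a 9-element constants table (most-abundant
isotope, CODATA/IUPAC, ≥6 decimals: H, C, N, O, P, S, Na, K, Cl). Adduct
deltas subtract one electron mass per positive charge — e.g. [M+H]⁺ adds
1.007276 Da, not the 1.007825 Da hydrogen atomic mass; omitting the electron
correction shifts every theoretical m/z by ~0.5 mDa, which is visible at the
fourth decimal. Only singly charged adducts are supported (the species
relevant to small-molecule positive/negative DI-MS). Reported m/z values are
rounded half-up to 4 decimals at print time only; annotation keeps full
precision. Matching is within a configurable ppm tolerance (default 10,
inclusive), results sorted by |ppm error| with lexicographic tie-breaks for
determinism.

## The synthetic generator

`pulsedims.synth` emulates the acquisition conditions of pulsed-DI-MS
fingerprinting studies. Defaults, with units and why:

| parameter | default | rationale |
|---|---|---|
| pulse rate | 0.8 Hz | observed pulse trains (~1200 pulses / 25 min) |
| scan period | 0.1 s | so 6–7 scans span a pulse with baseline gaps between 0.8 Hz events; a 0.2 s period cannot give 6–7 scans per pulse without adjacent pulses overlapping |
| pulse envelope | Gaussian, σ = 0.13 s | simplest unimodal shape; above-threshold span ≈ 0.6–0.7 s |
| pulse width CV | 8.9% | the reported pulse-width variation |
| pulses per run | 40 (20 for the cell-study profile) | reported acquisition counts |
| amplitude CV | 10% log-normal, common-mode | unreported; chosen so the ±20% IS window rejects a small minority (~4–5%) of normal pulses |
| outlier pulses | 10% at 1.5× | planted spray instabilities for QC validation |
| IS | m/z 183.0879, area 5×10⁴ counts·s | spiked isotope-labelled standard |
| baseline noise | 200 counts/channel/scan | well below the 2×10³ abundance threshold |
| base abundances | log-normal, median 3×10⁵, σ_ln = 0.8 | typical DI-MS dynamic range; keeps down-regulated features above threshold |
| between-sample CV | 20% log-normal | typical biological variability |
| missingness | 90% of features always detected; a random 10% "sporadic" subset with per-run detection probability U(0.6, 0.95) | detection-limit censoring: abundant signals do not vanish at random; sporadic detection is a property of borderline features. Uniform abundance-independent dropout would let a single missing value in the high group (imputed to half-minimum) destroy the Welch test for a genuinely 5-fold-changed feature — an artifact of the wrong missingness model, not of the pipeline |

Pooled QCs use the mean of all realized sample abundance vectors (exactly
what physical pooling does), so the QC expectation equals the average sample
expectation. Blanks carry zero feature signal — IS and noise only. All
randomness flows from one study seed through spawned `SeedSequence`
children, one per run, so studies are byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: per-feature ionization noise beyond the
common-mode pulse amplitude (so synthetic RSD^QC after IS normalization is
near zero, far cleaner than the 10–20% typical of real platforms; QC-RSD
behaviour is therefore validated with table-level simulations at a
configured per-feature CV), electrospray matrix effects and ion
suppression, mass-calibration drift (feature m/z are exact up to alignment),
in-source fragmentation, isotope envelopes, correlated chemical background
in blanks, and run-order drift. The filter cascade and statistics are
validated against these conditions by construction-based oracles and
brute-force re-implementations, not by resemblance to any particular
instrument's output.

## Validation problem sizes

The test suite validates the pipeline at desk scale: brute-force oracle
equivalence on 500 random tables (filters) and 1000 random area vectors
(pulse QC); pulse-QC error rates on 20 simulated 40-pulse runs; end-to-end
parameter recovery on 20 independent studies of 24 runs each (100 features,
10 planted at 5-fold, n = 10/group, 20% CV) — recovery averages ~90% with
≈0 false selections and LOO accuracy 100% — and QC-precision simulations
with two pooled-QC triplicates × 200 features per seed. Two QC triplicates
(not one) are used for the RSD^QC simulations because the n−1 standard
deviation is biased low at n = 3 (E[s] ≈ 0.886σ), and the every-six-samples
QC schedule provides six replicates in any real study of this size.

## Known limitations

* Profile-mode data are out of scope; the mzML importer accepts centroided
  spectra only (32/64-bit float, plain or zlib-compressed arrays).
* Annotation is accurate-mass + adduct only: no MS/MS matching, isotope
  scoring, or database queries; candidates come from local CSV lists.
* No drift or batch correction (QC-RSC/LOESS) — the target protocol does
  not use them, and the generator does not simulate drift.
* Charge states |z| > 1 are unsupported in the adduct table.
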