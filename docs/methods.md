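# Methods

## Ion chemistry

Free fatty acids are modelled as CnH(2n−2d)O2 (n carbons, d double
bonds); the package refuses labels below 12 carbons or with fewer than
two hydrogens. Monoisotopic element masses are CODATA/IUPAC values to
≥ 8 decimals (C 12, H 1.00782503207, O 15.99491461956 Da). The
deprotonated ion is computed as neutral mass − 1.00727646688 Da (the
proton); this is algebraically identical to removing a hydrogen atom and
adding an electron, the two bookkeepings agreeing to ~1.5e−8 Da.
Computed [M−H]⁻ values reproduce all 31 published panel entries at their
printed precision (the packaged table mixes 3- and 4-decimal rows); the
calculator is authoritative and the packaged table is a validation
fixture, not a data source.

Fragments are modelled as decarboxylation (−CO₂, 43.9898 Da) followed by
k CH₂ losses (14.0157 Da each); predicted products for 32:6 and 34:5
fall within 2 ppm of the published measured product ions. No isotope
patterns, adducts other than [M−H]⁻, or esterified lipids are modelled.
Positional (omega-series) isomerism is carried as an annotation only: a
mass-only method cannot resolve n−3 from n−6.

Gravimetric conversion (the 1 µg internal-standard spike → 3.160e−9 mol)
uses the *average* molar mass from standard atomic weights (316.485
g/mol for 21:5), since a weighed standard contains the natural isotope
mixture; monoisotopic masses are used only for m/z.

## Chromatogram extraction and peak quantification

EICs sum centroid intensities per spectrum within a symmetric relative
window m/z·(1 ± tol·1e−6); the default 5 ppm matches the acquisition
method the assay was developed on. Two invariants are tested: widening
the window never loses signal, and EICs over a disjoint partition of the
m/z axis sum to the TIC.

Peak detection operates on an optionally moving-average-smoothed trace
(default window 3). Baseline is the trace median and noise the scaled
median absolute deviation (1.4826·MAD), both robust to the peaks
themselves; apexes must exceed baseline + min_snr·noise (default
min_snr 3, with a tiny floor so noiseless traces still threshold above
zero). Boundaries walk outward from the apex to the baseline crossing
or — when the trace rises again into a neighbouring peak — to the valley
floor; the walk tracks the running minimum so single-scan noise upticks
do not truncate peaks. Overlapping detections (> 50% interval overlap)
collapse to the tallest.

Integration is trapezoidal over a local linear baseline joining the
boundary trace values, each anchor clipped to the trace median so a
valley boundary between overlapping peaks drops to the background level
rather than slicing off the flanks; areas are floored at zero. On
sampled Gaussians this recovers analytic areas within 1% (±4σ bounds)
and within 2% for 6σ-separated pairs.

Identification is by retention time only: the peak nearest the library
RT within ±0.15 min wins, ties going to the larger area. The published
library shows ≤ 0.05 min standard-vs-tissue drift, so ±0.15 gives 3×
headroom. Isomer pairs sharing one m/z (22:5, 24:4, 30:5, 32:4, 32:5)
are resolved purely by RT from one shared EIC. Area, not height, is the
quantitative response throughout.

## Quantification model

response_i = area_i / area_IS; amount_i = response_i · n_IS / RF_i. Per-
species response factors RF are configurable but default to 1.0 relative
to the 21:5 internal standard — no published per-species factors exist,
so molar amounts are nominal-response-factor approximations, which
cancel entirely in ratios (percent change, composition, CV). IS
normalization makes all downstream quantities invariant to global
intensity rescaling of a run.

Calibration fits are ordinary least squares with Pearson r; the limit of
quantification is the lowest level whose back-calculated concentration
is within 20% of nominal (a standard accuracy criterion; the assay's
instrument-specific LOQ is not a property of this software). Impairment
summaries use the arithmetic mean and the n−1 sample SD across markers —
the convention that reproduces the published five-marker summary
(82.01 ± 7.90). CV is 100·SD(n−1)/mean.

The reference sample for per-cell uptake is an explicit argument
(unchallenged cells by convention); negative differences are reported,
not clipped. "Not detected" (no RT-matched peak) is flagged distinctly
from a zero-area detection; composition treats both as zero.

## Synthetic data generator

Each species with a positive amount and a library RT contributes a
Gaussian elution profile with area = amount × response constant
(1e20 counts·min/mol, an arbitrary but fixed instrument sensitivity) and
σ = 0.04 min, sampled every 0.01 min over 0–8 min; each scan carries one
centroid per species at its theoretical m/z shifted by a per-run uniform
offset within ±2 ppm (inside the 5-ppm window). Per-scan multiplicative
noise is clipped-Gaussian with the configured CV; background is 4
uniform-random centroids per scan at ~0.1× the median peak height,
placed outside every target's 10-ppm window. The IS is always present at
the 1 µg amount. σ = 0.04 min leaves same-m/z isomers ≥ 0.12 min apart
baseline-resolved; the 22:5 pair (0.09 min apart) is below that limit
and the generator warns that it is unresolvable by design — mirroring a
genuine chromatographic limitation, and excluded from recovery
assertions.

Scenarios: `untreated_rpe` (LC-PUFAs 20:4–22:6 at nmol-scale amounts, no
species ≥ 30 carbons), `pos_only`, `pos_challenge` (marker amounts =
POS/cell × cells × per-POS content × uptake fraction, added to the
untreated background), `knockdown` (uptake × (1 − effect)),
`replicate_cv`, and `calibration_series` (50–1000 nmol/L of 32:6,
mapped to moles through a nominal 1 mL extract volume). Default per-POS
contents use the three published values (1.20e−15, 2.01e−15, 9.86e−16
mol for 32:6/34:6/36:6) with same-order defaults for 34:4 (8.0e−16) and
34:5 (1.5e−15), for which no published values exist. Default cell count
is 1e5 (a confluent multiwell-plate well) and default uptake fraction
1.0 (full internalization), both configurable.

In `simulate_experiment`, one `noise_cv` knob drives both per-scan
multiplicative noise and a per-replicate lognormal jitter of every
nominal amount (mean-one, CV = noise_cv), emulating prep-to-prep
variability; ground truth records the realized amounts. All randomness
derives from a single seed; identical seeds give byte-identical runs.

What the generator does *not* emulate: real chemical noise structure,
detector saturation or nonlinearity, RT drift between runs, co-eluting
isobaric interferences beyond the panel itself, and MS2 acquisition.
Passing recovery tests therefore demonstrates correctness of the
extraction/quantification chain, not robustness to every instrument
artefact.

## Validation sizes and numerical choices

Recovery tests use single runs (800 scans, ~30 species) per condition;
dose-response uses 4 doses × 2 replicates; knockdown recovery 2 arms × 4
replicates (the published design's replicate count); the false-positive
screen 100 seeded untreated runs quantified against the ≥ 30-carbon
subpanel with ≤ 1 spurious detection tolerated; EIC invariants 100
seeded random runs. The replicate-CV check uses n = 10 with a 6–26%
acceptance band, the ≥ 99% chi-square interval for a sample CV of a 15%
process at that n.

mzML I/O is self-contained: the writer emits centroid MS1 spectra with
PSI CV accessions (64-bit float, zlib or uncompressed, minute-valued
scan times); the reader handles 32/64-bit floats, zlib, gzip files,
second- or minute-valued RTs, and skips non-MS1 spectra. Write→read
round-trips are bit-exact for doubles. The TSV dialect stores
(rt_min, mz, intensity) rows at 6 decimals, grouping spectra by the
exact rt text.

## Known limitations

* Molar amounts inherit the RF = 1 approximation; only ratios are
  calibration-free.
* Shoulder peaks closer than ~2σ at the same m/z merge into one
  integrated area (both RT matches then receive the merged area).
* The naive profile-mode centroider (optional) is a local-maximum pick,
  suitable for well-resolved profile data only.
* Retention-time alignment/warping across runs is out of scope; the RT
  library assumes a stable gradient.
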