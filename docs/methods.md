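# Methods

## Background and model

Most genomes carry a periodic pattern in the spacing of A-tracts — short
runs of A (or T on the complementary strand) — phased with the DNA helical
repeat of ~10.5 bp. Phased A-tracts are the primary sequence determinant of
intrinsic DNA curvature, contribute to nucleosome positioning in eukaryotes
and to nucleoid organisation and supercoiling in prokaryotes, and their
intensity varies both between genomes and along a single chromosome. This
package detects and quantifies that signal.

The statistic is a normalised spacing periodogram. For a chosen A-tract
definition, let `N(s)` be the number of ordered occurrence pairs at
start-to-start distance `s`. The pipeline is:

1. **Tract occurrences.** Ten definitions are supported: a single A or T
   (`AT`); homopolymer runs `A^k`/`T^k` of length k = 2–5 (`A2T2` …
   `A5T5`); and the k+1 words `A^i T^(k-i)` of length k = 2–6 (`AT2` …
   `AT6`), i.e. words containing only the dinucleotides AA, AT and TT.
   Occurrences are **overlapping** fixed-length matches (a run `AAA`
   contains `AA` at two offsets), which treats every dinucleotide instance
   as an occurrence; maximal-run counting would undercount phased long
   runs. Windows containing any non-ACGT character never match, which is
   also how masking is represented.

2. **Pair-spacing counts.** `N(s)` equals the lag-`s` autocorrelation of
   the 0/1 occurrence indicator and is computed exactly with one dot
   product per lag, O(L·s_max) regardless of occurrence density.

3. **Normalisation and detrending.** `n(s) = N(s) / E(s)` with the
   uniform-placement expectation `E(s) = m(m−1)(L−s)/L²` for `m`
   occurrences on `L` bp. The exact form of `E(s)` is uncritical: any
   smooth alternative differing by a low-order polynomial factor is
   absorbed by the subsequent parabolic detrend and unit-mean scaling.
   A 3-point centred moving average removes the codon-driven 3 bp signal
   (computed on `[s_min−1, s_max+1]` so interior points use true
   neighbours), then a least-squares quadratic in `s` fitted on
   `[s_min, s_max]` is subtracted; its residuals `y(s)` average to zero by
   construction. Defaults `s_min = 30`, `s_max = 100` bp: the lower bound
   excludes most of the periodicity contributed by amphipathic α-helices
   of encoded proteins, the upper bound reflects the observed decay of
   phasing coherence beyond ~150 bp.

4. **Spectrum.** The Fourier amplitude
   `Q(P) = |Σ_s y(s) exp(2πi s/P)|` is evaluated **directly on a dense
   period grid** (default [2, 20] bp at 0.05 bp) rather than on DFT bins —
   dominant periods are conventionally reported with sub-bp resolution
   (e.g. 11.1 bp), which DFT bins of a 71-point window cannot provide.
   `Q*(P) = Q(P) / mean(Q over P ∈ [5, 20])`: assuming most periods in
   5–20 bp carry no coherent signal, that mean measures the stochastic
   noise floor, so `Q*` is comparable across sequence lengths and
   compositions. The summary indices are `MaxQ = max Q*` and `PMaxQ =
   argmax Q*` over 5–20 bp, ties broken toward the smaller period.

   The intensity is deliberately defined on the **amplitude** scale
   (modulus, not squared modulus). This is the scale on which the packaged
   significance table is calibrated: under it the reduced-replicate null
   simulations reproduce the reference percentiles (medians within ±0.03),
   whereas squared-modulus intensities would be roughly the square of the
   tabulated values.

## Significance calibration

Under the null hypothesis the sequence is homogeneous Bernoulli —
independently drawn letters at fixed frequencies — and peaks in `Q*` arise
from noise alone. The package ships a reference table of the 99th/95th/
50th percentiles of MaxQ for all 10 tract methods × 5 spacing-range widths
(Δ = s_max − s_min ∈ {40, 70, 100, 150, 200} bp), derived from a large
calibration over chromosome-matched random sequences. Because null
sequences are i.i.d. strings, the MaxQ distribution depends on the spacing
range only through Δ, and is insensitive to sequence length (over
chromosome-like lengths, ~0.5–2 Mb and beyond) and to G+C content; the
test suite verifies all three invariances by two-sample Kolmogorov–Smirnov
tests at α = 0.01 with 200 replicates per condition. Thresholds at
intermediate widths are componentwise linear interpolations between the
bracketing columns; widths outside [40, 200] bp are clamped to the nearest
endpoint with a warning, since extrapolating empirical percentiles is
unsafe.

Recalibration (`perioscan calibrate`, `significance.simulate_null`) uses a
reduced desk-scale profile: 500 sequences of 1 Mb at 50% G+C under a fixed
seed. At this size the Monte-Carlo standard error is ≈0.01 on the median
and ≈0.04 on the 95th percentile, and the quantile interpolation rule
(linear between order statistics) matters less than that noise.

## Sliding-window scan

`perscan` applies the full pipeline in a sliding window (default 10 kb,
stepped by 5 kb) to resolve intrachromosomal heterogeneity. Design
choices:

- Trailing partial windows are **dropped**, not padded: a shorter window
  has a different null MaxQ distribution and would corrupt the fraction
  curves.
- Windows with more than 10% non-ACGT content or fewer than two tract
  occurrences are skipped, recorded with a reason, and excluded from all
  fraction denominators (they render as blank heat-map columns).
- The heat map grey level is `clamp((Q* − 1.8)/(4.0 − 1.8), 0, 1)`,
  white at Q* ≤ 1.8 and black at Q* ≥ 4.0; a window's horizontal
  coordinate is its midpoint in bp.
- The argmax-fraction curve counts each window's spectrum maximum within
  ±0.2 bp of the abscissa period **regardless of the maximum's height**;
  the exceedance curves use thresholds {2.0, 2.5, 3.0, 4.0, 6.0}
  (configurable, matching the standard colour key).
- The six persistency indices are the peak height and period of the
  argmax-fraction curve (MaxMax/PMaxMax) and of the 2.0 and 3.0
  exceedance curves (Max2/PMax2, Max3/PMax3), searched over 5–20 bp with
  ties toward the smaller period. A curve that is identically zero
  reports height 0 and an undefined (None) period rather than an
  arbitrary one.

## Annotation handling

Input is a single-entry FASTA or GenBank file. CDS masking replaces
protein-coding (or, conversely, all non-coding) positions with `N`
**in place**, preserving coordinates so that no tract spacing ever spans a
collapsed gap. Postprocessing selects retained scan windows whose maximum
`Q*` over a user-chosen period range is above (or below) a cutoff, then
reports every annotated feature — of any type, not just CDS — overlapping
a selected window by ≥ 1 bp. `join()` locations trigger on any exon span
and the feature is reported once. Outputs are a filtered GenBank record
(which round-trips through the reader) and a compact tab-delimited table
(locus_tag, start, end, strand, product). GenBank coordinates are 1-based
inclusive; internally everything is 0-based half-open, with the conversion
centralised in `genbank_io`. Features spanning the origin of a circular
chromosome are skipped with a warning. Scans are written to a
tab-delimited file once and can be postprocessed repeatedly without
recomputation.

## Synthetic data

The generators in `perioscan.fixtures` define the package's test
conditions:

- `bernoulli_sequence` — the homogeneous Bernoulli null, the same model
  the significance table assumes.
- `plant_periodicity` — Bernoulli background with a tract string written
  in at phase positions `round(start + i·period)`; real-valued periods
  (10.5 bp) are realised by rounding the phase lattice per planting, so
  consecutive plantings average to the requested period. `density` < 1
  drops plantings at random, and integer `jitter` displaces each planting
  uniformly within ±jitter bp, modelling partial and imperfect phasing.
  Ground truth records every planting intact in the final sequence.

Validated detection conditions: with density 1 and no jitter over 50 kb,
the planted period (10.0/10.5/11.0/12.0 bp) is recovered within ±0.2 bp
with MaxQ above the null 99th percentile in ≥95% of 40 seeds.

What the synthetic conditions do **not** emulate: codon bias and genic
3 bp periodicity, isochore-scale compositional structure, tandem repeats
(which can place spurious peaks at curvature-unrelated periods, e.g. 7 bp
heptamer repeats), and correlated A-tract placement. A pass on synthetic
data therefore demonstrates the statistic's calibration and power under
its own null model, not the biological interpretation of any particular
genome's signal.

## Problem sizes

The default validation sizes were chosen to keep Monte-Carlo error below
the assertion tolerances: 500 × 1 Mb replicates for percentile
reproduction (MC SE ≈ 0.01 on medians), 200 replicates per condition for
the KS invariance checks, 40 seeds for detection-power regression, and
10 kb sequences for exhaustive O(m²) pair-count cross-checks against the
autocorrelation counter.

## Genome-scale reproduction (optional)

The published example analyses — the ~11 bp dominant period of
*H. influenzae*, ~10 bp of *M. jannaschii* and *S. cerevisiae* chromosome
IV, and the centromere-restricted 10 bp signal of *A. thaliana*
chromosome 1 — require the complete chromosome sequences, which are not
bundled. `scripts/reproduce_genomes.py` runs the periodicity plot and
scan on locally downloaded GenBank records and prints the corresponding
indices with their significance thresholds.

## Known limitations

- The expected-count model assumes uniform occurrence placement; this is
  exact only under the Bernoulli null, but deviations are low-order and
  removed by detrending (verified by the quadratic-absorption tests).
- The null model is zeroth-order; no Markov-chain composition nulls are
  provided.
- Significance thresholds assume an unmasked sequence of chromosome-like
  length; heavy masking reduces the effective occurrence count and makes
  the packaged thresholds conservative guidance rather than exact levels.
- Periods at multiples of 3 bp (e.g. 12 bp) can arise from amino-acid
  repeats in coding sequence rather than DNA curvature; interpretation is
  the user's responsibility (CDS masking helps separate the sources).
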