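# Methods

## 1. The AHL mass library

An N-acyl-homoserine lactone is modeled by an acyl descriptor
(chain length *n* ≥ 2, optional 3-oxo or 3-hydroxy substitution, number
of C=C unsaturations ≤ *n* − 3). The neutral elemental formula follows
the chain rule C(n+4) H(2n+5) N O3, with +O/−2H for 3-oxo, +O for
3-hydroxy and −2H per unsaturation. Two mass scales are kept side by
side:

* **nominal** [M+H]+ — integer atomic masses (C=12, H=1, N=14, O=16)
  plus 1 for the proton; this is the scale of unit-resolution
  triple-quadrupole data, where the family obeys 14·n + 116 (+14 for
  3-oxo, −2 per unsaturation);
* **monoisotopic** [M+H]+ — exact masses (H 1.0078250319, N
  14.0030740052, O 15.9949146221, proton 1.00727646) for
  high-resolution matching.

The default library enumerates n = 4..18 with 3-oxo allowed and up to
two unsaturations (88 entries): wide enough to cover the nine commercial
reference standards (C4 to Oxo-C12) and longer-chain predictions such as
Oxo-C14:1-HSL, while staying inside the 120–450 amu acquisition window.
3-hydroxy variants are off by default (none among the standards) and can
be enabled with a flag.

**Annotation and ties.** `annotate_mz` returns every library entry
within the tolerance (default ±0.5 m/z nominal; ±0.01 recommended for
monoisotopic mode), ranked by absolute mass error; an empty result is
meaningful (the ion need not be a simple acyl-HSL). Distinct structures
can share a nominal mass (e.g. 324 = Oxo-C14:1-HSL = C15:1-HSL;
256 = C10-HSL = Oxo-C9-HSL). Such exact ties are reported as co-matches
and ordered by a fixed preference: even acyl chains first (fatty acyl
chains are assembled from C2 units, so even-chain AHLs dominate in
nature), then fewer unsaturations, then the unmodified chain, then the
shorter one. Monoisotopic mode resolves these isomers outright.

## 2. The MS/MS screening chain

Product-ion runs are read from mzML or MGF with retention times
normalized to minutes. The package includes its own compact mzML reader
(MS2 scans, 32/64-bit float arrays, zlib or uncompressed, minute/second
units); MGF goes through pyteomics. The chain then applies, in order:

1. **Characteristic-ion screen** — keep spectra with a fragment within
   ±0.5 m/z of 102 whose intensity is ≥ 1% of the spectrum's base peak.
   The intensity gate suppresses accidental matches to electronic noise.
2. **Confirmation** — require at least one further daughter at m/z 56,
   74 or 84 under the same rule. The three confirmation masses are
   treated as fixed targets of the compound family, not derived
   fragments.
3. **EIC and peak detection** — for each surviving nominal precursor
   mass, the extracted ion chromatogram on the run's unique scan-time
   grid (zero points kept, so disjoint-mass EICs sum to the TIC).
   "Significant peak" is operationalized as a local maximum with height
   ≥ 1000 a.u. and ≥ 3× a 1.4826·MAD noise floor, with bounds at the
   nearest valleys.
4. **Control comparison** — a sample peak survives when its height is at
   least 3× the maximum control-EIC intensity at the same mass within
   ±0.5 min of the apex (floored at 1 a.u. to avoid division by zero).
   A medium-control run is mandatory; its absence is an error, not a
   warning.
5. **Annotation and clustering** — retained (mass, apex) pairs become
   features carrying the observed daughter subset and fold-change, are
   annotated against the library, and can be clustered by k-means on
   z-standardized (m/z, RT) with k = 4 by default, 10 restarts and a
   fixed seed. k-means was chosen for the unnamed grouping step because
   the feature space is two-dimensional and standardized; k is a
   parameter, not a fitted quantity.

All tolerances and thresholds live in `ScreenParams`/`PipelineConfig`
and are echoed into every run report. The whole chain is a pure function
of (inputs, parameters, seed): reruns produce byte-identical CSVs.

## 3. Genome-mining post-processing

Hit tables are upstream products (hmmsearch `--tblout`, BLAST
`-outfmt 6`); no search is re-run here. Choices that the upstream
formats leave open:

* the **full-sequence E-value** column of tblout is filtered on (not the
  best-domain column); the threshold is strict (E < 1e-5), so a
  borderline 9.7e-5 hit is excluded;
* when several profile HMMs recognize one protein, the lowest-E-value
  hit wins; ties break by higher bit score, then lexicographic model id
  — deterministic and documented rather than parser-order-dependent;
* copy numbers are counts of distinct surviving protein ids per family
  per assembly; the assembly universe is an explicit manifest so that
  zero-hit genomes are reported as (0, 0) instead of silently missing;
* species deduplication keeps, per species, the assembly maximizing
  luxI_count × luxR_count (ties: higher receptor count, then smallest
  assembly id); strain suffixes are stripped by a configurable regex
  that preserves "Genus sp. XYZ" placeholder names;
* BLAST filtering is strict (E < 0.01); query coverage needs the query
  length, which outfmt 6 does not carry, so it is a parameter (NaN when
  unknown); subject-to-species mapping comes from a sidecar TSV.

Summaries (median, mean, min, max, counts of ≥1 and =1) are computed
over the deduplicated species set; the median of an even count is the
midpoint average.

## 4. Synthetic data: what it emulates, and what it does not

`make_ms_run` emulates precursor-ion-scan acquisition on a
unit-resolution instrument over a 0–40 min gradient at a 0.05-min scan
interval: each planted AHL elutes as a Gaussian (default sigma 0.1 min)
and emits product spectra containing the ring ion plus a fixed non-empty
random subset of {56, 74, 84} at 25–55% relative intensity; fragment
intensities can carry lognormal jitter and Poisson-count chemical-noise
fragments uniform in [50, precursor−1]. Decoys come in the two kinds
that matter to the screen (no 102; 102 without confirmation daughters)
and are placed at least 2 m/z from every planted mass so EICs stay
interpretable. Background ions appear in both runs at matched intensity.

`make_cohort` draws synthase copy numbers as 1 + Poisson(4.3) and
receptor copy numbers as round(Normal(123, 25)) floored at 5 — shapes
loosely matching genus-wide medians of ~5 and ~123 — with configurable
duplicate-species fraction, significant E-values log-uniform in
[1e-30, 1e-6], decoy rows log-uniform in [1e-4, 1], and a 10%
multi-model collision rate. These are fixture choices, not biological
claims.

What passing the synthetic benchmarks shows: the bookkeeping
(thresholds, resolution, counting, deduplication, summaries) and the
screening logic are exact on inputs whose truth is known. What it does
not show: performance on real chromatography (coeluting isomers,
retention drift, detector saturation), real HMM score distributions, or
real taxonomy (the strain-stripping regex is a convention). Genus-scale
results additionally require the live sequence databases and raw
vendor data, which are outside this package's scope.

## 5. Problem sizes and numerical notes

The test suite runs the mining truth-recovery benchmark at 200 species
(≥10% duplicated assemblies), the dedup-oracle sweep on 100 random
cohorts of 30 species, and the screening recovery sweep over 20 seeds of
four planted AHLs plus 15 decoys on a 20-min span — sizes chosen so the
full suite completes in well under a minute while exercising every rule
at realistic copy-number scales. Degenerate inputs are defined, not
accidental: empty EICs raise, flat-zero EICs return no peaks, empty
match lists and zero-hit assemblies are valid results, and an empty
record list refuses to summarize. All randomness flows through
`numpy.random.default_rng(seed)`; identical spec and seed give
byte-identical output files.
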