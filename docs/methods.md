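# Methods

Models, assumptions and numerical choices behind `radopt`. Nothing in this
document asserts empirical results beyond what the test suite and
`scripts/acceptance.py` actually compute.

## Restriction digestion

- **Site matching.** Recognition sites use IUPAC degenerate codes; a site
  position matches only when every genome base is one of the site symbol's
  allowed bases. An `N` in the genome matches nothing (ambiguous reference
  bases cannot certify a site), while `N` in a site matches any of A/C/G/T.
  Matching is case-insensitive and reports overlapping occurrences.
- **Strands and cuts.** The cut coordinate is the top-strand cut position
  (caret notation: `G^AATTC` cuts after base 1 of the site). Palindromic
  sites (site equals its IUPAC reverse complement) occur identically on both
  strands and contribute one cut per occurrence. Non-palindromic sites are
  additionally searched as their reverse complement; a bottom-strand site at
  position `s` with length `L` and offset `c` cuts the top strand at
  `s + L − c`.
- **Fragments** are the half-open cut-to-cut intervals tiling each sequence.
  Cuts at coordinate 0 or at the sequence end coincide with the molecule
  boundary and do not create empty fragments; the adjacent fragment is
  labelled with the cutting enzyme. Coincident cuts by several enzymes are
  recorded as a `+`-joined label. Terminal fragments (one end a sequence
  end) can be excluded from design searches since they lack one ligatable
  cut end.
- **Size selection** keeps fragments with length inside an inclusive window,
  default 224–424 bp.
- **Classification.** A fragment is `rRNA` when it overlaps an annotated
  rRNA interval by at least one base, `chloroplast` when its sequence is a
  chloroplast replicon, otherwise `genomic`.

## First-round enzyme search

All combinations of 2..`max_first_round_combo` (default 3) candidate
enzymes (default EcoRI, HindIII, MspI, MseI) are digested jointly.
Combinations are ranked by:

1. meeting the minimum selected-genomic-fragment count (default 10,000 —
   enough target regions for dense genotyping);
2. fewest selected organellar fragments;
3. most polymorphisms falling inside selected fragments (when a variant
   list is supplied);
4. most selected fragments; ties broken by enzyme names.

The objective deliberately prioritizes low organellar co-selection over raw
target count: every organellar fragment is amplified by its copy number, so
one chloroplast fragment can cost more reads than hundreds of targets.

## Second-round search

Given the selected fragments of a first-round digest, the search looks for
an enzyme set of size ≤3 from the shipped catalog whose members cut every
organellar fragment internally (a cut strictly inside the fragment; a cut
at a fragment boundary recreates the existing end and does not destroy it).

- A per-enzyme incidence bitmask over fragments is computed once; subset
  evaluation is then a bitwise union, keeping full enumeration over a
  couple of hundred enzymes and three-way combinations tractable.
- Enzymes cutting no organellar fragment are pruned before enumeration:
  adding one can only destroy genomic fragments, so no optimal set contains
  one. The test suite verifies pruning never changes the optimum.
- Ranking: complete organellar removal first; then (for incomplete covers)
  more organellar fragments cut; then more genomic fragments left intact;
  then fewer enzymes; then lexicographic names. When no complete cover
  exists the best partial covers are returned with a warning.
- The enzyme catalog (`src/radopt/data/enzymes.tsv`) lists 81 commercially
  available Type IIP enzymes with unambiguous double-strand cut positions,
  transcribed from the public REBASE listing. Users can supply their own
  catalog in the same two-column caret format.

## Read-proportion (dilution) model

Per-cell template copies:

| class | copies |
| --- | --- |
| genomic | `n_genomic × ploidy` |
| rRNA | `n_rRNA × rrna_copies_per_haploid × ploidy` |
| chloroplast | `n_chloroplast × chloroplast_copies_per_cell` |

Defaults: 700 rRNA copies per haploid genome and 1,200 chloroplast copies
per cell (typical leaf-tissue values; chloroplast number is a per-cell
property, hence ploidy-independent). Expected read shares are copy counts
over the total; percentages round half-up to one decimal. Assumptions:
amplification and sequencing are unbiased with respect to fragment class,
and fragments within a class are equally represented.

Coverage planning divides total read pairs by distinct selected fragments
(`1.25 M pairs / 10,000 fragments = 125×`), and an even n-sample pool gives
each sample `1/n` of the lane.

## Demultiplexing

Read 1 begins with an inline sample barcode (default 5 bp). A pair is
assigned when exactly one barcode matches the prefix within the mismatch
tolerance `t`; barcode sets are validated for pairwise Hamming distance
≥ `2t + 1`, which makes single-tolerant correction unambiguous. Optionally
the enzyme overhang directly after the barcode is required verbatim.
Balance statistics: coefficient of variation with the sample (n−1)
standard deviation, and a two-sided one-sample t-test of per-sample counts
against `total / pool_size`.

## Library evaluation

Operates on mapped read-pair outer spans (BED-like TSV), not BAM files —
alignment is left to standard mappers. Pairs below mapping quality 20 or
mean base quality 20 are excluded. Depth is computed per base with numpy
difference arrays; summaries report bases covered at ≥2× and ≥10× per
sample, genome-wide and inside selected regions, plus bases deep in at
least k samples. Marker dispersion uses equal physical bins (a stand-in
for genetic-map bins when no map is available) and counts bins containing
at least one marker.

## Variant filtering and segregation

- **Filtering order.** Depth (<10) and genotype quality (<20) first mask
  individual calls (an unknown depth/quality also masks — a threshold that
  cannot be verified is not met); then sites are rejected by the first
  failing criterion: a parent missing → fewer than 7 genotyped offspring →
  an offspring allele absent from both parents → more than two alleles.
  The tally therefore attributes each rejected site to exactly one
  criterion.
- **Classification** is by allele presence, which is what a sequencing
  genotype caller reports reliably without dosage: `homP1`/`homP2` when
  only one parent's distinguishing alleles are seen, `het` when both. In a
  homozygous×heterozygous cross the shared allele stands for the homozygous
  parent.
- **Chi-square.** Pearson `Σ(O−E)²/E` against expected class frequencies;
  df = classes − 1. A class with zero expectation and zero observations is
  dropped (df reduced); observations in a zero-expectation class flag the
  marker as model-inconsistent rather than producing a bogus p-value.
  Cross-checked against `scipy.stats.chisquare` in the tests.
- **Multiple testing.** Sidak per-test threshold `1 − (1 − α)^(1/m)` over
  the m consistent markers; the null family-wise error rate is verified by
  simulation in the acceptance suite.
- **Tetraploid models.** With double-reduction coefficient α (upper bound
  1/6 under complete equational separation): a duplex×duplex F2 has
  homozygote-class frequency `g² `per side with `g = (1 + 2α)/6`
  (a gamete is homozygous via double reduction with probability α/2 per
  allele, or by drawing both copies of one allele, 1/6); a
  simplex×nulliplex F1 has class frequencies (0, ½ − α/4, ½ + α/4). Both
  are verified against exact gamete enumeration in the tests. Custom
  expected frequencies can be supplied for other designs. Double reduction
  predicts homozygote excess increasing with centromere distance; the
  package reports the Pearson correlation between per-marker homozygote
  frequency and distance to user-supplied centromere coordinates.

## Synthetic data generator

The generator is the package's study environment: its defaults define the
problem sizes the tests and examples run at (5 × 1 Mb chromosomes, GC 0.36,
60 planted EcoRI–MspI fragments of 224–424 bp, a 150 kb chloroplast at
1,200 copies per cell with 5 selected fragments, a 10 kb rRNA unit at 700
copies per haploid with 3 selected fragments, 12-sample pools, diploid F2
populations). Tests use scaled-down configurations of the same generator.

Construction guarantees a known ground truth:

- Planted fragments are written as concrete enzyme sites flanking random
  interiors; interiors are rejection-resampled until a padded window around
  the fragment contains no unintended cut site of the relevant enzymes, so
  digestion recovers each planted fragment exactly.
- Organellar planted fragments carry an internal site of a designated
  cutter (default SnaBI); after genome assembly a fixpoint pass injects
  that site into any *incidental* organellar fragment that lands in the
  size window, so a complete second-round cover exists by construction.
  Genomic planted fragments avoid that cutter.
- Read pools draw source fragments with probability proportional to
  per-cell copy number, so organellar dilution is reproduced; read 1 is
  barcode + fragment 5′ end, read 2 the reverse-complemented 3′ end, with
  optional uniform substitution errors.
- Population VCFs draw offspring classes from the configured model's
  expected frequencies; a configurable fraction of calls is written with
  sub-threshold depth to exercise the filters.

All randomness flows from `numpy.random.default_rng` seeded from the
configuration; sub-generators (genome, read pool, VCF) use fixed small
offsets from the base seed so artifacts are independently reproducible.

## Numerical choices

- Exact integer arithmetic for copy counts; percentage rounding is decimal
  half-up (not banker's rounding) to match conventional table formatting.
- Depth and binning use `numpy` integer arrays; statistics
  (`chi2.sf`, `ttest_1samp`, `pearsonr`) come from `scipy.stats`.
- Zero-variance inputs short-circuit before `pearsonr`/`ttest_1samp` to
  avoid NaNs from exact-constant arrays.
- Bitmask subset enumeration keeps the second-round search exact rather
  than heuristic; its cost is linear in catalog size for incidence and
  cubic (combinations of 3) for enumeration.

## Limitations

- Fragment counting is purely in-silico: methylation sensitivity, star
  activity, partial digestion and PCR bias are not modelled.
- The dilution model treats all fragments in a class as equally amplified;
  real libraries show length- and GC-dependent bias.
- Library evaluation consumes pair spans, not alignments; mapping artifacts
  (multi-mapping, soft-clipping) must be handled upstream.
- Genotype classification ignores allele dosage; autotetraploid duplex
  genotypes are collapsed to allele presence, which is what the expected
  frequencies are stated for.
- The chi-square test relies on the asymptotic distribution; at extreme
  Sidak thresholds and moderate family sizes the discrete tail makes the
  scan slightly conservative (observed in the calibration test).
- The shipped catalog is a curated subset of commercial Type IIP enzymes;
  completeness of the second-round optimum is relative to the catalog used.
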