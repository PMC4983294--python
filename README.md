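# radopt

Design toolkit for optimized RAD-seq (restriction-site-associated DNA
sequencing) experiments in plants: in-silico enzyme selection against
organellar read contamination, plus the downstream bookkeeping — barcode
demultiplexing, library evaluation, variant filtering and segregation
testing — needed to run and check such an experiment.

## The problem

RAD-seq genotypes a population by sequencing only the genome fragments that
flank restriction-enzyme cut sites and fall inside a size-selection window.
In plants this plan collides with copy number: a leaf cell carries one or two
copies of each nuclear locus but hundreds of tandem rRNA gene repeats per
haploid genome and on the order of a thousand chloroplast genomes per cell.
Any rRNA or chloroplast fragment that survives size selection is amplified by
its copy number and can consume most of the sequencing output. With 20,745
genomic, 4 rRNA and 40 chloroplast fragments selected per haploid genome,
700 rRNA copies per haploid genome and 1,200 chloroplast copies per cell, a
diploid library is predicted to spend 50.5 % of its reads on chloroplast
DNA and only 43.6 % on nuclear targets.

`radopt` attacks this in two rounds:

1. **First round** — evaluate combinations of candidate enzymes (default
   EcoRI, HindIII, MspI, MseI) on the nuclear genome, the chloroplast genome
   and the rRNA repeat: keep combinations producing enough size-selected
   genomic fragments (default ≥10,000 in the 224–424 bp window) and rank
   them by the fewest organellar fragments co-selected.
2. **Second round** — exhaustively search a catalog of commercial Type IIP
   enzymes for a small set (≤3) whose sites destroy *every* selected
   organellar fragment while leaving as many genomic fragments intact as
   possible. Cut fragments fail amplification and vanish from the library.

The read-proportion model then predicts the sequencing composition from
per-haploid fragment counts, ploidy and organelle copy numbers, so the gain
from the second digest can be quantified before any sequencing is bought.

## The model

- **Digestion** uses IUPAC-degenerate site matching on both strands with
  top-strand cut coordinates (caret notation, e.g. `G^AATTC`); fragments are
  the cut-to-cut intervals, and overlapping site occurrences all count.
- **Read proportions**: per-cell copies are
  `genomic = n_genomic × ploidy`, `rRNA = n_rRNA × ploidy × 700`,
  `chloroplast = n_chloroplast × 1200` (chloroplast count is per cell, not
  per haploid genome); expected read shares are copies over total copies.
- **Second-round search** is exact set cover by enumeration: a per-enzyme
  bitmask of internally-cut fragments is precomputed once, subsets are
  scored by bitwise union, and enzymes that cut no organellar fragment are
  pruned (they can only destroy genomic targets).
- **Segregation testing** classifies offspring by allele presence
  (homP1 / het / homP2), applies a Pearson chi-square goodness-of-fit test
  per marker and a Sidak-corrected family threshold
  `1 − (1 − α)^(1/m)`. Autotetraploid models include the double-reduction
  coefficient α ∈ [0, 1/6]: duplex×duplex F2 expectations
  (g², 1 − 2g², g²) with g = (1 + 2α)/6, and simplex×nulliplex F1
  expectations (0, ½ − α/4, ½ + α/4).
- **Variant filtering** masks calls below depth 10 or genotype quality 20,
  then rejects sites by the first failing criterion: incomplete parents →
  <7 genotyped offspring → offspring allele absent from both parents →
  more than two alleles.

See [docs/methods.md](docs/methods.md) for assumptions, parameter defaults
and limitations.

## Worked example

The package ships a synthetic-study generator, so the whole workflow runs
without external data. Generate a small study (two 200 kb chromosomes, a
50 kb chloroplast, an rRNA repeat, a barcoded 6-sample read pool and a
60-marker F2 population VCF):

```sh
$ cat config.json
{"seed": 7, "n_chromosomes": 2, "chromosome_length": 200000,
 "n_planted_fragments": 30, "chloroplast_length": 50000,
 "n_chloroplast_fragments": 4, "rrna_unit_length": 9000, "n_rrna_fragments": 2,
 "n_polymorphisms": 50, "n_samples": 6, "reads_per_sample": 500, "n_markers": 60}

$ radopt simulate --config config.json -o study
wrote study/genome.fa, study/chloroplast.fa, study/rrna.bed, study/manifest.json, study/pool and study/population.vcf
```

First-round enzyme search (the threshold is lowered to suit the small
genome):

```sh
$ radopt design --genome study/genome.fa --chloroplast study/chloroplast.fa \
    --rrna study/rrna.bed --min-regions 10 -o design_out
best combination: EcoRI+HindIII (44 selected fragments, 7 organellar)

$ head -3 design_out/first_round.tsv
enzymes	total_fragments	total_coverage	selected_fragments	selected_coverage	organellar_selected	detectable_variants
EcoRI+HindIII	346	0.9791	44	0.0313	7
HindIII+MspI	684	0.9837	134	0.0962	24
```

Second-round search for complete organellar removal after an EcoRI+MspI
digest:

```sh
$ radopt second-round --genome study/genome.fa --chloroplast study/chloroplast.fa \
    --rrna study/rrna.bed --first-round EcoRI,MspI -o second_round.tsv
best set: SnaBI (complete=True, 124 genomic intact)

$ head -3 second_round.tsv
enzymes	complete	organellar_cut	organellar_total	genomic_intact	genomic_total
SnaBI	True	27	27	124	134
SacII+SnaBI	True	27	27	124	134
```

A single enzyme (SnaBI) cuts all 27 selected organellar fragments while
sparing 124 of the 134 genomic ones.

Predicted read composition for a full-scale diploid and tetraploid library:

```sh
$ radopt predict --n-genomic 20745 --n-rrna 4 --n-chloroplast 40
per-cell copies: genomic=41490 rRNA=5600 chloroplast=48000 total=95090
read proportions: genomic=43.6% rRNA=5.9% chloroplast=50.5%

$ radopt predict --n-genomic 20745 --n-rrna 4 --n-chloroplast 40 --ploidy 4
per-cell copies: genomic=82980 rRNA=11200 chloroplast=48000 total=142180
read proportions: genomic=58.4% rRNA=7.9% chloroplast=33.8%
```

Demultiplex the simulated pool and run the family variant filters and
segregation scan:

```sh
$ radopt demux --r1 study/pool/pool.R1.fastq --r2 study/pool/pool.R2.fastq \
    --barcodes study/pool/barcodes.tsv -o demux_out
S01	500	0.1667
S02	500	0.1667
S03	500	0.1667
S04	500	0.1667
S05	500	0.1667
S06	500	0.1667
unassigned	0	0.0000

$ radopt filter-vcf --vcf study/population.vcf --parents P1,P2 -o passing.tsv
passing: 60 / 60
rejected[parents_missing]: 0
rejected[too_few_offspring]: 0
rejected[allele_inconsistency]: 0
rejected[multiallelic]: 0

$ radopt segregate --vcf study/population.vcf --parents P1,P2 -o segregation.tsv
tested 60 markers; 0 significant at Sidak threshold 0.000855
```

Every command is also available as a library call (`radopt.design`,
`radopt.digest`, `radopt.demux`, `radopt.libeval`, `radopt.variantqc`,
`radopt.simulate`).

## Testing and reproduction

The test suite checks the digestion engine and the second-round optimizer
against independent brute-force oracles, the tetraploid expectations against
exact gamete enumeration, and the statistics against `scipy`; stochastic
checks use fixed seeds with tolerances taken from the sampling distribution.

```sh
python -m pytest -q tests/
```

The headline read-composition percentages can be recomputed from scratch
and written as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which reports the diploid chloroplast read percentage (`t4`) and the
tetraploid genomic read percentage (`t5`), each with the per-cell copy
total (`n`) it is computed over.
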