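"""Synthetic inputs with fully known ground truth.

Generates the complete set of inputs a RAD-seq design and QC run consumes —
a nuclear genome with planted, cleanly bounded restriction fragments, a
high-copy chloroplast sequence and rRNA gene array whose size-selected
fragments all carry a site for a designated second-round enzyme, barcoded
paired-end read pools sampled under the per-cell copy-number dilution
model, and segregating-population VCFs — together with truth manifests, so
every downstream module can be tested without external downloads.

The study design emulated throughout is a 12-sample pool (2 parents + 10
offspring), 5 bp inline barcodes, a 224-424 bp size window, 700 rRNA
copies per haploid genome and 1200 chloroplast copies per cell.

Background sequence is i.i.d. with a configurable GC content.  Spurious
recognition sites are rejected only inside planted fragments; incidental
sites elsewhere are allowed (and incidental organellar fragments falling in
the size window are retro-fitted with a second-round cut site), which keeps
generation linear in genome length while guaranteeing that complete
organellar removal exists by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .demux import BarcodeSpec, FastqRecord, write_fastq_record
from .digest import (
    CHLOROPLAST,
    GENOMIC,
    RRNA,
    Fragment,
    SequenceRegion,
    SizeWindow,
    classify_fragments,
    digest,
    size_select,
)
from .enzymes import (
    EnzymeCatalog,
    IUPAC_SETS,
    RestrictionEnzyme,
    find_cut_sites,
    load_default_catalog,
    reverse_complement,
)
from .variantqc import HET, HOM_P1, HOM_P2, SegregationModel, expected_genotype_freqs

__all__ = [
    "SimulationConfig",
    "PlantedFragment",
    "GenomeTruth",
    "simulate_genome",
    "simulate_read_pool",
    "simulate_population_vcf",
    "generate_barcodes",
    "copy_number_weights",
    "sample_fragment_indices",
    "write_genome_files",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults matching the
    emulated design (12-sample pools of 2 parents + 10 offspring, 224-424 bp
    window, 700 rRNA copies per haploid genome, 1200 chloroplast copies per
    cell)."""

    seed: int = 0
    # nuclear genome
    n_chromosomes: int = 5
    chromosome_length: int = 1_000_000
    gc_content: float = 0.36
    n_planted_fragments: int = 60
    planted_enzymes: tuple[str, str] = ("EcoRI", "MspI")
    fragment_length_range: tuple[int, int] = (224, 424)
    avoid_enzymes: tuple[str, ...] = ("SnaBI",)
    n_polymorphisms: int = 100
    # organelles
    chloroplast_length: int = 150_000
    chloroplast_copies_per_cell: int = 1200
    n_chloroplast_fragments: int = 5
    rrna_unit_length: int = 10_000
    rrna_copies_per_haploid: int = 700
    n_rrna_fragments: int = 3
    organellar_cut_enzyme: str = "SnaBI"
    ploidy: int = 2
    # read pool
    n_samples: int = 12
    reads_per_sample: int = 1_000
    read_length: int = 100
    error_rate: float = 0.0
    barcode_length: int = 5
    # segregating population
    population: str = "diploid_F2"
    n_offspring: int = 10
    n_markers: int = 200
    alpha: float = 0.0
    depth_mean: int = 60
    genotype_quality: int = 60
    filter_fail_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        lo, hi = self.fragment_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid fragment_length_range")

    @property
    def window(self) -> SizeWindow:
        return SizeWindow(*self.fragment_length_range)


@dataclass(frozen=True)
class PlantedFragment:
    """Truth record of one planted fragment (cut-to-cut interval)."""

    seq_id: str
    start: int
    end: int
    region_class: str
    left_enzyme: str
    right_enzyme: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeTruth:
    """Synthetic reference plus full ground-truth manifest."""

    regions: list[SequenceRegion]
    planted: list[PlantedFragment]
    polymorphisms: list[tuple[str, int]]
    config: SimulationConfig

    @property
    def regions_by_id(self) -> dict[str, SequenceRegion]:
        return {r.seq_id: r for r in self.regions}


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _concrete_site(enzyme: RestrictionEnzyme) -> str:
    """A fixed A/C/G/T realization of a (possibly degenerate) site."""
    return "".join(min(IUPAC_SETS[sym]) for sym in enzyme.recognition)


def _window_clean(
    window_seq: str,
    check_enzymes: Sequence[RestrictionEnzyme],
    interior: tuple[int, int],
    allowed: dict[str, set[int]],
) -> bool:
    """No check enzyme may cut strictly inside ``interior`` except as allowed."""
    lo, hi = interior
    for enz in check_enzymes:
        ok = allowed.get(enz.name, set())
        for c in find_cut_sites(window_seq, enz):
            if lo < c < hi and c not in ok:
                return False
    return True


def simulate_genome(
    config: SimulationConfig, catalog: EnzymeCatalog | None = None
) -> GenomeTruth:
    """Build the synthetic reference and its truth manifest.

    Planted fragments are bounded by the configured enzyme pair and are
    guaranteed free of internal sites of the planted pair, the avoid list
    and (for genomic fragments) the designated second-round enzyme, so a
    first-round digest recovers them exactly.  Every size-selected
    organellar fragment — planted or incidental — carries at least one
    internal site of the second-round enzyme.
    """
    rng = np.random.default_rng(config.seed)
    catalog = catalog or load_default_catalog()
    left = catalog[config.planted_enzymes[0]]
    right = catalog[config.planted_enzymes[1]]
    cutter = catalog[config.organellar_cut_enzyme]
    check_enzymes = [left, right, cutter] + [
        catalog[n] for n in config.avoid_enzymes if n not in
        {left.name, right.name, cutter.name}
    ]

    site_l, site_r = _concrete_site(left), _concrete_site(right)
    cut_site = _concrete_site(cutter)
    pad = max(len(e.recognition) for e in check_enzymes) + 4
    lo, hi = config.fragment_length_range
    max_span = len(site_l) + hi + len(site_r)

    regions: list[SequenceRegion] = []
    planted: list[PlantedFragment] = []

    # --- nuclear chromosomes -------------------------------------------
    rrna_chrom_idx = config.n_chromosomes - 1
    rrna_start = config.chromosome_length - config.rrna_unit_length - 2 * pad
    per_chrom = _split_evenly(config.n_planted_fragments, config.n_chromosomes)

    for ci in range(config.n_chromosomes):
        seq_id = f"chr{ci + 1}"
        seq = _random_bases(rng, config.chromosome_length, config.gc_content)
        usable = rrna_start - max_span - 2 * pad if ci == rrna_chrom_idx else \
            config.chromosome_length
        k = per_chrom[ci]
        if k:
            spacing = usable // (k + 1)
            if spacing <= max_span + 2 * pad:
                raise ValueError(
                    "infeasible config: planted fragments exceed chromosome capacity"
                )
            for j in range(k):
                pos = spacing * (j + 1)
                frag = _plant_fragment(
                    rng, seq, pos, left, right, site_l, site_r, None, "",
                    check_enzymes, pad, lo, hi, config.gc_content,
                )
                planted.append(
                    PlantedFragment(seq_id, frag[0], frag[1], GENOMIC,
                                    left.name, right.name)
                )
        rrna_intervals = []
        if ci == rrna_chrom_idx:
            rrna_intervals = [(rrna_start, rrna_start + config.rrna_unit_length)]
            # plant rRNA fragments inside the array interval
            k_r = config.n_rrna_fragments
            spacing = config.rrna_unit_length // (k_r + 1)
            if spacing <= max_span + 2 * pad:
                raise ValueError("infeasible config: rRNA fragments exceed array length")
            for j in range(k_r):
                pos = rrna_start + spacing * (j + 1)
                frag = _plant_fragment(
                    rng, seq, pos, left, right, site_l, site_r, cutter, cut_site,
                    check_enzymes, pad, lo, hi, config.gc_content,
                )
                planted.append(
                    PlantedFragment(seq_id, frag[0], frag[1], RRNA,
                                    left.name, right.name)
                )
        regions.append(
            SequenceRegion(seq_id, "".join(seq), GENOMIC, rrna_intervals)
        )

    # --- chloroplast ----------------------------------------------------
    cp_seq = _random_bases(rng, config.chloroplast_length, config.gc_content)
    k_c = config.n_chloroplast_fragments
    if k_c:
        spacing = config.chloroplast_length // (k_c + 1)
        if spacing <= max_span + 2 * pad:
            raise ValueError("infeasible config: chloroplast fragments exceed capacity")
        for j in range(k_c):
            pos = spacing * (j + 1)
            frag = _plant_fragment(
                rng, cp_seq, pos, left, right, site_l, site_r, cutter, cut_site,
                check_enzymes, pad, lo, hi, config.gc_content,
            )
            planted.append(
                PlantedFragment("chloroplast", frag[0], frag[1], CHLOROPLAST,
                                left.name, right.name)
            )
    regions.append(SequenceRegion("chloroplast", "".join(cp_seq), CHLOROPLAST))

    # --- retrofit incidental organellar fragments -----------------------
    _ensure_organellar_cuttable(regions, [left, right], cutter, cut_site,
                                config.window)

    # --- planted polymorphisms ------------------------------------------
    genomic_planted = [p for p in planted if p.region_class == GENOMIC]
    polymorphisms: list[tuple[str, int]] = []
    if config.n_polymorphisms and genomic_planted:
        choice = rng.integers(0, len(genomic_planted), size=config.n_polymorphisms)
        offsets = rng.integers(0, 1 << 30, size=config.n_polymorphisms)
        seen = set()
        for fi, off in zip(choice, offsets):
            frag = genomic_planted[int(fi)]
            pos = frag.start + int(off) % frag.length
            if (frag.seq_id, pos) not in seen:
                seen.add((frag.seq_id, pos))
                polymorphisms.append((frag.seq_id, pos))

    return GenomeTruth(
        regions=regions,
        planted=sorted(planted, key=lambda p: (p.seq_id, p.start)),
        polymorphisms=sorted(polymorphisms),
        config=config,
    )


def _split_evenly(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _plant_fragment(
    rng: np.random.Generator,
    seq: np.ndarray,
    pos: int,
    left: RestrictionEnzyme,
    right: RestrictionEnzyme,
    site_l: str,
    site_r: str,
    interior_enzyme: RestrictionEnzyme | None,
    interior_site: str,
    check_enzymes: Sequence[RestrictionEnzyme],
    pad: int,
    lo: int,
    hi: int,
    gc: float,
    max_tries: int = 500,
) -> tuple[int, int]:
    """Write one planted fragment into ``seq`` starting near ``pos``.

    Returns the cut-to-cut (start, end) interval.  The interior is
    resampled until no check enzyme cuts strictly inside it except the
    intended boundary cuts (and, for organellar fragments, one embedded
    second-round site at the interior midpoint).
    """
    length = int(rng.integers(lo, hi + 1))
    cut_l = pos + left.cut_offset
    cut_r = cut_l + length
    site_r_pos = cut_r - right.cut_offset
    span_end = site_r_pos + len(site_r)

    interior_lo = pos + len(site_l)
    interior_hi = site_r_pos
    if interior_hi < interior_lo:
        raise ValueError("fragment too short for its bounding sites")

    allowed: dict[str, set[int]] = {}
    mid = None
    if interior_enzyme is not None:
        mid = (interior_lo + interior_hi - len(interior_site)) // 2
        allowed[interior_enzyme.name] = {mid - pos + pad + interior_enzyme.cut_offset}
    # boundary cuts of the planted pair are always allowed
    allowed.setdefault(left.name, set()).add(cut_l - pos + pad)
    allowed.setdefault(right.name, set()).add(cut_r - pos + pad)

    for _ in range(max_tries):
        interior = _random_bases(rng, interior_hi - interior_lo, gc)
        seq[pos : pos + len(site_l)] = list(site_l)
        seq[interior_lo:interior_hi] = interior
        seq[site_r_pos:span_end] = list(site_r)
        if interior_enzyme is not None and mid is not None:
            seq[mid : mid + len(interior_site)] = list(interior_site)
        window = "".join(seq[pos - pad : span_end + pad])
        if _window_clean(window, check_enzymes,
                         (cut_l - pos + pad, cut_r - pos + pad), allowed):
            return cut_l, cut_r
    raise ValueError("could not realize a clean planted fragment; relax the config")


def _ensure_organellar_cuttable(
    regions: list[SequenceRegion],
    pair: Sequence[RestrictionEnzyme],
    cutter: RestrictionEnzyme,
    cut_site: str,
    window: SizeWindow,
    max_rounds: int = 30,
) -> None:
    """Inject second-round sites into incidental organellar fragments.

    Repeats digest -> size-select -> classify and overwrites the midpoint
    of every organellar size-selected fragment lacking an internal cutter
    site, until all such fragments are cuttable.  Injection may reshape the
    local fragmentation, hence the fixed-point loop.
    """
    arrays = {r.seq_id: np.array(list(r.sequence)) for r in regions}
    for _ in range(max_rounds):
        for r in regions:
            r.sequence = "".join(arrays[r.seq_id])
        frags = classify_fragments(digest(regions, pair), regions)
        selected = size_select([f for f in frags if not f.is_terminal], window)
        dirty = False
        for frag in selected:
            if frag.region_class == GENOMIC:
                continue
            seq = "".join(arrays[frag.seq_id][frag.start : frag.end])
            if any(0 < c < len(seq) for c in find_cut_sites(seq, cutter)):
                continue
            mid = frag.start + (frag.length - len(cut_site)) // 2
            arrays[frag.seq_id][mid : mid + len(cut_site)] = list(cut_site)
            dirty = True
        if not dirty:
            for r in regions:
                r.sequence = "".join(arrays[r.seq_id])
            return
    raise RuntimeError("organellar retrofit did not converge")


# ---------------------------------------------------------------------------
# read pools
# ---------------------------------------------------------------------------

def generate_barcodes(
    rng: np.random.Generator, n: int, length: int = 5, min_distance: int = 3
) -> list[str]:
    """Random barcode set with a guaranteed pairwise Hamming distance."""
    barcodes: list[str] = []
    tries = 0
    while len(barcodes) < n:
        tries += 1
        if tries > 100_000:
            raise ValueError("cannot satisfy barcode distance constraint")
        cand = "".join(rng.choice(_BASES, size=length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_distance for bc in barcodes):
            barcodes.append(cand)
    return barcodes


def copy_number_weights(
    fragments: Sequence[Fragment], config: SimulationConfig
) -> np.ndarray:
    """Expected per-cell copy number of each fragment.

    Genomic fragments scale with ploidy, rRNA fragments with ploidy times
    the per-haploid array copy number, chloroplast fragments with the
    per-cell chloroplast copy number.
    """
    weights = np.empty(len(fragments), dtype=float)
    for i, frag in enumerate(fragments):
        if frag.region_class == GENOMIC:
            weights[i] = config.ploidy
        elif frag.region_class == RRNA:
            weights[i] = config.ploidy * config.rrna_copies_per_haploid
        elif frag.region_class == CHLOROPLAST:
            weights[i] = config.chloroplast_copies_per_cell
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown class {frag.region_class!r}")
    return weights


def sample_fragment_indices(
    rng: np.random.Generator,
    fragments: Sequence[Fragment],
    config: SimulationConfig,
    n: int,
) -> np.ndarray:
    """Draw source-fragment indices proportional to per-cell copy number."""
    if not fragments:
        raise ValueError("no fragments to sample from")
    w = copy_number_weights(fragments, config)
    return rng.choice(len(fragments), size=n, p=w / w.sum())


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        subs = rng.choice(_BASES, size=int(hit.sum()))
        arr[hit] = subs
    return "".join(arr)


def simulate_read_pool(
    truth: GenomeTruth,
    fragments: Sequence[Fragment],
    out_dir: str | Path,
    config: SimulationConfig | None = None,
    barcodes: Sequence[BarcodeSpec] | None = None,
) -> tuple[list[BarcodeSpec], list[dict]]:
    """Write a barcoded paired-end FASTQ pool plus its truth assignments.

    Each pair draws a source fragment with probability proportional to its
    per-cell copy number; read 1 is the sample barcode followed by the
    fragment 5' end, read 2 the reverse-complemented 3' end.  Substitution
    errors are applied at the configured rate (barcode bases included).
    Returns the barcode table and one truth record per pair
    (read id, sample, fragment index, region class).
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    if barcodes is None:
        codes = generate_barcodes(rng, config.n_samples, config.barcode_length)
        barcodes = [BarcodeSpec(f"S{i + 1:02d}", bc) for i, bc in enumerate(codes)]
    else:
        barcodes = list(barcodes)
    regions_by_id = truth.regions_by_id

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_total = config.reads_per_sample * len(barcodes)
    sources = sample_fragment_indices(rng, fragments, config, n_total)

    records: list[dict] = []
    with open(out_dir / "pool.R1.fastq", "w") as r1, \
            open(out_dir / "pool.R2.fastq", "w") as r2:
        for i in range(n_total):
            spec = barcodes[i // config.reads_per_sample]
            frag = fragments[int(sources[i])]
            frag_seq = regions_by_id[frag.seq_id].sequence[frag.start : frag.end]
            fwd = spec.barcode + frag_seq[: config.read_length]
            rev = reverse_complement(frag_seq)[: config.read_length]
            fwd = _mutate(rng, fwd, config.error_rate)
            rev = _mutate(rng, rev, config.error_rate)
            name = f"pair{i:07d}"
            write_fastq_record(r1, FastqRecord(name, fwd, "I" * len(fwd)))
            write_fastq_record(r2, FastqRecord(name, rev, "I" * len(rev)))
            records.append(
                {
                    "read": name,
                    "sample": spec.sample_id,
                    "fragment": int(sources[i]),
                    "region_class": frag.region_class,
                }
            )
    with open(out_dir / "barcodes.tsv", "w") as fh:
        for spec in barcodes:
            fh.write(f"{spec.sample_id}\t{spec.barcode}\n")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(records, fh)
    return barcodes, records


# ---------------------------------------------------------------------------
# segregating populations
# ---------------------------------------------------------------------------

_CLASS_TO_GT = {HOM_P1: "0/0", HET: "0/1", HOM_P2: "1/1"}


def simulate_population_vcf(
    config: SimulationConfig,
    path: str | Path,
    truth_freqs: tuple[float, float, float] | None = None,
) -> dict:
    """Write a 2-parents + n-offspring VCF of segregating biallelic markers.

    Offspring genotype classes are drawn marker-wise from the expected
    class frequencies of the configured population model (or
    ``truth_freqs``).  A configurable fraction of calls is given a depth
    below the standard filter threshold so that filtering behaviour can be
    exercised.  Returns the truth manifest (per-marker offspring classes).
    """
    rng = np.random.default_rng(config.seed + 2)
    model = SegregationModel(population=config.population, alpha=config.alpha)
    freqs = truth_freqs if truth_freqs is not None else expected_genotype_freqs(model)
    classes = (HOM_P1, HET, HOM_P2)

    if config.population == "diploid_F1_AAxAa":
        parent_gts = ("0/0", "0/1")
    elif config.population == "tetraploid_F1":
        parent_gts = ("0/1", "1/1")  # simplex (presence A,a) x nulliplex (a only)
    else:
        parent_gts = ("0/0", "1/1")
        if config.population == "tetraploid_F2":
            parent_gts = ("0/1", "0/1")  # duplex x duplex: both parents carry A and a

    samples = ["P1", "P2"] + [f"O{i + 1:02d}" for i in range(config.n_offspring)]
    truth: dict = {"markers": []}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("##contig=<ID=chr1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for m in range(config.n_markers):
            pos = 1000 * m + 100
            drawn = rng.choice(3, size=config.n_offspring, p=np.asarray(freqs))
            offspring_classes = [classes[int(d)] for d in drawn]
            calls = []
            gts = list(parent_gts) + [_CLASS_TO_GT[c] for c in offspring_classes]
            for gt in gts:
                if rng.random() < config.filter_fail_fraction:
                    dp = 5  # below the depth-10 filter
                else:
                    dp = config.depth_mean
                calls.append(f"{gt}:{dp}:{config.genotype_quality}")
            fh.write(
                f"chr1\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT:DP:GQ\t" + "\t".join(calls) + "\n"
            )
            truth["markers"].append(
                {"seq_id": "chr1", "pos": pos, "classes": offspring_classes}
            )
    return truth


# ---------------------------------------------------------------------------
# file writers
# ---------------------------------------------------------------------------

def write_genome_files(truth: GenomeTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write genome/chloroplast FASTA, rRNA BED and the JSON truth manifest."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "chloroplast": out_dir / "chloroplast.fa",
        "rrna_bed": out_dir / "rrna.bed",
        "manifest": out_dir / "manifest.json",
    }
    nuclear = [r for r in truth.regions if r.region_class == GENOMIC]
    organellar = [r for r in truth.regions if r.region_class == CHLOROPLAST]
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in nuclear],
        paths["genome"], "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in organellar],
        paths["chloroplast"], "fasta",
    )
    with open(paths["rrna_bed"], "w") as fh:
        for r in nuclear:
            for s, e in r.rrna_intervals:
                fh.write(f"{r.seq_id}\t{s}\t{e}\trRNA\n")
    manifest = {
        "planted": [asdict(p) for p in truth.planted],
        "polymorphisms": [list(p) for p in truth.polymorphisms],
        "config": asdict(truth.config),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1)
    return paths
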