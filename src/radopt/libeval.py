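"""Post-mapping evaluation of RAD-seq libraries.

Works on pair outer spans — the interval from the leftmost mate start to
the rightmost mate end — rather than on alignment records, so the module is
not bound to a particular aligner output.  The outer span equals the
sequenced fragment, which is the unit the design targets: read-class
proportions, fragment-length recovery, per-base depth inside the selected
regions, cross-sample consistency and marker density per genome bin are
all fragment-centric summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digest import CHLOROPLAST, GENOMIC, RRNA, SequenceRegion

__all__ = [
    "MappedPair",
    "BinGrid",
    "ClassifiedReads",
    "LengthDistribution",
    "DepthSummary",
    "classify_mapped_reads",
    "fragment_length_distribution",
    "depth_summary",
    "bin_marker_coverage",
    "read_pairs_from_tsv",
]


@dataclass(frozen=True)
class MappedPair:
    """Outer span of a mapped read pair."""

    seq_id: str
    outer_start: int
    outer_end: int
    sample_id: str = ""
    mapping_quality: float = 60.0
    mean_base_quality: float | None = None

    def __post_init__(self) -> None:
        if not self.outer_start < self.outer_end:
            raise ValueError("outer_start must be < outer_end")

    @property
    def length(self) -> int:
        return self.outer_end - self.outer_start


@dataclass
class ClassifiedReads:
    """Read-pair counts and proportions per reference class."""

    counts: dict[str, int]
    excluded_by_quality: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float] | None:
        total = self.total
        if total == 0:
            return None
        return {k: v / total for k, v in self.counts.items()}


@dataclass
class LengthDistribution:
    lengths: np.ndarray
    in_window: int

    @property
    def fraction_in_window(self) -> float:
        return self.in_window / len(self.lengths) if len(self.lengths) else float("nan")

    def histogram(self, bin_width: int = 10) -> tuple[np.ndarray, np.ndarray]:
        lo = int(self.lengths.min()) if len(self.lengths) else 0
        hi = int(self.lengths.max()) + bin_width if len(self.lengths) else bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(self.lengths, bins=edges)
        return counts, edges


@dataclass
class DepthSummary:
    """Per-sample covered base pairs and cross-sample consistency."""

    covered_bp: dict[str, dict[int, int]]  # sample -> threshold -> bp
    consistent_deep_bp: dict[int, int]  # min samples k -> bp deep in >= k samples
    deep_threshold: int


def _rrna_lookup(regions: Iterable[SequenceRegion]):
    by_id = {}
    for r in regions:
        by_id[r.seq_id] = (r.region_class, sorted(r.rrna_intervals), r.length)
    return by_id


def _classify_span(seq_id: str, start: int, end: int, lookup) -> str:
    if seq_id not in lookup:
        raise KeyError(f"unknown sequence {seq_id!r}")
    cls, rrna, _ = lookup[seq_id]
    if cls != GENOMIC:
        return cls
    for s, e in rrna:
        if s < end and start < e:
            return RRNA
    return GENOMIC


def classify_mapped_reads(
    pairs: Iterable[MappedPair],
    regions: Iterable[SequenceRegion],
    unmapped: int = 0,
    min_mapping_quality: float = 20.0,
    min_base_quality: float = 20.0,
) -> ClassifiedReads:
    """Proportions of read pairs mapping to each reference class.

    Alignment is external; this classifies already-mapped pair spans, with
    the unmapped pair count supplied separately.  Pairs below the mapping-
    or base-quality thresholds are excluded before classification (an rRNA
    overlap beats genomic on any shared base).  Proportions are reported
    over {genomic, chloroplast, rRNA, unmapped}; with every mapped pair
    excluded and no unmapped reads, proportions are undefined and reported
    as ``None``.
    """
    lookup = _rrna_lookup(regions)
    counts = {GENOMIC: 0, CHLOROPLAST: 0, RRNA: 0, "unmapped": unmapped}
    excluded = 0
    for p in pairs:
        if p.mapping_quality < min_mapping_quality or (
            p.mean_base_quality is not None and p.mean_base_quality < min_base_quality
        ):
            excluded += 1
            continue
        counts[_classify_span(p.seq_id, p.outer_start, p.outer_end, lookup)] += 1
    return ClassifiedReads(counts=counts, excluded_by_quality=excluded)


def fragment_length_distribution(
    pairs: Iterable[MappedPair], window
) -> LengthDistribution:
    """Outer-span length distribution and the fraction inside the size window."""
    lengths = np.asarray([p.length for p in pairs], dtype=int)
    in_window = int(np.sum((lengths >= window.min_bp) & (lengths <= window.max_bp)))
    return LengthDistribution(lengths=lengths, in_window=in_window)


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def depth_summary(
    pairs_by_sample: Mapping[str, Sequence[MappedPair]],
    chromosome_lengths: Mapping[str, int],
    selected_regions: Sequence[tuple[str, int, int]] | None = None,
    thresholds: Sequence[int] = (2, 10),
    deep_threshold: int = 10,
    min_consistent_samples: Sequence[int] | None = None,
) -> tuple[DepthSummary, DepthSummary | None]:
    """Covered base pairs per sample genome-wide and in the selected regions.

    Per-base depth counts the pair outer spans covering a base; a base is
    covered at threshold t when its depth is >= t.  Cross-sample
    consistency counts bases whose depth reaches ``deep_threshold`` in at
    least k of the samples.  Returns (genome-wide summary, selected-region
    summary) — the latter ``None`` when no regions are given.  Overlapping
    selected regions are merged with a warning.
    """
    samples = sorted(pairs_by_sample)
    n_samples = len(samples)
    if min_consistent_samples is None:
        min_consistent_samples = [max(1, n_samples - 2)] if n_samples else []

    sel_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if selected_regions is not None:
        for seq_id, s, e in selected_regions:
            sel_by_chrom.setdefault(seq_id, []).append((s, e))
        for seq_id, ivals in sel_by_chrom.items():
            merged = _merge_intervals(ivals)
            if len(merged) != len(ivals):
                warnings.warn(f"{seq_id}: overlapping selected regions merged")
            sel_by_chrom[seq_id] = merged

    # depth[sample][chrom] as int arrays via difference accumulation
    depth: dict[str, dict[str, np.ndarray]] = {}
    for sample in samples:
        per_chrom: dict[str, np.ndarray] = {}
        diffs = {
            chrom: np.zeros(length + 1, dtype=np.int32)
            for chrom, length in chromosome_lengths.items()
        }
        for p in pairs_by_sample[sample]:
            if p.seq_id not in diffs:
                raise KeyError(f"pair on unknown sequence {p.seq_id!r}")
            diffs[p.seq_id][p.outer_start] += 1
            diffs[p.seq_id][min(p.outer_end, chromosome_lengths[p.seq_id])] -= 1
        for chrom, d in diffs.items():
            per_chrom[chrom] = np.cumsum(d[:-1])
        depth[sample] = per_chrom

    def summarize(region_masks: dict[str, np.ndarray] | None) -> DepthSummary:
        covered: dict[str, dict[int, int]] = {}
        for sample in samples:
            covered[sample] = {}
            for t in thresholds:
                bp = 0
                for chrom, d in depth[sample].items():
                    mask = d >= t
                    if region_masks is not None:
                        mask = mask & region_masks[chrom]
                    bp += int(mask.sum())
                covered[sample][t] = bp
        consistent: dict[int, int] = {}
        for k in min_consistent_samples:
            bp = 0
            for chrom in chromosome_lengths:
                deep_count = np.zeros(chromosome_lengths[chrom], dtype=np.int16)
                for sample in samples:
                    deep_count += depth[sample][chrom] >= deep_threshold
                mask = deep_count >= k
                if region_masks is not None:
                    mask = mask & region_masks[chrom]
                bp += int(mask.sum())
            consistent[k] = bp
        return DepthSummary(covered_bp=covered, consistent_deep_bp=consistent,
                            deep_threshold=deep_threshold)

    genome_summary = summarize(None)
    selected_summary = None
    if selected_regions is not None:
        masks = {}
        for chrom, length in chromosome_lengths.items():
            m = np.zeros(length, dtype=bool)
            for s, e in sel_by_chrom.get(chrom, []):
                m[s:e] = True
            masks[chrom] = m
        selected_summary = summarize(masks)
    return genome_summary, selected_summary


@dataclass
class BinGrid:
    """Equal half-open bins tiling each chromosome (last bin may be short)."""

    bins: dict[str, list[tuple[int, int]]]

    @classmethod
    def from_bin_size(cls, chromosome_lengths: Mapping[str, int], bin_size: int) -> "BinGrid":
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        bins = {}
        for chrom, length in chromosome_lengths.items():
            edges = list(range(0, length, bin_size)) + [length]
            bins[chrom] = [(a, b) for a, b in zip(edges[:-1], edges[1:])]
        return cls(bins=bins)

    @classmethod
    def from_total_bins(cls, chromosome_lengths: Mapping[str, int], n_bins: int) -> "BinGrid":
        """Split the genome into approximately ``n_bins`` equal physical bins.

        Bins are apportioned to chromosomes proportionally to length; this
        mirrors the common practice of approximating 1 cM intervals by equal
        physical intervals when no genetic map is available.
        """
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        total = sum(chromosome_lengths.values())
        bins = {}
        for chrom, length in chromosome_lengths.items():
            k = max(1, round(n_bins * length / total))
            edges = np.linspace(0, length, k + 1).astype(int)
            bins[chrom] = [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]
        return cls(bins=bins)

    @property
    def n_bins(self) -> int:
        return sum(len(v) for v in self.bins.values())


def bin_marker_coverage(
    markers: Iterable[tuple[str, int]], grid: BinGrid
) -> tuple[int, float]:
    """Count and fraction of bins containing at least one marker.

    Markers are (seq_id, 0-based position); bin membership is half-open.
    Markers outside the grid extent (or on unknown chromosomes) are ignored
    with a warning.
    """
    nonempty: set[tuple[str, int]] = set()
    ignored = 0
    for seq_id, pos in markers:
        bins = grid.bins.get(seq_id)
        if bins is None:
            ignored += 1
            continue
        # bins are contiguous from 0; locate by scanning edges
        idx = None
        for i, (s, e) in enumerate(bins):
            if s <= pos < e:
                idx = i
                break
        if idx is None:
            ignored += 1
            continue
        nonempty.add((seq_id, idx))
    if ignored:
        warnings.warn(f"{ignored} marker(s) outside the bin grid ignored")
    total = grid.n_bins
    return len(nonempty), len(nonempty) / total if total else float("nan")


def read_pairs_from_tsv(path) -> list[MappedPair]:
    """Load pair outer spans from a ``seq_id start end sample_id mapq`` TSV."""
    pairs = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed pair-span line: {line!r}")
            pairs.append(
                MappedPair(
                    seq_id=parts[0],
                    outer_start=int(parts[1]),
                    outer_end=int(parts[2]),
                    sample_id=parts[3] if len(parts) > 3 else "",
                    mapping_quality=float(parts[4]) if len(parts) > 4 else 60.0,
                )
            )
    return pairs
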