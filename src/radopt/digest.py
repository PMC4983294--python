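"""Complete in-silico digestion, fragment classification and size selection.

A digestion of a sequence with a set of enzymes produces fragments that tile
the sequence exactly: the cut coordinates are the union of every enzyme's
cut sites, fragments are the intervals between consecutive cuts, and the two
terminal intervals are flagged with the ``SEQ_END`` sentinel on their outer
boundary.  All intervals are 0-based half-open.

Region classes follow the make-up of a plant reference used for RAD-seq
design: nuclear chromosomes (``genomic``), the chloroplast genome
(``chloroplast``), and annotated rRNA gene arrays on nuclear chromosomes
(``rRNA``).  Chloroplast and rRNA sequences are present in hundreds to
thousands of copies per cell, so fragments drawn from them must be tracked
separately from single-copy genomic fragments.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .enzymes import RestrictionEnzyme, find_cut_sites

__all__ = [
    "SEQ_END",
    "GENOMIC",
    "CHLOROPLAST",
    "RRNA",
    "SequenceRegion",
    "Fragment",
    "SizeWindow",
    "digest",
    "size_select",
    "classify_fragments",
    "filter_by_end_composition",
    "fragment_sequence",
]

SEQ_END = "SEQ_END"

GENOMIC = "genomic"
CHLOROPLAST = "chloroplast"
RRNA = "rRNA"
_CLASSES = (GENOMIC, CHLOROPLAST, RRNA)


@dataclass
class SequenceRegion:
    """A reference sequence with its region class and optional rRNA annotation.

    ``rrna_intervals`` are half-open intervals on a *genomic* sequence marking
    rRNA gene arrays; fragments overlapping them classify as rRNA.
    """

    seq_id: str
    sequence: str
    region_class: str = GENOMIC
    rrna_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.region_class not in _CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for start, end in self.rrna_intervals:
            if not (0 <= start < end <= n):
                raise ValueError(
                    f"{self.seq_id}: rRNA interval [{start}, {end}) outside [0, {n})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Fragment:
    """Half-open genomic interval bounded by enzyme cuts (or sequence ends)."""

    seq_id: str
    start: int
    end: int
    left_cutter: str = SEQ_END
    right_cutter: str = SEQ_END
    region_class: str = GENOMIC

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid fragment interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_terminal(self) -> bool:
        return self.left_cutter == SEQ_END or self.right_cutter == SEQ_END


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-length window retained by size selection.

    The default 224-424 bp window targets the insert range suited to
    Illumina paired-end sequencing of RAD libraries.
    """

    min_bp: int = 224
    max_bp: int = 424

    def __post_init__(self) -> None:
        if not 1 <= self.min_bp <= self.max_bp:
            raise ValueError(f"invalid size window [{self.min_bp}, {self.max_bp}]")

    def __contains__(self, length: int) -> bool:
        return self.min_bp <= length <= self.max_bp


def digest(
    regions: Iterable[SequenceRegion],
    enzymes: Iterable[RestrictionEnzyme],
    cut_cache: Mapping[tuple[str, str], Sequence[int]] | None = None,
) -> list[Fragment]:
    """Completely digest every region with the union of the given enzymes.

    Internal boundaries are labelled with the enzyme(s) cutting there; when
    several enzymes share a coordinate all are recorded, joined by ``+`` in
    deterministic name order.  Terminal fragments carry ``SEQ_END``.

    ``cut_cache`` optionally maps ``(seq_id, enzyme_name)`` to precomputed
    cut coordinates, so that combination searches scan each sequence once
    per enzyme rather than once per combination.
    """
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("at least one enzyme is required")
    regions = list(regions)
    if not regions:
        raise ValueError("no sequences to digest")

    fragments: list[Fragment] = []
    for region in regions:
        n = region.length
        cutters: dict[int, list[str]] = {}
        for enz in enzymes:
            if cut_cache is not None and (region.seq_id, enz.name) in cut_cache:
                cuts: Sequence[int] = cut_cache[(region.seq_id, enz.name)]
            else:
                cuts = find_cut_sites(region.sequence, enz)
            for c in cuts:
                cutters.setdefault(c, []).append(enz.name)
        if n == 0:
            continue
        # A cut at coordinate 0 or n leaves no residual terminal fragment:
        # it merges with the sequence boundary and the adjacent fragment is
        # labelled with the cutting enzyme rather than SEQ_END.
        boundaries = sorted(set(cutters) | {0, n})
        for start, end in zip(boundaries[:-1], boundaries[1:]):
            left = "+".join(sorted(cutters[start])) if start in cutters else SEQ_END
            right = "+".join(sorted(cutters[end])) if end in cutters else SEQ_END
            fragments.append(
                Fragment(
                    seq_id=region.seq_id,
                    start=start,
                    end=end,
                    left_cutter=left,
                    right_cutter=right,
                    region_class=region.region_class,
                )
            )
    return fragments


def size_select(fragments: Iterable[Fragment], window: SizeWindow) -> list[Fragment]:
    """Keep fragments whose length lies inside the inclusive window."""
    return [f for f in fragments if f.length in window]


def classify_fragments(
    fragments: Iterable[Fragment], regions: Iterable[SequenceRegion]
) -> list[Fragment]:
    """Assign a region class to each fragment.

    Fragments on a chloroplast sequence are chloroplast; fragments
    overlapping (by at least 1 bp) an annotated rRNA interval are rRNA;
    everything else is genomic.
    """
    by_id: dict[str, SequenceRegion] = {}
    rrna_starts: dict[str, list[int]] = {}
    rrna_ends: dict[str, list[int]] = {}
    for region in regions:
        by_id[region.seq_id] = region
        ivals = sorted(region.rrna_intervals)
        rrna_starts[region.seq_id] = [s for s, _ in ivals]
        rrna_ends[region.seq_id] = [e for _, e in ivals]

    out: list[Fragment] = []
    for frag in fragments:
        if frag.seq_id not in by_id:
            raise KeyError(f"fragment on unknown sequence {frag.seq_id!r}")
        region = by_id[frag.seq_id]
        cls = region.region_class
        if cls == GENOMIC and rrna_starts[frag.seq_id]:
            if _overlaps_any(frag.start, frag.end, rrna_starts[frag.seq_id], rrna_ends[frag.seq_id]):
                cls = RRNA
        out.append(replace(frag, region_class=cls))
    return out


def _overlaps_any(start: int, end: int, ival_starts: list[int], ival_ends: list[int]) -> bool:
    # Intervals are sorted and assumed non-overlapping; check the neighbour
    # intervals around the insertion point.
    i = bisect_right(ival_starts, start)
    if i > 0 and ival_ends[i - 1] > start:
        return True
    return i < len(ival_starts) and ival_starts[i] < end


def _ends(frag: Fragment) -> list[set[str]]:
    return [
        set() if frag.left_cutter == SEQ_END else set(frag.left_cutter.split("+")),
        set() if frag.right_cutter == SEQ_END else set(frag.right_cutter.split("+")),
    ]


def filter_by_end_composition(
    fragments: Iterable[Fragment],
    barcoded_enzymes: set[str],
    universal_enzymes: set[str],
    mode: str = "all",
) -> list[Fragment]:
    """Filter fragments by which adapter class each end can accept.

    ``all`` keeps everything; ``one_rare_end`` requires at least one end cut
    by a barcoded-adapter enzyme; ``mixed_ends`` models ddRAD
    sequenceability, requiring exactly one barcoded end and one universal
    end.  A ``SEQ_END`` boundary never qualifies as either.
    """
    fragments = list(fragments)
    if mode == "all":
        return fragments
    if mode not in ("one_rare_end", "mixed_ends"):
        raise ValueError(f"unknown end-composition mode {mode!r}")

    kept = []
    for frag in fragments:
        left, right = _ends(frag)
        if mode == "one_rare_end":
            if (left & barcoded_enzymes) or (right & barcoded_enzymes):
                kept.append(frag)
        else:  # mixed_ends
            lb, rb = bool(left & barcoded_enzymes), bool(right & barcoded_enzymes)
            lu, ru = bool(left & universal_enzymes), bool(right & universal_enzymes)
            if (lb and ru and not rb) or (rb and lu and not lb):
                kept.append(frag)
    return kept


def fragment_sequence(fragment: Fragment, regions_by_id: Mapping[str, SequenceRegion]) -> str:
    """Residues of a fragment looked up from its source region."""
    return regions_by_id[fragment.seq_id].sequence[fragment.start : fragment.end]
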