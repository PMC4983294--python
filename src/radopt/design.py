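"""Enzyme-combination search and read-yield prediction for RAD-seq design.

The design problem has two rounds.  The first round picks a combination of
common restriction enzymes whose complete digest of the nuclear genome
yields at least the required number of fragments inside the size-selection
window, while producing as few size-selected fragments from the chloroplast
genome and rRNA gene arrays as possible.  The second round searches the full
catalog of commercial enzymes for a small set whose sites destroy *every*
size-selected organellar fragment while leaving the maximum number of
genomic fragments intact — a weighted set-cover-style problem solved
exactly by exhaustive enumeration over precomputed cut incidences.

The read-proportion model converts per-haploid fragment counts into
expected per-cell fragment copies: nuclear fragments scale with ploidy,
rRNA fragments with ploidy times the rRNA array copy number per haploid
genome, and chloroplast fragments with the (ploidy-independent) chloroplast
copy number per cell.  Equimolar pooling then makes expected read-class
proportions equal to per-cell copy proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .digest import (
    CHLOROPLAST,
    GENOMIC,
    RRNA,
    Fragment,
    SequenceRegion,
    SizeWindow,
    classify_fragments,
    digest,
    filter_by_end_composition,
    size_select,
)
from .enzymes import EnzymeCatalog, RestrictionEnzyme, find_cut_sites

__all__ = [
    "ComboStats",
    "SecondRoundResult",
    "ReadProportionModel",
    "ReadProportions",
    "DesignConfig",
    "first_round_search",
    "second_round_search",
    "build_cut_incidence",
    "predict_read_proportions",
    "expected_coverage",
    "expected_sample_share",
    "count_covered_polymorphisms",
]


@dataclass
class DesignConfig:
    """Parameters of the first-round combination search.

    Defaults mirror a typical plant design: four widely used enzymes as
    candidates, at least 10,000 size-selected fragments, and a 224-424 bp
    window.
    """

    candidate_first_round: tuple[str, ...] = ("EcoRI", "HindIII", "MspI", "MseI")
    min_regions: int = 10_000
    window: SizeWindow = field(default_factory=SizeWindow)
    max_first_round_combo: int = 3
    max_second_round_combo: int = 3
    end_mode: str = "all"
    barcoded_enzymes: frozenset[str] = frozenset({"EcoRI", "HindIII"})
    universal_enzymes: frozenset[str] = frozenset({"MspI", "MseI"})
    include_terminal: bool = False

    def __post_init__(self) -> None:
        if self.min_regions < 1:
            raise ValueError("min_regions must be >= 1")
        if self.max_first_round_combo < 1 or self.max_second_round_combo < 1:
            raise ValueError("combination sizes must be >= 1")


@dataclass
class ComboStats:
    """Digest statistics of one first-round enzyme combination."""

    enzymes: tuple[str, ...]
    total_fragments: int
    total_coverage_fraction: float
    selected_fragments: int
    selected_coverage_fraction: float
    organellar_selected: int
    detectable_variants: int | None = None

    def __post_init__(self) -> None:
        if not (
            0 <= self.organellar_selected <= self.selected_fragments <= self.total_fragments
        ):
            raise ValueError("inconsistent fragment counts")


@dataclass
class SecondRoundResult:
    """Outcome of one candidate second-round enzyme set."""

    enzymes: tuple[str, ...]
    organellar_cut: int
    organellar_total: int
    genomic_cut: int
    genomic_total: int
    intact_variants: int | None = None

    @property
    def genomic_intact(self) -> int:
        return self.genomic_total - self.genomic_cut

    @property
    def complete(self) -> bool:
        return self.organellar_cut == self.organellar_total


@dataclass
class ReadProportionModel:
    """Per-haploid selected fragment counts and copy-number parameters.

    ``rrna_copies_per_haploid`` defaults to 700 and
    ``chloroplast_copies_per_cell`` to 1200, the mid-range copy numbers
    reported for Arabidopsis leaf tissue.
    """

    n_genomic: int
    n_rrna: int
    n_chloroplast: int
    rrna_copies_per_haploid: int = 700
    chloroplast_copies_per_cell: int = 1200
    ploidy: int = 2

    def __post_init__(self) -> None:
        for name in ("n_genomic", "n_rrna", "n_chloroplast",
                     "rrna_copies_per_haploid", "chloroplast_copies_per_cell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


@dataclass
class ReadProportions:
    """Expected per-cell fragment copies and read-class proportions."""

    genomic_copies: int
    rrna_copies: int
    chloroplast_copies: int

    @property
    def total_copies(self) -> int:
        return self.genomic_copies + self.rrna_copies + self.chloroplast_copies

    @property
    def genomic(self) -> float:
        return self.genomic_copies / self.total_copies

    @property
    def rrna(self) -> float:
        return self.rrna_copies / self.total_copies

    @property
    def chloroplast(self) -> float:
        return self.chloroplast_copies / self.total_copies

    def as_percentages(self, ndigits: int = 1) -> tuple[float, float, float]:
        """Proportions as percentages, rounded half-up to ``ndigits``."""
        return tuple(_round_half_up(100.0 * p, ndigits) for p in
                     (self.genomic, self.rrna, self.chloroplast))


def _round_half_up(x: float, ndigits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def predict_read_proportions(model: ReadProportionModel) -> ReadProportions:
    """Expected read-class proportions under equimolar pooling.

    Genomic and rRNA fragment copies scale with ploidy (rRNA additionally
    with its per-haploid array copy number); chloroplast copies are counted
    per cell and do not scale with nuclear ploidy.
    """
    result = ReadProportions(
        genomic_copies=model.n_genomic * model.ploidy,
        rrna_copies=model.n_rrna * model.ploidy * model.rrna_copies_per_haploid,
        chloroplast_copies=model.n_chloroplast * model.chloroplast_copies_per_cell,
    )
    if result.total_copies == 0:
        raise ValueError("all fragment classes are empty; proportions undefined")
    return result


def expected_coverage(read_pairs_per_sample: int, target_fragments: int) -> float:
    """Average read-pair coverage per targeted fragment."""
    if target_fragments < 1:
        raise ValueError("target_fragments must be >= 1")
    if read_pairs_per_sample < 0:
        raise ValueError("read_pairs_per_sample must be non-negative")
    return read_pairs_per_sample / target_fragments


def expected_sample_share(pool_size: int) -> float:
    """Expected per-sample read fraction in an equimolar pool."""
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    return 1.0 / pool_size


def count_covered_polymorphisms(
    fragments: Iterable[Fragment],
    positions: Iterable[tuple[str, int]],
) -> int:
    """Number of known polymorphic positions inside any fragment interval.

    Positions are (seq_id, 0-based coordinate); membership is half-open.
    Positions on sequences absent from the fragment set are skipped with a
    warning.  Each position counts at most once.
    """
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for frag in fragments:
        by_seq.setdefault(frag.seq_id, []).append((frag.start, frag.end))
    for ivals in by_seq.values():
        ivals.sort()

    from bisect import bisect_right

    count = 0
    skipped = 0
    for seq_id, pos in set(positions):
        ivals = by_seq.get(seq_id)
        if ivals is None:
            skipped += 1
            continue
        i = bisect_right(ivals, (pos, float("inf")))
        if i > 0 and ivals[i - 1][0] <= pos < ivals[i - 1][1]:
            count += 1
    if skipped:
        warnings.warn(f"{skipped} polymorphism position(s) on unknown sequences skipped")
    return count


def first_round_search(
    regions: Sequence[SequenceRegion],
    catalog: EnzymeCatalog,
    config: DesignConfig,
    polymorphisms: Sequence[tuple[str, int]] | None = None,
) -> list[ComboStats]:
    """Evaluate and rank every candidate first-round enzyme combination.

    Combinations of size 2 up to ``max_first_round_combo`` are each run
    through digest -> size-select -> classify.  Ranking: combinations
    meeting the ``min_regions`` requirement first, then fewest organellar
    size-selected fragments, then most detectable variants (when a
    polymorphism list is given), then most selected fragments; remaining
    ties break on lexicographic enzyme names.  Terminal fragments are
    excluded from the statistics unless ``config.include_terminal``.
    """
    regions = sorted(regions, key=lambda r: r.seq_id)
    if not regions or all(r.length == 0 for r in regions):
        raise ValueError("empty genome")
    candidates = [catalog[name] for name in config.candidate_first_round]
    total_bp = sum(r.length for r in regions)

    # Scan each sequence once per candidate enzyme; combination evaluation
    # reuses the cached cut coordinates.
    cut_cache: dict[tuple[str, str], list[int]] = {
        (region.seq_id, enz.name): find_cut_sites(region.sequence, enz)
        for region in regions
        for enz in candidates
    }

    results: list[ComboStats] = []
    max_k = min(config.max_first_round_combo, len(candidates))
    for k in range(2, max_k + 1):
        for combo in combinations(sorted(candidates, key=lambda e: e.name), k):
            frags = digest(regions, combo, cut_cache=cut_cache)
            if not config.include_terminal:
                frags = [f for f in frags if not f.is_terminal]
            frags = classify_fragments(frags, regions)
            frags = filter_by_end_composition(
                frags,
                set(config.barcoded_enzymes),
                set(config.universal_enzymes),
                config.end_mode,
            )
            selected = size_select(frags, config.window)
            organellar = [f for f in selected if f.region_class != GENOMIC]
            genomic_selected = [f for f in selected if f.region_class == GENOMIC]
            detectable = (
                count_covered_polymorphisms(genomic_selected, polymorphisms)
                if polymorphisms is not None
                else None
            )
            results.append(
                ComboStats(
                    enzymes=tuple(e.name for e in combo),
                    total_fragments=len(frags),
                    total_coverage_fraction=sum(f.length for f in frags) / total_bp,
                    selected_fragments=len(selected),
                    selected_coverage_fraction=sum(f.length for f in selected) / total_bp,
                    organellar_selected=len(organellar),
                    detectable_variants=detectable,
                )
            )

    if all(r.selected_fragments == 0 for r in results):
        warnings.warn("no combination yields any size-selected fragment")

    def rank_key(stats: ComboStats):
        return (
            stats.selected_fragments < config.min_regions,
            stats.organellar_selected,
            -(stats.detectable_variants or 0),
            -stats.selected_fragments,
            stats.enzymes,
        )

    results.sort(key=rank_key)
    return results


def build_cut_incidence(
    fragments: Sequence[Fragment],
    residues: Sequence[str],
    catalog: Iterable[RestrictionEnzyme],
) -> dict[str, int]:
    """Bitmask per enzyme of which fragments it cuts internally.

    Bit ``i`` of ``incidence[name]`` is set when the enzyme has at least one
    cut site strictly inside fragment ``i`` (a cut at a fragment boundary
    cannot exist after the first-round digest and would not destroy it).
    Each (enzyme, fragment) pair is scanned exactly once; subset evaluation
    afterwards is a pure bitwise union, which is what keeps the exhaustive
    triple enumeration over a couple of hundred enzymes tractable.
    """
    if len(fragments) != len(residues):
        raise ValueError("fragments and residues differ in length")
    incidence: dict[str, int] = {}
    for enz in catalog:
        mask = 0
        for i, seq in enumerate(residues):
            if any(0 < c < len(seq) for c in find_cut_sites(seq, enz)):
                mask |= 1 << i
        incidence[enz.name] = mask
    return incidence


def second_round_search(
    fragments: Sequence[Fragment],
    residues: Sequence[str],
    catalog: EnzymeCatalog,
    max_combo_size: int = 3,
    top_k: int = 10,
    variant_positions: Sequence[tuple[str, int]] | None = None,
    prune: bool = True,
) -> list[SecondRoundResult]:
    """Exhaustively search enzyme sets destroying all organellar fragments.

    Every subset of size 1..``max_combo_size`` of the (pruned) catalog is
    scored; a fragment counts as cut when at least one subset member has a
    site inside it.  Ranking: complete organellar removal first, then most
    genomic fragments left intact, then fewer enzymes, then lexicographic
    names.  Enzymes cutting no organellar fragment are pruned before
    enumeration when ``prune`` is set — they can only destroy genomic
    fragments, so no optimal complete set contains one.

    Returns the ``top_k`` best results.  With no organellar fragments the
    empty enzyme set is the optimum; when no subset achieves complete
    removal the best incomplete subsets are returned with a warning.
    """
    if not fragments:
        raise ValueError("empty fragment set")
    incidence = build_cut_incidence(fragments, residues, catalog)

    org_mask = 0
    gen_mask = 0
    for i, frag in enumerate(fragments):
        if frag.region_class == GENOMIC:
            gen_mask |= 1 << i
        else:
            org_mask |= 1 << i
    organellar_total = org_mask.bit_count()
    genomic_total = gen_mask.bit_count()

    variant_masks: list[int] | None = None
    if variant_positions is not None:
        variant_masks = []
        for seq_id, pos in variant_positions:
            m = 0
            for i, frag in enumerate(fragments):
                if frag.region_class == GENOMIC and frag.seq_id == seq_id and frag.start <= pos < frag.end:
                    m |= 1 << i
            variant_masks.append(m)

    def score(names: tuple[str, ...]) -> SecondRoundResult:
        union = 0
        for n in names:
            union |= incidence[n]
        intact_variants = None
        if variant_masks is not None:
            intact_gen = gen_mask & ~union
            intact_variants = sum(1 for m in variant_masks if m & intact_gen)
        return SecondRoundResult(
            enzymes=names,
            organellar_cut=(union & org_mask).bit_count(),
            organellar_total=organellar_total,
            genomic_cut=(union & gen_mask).bit_count(),
            genomic_total=genomic_total,
            intact_variants=intact_variants,
        )

    if organellar_total == 0:
        return [score(())]

    names = sorted(incidence)
    if prune:
        names = [n for n in names if incidence[n] & org_mask]
    if not names:
        warnings.warn(
            "no catalog enzyme cuts any organellar fragment; "
            "complete removal is impossible"
        )
        return [score(())]

    results = []
    for k in range(1, max_combo_size + 1):
        for combo in combinations(names, k):
            results.append(score(combo))

    # incomplete covers rank by organellar coverage before intact genomic
    # fragments, otherwise an enzyme cutting nothing at all would "win"
    results.sort(
        key=lambda r: (
            not r.complete,
            -r.organellar_cut,
            -r.genomic_intact,
            len(r.enzymes),
            r.enzymes,
        )
    )
    if results and not results[0].complete:
        warnings.warn(
            "no enzyme subset achieves complete organellar removal; "
            "returning best partial covers"
        )
    return results[:top_k]
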