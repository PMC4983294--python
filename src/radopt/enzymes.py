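"""Restriction enzyme definitions and cut-site scanning.

A restriction enzyme is modelled by its (possibly degenerate) IUPAC
recognition sequence together with the top-strand cut offset relative to the
start of the site, written in the conventional caret notation (``G^AATTC``
for EcoRI).  Only Type IIP-style enzymes cutting *within* their recognition
site are supported: fragment boundaries in a complete digest are then fully
determined by the positions of the recognition sites, which is what makes
in-silico digestion of a reference genome meaningful.

Coordinates are 0-based: a cut coordinate ``c`` means the top strand is
severed between positions ``c - 1`` and ``c``.  Overhang stagger between the
two strands is deliberately ignored; fragment lengths are measured
cut-to-cut on the top strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "IUPAC_SETS",
    "RestrictionEnzyme",
    "EnzymeCatalog",
    "CatalogError",
    "parse_catalog",
    "load_default_catalog",
    "find_cut_sites",
    "reverse_complement",
    "iupac_reverse_complement",
]

# Base sets denoted by each IUPAC nucleotide symbol.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T/N sequence."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def iupac_reverse_complement(site: str) -> str:
    """Reverse complement of a degenerate IUPAC recognition sequence."""
    return site.translate(_IUPAC_COMPLEMENT)[::-1]


class CatalogError(ValueError):
    """Raised for malformed enzyme definitions or catalog files."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A named recognition site with a top-strand cut offset.

    Parameters
    ----------
    name :
        Unique enzyme name (e.g. ``"EcoRI"``).
    recognition :
        Uppercase IUPAC recognition sequence.
    cut_offset :
        Top-strand cut position relative to the site start,
        ``0 <= cut_offset <= len(recognition)``.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.name:
            raise CatalogError("enzyme name must be non-empty")
        if not self.recognition:
            raise CatalogError(f"{self.name}: recognition site must be non-empty")
        bad = set(self.recognition) - set(IUPAC_SETS)
        if bad:
            raise CatalogError(
                f"{self.name}: invalid IUPAC symbol(s) {sorted(bad)} in "
                f"recognition site {self.recognition!r}"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise CatalogError(
                f"{self.name}: cut offset {self.cut_offset} outside recognition "
                f"site of length {len(self.recognition)}"
            )

    @property
    def palindromic(self) -> bool:
        """True when the site equals its IUPAC reverse complement."""
        return self.recognition == iupac_reverse_complement(self.recognition)

    @property
    def site_with_caret(self) -> str:
        return self.recognition[: self.cut_offset] + "^" + self.recognition[self.cut_offset:]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}({self.site_with_caret})"


@dataclass
class EnzymeCatalog:
    """Ordered collection of restriction enzymes keyed by unique name."""

    enzymes: dict[str, RestrictionEnzyme] = field(default_factory=dict)

    def add(self, enzyme: RestrictionEnzyme) -> None:
        if enzyme.name in self.enzymes:
            raise CatalogError(f"duplicate enzyme name {enzyme.name!r}")
        self.enzymes[enzyme.name] = enzyme

    def __getitem__(self, name: str) -> RestrictionEnzyme:
        try:
            return self.enzymes[name]
        except KeyError:
            raise KeyError(f"enzyme {name!r} not in catalog") from None

    def __contains__(self, name: str) -> bool:
        return name in self.enzymes

    def __iter__(self) -> Iterator[RestrictionEnzyme]:
        return iter(self.enzymes.values())

    def __len__(self) -> int:
        return len(self.enzymes)

    def names(self) -> list[str]:
        return list(self.enzymes)

    def subset(self, names: Iterable[str]) -> list[RestrictionEnzyme]:
        return [self[n] for n in names]


def _parse_site(token: str, name: str, lineno: int) -> RestrictionEnzyme:
    if token.count("^") != 1:
        raise CatalogError(
            f"line {lineno}: site {token!r} for {name} must contain exactly one "
            "'^' cut marker (enzymes cutting outside their recognition site "
            "are not supported)"
        )
    offset = token.index("^")
    recognition = token.replace("^", "").upper()
    try:
        return RestrictionEnzyme(name=name, recognition=recognition, cut_offset=offset)
    except CatalogError as exc:
        raise CatalogError(f"line {lineno}: {exc}") from None


def parse_catalog(path: str | Path) -> EnzymeCatalog:
    """Parse a TSV catalog (``name<TAB>site``, caret cut notation).

    Lines starting with ``#`` are comments.  Duplicate names, malformed
    IUPAC symbols and missing cut markers raise :class:`CatalogError`
    naming the offending line.
    """
    catalog = EnzymeCatalog()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CatalogError(f"line {lineno}: expected 'name<TAB>site', got {line!r}")
            name, site = parts[0].strip(), parts[1].strip()
            enzyme = _parse_site(site, name, lineno)
            try:
                catalog.add(enzyme)
            except CatalogError as exc:
                raise CatalogError(f"line {lineno}: {exc}") from None
    return catalog


def load_default_catalog() -> EnzymeCatalog:
    """Load the catalog of commercial Type IIP enzymes bundled with the package."""
    ref = resources.files("radopt").joinpath("data/enzymes.tsv")
    with resources.as_file(ref) as path:
        return parse_catalog(path)


def _site_regex(site: str) -> re.Pattern[str]:
    # Lookahead so overlapping occurrences are all reported.  Degenerate
    # symbols expand to character classes over A/C/G/T only, so an N in the
    # genome never matches.
    parts = []
    for sym in site:
        bases = sorted(IUPAC_SETS[sym])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("(?=" + "".join(parts) + ")")


def find_cut_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Locate all top-strand cut coordinates of ``enzyme`` in ``sequence``.

    Both strands are scanned.  For a site found on the reverse strand at
    top-strand position ``s`` the cut maps to ``s + len(site) - cut_offset``.
    For palindromic enzymes the reverse-strand scan is redundant and skipped.
    Returns a sorted, duplicate-free list of coordinates in
    ``[0, len(sequence)]``.
    """
    seq = sequence.upper()
    site = enzyme.recognition
    cuts: set[int] = set()
    for m in _site_regex(site).finditer(seq):
        cuts.add(m.start() + enzyme.cut_offset)
    if not enzyme.palindromic:
        rc_site = iupac_reverse_complement(site)
        for m in _site_regex(rc_site).finditer(seq):
            cuts.add(m.start() + len(site) - enzyme.cut_offset)
    return sorted(cuts)
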