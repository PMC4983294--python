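"""Inline-barcode demultiplexing of pooled paired-end RAD-seq reads.

Each sample in a pool is identified by a short (default 5 bp) barcode
ligated immediately 5' of the restriction overhang on read 1.  A read pair
is assigned to a sample when exactly one barcode matches the start of read
1 within the mismatch tolerance (optionally requiring the regenerated
enzyme overhang right after the barcode); everything else goes to the
``unassigned`` sink, so pair counts are conserved by construction.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from scipy import stats

__all__ = [
    "BarcodeSpec",
    "DemuxReport",
    "BalanceReport",
    "parse_barcode_table",
    "validate_barcode_set",
    "demultiplex",
    "read_balance_report",
    "FastqRecord",
    "iter_fastq",
    "write_fastq_record",
]


@dataclass(frozen=True)
class BarcodeSpec:
    """A sample's inline barcode and optional post-barcode enzyme anchor."""

    sample_id: str
    barcode: str
    enzyme_anchor: str = ""

    def __post_init__(self) -> None:
        if not self.barcode or set(self.barcode) - set("ACGT"):
            raise ValueError(f"{self.sample_id}: barcode must be non-empty A/C/G/T")
        if set(self.enzyme_anchor) - set("ACGT"):
            raise ValueError(f"{self.sample_id}: anchor must be A/C/G/T")


@dataclass
class DemuxReport:
    """Per-sample read-pair counts for one demultiplexed pool."""

    counts: dict[str, int]
    unassigned: int

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unassigned

    @property
    def fractions(self) -> dict[str, float]:
        total = self.total
        out = {s: c / total for s, c in self.counts.items()}
        out["unassigned"] = self.unassigned / total
        return out


@dataclass
class BalanceReport:
    """Evenness statistics of read counts across a pool."""

    fractions: dict[str, float]
    cv: float
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class FastqRecord:
    name: str
    sequence: str
    quality: str

    def trimmed(self, n: int) -> "FastqRecord":
        return FastqRecord(self.name, self.sequence[n:], self.quality[n:])


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path: str | Path) -> Iterator[FastqRecord]:
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ near {header!r}")
            if len(qual) != len(seq) or not seq:
                raise ValueError(f"{path}: truncated FASTQ record {header!r}")
            yield FastqRecord(header[1:].split()[0], seq.upper(), qual)


def write_fastq_record(fh: IO[str], rec: FastqRecord) -> None:
    fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n")


def parse_barcode_table(path: str | Path) -> list[BarcodeSpec]:
    """Read a ``sample_id<TAB>barcode[<TAB>anchor]`` table."""
    specs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"line {lineno}: expected 2 or 3 columns")
            specs.append(BarcodeSpec(parts[0], parts[1].upper(),
                                     parts[2].upper() if len(parts) == 3 else ""))
    return specs


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_barcode_set(barcodes: Iterable[BarcodeSpec], mismatch_tolerance: int) -> None:
    """Reject duplicate barcodes and sets too close for the chosen tolerance.

    With tolerance t, unambiguous assignment requires every pairwise
    Hamming distance to be at least 2t + 1.
    """
    specs = list(barcodes)
    lengths = {len(s.barcode) for s in specs}
    if len(lengths) > 1:
        raise ValueError("barcodes must share a single length")
    seen: dict[str, str] = {}
    for s in specs:
        if s.barcode in seen:
            raise ValueError(
                f"barcode {s.barcode} shared by {seen[s.barcode]} and {s.sample_id}"
            )
        seen[s.barcode] = s.sample_id
    if mismatch_tolerance > 0:
        need = 2 * mismatch_tolerance + 1
        for i, a in enumerate(specs):
            for b in specs[i + 1:]:
                d = _hamming(a.barcode, b.barcode)
                if d < need:
                    raise ValueError(
                        f"barcodes {a.barcode}/{b.barcode} at Hamming distance {d} "
                        f"are ambiguous at mismatch tolerance {mismatch_tolerance} "
                        f"(need >= {need})"
                    )


def demultiplex(
    r1_path: str | Path,
    r2_path: str | Path,
    barcodes: Iterable[BarcodeSpec],
    out_dir: str | Path,
    mismatch_tolerance: int = 0,
    trim: bool = True,
    check_anchor: bool = False,
) -> DemuxReport:
    """Assign read pairs to samples by the barcode at the start of read 1.

    A pair is assigned iff exactly one barcode matches within the mismatch
    tolerance (and, with ``check_anchor``, the enzyme overhang follows the
    barcode verbatim).  ``trim`` removes the barcode (and nothing else)
    from read 1.  Per-sample mate files plus an ``unassigned`` pair are
    written under ``out_dir``; desynchronized mates raise.
    """
    specs = list(barcodes)
    validate_barcode_set(specs, mismatch_tolerance)
    bc_len = len(specs[0].barcode)
    exact = {s.barcode: s for s in specs}

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sinks: dict[str, tuple[IO[str], IO[str]]] = {}
    for s in specs:
        sinks[s.sample_id] = (
            open(out_dir / f"{s.sample_id}.R1.fastq", "w"),
            open(out_dir / f"{s.sample_id}.R2.fastq", "w"),
        )
    sinks["unassigned"] = (
        open(out_dir / "unassigned.R1.fastq", "w"),
        open(out_dir / "unassigned.R2.fastq", "w"),
    )

    counts = {s.sample_id: 0 for s in specs}
    unassigned = 0
    try:
        for rec1, rec2 in zip(iter_fastq(r1_path), iter_fastq(r2_path), strict=True):
            if rec1.name != rec2.name:
                raise ValueError(
                    f"desynchronized mates: {rec1.name!r} vs {rec2.name!r}"
                )
            spec = _match_barcode(rec1.sequence, specs, exact, bc_len,
                                  mismatch_tolerance, check_anchor)
            if spec is None:
                unassigned += 1
                w1, w2 = sinks["unassigned"]
                write_fastq_record(w1, rec1)
                write_fastq_record(w2, rec2)
            else:
                counts[spec.sample_id] += 1
                w1, w2 = sinks[spec.sample_id]
                write_fastq_record(w1, rec1.trimmed(bc_len) if trim else rec1)
                write_fastq_record(w2, rec2)
    finally:
        for w1, w2 in sinks.values():
            w1.close()
            w2.close()
    return DemuxReport(counts=counts, unassigned=unassigned)


def _match_barcode(
    seq: str,
    specs: list[BarcodeSpec],
    exact: dict[str, BarcodeSpec],
    bc_len: int,
    tolerance: int,
    check_anchor: bool,
) -> BarcodeSpec | None:
    prefix = seq[:bc_len]
    if len(prefix) < bc_len:
        return None
    hit = exact.get(prefix)
    if hit is None and tolerance > 0:
        matches = [s for s in specs if _hamming(prefix, s.barcode) <= tolerance]
        if len(matches) == 1:
            hit = matches[0]
    if hit is None:
        return None
    if check_anchor and hit.enzyme_anchor:
        anchor = seq[bc_len : bc_len + len(hit.enzyme_anchor)]
        if anchor != hit.enzyme_anchor:
            return None
    return hit


def read_balance_report(counts: dict[str, int], pool_size: int) -> BalanceReport:
    """Coefficient of variation and one-sample t-test of pool balance.

    The CV uses the sample standard deviation (n-1 denominator).  The
    two-sided one-sample t-test compares the per-sample counts against the
    expected mean ``total / pool_size``; when all pooled samples are
    included the counts average to that mean by construction, so the test
    is mainly informative for per-lane subsets or externally fixed
    expectations.
    """
    if pool_size < 2:
        raise ValueError("pool balance statistics require pool_size >= 2")
    if len(counts) < 2:
        raise ValueError("need counts for at least 2 samples")
    values = np.asarray(list(counts.values()), dtype=float)
    total = values.sum()
    expected_mean = total / pool_size
    mean = values.mean()
    sd = values.std(ddof=1)
    cv = float(sd / mean) if mean > 0 else float("nan")
    if sd == 0:
        t_stat = 0.0
        p_value = 1.0
    else:
        t_stat, p_value = stats.ttest_1samp(values, expected_mean)
        t_stat, p_value = float(t_stat), float(p_value)
    fractions = {s: c / total for s, c in counts.items()} if total > 0 else \
        {s: float("nan") for s in counts}
    return BalanceReport(fractions=fractions, cv=cv, t_statistic=t_stat, p_value=p_value)
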