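"""Variant filtering and segregation-based genotype validation.

Filtering applies the stringent criteria used for RAD-seq genotype calls
in a two-parent family design: per-call depth and genotype-quality masking,
complete parental genotypes, a minimum number of genotyped offspring,
offspring alleles consistent with the parental alleles, and (optionally)
biallelic sites only.

Segregation testing compares observed offspring genotype-class counts at
each marker against Mendelian expectations with a Pearson chi-square
goodness-of-fit test, Sidak-corrected across markers.  For autotetraploids
the expectations are parameterized by the double-reduction coefficient
alpha — the probability that a gamete carries two copies of the same
parental chromosome segment — which inflates homozygote classes with
distance from the centromere.  Tetraploid "genotype" here means the
allele-presence class only (which alleles are observed), not allelic
dosage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "HOM_P1",
    "HET",
    "HOM_P2",
    "MISSING",
    "ALPHA_MAX",
    "FilterCriteria",
    "VariantRecord",
    "GenotypeMatrix",
    "SegregationModel",
    "ChiSquareResult",
    "CorrelationResult",
    "filter_variants",
    "expected_genotype_freqs",
    "chisq_gof",
    "sidak_threshold",
    "segregation_scan",
    "homozygote_centromere_correlation",
]

HOM_P1 = "homP1"
HET = "het"
HOM_P2 = "homP2"
MISSING = "missing"

#: Theoretical maximum of the double-reduction coefficient under complete
#: equational separation.
ALPHA_MAX = 1.0 / 6.0


@dataclass
class FilterCriteria:
    """Thresholds of the five-step variant filter."""

    min_depth: int = 10
    min_genotype_quality: int = 20
    require_both_parents: bool = True
    min_offspring_genotyped: int = 7
    require_allele_consistency: bool = True
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_genotype_quality < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class VariantRecord:
    """One variant site across 2 parents and n offspring.

    ``parent_alleles`` / ``offspring_alleles`` hold per-sample allele sets
    (``None`` = missing call); ``depths`` and ``quals`` are aligned to
    parents first, then offspring.
    """

    seq_id: str
    position: int  # 1-based, as printed in VCF
    ref: str
    alts: tuple[str, ...]
    parent_alleles: list[frozenset[str] | None]
    offspring_alleles: list[frozenset[str] | None]
    depths: list[float]
    quals: list[float]

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)


@dataclass
class GenotypeMatrix:
    """Variant records for a two-parent family (2 parents + n offspring)."""

    records: list[VariantRecord]
    parent_ids: tuple[str, str]
    offspring_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.parent_ids) != 2:
            raise ValueError("exactly 2 parents must be labelled")

    @classmethod
    def from_vcf(cls, path, parent_ids: Sequence[str]) -> "GenotypeMatrix":
        """Load a VCFv4.2 file; GT/DP/GQ are read per sample.

        Missing genotypes (``./.`` or absent fields) become ``None``.
        """
        from cyvcf2 import VCF

        parent_ids = tuple(parent_ids)
        if len(parent_ids) != 2:
            raise ValueError("exactly 2 parents must be labelled")
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        for p in parent_ids:
            if p not in samples:
                raise ValueError(f"parent {p!r} not among VCF samples")
        offspring_ids = tuple(s for s in samples if s not in parent_ids)
        p_idx = [samples.index(p) for p in parent_ids]
        o_idx = [samples.index(o) for o in offspring_ids]

        records = []
        for v in vcf:
            alleles = [v.REF] + list(v.ALT)
            gts = v.genotypes  # [a, b, phased] per sample
            dp = _format_field(v, "DP", len(samples))
            gq = _format_field(v, "GQ", len(samples))

            def allele_set(i: int) -> frozenset[str] | None:
                calls = [a for a in gts[i][:-1] if a >= 0]
                if not calls:
                    return None
                return frozenset(alleles[a] for a in calls)

            order = p_idx + o_idx
            records.append(
                VariantRecord(
                    seq_id=v.CHROM,
                    position=v.POS,
                    ref=v.REF,
                    alts=tuple(v.ALT),
                    parent_alleles=[allele_set(i) for i in p_idx],
                    offspring_alleles=[allele_set(i) for i in o_idx],
                    depths=[dp[i] for i in order],
                    quals=[gq[i] for i in order],
                )
            )
        return cls(records=records, parent_ids=parent_ids, offspring_ids=offspring_ids)


def _format_field(variant, key: str, n: int) -> list[float]:
    try:
        arr = variant.format(key)
    except KeyError:
        arr = None
    if arr is None:
        return [float("nan")] * n
    vals = np.asarray(arr, dtype=float).reshape(n, -1)[:, 0]
    return [float(x) for x in vals]


def _masked_record(rec: VariantRecord, criteria: FilterCriteria) -> VariantRecord:
    """Set calls failing the depth/GQ thresholds to missing."""

    def ok(i: int) -> bool:
        # an unknown (NaN) depth or quality cannot certify the threshold
        d, q = rec.depths[i], rec.quals[i]
        if math.isnan(d) or d < criteria.min_depth:
            return False
        if math.isnan(q) or q < criteria.min_genotype_quality:
            return False
        return True

    n_par = len(rec.parent_alleles)
    parents = [a if ok(i) else None for i, a in enumerate(rec.parent_alleles)]
    offspring = [
        a if ok(n_par + i) else None for i, a in enumerate(rec.offspring_alleles)
    ]
    return VariantRecord(
        seq_id=rec.seq_id,
        position=rec.position,
        ref=rec.ref,
        alts=rec.alts,
        parent_alleles=parents,
        offspring_alleles=offspring,
        depths=rec.depths,
        quals=rec.quals,
    )


def filter_variants(
    matrix: GenotypeMatrix, criteria: FilterCriteria | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the five filtering criteria; return survivors and a rejection tally.

    Calls failing the depth/GQ thresholds are first set missing; a record is
    then rejected by the *first* failing criterion, checked in the fixed
    order: both parents genotyped -> minimum offspring genotyped ->
    offspring alleles consistent with parental alleles -> biallelic.  The
    tally maps criterion names to rejected-record counts.
    """
    if criteria is None:
        criteria = FilterCriteria()
    tally = {
        "parents_missing": 0,
        "too_few_offspring": 0,
        "allele_inconsistency": 0,
        "multiallelic": 0,
    }
    passing = []
    for rec in matrix.records:
        masked = _masked_record(rec, criteria)
        if criteria.require_both_parents and any(
            a is None for a in masked.parent_alleles
        ):
            tally["parents_missing"] += 1
            continue
        genotyped = [a for a in masked.offspring_alleles if a is not None]
        if len(genotyped) < criteria.min_offspring_genotyped:
            tally["too_few_offspring"] += 1
            continue
        if criteria.require_allele_consistency:
            parental_union: set[str] = set()
            for a in masked.parent_alleles:
                if a is not None:
                    parental_union |= a
            if any(not a <= parental_union for a in genotyped):
                tally["allele_inconsistency"] += 1
                continue
        if criteria.biallelic_only and masked.n_alleles > 2:
            tally["multiallelic"] += 1
            continue
        passing.append(masked)
    return (
        GenotypeMatrix(
            records=passing,
            parent_ids=matrix.parent_ids,
            offspring_ids=matrix.offspring_ids,
        ),
        tally,
    )


def classify_offspring(rec: VariantRecord) -> list[str]:
    """Allele-presence class of each offspring call.

    ``homP1``/``homP2`` mean only one parent's distinguishing allele is
    observed, ``het`` means alleles from both.  For a homozygous x
    heterozygous cross (e.g. AA x Aa) the shared allele labels the
    homozygous parent's class and the allele unique to the heterozygous
    parent labels the other.
    """
    s1, s2 = rec.parent_alleles
    if s1 is None or s2 is None:
        raise ValueError("both parental genotypes are required for classification")
    only1 = s1 - s2
    only2 = s2 - s1
    shared = s1 & s2
    # Distinguishing allele set of each parent: the alleles unique to it,
    # with a homozygous parent in a hom x het cross represented by the
    # shared allele.  Two identically heterozygous parents (an F1 self at a
    # biallelic site) are split deterministically by allele order; the
    # homP1/homP2 labels are then arbitrary but the class counts are not.
    if only1 and only2:
        set1, set2 = only1, only2
    elif only1:
        set1, set2 = only1, shared
    elif only2:
        set1, set2 = shared, only2
    elif len(shared) == 2:
        a, b = sorted(shared)
        set1, set2 = frozenset([a]), frozenset([b])
    else:
        set1 = set2 = frozenset()
    if not set1 or not set2:
        raise ValueError(
            f"{rec.seq_id}:{rec.position}: parents are not distinguishable "
            f"({set(s1)} x {set(s2)})"
        )
    classes = []
    for alleles in rec.offspring_alleles:
        if alleles is None:
            classes.append(MISSING)
            continue
        in1 = bool(alleles & set1)
        in2 = bool(alleles & set2)
        if in1 and in2:
            classes.append(HET)
        elif in1:
            classes.append(HOM_P1)
        elif in2:
            classes.append(HOM_P2)
        else:
            classes.append(MISSING)
    return classes


@dataclass
class SegregationModel:
    """Expected genotype-class frequencies for a population design.

    ``population`` is one of ``diploid_F2``, ``diploid_F1_AAxAa``,
    ``tetraploid_F2`` and ``tetraploid_F1``; ``alpha`` is the
    double-reduction coefficient (tetraploid populations only), bounded by
    1/6 under complete equational separation.  ``custom_freqs`` overrides
    the model-derived expectations.
    """

    population: str
    alpha: float = 0.0
    custom_freqs: tuple[float, float, float] | None = None
    alpha_upper_bound: float = ALPHA_MAX

    def __post_init__(self) -> None:
        known = {"diploid_F2", "diploid_F1_AAxAa", "tetraploid_F2", "tetraploid_F1"}
        if self.population not in known:
            raise ValueError(f"unknown population {self.population!r}")
        if not 0.0 <= self.alpha <= self.alpha_upper_bound:
            raise ValueError(
                f"alpha {self.alpha} outside [0, {self.alpha_upper_bound}]"
            )
        if self.custom_freqs is not None:
            f = self.custom_freqs
            if any(x < 0 for x in f) or not math.isclose(sum(f), 1.0, abs_tol=1e-9):
                raise ValueError("custom frequencies must be non-negative and sum to 1")


def expected_genotype_freqs(model: SegregationModel) -> tuple[float, float, float]:
    """Expected (homP1, het, homP2) class frequencies.

    diploid_F2: 1:2:1.  diploid_F1_AAxAa: 1:1:0.  tetraploid_F2 (duplex x
    duplex AAaa x AAaa, allele-presence classes): a gamete is homozygous
    for a given allele with probability g = (1 + 2*alpha)/6 — the
    double-reduction gamete doubles a random chromosome (probability
    alpha/2 per allele) while a normal gamete draws 2 of 4 chromosomes
    (1/6 per homozygous class) — so each offspring homozygote class has
    frequency g**2 and the heterozygous class 1 - 2*g**2.  tetraploid_F1
    (simplex x nulliplex, Aaaa x aaaa): the simplex parent transmits an
    A-bearing gamete with probability (1 - alpha)/2 + alpha/4, giving
    classes (0, 1/2 - alpha/4, 1/2 + alpha/4).
    """
    if model.custom_freqs is not None:
        return model.custom_freqs
    a = model.alpha
    if model.population == "diploid_F2":
        return (0.25, 0.5, 0.25)
    if model.population == "diploid_F1_AAxAa":
        return (0.5, 0.5, 0.0)
    if model.population == "tetraploid_F2":
        g = (1.0 + 2.0 * a) / 6.0
        return (g * g, 1.0 - 2.0 * g * g, g * g)
    # tetraploid_F1 simplex x nulliplex
    het = 0.5 - a / 4.0
    return (0.0, het, 1.0 - het)


@dataclass
class ChiSquareResult:
    """Pearson goodness-of-fit result for one marker."""

    statistic: float
    df: int
    p_value: float
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    significant_after_sidak: bool | None = None
    consistent: bool = True  # False when a zero-expectation class was observed


def chisq_gof(
    observed: Sequence[int], expected_freqs: Sequence[float]
) -> ChiSquareResult:
    """Pearson chi-square goodness of fit of class counts to expected frequencies.

    ``chi2 = sum((O_i - E_i)**2 / E_i)`` with ``E_i = n * f_i``.  With three
    positive-expectation classes df = 2.  A class with expected frequency 0
    and observed 0 is dropped (reducing df); observed counts in a
    zero-expectation class flag the marker as inconsistent with the model
    instead of being tested.
    """
    obs = [int(o) for o in observed]
    freqs = [float(f) for f in expected_freqs]
    if len(obs) != len(freqs):
        raise ValueError("observed and expected lengths differ")
    n = sum(obs)
    if n == 0:
        raise ValueError("no observations")
    if any(f < 0 for f in freqs) or not math.isclose(sum(freqs), 1.0, abs_tol=1e-9):
        raise ValueError("expected frequencies must be non-negative and sum to 1")

    expected = tuple(n * f for f in freqs)
    for o, e in zip(obs, expected):
        if e == 0 and o > 0:
            return ChiSquareResult(
                statistic=float("nan"),
                df=0,
                p_value=float("nan"),
                observed=tuple(obs),
                expected=expected,
                consistent=False,
            )
    keep = [(o, e) for o, e in zip(obs, expected) if e > 0]
    stat = sum((o - e) ** 2 / e for o, e in keep)
    df = len(keep) - 1
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return ChiSquareResult(
        statistic=float(stat),
        df=df,
        p_value=p,
        observed=tuple(obs),
        expected=expected,
    )


def sidak_threshold(family_alpha: float = 0.05, m: int = 1) -> float:
    """Per-test p-value threshold controlling the family-wise error rate.

    ``1 - (1 - family_alpha)**(1/m)`` for m independent tests.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    return 1.0 - (1.0 - family_alpha) ** (1.0 / m)


@dataclass
class SegregationScan:
    results: list[ChiSquareResult]
    threshold: float
    n_significant: int
    mean_frequencies: tuple[float, float, float] | None


def segregation_scan(
    matrix: GenotypeMatrix,
    model: SegregationModel,
    family_alpha: float = 0.05,
    observed_counts: Sequence[Sequence[int]] | None = None,
) -> SegregationScan:
    """Chi-square goodness-of-fit test at every marker, Sidak-corrected.

    Observed class counts are tallied from the offspring calls of each
    record (missing calls excluded); ``observed_counts`` can supply
    pre-tallied (homP1, het, homP2) counts directly.  The Sidak correction
    uses m = number of tested markers.  The summary reports the mean
    observed class frequencies across markers and the significant-marker
    count.
    """
    freqs = expected_genotype_freqs(model)
    if observed_counts is None:
        counts_list = []
        for rec in matrix.records:
            classes = classify_offspring(rec)
            counts_list.append(
                (
                    classes.count(HOM_P1),
                    classes.count(HET),
                    classes.count(HOM_P2),
                )
            )
    else:
        counts_list = [tuple(int(x) for x in row) for row in observed_counts]

    results = [chisq_gof(c, freqs) for c in counts_list]
    tested = [r for r in results if r.consistent]
    m = len(tested)
    threshold = sidak_threshold(family_alpha, m) if m else family_alpha
    n_sig = 0
    for r in results:
        if r.consistent:
            r.significant_after_sidak = r.p_value < threshold
            n_sig += r.significant_after_sidak
    mean_freqs = None
    if counts_list:
        arr = np.asarray(counts_list, dtype=float)
        totals = arr.sum(axis=1, keepdims=True)
        valid = totals[:, 0] > 0
        if valid.any():
            mean_freqs = tuple(np.mean(arr[valid] / totals[valid], axis=0))
    return SegregationScan(
        results=results,
        threshold=threshold,
        n_significant=n_sig,
        mean_frequencies=mean_freqs,
    )


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    zero_variance: bool = False


def homozygote_centromere_correlation(
    markers: Sequence[tuple[str, int, float]],
    centromeres: dict[str, int],
) -> CorrelationResult:
    """Pearson correlation of homozygote frequency with centromere distance.

    ``markers`` are (seq_id, position, homozygote frequency); the distance
    is the absolute offset to that chromosome's centromere coordinate.
    Double reduction predicts a positive correlation.  Constant inputs
    yield an explicit zero-variance result (r = 0).
    """
    if len(markers) < 3:
        raise ValueError("need at least 3 markers")
    dist = []
    freq = []
    for seq_id, pos, f in markers:
        if seq_id not in centromeres:
            raise KeyError(f"no centromere coordinate for {seq_id!r}")
        dist.append(abs(pos - centromeres[seq_id]))
        freq.append(f)
    dist_arr = np.asarray(dist, dtype=float)
    freq_arr = np.asarray(freq, dtype=float)
    if np.all(dist_arr == dist_arr[0]) or np.all(freq_arr == freq_arr[0]):
        return CorrelationResult(r=0.0, p_value=1.0, n=len(markers), zero_variance=True)
    r, p = stats.pearsonr(dist_arr, freq_arr)
    return CorrelationResult(r=float(r), p_value=float(p), n=len(markers))
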