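"""Variant filtering, genotype classification and segregation statistics."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from radopt.variantqc import (
    ALPHA_MAX,
    HET,
    HOM_P1,
    HOM_P2,
    MISSING,
    ChiSquareResult,
    FilterCriteria,
    GenotypeMatrix,
    SegregationModel,
    VariantRecord,
    chisq_gof,
    classify_offspring,
    expected_genotype_freqs,
    filter_variants,
    homozygote_centromere_correlation,
    segregation_scan,
    sidak_threshold,
)


def make_rec(parents, offspring, depths=None, quals=None, alts=("G",), pos=100):
    n = 2 + len(offspring)
    return VariantRecord(
        seq_id="chr1",
        position=pos,
        ref="A",
        alts=tuple(alts),
        parent_alleles=[frozenset(p) if p is not None else None for p in parents],
        offspring_alleles=[frozenset(o) if o is not None else None for o in offspring],
        depths=list(depths) if depths is not None else [30.0] * n,
        quals=list(quals) if quals is not None else [60.0] * n,
    )


# ---------------------------------------------------------------------------
# gamete-enumeration oracle for tetraploid expectations
# ---------------------------------------------------------------------------

def oracle_tetraploid_gamete(chromosomes, alpha):
    """Exact gamete allele-pair distribution under double reduction.

    With probability alpha the gamete carries two copies of one uniformly
    chosen chromosome; otherwise it carries two distinct uniformly chosen
    chromosomes.
    """
    alpha = Fraction(alpha)
    probs = {}
    for c in chromosomes:
        key = frozenset([c])
        probs[key] = probs.get(key, Fraction(0)) + alpha * Fraction(1, len(chromosomes))
    pairs = list(combinations(range(len(chromosomes)), 2))
    for i, j in pairs:
        key = frozenset([chromosomes[i], chromosomes[j]])
        probs[key] = probs.get(key, Fraction(0)) + (1 - alpha) * Fraction(1, len(pairs))
    return probs


def oracle_offspring_presence(g1, g2):
    """Class probabilities (only-A, both, only-a) of the union of two gametes."""
    out = {"A": Fraction(0), "Aa": Fraction(0), "a": Fraction(0)}
    for k1, p1 in g1.items():
        for k2, p2 in g2.items():
            alleles = set(k1) | set(k2)
            key = "Aa" if alleles == {"A", "a"} else alleles.pop()
            out[key] += p1 * p2
    return out


class TestExpectedFrequencies:
    def test_diploid_models(self):
        assert expected_genotype_freqs(SegregationModel("diploid_F2")) == (0.25, 0.5, 0.25)
        assert expected_genotype_freqs(SegregationModel("diploid_F1_AAxAa")) == (0.5, 0.5, 0.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.05, Fraction(1, 6)])
    def test_tetraploid_f2_matches_gamete_enumeration(self, alpha):
        gam = oracle_tetraploid_gamete(["A", "A", "a", "a"], alpha)
        probs = oracle_offspring_presence(gam, gam)
        got = expected_genotype_freqs(SegregationModel("tetraploid_F2", float(alpha)))
        assert got[0] == pytest.approx(float(probs["A"]), abs=1e-12)
        assert got[1] == pytest.approx(float(probs["Aa"]), abs=1e-12)
        assert got[2] == pytest.approx(float(probs["a"]), abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.1, Fraction(1, 6)])
    def test_tetraploid_f1_matches_gamete_enumeration(self, alpha):
        simplex = oracle_tetraploid_gamete(["A", "a", "a", "a"], alpha)
        nulliplex = oracle_tetraploid_gamete(["a", "a", "a", "a"], alpha)
        probs = oracle_offspring_presence(simplex, nulliplex)
        got = expected_genotype_freqs(SegregationModel("tetraploid_F1", float(alpha)))
        assert got[0] == pytest.approx(float(probs["A"]), abs=1e-12)
        assert got[1] == pytest.approx(float(probs["Aa"]), abs=1e-12)
        assert got[2] == pytest.approx(float(probs["a"]), abs=1e-12)

    def test_zero_alpha_tetraploid_f2_is_one_thirtysixth(self):
        f = expected_genotype_freqs(SegregationModel("tetraploid_F2", 0.0))
        assert f[0] == pytest.approx(1 / 36)
        assert f[1] == pytest.approx(34 / 36)

    def test_double_reduction_increases_homozygotes(self):
        lo = expected_genotype_freqs(SegregationModel("tetraploid_F2", 0.0))
        hi = expected_genotype_freqs(SegregationModel("tetraploid_F2", ALPHA_MAX))
        assert hi[0] > lo[0] and hi[2] > lo[2] and hi[1] < lo[1]

    def test_alpha_bounds_and_custom_freqs(self):
        with pytest.raises(ValueError):
            SegregationModel("tetraploid_F2", 0.2)
        with pytest.raises(ValueError):
            SegregationModel("nope")
        with pytest.raises(ValueError):
            SegregationModel("diploid_F2", custom_freqs=(0.5, 0.6, -0.1))
        model = SegregationModel("diploid_F2", custom_freqs=(0.06, 0.88, 0.06))
        assert expected_genotype_freqs(model) == (0.06, 0.88, 0.06)


class TestClassifyOffspring:
    def test_f2_cross(self):
        rec = make_rec([{"A"}, {"G"}], [{"A"}, {"A", "G"}, {"G"}, None])
        assert classify_offspring(rec) == [HOM_P1, HET, HOM_P2, MISSING]

    def test_hom_by_het_cross_uses_shared_allele(self):
        rec = make_rec([{"A"}, {"A", "G"}], [{"A"}, {"A", "G"}])
        assert classify_offspring(rec) == [HOM_P1, HET]

    def test_foreign_allele_is_missing(self):
        rec = make_rec([{"A"}, {"G"}], [{"T"}])
        assert classify_offspring(rec) == [MISSING]

    def test_identical_parents_rejected(self):
        rec = make_rec([{"A"}, {"A"}], [{"A"}])
        with pytest.raises(ValueError, match="distinguishable"):
            classify_offspring(rec)

    def test_missing_parent_rejected(self):
        rec = make_rec([None, {"G"}], [{"G"}])
        with pytest.raises(ValueError):
            classify_offspring(rec)

    def test_deterministic_across_orderings(self):
        rec = make_rec([{"A", "C"}, {"G", "T"}], [{"A", "G"}])
        assert classify_offspring(rec) == [HET]
        rec2 = make_rec([{"C", "A"}, {"T", "G"}], [{"C", "T"}])
        assert classify_offspring(rec2) == [HET]


class TestFilterVariants:
    def matrix(self, records):
        return GenotypeMatrix(
            records=records,
            parent_ids=("P1", "P2"),
            offspring_ids=tuple(f"o{i}" for i in range(8)),
        )

    def test_each_criterion_tallied_in_order(self):
        good_off = [{"A"}] * 4 + [{"G"}] * 4
        recs = [
            # parent depth below threshold -> call masked -> parents_missing
            make_rec([{"A"}, {"G"}], good_off,
                     depths=[5.0, 30.0] + [30.0] * 8, pos=1),
            # two offspring GQ-fail leaves 6 < 7 genotyped
            make_rec([{"A"}, {"G"}], good_off,
                     quals=[60.0, 60.0, 5.0, 5.0] + [60.0] * 6, pos=2),
            # offspring carries an allele absent from both parents
            make_rec([{"A"}, {"G"}], [{"T"}] + good_off[1:], pos=3),
            # triallelic record
            make_rec([{"A"}, {"G"}], good_off, alts=("G", "T"), pos=4),
            # clean record
            make_rec([{"A"}, {"G"}], good_off, pos=5),
        ]
        passed, tally = filter_variants(self.matrix(recs))
        assert tally == {
            "parents_missing": 1,
            "too_few_offspring": 1,
            "allele_inconsistency": 1,
            "multiallelic": 1,
        }
        assert [r.position for r in passed.records] == [5]

    def test_first_failure_wins(self):
        # missing parent AND too few offspring: only parents_missing counts
        rec = make_rec([None, {"G"}], [None] * 8)
        _, tally = filter_variants(self.matrix([rec]))
        assert tally["parents_missing"] == 1
        assert tally["too_few_offspring"] == 0

    def test_thresholds_are_inclusive(self):
        rec = make_rec([{"A"}, {"G"}], [{"A"}] * 7 + [None],
                       depths=[10.0] * 10, quals=[20.0] * 10)
        passed, tally = filter_variants(self.matrix([rec]))
        assert len(passed.records) == 1 and sum(tally.values()) == 0

    def test_nan_depth_is_missing(self):
        rec = make_rec([{"A"}, {"G"}], [{"A"}] * 8,
                       depths=[float("nan"), 30.0] + [30.0] * 8)
        _, tally = filter_variants(self.matrix([rec]))
        assert tally["parents_missing"] == 1

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            FilterCriteria(min_depth=-1)


class TestChiSquare:
    def test_perfect_f2_fit(self):
        r = chisq_gof((25, 50, 25), (0.25, 0.5, 0.25))
        assert r.statistic == 0.0 and r.df == 2 and r.p_value == 1.0

    def test_textbook_example(self):
        # chi2 = (18-25)^2/25 + (55-50)^2/50 + (27-25)^2/25 = 2.62
        r = chisq_gof((18, 55, 27), (0.25, 0.5, 0.25))
        assert r.statistic == pytest.approx(2.62)
        assert r.p_value == pytest.approx(float(stats.chi2.sf(2.62, 2)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_chisquare(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.multinomial(200, [0.25, 0.5, 0.25])
        r = chisq_gof(obs, (0.25, 0.5, 0.25))
        stat, p = stats.chisquare(obs, f_exp=[50, 100, 50])
        assert r.statistic == pytest.approx(float(stat))
        assert r.p_value == pytest.approx(float(p))

    def test_zero_expectation_class_dropped(self):
        r = chisq_gof((12, 8, 0), (0.5, 0.5, 0.0))
        assert r.df == 1 and r.consistent
        assert r.statistic == pytest.approx((12 - 10) ** 2 / 10 + (8 - 10) ** 2 / 10)

    def test_observed_in_zero_class_flags_inconsistent(self):
        r = chisq_gof((10, 9, 1), (0.5, 0.5, 0.0))
        assert not r.consistent and math.isnan(r.p_value)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            chisq_gof((0, 0, 0), (0.25, 0.5, 0.25))
        with pytest.raises(ValueError):
            chisq_gof((1, 2), (0.25, 0.5, 0.25))
        with pytest.raises(ValueError):
            chisq_gof((1, 2, 3), (0.3, 0.3, 0.3))


class TestSidak:
    def test_single_test_identity(self):
        assert sidak_threshold(0.05, 1) == pytest.approx(0.05)

    def test_agrees_with_closed_form(self):
        for m in (2, 10, 848):
            assert sidak_threshold(0.05, m) == pytest.approx(1 - 0.95 ** (1 / m))

    def test_monotone_decreasing_in_m(self):
        vals = [sidak_threshold(0.05, m) for m in (1, 2, 5, 100, 10_000)]
        assert vals == sorted(vals, reverse=True)

    def test_familywise_bound(self):
        # with independent tests the family-wise error is exactly alpha
        t = sidak_threshold(0.05, 100)
        assert 1 - (1 - t) ** 100 == pytest.approx(0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            sidak_threshold(0.05, 0)
        with pytest.raises(ValueError):
            sidak_threshold(1.5, 10)


class TestSegregationScan:
    def test_distorted_marker_detected(self):
        counts = [(25, 50, 25), (22, 55, 23), (90, 8, 2)]
        scan = segregation_scan(
            GenotypeMatrix([], ("P1", "P2"), ()),
            SegregationModel("diploid_F2"),
            observed_counts=counts,
        )
        assert scan.threshold == pytest.approx(sidak_threshold(0.05, 3))
        assert scan.n_significant == 1
        assert scan.results[2].significant_after_sidak

    def test_counts_tallied_from_records(self):
        recs = [
            make_rec([{"A"}, {"G"}], [{"A"}, {"A", "G"}, {"A", "G"}, {"G"}, None])
        ]
        scan = segregation_scan(
            GenotypeMatrix(recs, ("P1", "P2"), tuple("abcde")),
            SegregationModel("diploid_F2"),
        )
        assert scan.results[0].observed == (1, 2, 1)  # missing call excluded
        assert scan.mean_frequencies == pytest.approx((0.25, 0.5, 0.25))

    def test_inconsistent_markers_excluded_from_correction(self):
        counts = [(10, 10, 0), (10, 8, 2)]
        scan = segregation_scan(
            GenotypeMatrix([], ("P1", "P2"), ()),
            SegregationModel("diploid_F1_AAxAa"),
            observed_counts=counts,
        )
        # only the consistent marker is tested, so m = 1
        assert scan.threshold == pytest.approx(0.05)
        assert scan.results[1].significant_after_sidak is None

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(42)
        n_rep, n_markers = 60, 50
        hits = 0
        for _ in range(n_rep):
            counts = rng.multinomial(80, [0.25, 0.5, 0.25], size=n_markers)
            scan = segregation_scan(
                GenotypeMatrix([], ("P1", "P2"), ()),
                SegregationModel("diploid_F2"),
                observed_counts=counts,
            )
            hits += scan.n_significant > 0
        # family-wise error should be near 5%; allow generous sampling slack
        assert hits / n_rep < 0.20


class TestCentromereCorrelation:
    def test_perfect_positive_correlation(self):
        markers = [("chr1", p, 0.02 + p / 1e7) for p in (10_000, 200_000, 900_000)]
        res = homozygote_centromere_correlation(markers, {"chr1": 0})
        assert res.r == pytest.approx(1.0)
        assert not res.zero_variance

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(9)
        pos = rng.integers(0, 10**6, size=20)
        freq = rng.random(20)
        markers = [("chr1", int(p), float(f)) for p, f in zip(pos, freq)]
        res = homozygote_centromere_correlation(markers, {"chr1": 500_000})
        r, p = stats.pearsonr(np.abs(pos - 500_000), freq)
        assert res.r == pytest.approx(float(r))
        assert res.p_value == pytest.approx(float(p))

    def test_constant_frequency_zero_variance(self):
        markers = [("chr1", p, 0.05) for p in (1, 2, 3)]
        res = homozygote_centromere_correlation(markers, {"chr1": 0})
        assert res.zero_variance and res.r == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            homozygote_centromere_correlation([("chr1", 1, 0.1)] * 2, {"chr1": 0})
        with pytest.raises(KeyError):
            homozygote_centromere_correlation(
                [("chrX", 1, 0.1), ("chrX", 2, 0.2), ("chrX", 3, 0.3)], {"chr1": 0}
            )


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\to1\to2
chr1\t101\t.\tA\tG\t50\tPASS\t.\tGT:DP:GQ\t0/0:30:60\t1/1:28:60\t0/1:25:55\t./.:0:0
chr1\t202\t.\tC\tT,G\t50\tPASS\t.\tGT:DP:GQ\t0/0:30:60\t1/2:30:60\t0/1:30:60\t0/2:30:60
"""


class TestVcfLoading:
    def test_from_vcf_round_trip(self, tmp_path):
        path = tmp_path / "family.vcf"
        path.write_text(VCF_TEXT)
        matrix = GenotypeMatrix.from_vcf(str(path), parent_ids=["P1", "P2"])
        assert matrix.parent_ids == ("P1", "P2")
        assert matrix.offspring_ids == ("o1", "o2")
        rec = matrix.records[0]
        assert (rec.seq_id, rec.position, rec.ref, rec.alts) == ("chr1", 101, "A", ("G",))
        assert rec.parent_alleles == [frozenset({"A"}), frozenset({"G"})]
        assert rec.offspring_alleles == [frozenset({"A", "G"}), None]
        assert rec.depths[:2] == [30.0, 28.0]
        assert matrix.records[1].n_alleles == 3

    def test_missing_parent_column_errors(self, tmp_path):
        path = tmp_path / "family.vcf"
        path.write_text(VCF_TEXT)
        with pytest.raises(ValueError):
            GenotypeMatrix.from_vcf(str(path), parent_ids=["P1", "nope"])
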