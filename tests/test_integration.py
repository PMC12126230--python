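"""Binding-site intersection, PAS distances, hypergeometric overlap tests."""

import math
from fractions import Fraction

import numpy as np
import pytest

from apakit.annotation import GenomicInterval, UTRRegion
from apakit.integration import (
    BindingSite,
    gene_set_enrichment,
    intersect_binding,
    overlap_test,
    pas_distance,
    read_bed6,
    read_gmt,
)


def utr(gene, start, end, strand="+", chrom="chr1"):
    distal = end if strand == "+" else start
    return UTRRegion(gene, GenomicInterval(chrom, start, end, strand), distal,
                     (f"{gene}.t1",))


def site(start, end, strand="+", chrom="chr1"):
    return BindingSite(GenomicInterval(chrom, start, end, strand))


def hypergeom_tail_exact(k, M, nA, nB):
    """Exact rational upper tail P[X >= k] by full enumeration."""
    total = Fraction(0)
    for j in range(k, min(nA, nB) + 1):
        if nB - j <= M - nA:
            total += Fraction(
                math.comb(nA, j) * math.comb(M - nA, nB - j), math.comb(M, nB)
            )
    return total


class TestPasDistance:
    def test_upstream_site_negative_and_proximal(self):
        # site whose last base sits 50 nt upstream of the PAS base
        assert pas_distance(site(900, 950), 999, "+") == (-50, True)

    def test_overlapping_site_is_zero(self):
        assert pas_distance(site(990, 1010), 999, "+") == (0, True)

    def test_downstream_beyond_75_not_proximal(self):
        assert pas_distance(site(1079, 1100), 999, "+") == (80, False)
        assert pas_distance(site(1074, 1100), 999, "+") == (75, True)  # boundary

    def test_antisymmetric_under_strand_flip(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pas = int(rng.integers(500, 1500))
            s0 = int(rng.integers(100, 2500))
            s1 = s0 + int(rng.integers(1, 80))
            d_plus, _ = pas_distance(site(s0, s1, "+"), pas, "+")
            d_minus, _ = pas_distance(site(s0, s1, "-"), pas, "-")
            assert d_plus == -d_minus


class TestIntersectBinding:
    def setup_method(self):
        self.utrs = [utr("g1", 700, 1000), utr("g2", 2000, 2400),
                     utr("g3", 5000, 5300, strand="-")]
        self.bodies = {
            "g1": GenomicInterval("chr1", 100, 1000, "+"),
            "g2": GenomicInterval("chr1", 1500, 2400, "+"),
            "g3": GenomicInterval("chr1", 5000, 6000, "-"),
        }

    def test_no_sites_all_none(self):
        anns, summary = intersect_binding(
            ["g1", "g2"], self.utrs, self.bodies, []
        )
        assert all(a.category == "none" for a in anns)
        assert summary["pct_bound"] == 0.0

    def test_category_precedence(self):
        sites = [
            site(800, 820),    # inside g1 UTR
            site(1600, 1650),  # g2 body, not UTR
        ]
        anns, summary = intersect_binding(
            ["g1", "g2", "g3"], self.utrs, self.bodies, sites
        )
        by = {a.gene_id: a for a in anns}
        assert by["g1"].category == "utr3"
        assert by["g2"].category == "other_region"
        assert by["g3"].category == "none"
        assert summary["n_bound"] == 2 and summary["n_utr3"] == 1

    def test_pas_proximity_recorded_on_minus_strand(self):
        # g3 is '-' with PAS base at 5000; site genomically right = upstream
        anns, _ = intersect_binding(
            ["g3"], self.utrs, self.bodies, [site(5030, 5050, "-")]
        )
        (a,) = anns
        assert a.category == "utr3"
        assert a.min_distance_to_pas == -30 and a.proximal_to_pas

    def test_unknown_chromosome_site_ignored(self):
        anns, _ = intersect_binding(
            ["g1"], self.utrs, self.bodies, [site(800, 820, chrom="chrUn")]
        )
        assert anns[0].category == "none"

    def test_bound_fraction_order_invariant_and_sums_to_100(self):
        sites = [site(800, 820)]
        _, s1 = intersect_binding(["g1", "g2", "g3"], self.utrs, self.bodies, sites)
        _, s2 = intersect_binding(["g3", "g1", "g2"], self.utrs, self.bodies, sites)
        assert s1 == s2
        unbound_pct = 100.0 - s1["pct_bound"]
        assert unbound_pct + s1["pct_bound"] == pytest.approx(100.0)

    def test_bound_fraction_reproduces_printed_ratio(self):
        # 164 of 320 APA genes carrying a 3'UTR site -> 51.3%
        utrs = [utr(f"g{i}", 1000 * i + 100, 1000 * i + 400) for i in range(320)]
        bodies = {u.gene_id: u.region for u in utrs}
        sites = [site(1000 * i + 150, 1000 * i + 170) for i in range(164)]
        _, summary = intersect_binding(
            [u.gene_id for u in utrs], utrs, bodies, sites
        )
        assert summary["pct_bound"] == 51.3
        assert summary["pct_utr3"] == 51.3


class TestOverlapTest:
    def test_identical_small_sets(self):
        genes = [f"g{i}" for i in range(3)]
        res = overlap_test(genes, genes, universe=10)
        assert res.overlap == 3
        assert res.p_value == pytest.approx(1 / 120, rel=1e-12)

    def test_hand_enumerated_tail(self):
        a = [f"g{i}" for i in range(5)]
        b = [f"g{i}" for i in range(1, 9)]  # overlap 4, |B| = 8
        res = overlap_test(a, b, universe=20)
        assert res.p_value == pytest.approx(7280 / 125970, rel=1e-12)

    def test_zero_overlap_p_is_one_tail(self):
        a, b = ["a1", "a2"], ["b1", "b2", "b3"]
        res = overlap_test(a, b, universe=25)
        assert res.overlap == 0
        assert res.p_value == pytest.approx(1.0)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_test(["a", "b"], ["c", "d"], universe=3)

    def test_matches_exact_enumeration_sampled(self):
        rng = np.random.default_rng(19)
        genes = [f"g{i}" for i in range(25)]
        for _ in range(200):
            M = int(rng.integers(2, 26))
            nA = int(rng.integers(0, M + 1))
            nB = int(rng.integers(0, M + 1))
            k_lo = max(0, nA + nB - M)
            k = int(rng.integers(k_lo, min(nA, nB) + 1)) if min(nA, nB) >= k_lo else 0
            a = genes[:nA]
            b = genes[nA - k:nA] + genes[nA:nA + nB - k]
            res = overlap_test(a, b, universe=M)
            assert res.overlap == k
            exact = float(hypergeom_tail_exact(k, M, nA, nB))
            assert abs(res.p_value - exact) <= 1e-12


class TestGeneSetEnrichment:
    def test_disjoint_query_all_p_one(self):
        collections = {"setA": frozenset({"x1", "x2"}), "setB": frozenset({"y1"})}
        df = gene_set_enrichment({"z1", "z2"}, collections, universe=100)
        assert (df["p_value"] == 1.0).all()

    def test_delegates_to_overlap_test(self):
        members = frozenset({"a", "b", "c"})
        df = gene_set_enrichment(members, {"set": members}, universe=10)
        expected = overlap_test(members, members, universe=10)
        assert df["p_value"][0] == pytest.approx(expected.p_value, rel=1e-12)

    def test_gmt_reader_round_trip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg4\n")
        sets = read_gmt(p)
        assert sets["setA"] == frozenset({"g1", "g2", "g3"})
        assert sets["setB"] == frozenset({"g4"})

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty query"):
            gene_set_enrichment(set(), {"s": frozenset({"a"})}, universe=10)

    def test_null_calibration_p_values_are_valid(self):
        # random queries against random collections: P(p <= α) must not
        # exceed α by more than Monte-Carlo slack at any tested level
        rng = np.random.default_rng(29)
        genes = [f"g{i}" for i in range(500)]
        pvals = []
        for _ in range(300):
            collections = {
                "s": frozenset(rng.choice(genes, size=50, replace=False))
            }
            query = set(rng.choice(genes, size=50, replace=False))
            df = gene_set_enrichment(query, collections, universe=500)
            pvals.append(df["p_value"][0])
        pvals = np.asarray(pvals)
        for alpha in (0.01, 0.05, 0.1, 0.5):
            assert (pvals <= alpha).mean() <= alpha + 0.04


def test_bed6_reader(tmp_path):
    p = tmp_path / "sites.bed"
    p.write_text(
        "track name=peaks\n"
        "chr1\t100\t150\tpeak1\t200\t+\n"
        "chr2\t500\t540\tpeak2\t.\t-\n"
    )
    sites = read_bed6(p)
    assert sites[0].interval == GenomicInterval("chr1", 100, 150, "+")
    assert sites[0].score == 200.0
    assert sites[1].score is None and sites[1].interval.strand == "-"
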