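"""Exact two-sided hypergeometric test, Bonferroni control, term filtering,
known/novel classification and the pathway-overlap network.

The independent oracle for the test statistic enumerates the full support
with exact rational arithmetic (math.comb + Fraction) and sums every point
probability not exceeding the observed one.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mibcnet import enrichment as enr
from mibcnet.published import SUBGRAPH_PATHWAYS


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------


def exact_pmf(x: int, K: int, n: int, N: int) -> Fraction:
    return Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))


def oracle_two_sided(k: int, K: int, n: int, N: int) -> float:
    lo, hi = max(0, n - (N - K)), min(n, K)
    pk = exact_pmf(k, K, n, N)
    total = sum(exact_pmf(x, K, n, N) for x in range(lo, hi + 1) if exact_pmf(x, K, n, N) <= pk)
    return float(total)


def random_valid_tuple(rng: np.random.Generator, n_max: int = 500):
    N = int(rng.integers(2, n_max + 1))
    K = int(rng.integers(0, N + 1))
    n = int(rng.integers(0, N + 1))
    lo, hi = max(0, n - (N - K)), min(n, K)
    k = int(rng.integers(lo, hi + 1))
    return k, K, n, N


class TestTwoSidedHypergeom:
    def test_degenerate_support_gives_p_one(self):
        # every background gene in the term: single achievable outcome
        assert enr.hypergeom_two_sided(5, 10, 5, 10) == 1.0

    def test_small_case_matches_enumeration_oracle(self):
        p = enr.hypergeom_two_sided(4, 5, 5, 20)
        assert p == pytest.approx(oracle_two_sided(4, 5, 5, 20), abs=1e-12)

    def test_support_completeness_of_oracle(self):
        for (k, K, n, N) in [(4, 5, 5, 20), (0, 3, 7, 12), (2, 6, 4, 9)]:
            lo, hi = max(0, n - (N - K)), min(n, K)
            assert sum(exact_pmf(x, K, n, N) for x in range(lo, hi + 1)) == 1

    def test_agrees_with_oracle_on_random_tuples(self):
        rng = np.random.default_rng(20240117)
        for _ in range(300):
            k, K, n, N = random_valid_tuple(rng, n_max=200)
            assert enr.hypergeom_two_sided(k, K, n, N) == pytest.approx(
                oracle_two_sided(k, K, n, N), abs=1e-12
            ), (k, K, n, N)

    def test_symmetry_in_K_and_n(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 200:
            k, K, n, N = random_valid_tuple(rng, n_max=150)
            # (k, n, K, N) must itself be a valid configuration
            if not max(0, K - (N - n)) <= k <= min(K, n):
                continue
            assert enr.hypergeom_two_sided(k, K, n, N) == pytest.approx(
                enr.hypergeom_two_sided(k, n, K, N), rel=1e-10
            )
            checked += 1

    def test_out_of_bounds_parameters_rejected(self):
        with pytest.raises(ValueError, match="k"):
            enr.hypergeom_two_sided(6, 5, 5, 20)
        with pytest.raises(ValueError, match="N"):
            enr.hypergeom_two_sided(0, 0, 0, 0)

    def test_doubling_variant_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k, K, n, N = random_valid_tuple(rng, n_max=100)
            p = enr.hypergeom_two_sided(k, K, n, N, method="doubling")
            assert 0 < p <= 1


class TestBonferroni:
    def test_identity_at_m_one_and_scaling(self):
        assert enr.bonferroni([0.2], 1) == [0.2]
        assert enr.bonferroni([0.04], 2) == [pytest.approx(0.08)]
        assert enr.bonferroni([0.9], 5) == [1.0]

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ValueError, match="family"):
            enr.bonferroni([0.1, 0.2], 1)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(1e-6, 1, size=50).tolist()
        for p, q in zip(ps, enr.bonferroni(ps, 80)):
            assert q >= p


class TestGmtAndFiltering:
    def test_two_line_gmt_parses_with_set_semantics(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("T1\tdesc\tA\tB\tB\nT2\tdesc\tC\n")
        db = enr.load_gmt(p)
        assert db.genes("T1") == {"A", "B"}
        assert db.universe == {"A", "B", "C"}

    def test_malformed_and_empty_lines_skipped(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("T1\tonlytwofields\nT2\tdesc\t\t\nT3\tdesc\tA\n")
        db = enr.load_gmt(p)
        assert set(db.terms) == {"T3"}

    def test_empty_file_gives_empty_db(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("")
        assert len(enr.load_gmt(p)) == 0

    def test_blacklist_is_case_insensitive_substring(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("Pathways in cancer\td\tA\tB\tC\nCell cycle\td\tA\tB\n")
        db = enr.load_gmt(p, blacklist={"pathways in cancer"})
        kept = enr.filter_terms(db)
        assert set(kept.terms) == {"Cell cycle"}

    def test_size_bounds(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("small\td\tA\tB\nmid\td\t" + "\t".join(f"g{i}" for i in range(10)) +
                     "\nbig\td\t" + "\t".join(f"h{i}" for i in range(900)) + "\n")
        db = enr.load_gmt(p)
        kept = enr.filter_terms(db, enr.EnrichmentConfig(min_term_size=3, max_term_size=500))
        assert set(kept.terms) == {"mid"}


class TestEnrich:
    def _db(self, terms):
        return enr.PathwayDB(terms={t: (t, frozenset(g)) for t, g in terms.items()})

    def test_toy_single_term_matches_oracle(self):
        universe = {f"g{i}" for i in range(20)}
        db = self._db({"T": {"g1", "g2", "g3", "g4", "g5"}})
        query = {"g1", "g2", "g3", "g4", "g10"}  # 4 term genes + 1 background gene
        res = enr.enrich(query, db, enr.EnrichmentConfig(min_overlap=1), background=universe)
        (r,) = res
        assert (r.k, r.K, r.n, r.N, r.m) == (4, 5, 5, 20, 1)
        assert r.p_raw == pytest.approx(oracle_two_sided(4, 5, 5, 20), abs=1e-12)
        assert r.p_adj == pytest.approx(r.p_raw)

    def test_below_min_overlap_terms_are_not_tested(self):
        db = self._db({"T1": {"a", "b", "c"}, "T2": {"x", "y", "z"}})
        res = enr.enrich({"a", "q", "r"}, db, enr.EnrichmentConfig(min_overlap=3),
                         background={"a", "b", "c", "x", "y", "z", "q", "r"})
        assert res == []

    def test_query_disjoint_from_background_raises(self):
        db = self._db({"T1": {"a", "b", "c"}})
        with pytest.raises(enr.EmptyQueryError):
            enr.enrich({"zz"}, db)

    def test_overlap_genes_self_consistency(self, synthetic_bundle):
        outdir, truth = synthetic_bundle
        db = enr.load_gmt(outdir / "pathways.gmt")
        query = set(list(truth.module_genes))
        res = enr.enrich(query, db, enr.EnrichmentConfig(min_overlap=1))
        assert res
        for r in res:
            assert len(r.overlap_genes) == r.k
            assert r.overlap_genes <= query
            assert r.overlap_genes <= db.genes(r.term_id)
            assert r.p_adj >= r.p_raw
            assert max(0, r.n - (r.N - r.K)) <= r.k <= min(r.n, r.K)

    def test_significance_set_shrinks_as_alpha_decreases(self, synthetic_bundle):
        outdir, truth = synthetic_bundle
        db = enr.load_gmt(outdir / "pathways.gmt")
        sig = {}
        for alpha in (0.1, 0.05, 0.01):
            res = enr.enrich(truth.module_genes, db, enr.EnrichmentConfig(alpha=alpha))
            sig[alpha] = {r.term_id for r in res if r.significant}
        assert sig[0.01] <= sig[0.05] <= sig[0.1]

    def test_result_ordering_is_deterministic(self, synthetic_bundle):
        outdir, truth = synthetic_bundle
        db = enr.load_gmt(outdir / "pathways.gmt")
        r1 = enr.enrich(truth.module_genes, db)
        r2 = enr.enrich(truth.module_genes, db)
        assert [r.term_id for r in r1] == [r.term_id for r in r2]
        keys = [(r.p_adj, -r.k, r.term_id) for r in r1]
        assert keys == sorted(keys)


class TestClassification:
    def test_empty_literature_list_makes_everything_novel(self):
        res = [enr.EnrichmentResult("t", "Cell cycle", 3, 5, 10, 100, 0.01, 0.02, 2,
                                    "enriched", True, frozenset({"A", "B", "C"}))]
        out = enr.classify_known_novel(res, [])
        assert out[0].status == "novel"

    def test_matching_is_case_punctuation_and_spelling_insensitive(self):
        res = [
            enr.EnrichmentResult("t1", "p53 Signaling Pathway", 3, 5, 10, 100, 0.01, 0.02,
                                 2, "enriched", True, frozenset("ABC")),
            enr.EnrichmentResult("t2", "ECM-receptor interaction", 3, 5, 10, 100, 0.01,
                                 0.02, 2, "enriched", True, frozenset("ABC")),
        ]
        out = enr.classify_known_novel(res, ["P53 signalling pathway", "ecm receptor interaction"])
        assert [r.status for r in out] == ["known", "known"]


class TestTermNetwork:
    @staticmethod
    def _results_from_memberships(memberships):
        return [
            enr.EnrichmentResult(name, name, len(genes), len(genes), 100, 1000,
                                 1e-4, 1e-3, 10, "enriched", True, frozenset(genes))
            for name, genes in memberships.items()
        ]

    def test_single_term_has_no_edges(self):
        g = enr.term_overlap_network(self._results_from_memberships({"A": {"x", "y", "z"}}))
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_published_mibc_membership_overlaps(self):
        """Cross-pathway shared-gene sets computed from the reported MIBC
        membership lists."""
        g = enr.term_overlap_network(self._results_from_memberships(SUBGRAPH_PATHWAYS))
        assert g.edges["Endocytosis", "Regulation of actin cytoskeleton"]["shared"] == {
            "EGFR", "FGFR3", "HRAS"
        }
        assert g.edges["Neurotrophin signalling pathway", "Endocytosis"]["shared"] == {"HRAS"}
        assert g.edges[
            "Regulation of actin cytoskeleton", "Serotonergic synapse"
        ]["shared"] == {"ARAF", "HRAS", "RAF1", "MAPK1"}
        assert g.edges[
            "Neurotrophin signalling pathway", "Serotonergic synapse"
        ]["shared"] == {"HRAS", "RAF1", "MAPK1"}

    def test_zero_overlap_pairs_have_no_edge(self):
        g = enr.term_overlap_network(
            self._results_from_memberships({"A": {"x", "y"}, "B": {"p", "q"}, "C": {"x", "p"}})
        )
        assert not g.has_edge("A", "B")
        assert g.has_edge("A", "C") and g.has_edge("B", "C")
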