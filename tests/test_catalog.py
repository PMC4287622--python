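"""Catalogue construction: study screening, symbol normalization,
consolidation with provenance, overlap accounting and the evidence filters."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mibcnet import catalog as cat


def feature(symbol: str, *provenance: tuple[str, str, str]) -> cat.MolecularFeature:
    return cat.MolecularFeature(symbol, set(provenance))


def _study(study_id="S1", omics="transcriptomics_mrna", n=60, fold=3.0, **kw):
    return cat.StudyRecord(study_id, omics, sample_size=n, max_abs_fold_change=fold, **kw)


class TestScreening:
    def test_sample_size_bound_is_inclusive_fold_bound_is_strict(self):
        assert cat.screen_studies([_study(n=50, fold=2.5)]) != []
        assert cat.screen_studies([_study(n=49, fold=5.0)]) == []
        # exactly 2-fold fails the strict ">2-fold" rule
        assert cat.screen_studies([_study(n=50, fold=2.0)]) == []

    def test_manual_trace_of_five_studies(self):
        studies = [
            _study("A", n=60, fold=3.0),
            _study("B", n=50, fold=2.0),
            _study("C", n=40, fold=5.0),
            _study("D", n=100, fold=1.5),
            cat.StudyRecord("E", "dna_mutation", sample_size=55),
        ]
        retained = cat.screen_studies(studies)
        assert [s.study_id for s in retained] == ["A", "E"]

    def test_fold_exemption_applies_to_literature_and_mutation_only(self):
        lit = cat.StudyRecord("L", "literature", sample_size=60)
        prof = cat.StudyRecord("P", "proteomics", sample_size=60)  # no fold reported
        retained = cat.screen_studies([lit, prof])
        assert [s.study_id for s in retained] == ["L"]

    def test_empty_input_gives_empty_output(self):
        assert cat.screen_studies([]) == []


class TestNormalization:
    def test_empty_input(self, toy_studies):
        feats, unmapped = cat.normalize_symbols([], {"x": "Y"}, toy_studies)
        assert feats == [] and unmapped == []

    def test_mapping_trace_reports_unmapped(self, toy_studies):
        raw = [cat.RawFeature(r, "PMID2") for r in ["p53", "EGFR_HUMAN", "XXX"]]
        mapping = {"p53": "TP53", "EGFR_HUMAN": "EGFR"}
        feats, unmapped = cat.normalize_symbols(raw, mapping, toy_studies)
        assert {f.symbol for f in feats} == {"TP53", "EGFR"}
        assert unmapped == ["XXX"]

    def test_mapping_route_follows_omics_layer(self, toy_studies):
        raw = [cat.RawFeature("hmdb1", "PMID3"), cat.RawFeature("g1", "PMID2")]
        feats, _ = cat.normalize_symbols(raw, {"hmdb1": "GAPDH", "g1": "EGFR"}, toy_studies)
        routes = {f.symbol: next(iter(f.provenance))[2] for f in feats}
        assert routes == {"GAPDH": "metabolite_enzyme", "EGFR": "direct"}


class TestConsolidation:
    def test_union_with_shared_provenance(self):
        a = [feature("A", ("s1", "literature", "direct")), feature("B", ("s1", "literature", "direct"))]
        b = [feature("B", ("s2", "proteomics", "direct")), feature("C", ("s2", "proteomics", "direct"))]
        catalog = cat.consolidate([a, b])
        assert catalog.n_input_features == 4
        assert catalog.symbols() == {"A", "B", "C"}
        assert catalog.features["B"].omics_types == {"literature", "proteomics"}

    def test_duplicate_free_list_is_identity(self):
        lst = [feature(s, ("s1", "literature", "direct")) for s in ["A", "B", "C"]]
        catalog = cat.consolidate([lst])
        assert len(catalog) == catalog.n_input_features == 3

    @given(
        lists=st.lists(
            st.lists(st.sampled_from([f"G{i}" for i in range(30)]), max_size=20),
            max_size=5,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_unique_count_matches_set_union_oracle(self, lists):
        """|catalogue| equals the brute-force union; equality with the summed
        sizes holds iff the deduplicated inputs are pairwise disjoint."""
        feats = [
            [feature(s, (f"s{i}", "literature", "direct")) for s in lst]
            for i, lst in enumerate(lists)
        ]
        catalog = cat.consolidate(feats)
        union = set().union(*[set(l) for l in lists]) if lists else set()
        assert catalog.symbols() == union
        assert len(catalog) <= sum(len(l) for l in lists)

    def test_consolidate_is_idempotent(self):
        a = [feature("A", ("s1", "literature", "direct")), feature("A", ("s2", "proteomics", "direct"))]
        once = cat.consolidate([a])
        twice = cat.consolidate([list(once.features.values())])
        assert {s: f.provenance for s, f in once.features.items()} == {
            s: f.provenance for s, f in twice.features.items()
        }


class TestOverlapMatrix:
    def test_disjoint_groups_have_zero_off_diagonal(self):
        catalog = cat.consolidate([
            [feature("A", ("s1", "literature", "direct"))],
            [feature("B", ("s2", "proteomics", "direct"))],
        ])
        m = cat.overlap_matrix(catalog, "omics_type")
        assert m.loc["literature", "proteomics"] == 0
        assert m.loc["literature", "literature"] == 1

    def test_symmetry_and_diagonal_dominance(self):
        catalog = cat.consolidate([
            [feature("A", ("s1", "literature", "direct")),
             feature("B", ("s1", "literature", "direct"))],
            [feature("B", ("s2", "proteomics", "direct")),
             feature("C", ("s2", "proteomics", "direct"))],
            [feature("B", ("s3", "dna_methylation", "direct"))],
        ])
        m = cat.overlap_matrix(catalog, "omics_type")
        assert (m.values == m.values.T).all()
        for g1 in m.index:
            for g2 in m.columns:
                assert m.loc[g1, g2] <= min(m.loc[g1, g1], m.loc[g2, g2])

    def test_literature_vs_omics_grouping(self):
        catalog = cat.consolidate([
            [feature("A", ("s1", "literature", "direct")),
             feature("B", ("s1", "literature", "direct"))],
            [feature("B", ("s2", "proteomics", "direct"))],
        ])
        m = cat.overlap_matrix(catalog, "literature_vs_omics")
        assert m.loc["literature", "omics"] == 1  # only B is in both

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError, match="grouping"):
            cat.overlap_matrix(cat.FeatureCatalog(), "by_chromosome")


class TestFilters:
    def test_exclude_indirect_keeps_mixed_route_symbols(self):
        catalog = cat.consolidate([
            [feature("A", ("s3", "metabolomics", "metabolite_enzyme"))],
            [feature("B", ("s3", "metabolomics", "metabolite_enzyme")),
             feature("B", ("s2", "transcriptomics_mrna", "direct"))],
        ])
        direct = cat.exclude_indirect(catalog)
        assert direct.symbols() == {"B"}

    def test_exclude_indirect_is_identity_without_indirect_routes(self):
        catalog = cat.consolidate([[feature("A", ("s1", "literature", "direct"))]])
        assert cat.exclude_indirect(catalog).symbols() == {"A"}

    def test_exclude_indirect_monotone_and_commutes_with_consolidate(self):
        lists = [
            [feature("A", ("s1", "metabolomics", "metabolite_enzyme"))],
            [feature("B", ("s2", "transcriptomics_mrna", "direct")),
             feature("A", ("s2", "transcriptomics_mrna", "direct"))],
        ]
        combined = cat.exclude_indirect(cat.consolidate(lists))
        per_list = cat.consolidate(
            [list(cat.exclude_indirect(cat.consolidate([l])).features.values()) for l in lists]
        )
        # A survives in both orders because it has a direct route in list 2
        assert combined.symbols() <= cat.consolidate(lists).symbols()
        assert combined.symbols() == per_list.symbols() == {"A", "B"}

    def test_multi_study_filter_counts_distinct_types(self):
        catalog = cat.consolidate([
            [feature("A", ("s1", "literature", "direct")),
             feature("A", ("s2", "proteomics", "direct"))],
            [feature("B", ("s2", "proteomics", "direct"))],
        ])
        assert cat.multi_study_filter(catalog, 1) == {"A", "B"}
        assert cat.multi_study_filter(catalog, 2) == {"A"}
        assert cat.multi_study_filter(catalog, 3) == set()

    def test_multi_study_filter_is_nested_in_min_types(self):
        catalog = cat.consolidate([
            [feature("A", ("s1", "literature", "direct")),
             feature("A", ("s2", "proteomics", "direct")),
             feature("A", ("s3", "dna_mutation", "direct")),
             feature("B", ("s2", "proteomics", "direct"))],
        ])
        for t in (1, 2, 3):
            assert cat.multi_study_filter(catalog, t + 1) <= cat.multi_study_filter(catalog, t)

    def test_biomarker_filter_requires_all_keywords(self, toy_studies):
        catalog = cat.consolidate([
            [feature("A", ("PMID1", "literature", "direct"))],     # tagged study
            [feature("B", ("PMID2", "transcriptomics_mrna", "direct"))],
        ])
        assert cat.biomarker_filter(catalog, toy_studies) == {"A"}
        # an untagged literature study contributes nothing
        untagged = dict(toy_studies)
        untagged["PMID9"] = cat.StudyRecord("PMID9", "literature", sample_size=70)
        catalog2 = cat.consolidate([[feature("C", ("PMID9", "literature", "direct"))]])
        assert cat.biomarker_filter(catalog2, untagged) == set()


class TestTableIO:
    def test_load_feature_table_skips_blank_identifiers(self, tmp_path, toy_studies):
        p = tmp_path / "t.tsv"
        p.write_text("raw_id\tdirection\tfold_change\ng1\tup\t2.5\n\tdown\t3.0\ng3\tdown\t-4.0\n")
        feats = cat.load_feature_table(p, toy_studies["PMID2"])
        assert [f.raw_id for f in feats] == ["g1", "g3"]
        assert feats[1].fold_change == -4.0

    def test_empty_table_with_header_gives_empty_list(self, tmp_path, toy_studies):
        p = tmp_path / "t.tsv"
        p.write_text("raw_id\tdirection\tfold_change\n")
        assert cat.load_feature_table(p, toy_studies["PMID2"]) == []

    def test_missing_identifier_column_names_expectation(self, tmp_path, toy_studies):
        p = tmp_path / "t.tsv"
        p.write_text("gene\tfc\nA\t2\n")
        with pytest.raises(cat.SchemaError, match="raw_id"):
            cat.load_feature_table(p, toy_studies["PMID2"])
        # a column map resolves the schema
        feats = cat.load_feature_table(p, toy_studies["PMID2"], columns={"raw_id": "gene"})
        assert [f.raw_id for f in feats] == ["A"]

    def test_missing_file_is_fatal(self, toy_studies):
        with pytest.raises(FileNotFoundError):
            cat.load_feature_table("nope.tsv", toy_studies["PMID2"])

    def test_catalog_tsv_round_trip(self, tmp_path):
        catalog = cat.consolidate([
            [feature("A", ("s1", "literature", "direct")),
             feature("B", ("s2", "metabolomics", "metabolite_enzyme"))],
        ])
        path = tmp_path / "catalog.tsv"
        catalog.write_tsv(path)
        back = cat.FeatureCatalog.read_tsv(path)
        assert back.symbols() == catalog.symbols()
        assert back.features["B"].provenance == {("s2", "metabolomics", "metabolite_enzyme")}
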