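"""Consolidating multi-study gene lists into a unique-symbol catalogue.

Four mock studies of muscle-invasive bladder cancer report overlapping gene
lists across different omics layers. We screen the studies for design quality,
normalize their raw identifiers to official symbols (with layer-appropriate
mapping routes), merge everything into a unique catalogue, and apply the
indirect-route exclusion and the multi-study-type filter.
"""

from mibcnet import catalog as cat

# -- study metadata: one literature review, two profiling screens, one
#    underpowered screen that will be rejected by the sample-size rule
studies = [
    cat.StudyRecord("LIT1", "literature", sample_size=120,
                    keywords={"molecular", "biomarker"}),
    cat.StudyRecord("MRNA1", "transcriptomics_mrna", sample_size=80,
                    max_abs_fold_change=3.5),
    cat.StudyRecord("MET1", "metabolomics", sample_size=60,
                    max_abs_fold_change=2.8),
    cat.StudyRecord("SMALL1", "transcriptomics_mrna", sample_size=12,
                    max_abs_fold_change=9.0),
]
retained = cat.screen_studies(studies)
print(f"study screening: {len(retained)}/{len(studies)} retained "
      f"({', '.join(s.study_id for s in retained)})")

# -- raw per-study feature tables (identifier rows before symbol mapping)
raw = {
    "LIT1": ["tp53", "fgfr3", "egfr"],
    "MRNA1": ["fgfr3", "ccnd1", "erbb2"],
    "MET1": ["odc1", "egfr"],  # enzymes of altered metabolites
    "SMALL1": ["mycn"],        # never enters: its study was screened out
}
mapping = {r: r.upper() for rows in raw.values() for r in rows}
by_id = {s.study_id: s for s in retained}

lists = []
for s in retained:
    feats, unmapped = cat.normalize_symbols(
        [cat.RawFeature(r, s.study_id) for r in raw[s.study_id]], mapping, by_id
    )
    lists.append(feats)

catalog = cat.consolidate(lists)
print(f"consolidation: {catalog.n_input_features} input features -> "
      f"{len(catalog)} unique symbols: {', '.join(sorted(catalog.symbols()))}")

# ODC1 is supported only by the metabolite->enzyme route, so the
# network-analysis catalogue drops it; EGFR survives via its direct route.
direct = cat.exclude_indirect(catalog)
print(f"indirect-route exclusion: {len(catalog)} -> {len(direct)} symbols "
      f"(removed {', '.join(sorted(catalog.symbols() - direct.symbols()))})")

# genes recurring in >= 2 distinct study types are the high-confidence core
core = cat.multi_study_filter(catalog, min_types=2)
print(f"multi-study-type filter (>=2 layers): {', '.join(sorted(core))}")

print("\nomics-layer overlap matrix (symbol counts):")
print(cat.overlap_matrix(catalog, grouping="omics_type"))
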