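from __future__ import annotations

import pytest

from mibcnet.catalog import StudyRecord


@pytest.fixture
def toy_studies() -> dict[str, StudyRecord]:
    """Three studies over distinct layers: a literature report tagged with the
    biomarker keywords, an mRNA screen, and a metabolomics screen."""
    studies = [
        StudyRecord("PMID1", "literature", sample_size=80,
                    keywords=frozenset({"molecular", "biomarker"})),
        StudyRecord("PMID2", "transcriptomics_mrna", sample_size=120,
                    max_abs_fold_change=3.5),
        StudyRecord("PMID3", "metabolomics", sample_size=60, max_abs_fold_change=2.8),
    ]
    return {s.study_id: s for s in studies}


@pytest.fixture
def synthetic_bundle(tmp_path_factory):
    """One small synthetic bundle shared across tests (module of 20 genes in a
    400-gene universe, 7 studies, 3 of 50 terms planted)."""
    from mibcnet.synthetic import SyntheticParams, generate_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    params = SyntheticParams(
        n_genes=400, module_size=20, n_studies=7, n_terms=50,
        term_size_range=(8, 20), n_planted_terms=3, planted_fraction=0.5,
    )
    truth = generate_bundle(outdir, params, seed=11)
    return outdir, truth
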