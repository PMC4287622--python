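"""End-to-end orchestration: screen → normalize → consolidate → exclude
indirect → induce → connectivity filter → enrich → classify → overlap network
→ literature ranking, driven by a single YAML configuration, with a run
manifest that records input digests, resolved parameters and the per-stage
feature funnel."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from . import catalog as cat
from . import enrichment as enr
from . import evidence as evd
from . import interactome as net

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; all paths absolute."""

    studies: Path
    feature_tables: dict[str, Path]
    id_mapping: Path
    edges: list[Path]
    pathways: Path
    outdir: Path
    blacklist: Path | None = None
    literature_terms: Path | None = None
    gene2pubmed: Path | None = None
    gene_id_map: Path | None = None
    relevant_pmids: Path | None = None
    screening: cat.ScreeningConfig = field(default_factory=cat.ScreeningConfig)
    enrichment: enr.EnrichmentConfig = field(default_factory=enr.EnrichmentConfig)
    multi_study_min_types: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def _p(key: str, required: bool = False) -> Path | None:
            v = raw.get(key)
            if v is None:
                if required:
                    raise ValueError(f"config missing required path {key!r}")
                return None
            return (base / v).resolve()

        scr = dict(raw.get("screening") or {})
        if "required_keywords" in scr:
            scr["required_keywords"] = frozenset(scr["required_keywords"])
        screening = cat.ScreeningConfig(**scr)
        enrichment = enr.EnrichmentConfig(**(raw.get("enrichment") or {}))
        tables = {
            str(k): (base / v).resolve() for k, v in (raw.get("feature_tables") or {}).items()
        }
        edges_raw = raw.get("edges") or []
        if isinstance(edges_raw, str):
            edges_raw = [edges_raw]
        cfg = cls(
            studies=_p("studies", required=True),
            feature_tables=tables,
            id_mapping=_p("id_mapping", required=True),
            edges=[(base / e).resolve() for e in edges_raw],
            pathways=_p("pathways", required=True),
            outdir=(base / raw.get("outdir", "out")).resolve(),
            blacklist=_p("blacklist"),
            literature_terms=_p("literature_terms"),
            gene2pubmed=_p("gene2pubmed"),
            gene_id_map=_p("gene_id_map"),
            relevant_pmids=_p("relevant_pmids"),
            screening=screening,
            enrichment=enrichment,
            multi_study_min_types=int(raw.get("multi_study_min_types", 2)),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.studies, self.id_mapping, self.pathways, *self.edges,
                 *self.feature_tables.values()]
        paths += [p for p in (self.blacklist, self.literature_terms, self.gene2pubmed,
                              self.gene_id_map, self.relevant_pmids) if p is not None]
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing inputs: {missing}")


def config_for_bundle(bundle_dir: str | Path, outdir: str | Path | None = None) -> PipelineConfig:
    """Build a configuration for a directory produced by
    :func:`mibcnet.synthetic.generate_bundle`."""
    bundle = Path(bundle_dir)
    studies = cat.load_studies_table(bundle / "studies.tsv")
    tables = {s.study_id: bundle / f"features_{s.study_id}.tsv" for s in studies}
    cfg = PipelineConfig(
        studies=bundle / "studies.tsv",
        feature_tables=tables,
        id_mapping=bundle / "id_mapping.tsv",
        edges=[bundle / "edges.tsv"],
        pathways=bundle / "pathways.gmt",
        outdir=Path(outdir) if outdir else bundle / "out",
        blacklist=bundle / "blacklist.txt",
        literature_terms=bundle / "literature_terms.txt",
        gene2pubmed=bundle / "gene2pubmed.tsv",
        gene_id_map=bundle / "gene_id_map.tsv",
        relevant_pmids=bundle / "relevant_pmids.txt",
    )
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_config_template(path: str | Path) -> Path:
    """Emit a fully commented configuration template with all defaults explicit."""
    template = """\
# mibcnet pipeline configuration (paths are relative to this file)
studies: studies.tsv            # study metadata table
feature_tables:                 # study_id -> per-study feature table
  S001: features_S001.tsv
id_mapping: id_mapping.tsv      # raw_id -> official symbol
edges:                          # one or more interaction edge lists
  - edges.tsv
pathways: pathways.gmt          # GMT pathway catalogue
blacklist: blacklist.txt        # general-disease term patterns, one per line
literature_terms: literature_terms.txt   # known-pathway names, one per line
gene2pubmed: gene2pubmed.tsv    # tax_id / GeneID / PubMed_ID
gene_id_map: gene_id_map.tsv    # GeneID -> symbol
relevant_pmids: relevant_pmids.txt       # phenotype-relevant PubMed IDs
outdir: out
seed: 0
multi_study_min_types: 2
screening:
  min_sample_size: 50           # inclusive ("at least 50 samples")
  min_fold_change: 2.0          # strict (">2-fold change"); profiling layers only
  required_keywords: [molecular, biomarker]
enrichment:
  alpha: 0.05
  background_mode: pathway_universe   # or interactome_restricted
  min_overlap: 3
  two_sided_method: minlike     # or doubling
"""
    path = Path(path)
    path.write_text(template)
    return path


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline; writes all stage outputs plus manifest.json
    into ``config.outdir`` and returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, Any] = {}

    # stage 1: study screening
    studies = cat.load_studies_table(config.studies)
    retained_studies = cat.screen_studies(studies, config.screening)
    studies_by_id = {s.study_id: s for s in retained_studies}
    counts["studies_total"] = len(studies)
    counts["studies_retained"] = len(retained_studies)

    # stage 2: ingestion + symbol normalization
    mapping = cat.load_mapping_table(config.id_mapping)
    feature_lists = []
    n_unmapped = 0
    for s in retained_studies:
        table = config.feature_tables.get(s.study_id)
        if table is None:
            logger.warning("no feature table configured for study %s", s.study_id)
            continue
        raw = cat.load_feature_table(table, s)
        feats, unmapped = cat.normalize_symbols(raw, mapping, studies_by_id)
        n_unmapped += len(unmapped)
        feature_lists.append(feats)
    counts["raw_unmapped"] = n_unmapped

    # stage 3: consolidation
    catalog = cat.consolidate(feature_lists, config.screening)
    catalog.write_tsv(out / "catalog.tsv")
    counts["features_input"] = catalog.n_input_features
    counts["features_unique"] = len(catalog)
    cat.overlap_matrix(catalog, "omics_type").to_csv(out / "overlap_omics.tsv", sep="\t")
    cat.overlap_matrix(catalog, "literature_vs_omics").to_csv(
        out / "overlap_literature_vs_omics.tsv", sep="\t"
    )

    # stage 4: indirect-feature exclusion
    direct = cat.exclude_indirect(catalog)
    direct.write_tsv(out / "catalog_direct.tsv")
    counts["features_direct"] = len(direct)
    multi = cat.multi_study_filter(direct, config.multi_study_min_types)
    (out / "multi_study_symbols.txt").write_text("".join(s + "\n" for s in sorted(multi)))
    counts["features_multi_study"] = len(multi)

    # stage 5: interactome merge + induction + connectivity filter
    edge_lists = [net.load_edges(p) for p in config.edges]
    network = net.merge_networks(edge_lists)
    counts["interactome_nodes"] = network.number_of_nodes()
    counts["interactome_edges"] = network.number_of_edges()
    sub = net.drop_isolated(net.induce_subgraph(network, direct.symbols()))
    sub.membership_frame().to_csv(out / "subgraph_membership.tsv", sep="\t", index=False)
    net.export_network(sub, out / "subgraph_edges.tsv", "tsv")
    net.export_network(sub, out / "subgraph.graphml", "graphml")
    counts["subgraph_members"] = len(sub.members)
    counts["subgraph_retained"] = len(sub.retained)

    # stage 6: pathway enrichment
    blacklist = enr.load_blacklist(config.blacklist) if config.blacklist else frozenset()
    db = enr.load_gmt(config.pathways, blacklist=blacklist)
    background = None
    if config.enrichment.background_mode == "interactome_restricted":
        background = db.universe & set(network.nodes)
    try:
        results = enr.enrich(sub.retained, db, config.enrichment, background=background)
    except enr.EmptyQueryError:
        logger.warning("enrichment query empty after background intersection")
        results = []
    if config.literature_terms:
        lit_terms = [
            t.strip() for t in Path(config.literature_terms).read_text().splitlines() if t.strip()
        ]
        results = enr.classify_known_novel(results, lit_terms)
    enr.results_to_frame(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    counts["terms_family"] = results[0].m if results else 0
    counts["terms_reported"] = len(results)
    counts["terms_significant"] = sum(r.significant for r in results)
    counts["terms_known"] = sum(r.status == "known" and r.significant for r in results)
    counts["terms_novel"] = sum(r.status == "novel" and r.significant for r in results)

    # stage 7: pathway-overlap network
    term_net = enr.term_overlap_network(results)
    with open(out / "term_network_edges.tsv", "w") as fh:
        fh.write("term_a\tterm_b\tn_shared\tshared_genes\n")
        for a, b, data in sorted(term_net.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']}\t{';'.join(sorted(data['shared']))}\n")
    counts["term_network_nodes"] = term_net.number_of_nodes()
    counts["term_network_edges"] = term_net.number_of_edges()

    # stage 8: literature-evidence ranking
    if config.gene2pubmed and config.gene_id_map and config.relevant_pmids:
        id_map = evd.load_id_mapping(config.gene_id_map)
        index = evd.load_gene2pubmed(config.gene2pubmed, id_map)
        index = evd.restrict_to_relevant(index, evd.load_pmid_list(config.relevant_pmids))
        candidates = cat.biomarker_filter(catalog, studies_by_id)
        path_df, gene_df, (n_cov, n_cand) = evd.rank_candidates(results, index, candidates)
        path_df.to_csv(out / "pathway_ranking.tsv", sep="\t", index=False)
        gene_df.to_csv(out / "gene_ranking.tsv", sep="\t", index=False)
        counts["literature_candidates"] = n_cand
        counts["literature_candidates_covered"] = n_cov

    manifest = build_manifest(config, counts)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def build_manifest(config: PipelineConfig, counts: Mapping[str, Any]) -> dict[str, Any]:
    inputs = {}
    for label, p in [
        ("studies", config.studies),
        ("id_mapping", config.id_mapping),
        ("pathways", config.pathways),
        ("blacklist", config.blacklist),
        ("literature_terms", config.literature_terms),
        ("gene2pubmed", config.gene2pubmed),
        ("gene_id_map", config.gene_id_map),
        ("relevant_pmids", config.relevant_pmids),
    ]:
        if p is not None:
            inputs[label] = _sha256(p)
    for i, p in enumerate(config.edges):
        inputs[f"edges_{i}"] = _sha256(p)
    for sid, p in sorted(config.feature_tables.items()):
        inputs[f"features_{sid}"] = _sha256(p)
    return {
        "tool": "mibcnet",
        "version": __version__,
        "seed": config.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": inputs,
        "parameters": {
            "alpha": config.enrichment.alpha,
            "min_overlap": config.enrichment.min_overlap,
            "background_mode": config.enrichment.background_mode,
            "two_sided_method": config.enrichment.two_sided_method,
            "min_sample_size": config.screening.min_sample_size,
            "min_fold_change": config.screening.min_fold_change,
            "required_keywords": sorted(config.screening.required_keywords),
            "multi_study_min_types": config.multi_study_min_types,
        },
        "counts": dict(counts),
    }


def write_report(outdir: str | Path) -> Path:
    """Merge manifest + enrichment results into one JSON summary."""
    out = Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    summary: dict[str, Any] = {"manifest": manifest}
    enr_path = out / "enrichment.tsv"
    if enr_path.exists():
        import pandas as pd

        df = pd.read_csv(enr_path, sep="\t")
        summary["significant_terms"] = (
            df[df["significant"]][["term_id", "name", "k", "p_adj", "status"]]
            .to_dict(orient="records")
            if not df.empty
            else []
        )
    report = out / "report.json"
    report.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return report
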