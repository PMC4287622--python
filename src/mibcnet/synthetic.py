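"""Synthetic multi-omics benchmark generator with a planted disease module.

Emulates the statistical structure the pipeline assumes: a scale-free
interactome containing a connected planted disease module; several studies
per omics layer, each reporting module genes with probability π
(signal_fraction) and background genes with probability ρ (noise_rate); a
pathway catalogue in which a chosen subset of terms is genuinely
over-represented in the module; and a gene2pubmed-style literature table
linking module genes to phenotype-relevant publications. Every generator is a
pure function of (parameters, seed), and all outputs use exactly the file
dialects consumed by the catalog / interactome / enrichment / evidence
modules, so the full pipeline can run end-to-end against exported ground
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .catalog import RawFeature, StudyRecord
from .enrichment import PathwayDB

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "gen_universe",
    "gen_network",
    "gen_pathway_db",
    "gen_disease_studies",
    "gen_gene2pubmed",
    "generate_bundle",
]

#: omics layers cycled over when assigning study types (includes the two
#: indirect-route layers so indirect-feature exclusion is exercised)
_OMICS_CYCLE = (
    "literature",
    "transcriptomics_mrna",
    "proteomics",
    "dna_methylation",
    "dna_mutation",
    "transcriptomics_mirna",
    "metabolomics",
)


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameterization. Defaults are the strong-signal benchmark
    regime: a 50-gene connected module in a 2,000-gene scale-free interactome,
    10 studies across 5 evidence layers reporting module genes with
    probability 0.8 and background genes with probability 0.01, and 5 planted
    terms among 200 drawing half their genes from the module."""

    n_genes: int = 2000
    network_model: str = "scale_free"  # or "erdos_renyi"
    ba_m: int = 3
    er_p: float = 0.01
    module_size: int = 50
    n_terms: int = 200
    term_size_range: tuple[int, int] = (10, 50)
    n_planted_terms: int = 5
    planted_fraction: float = 0.5
    n_studies: int = 10
    signal_fraction: float = 0.8  # pi: P(study reports a module gene)
    noise_rate: float = 0.01      # rho: P(study reports a background gene)
    min_sample_size: int = 50
    max_sample_size: int = 200
    pubs_per_module_gene: float = 3.0  # Poisson mean of relevant pubs
    module_pub_prob: float = 0.9       # P(module gene gets >= 1 relevant pub)
    background_pub_rate: float = 0.01  # P(background gene gets a relevant pub)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0 <= self.signal_fraction <= 1 and 0 <= self.noise_rate <= 1):
            raise ValueError("signal_fraction and noise_rate must lie in [0, 1]")
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")


@dataclass
class SyntheticTruth:
    """Exported ground truth of one generated bundle."""

    module_genes: set[str]
    planted_terms: set[str]
    seed: int
    params: SyntheticParams

    def to_json(self) -> str:
        payload = {
            "module_genes": sorted(self.module_genes),
            "planted_terms": sorted(self.planted_terms),
            "seed": self.seed,
            "params": asdict(self.params),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def gen_universe(n_genes: int, seed: int = 0) -> list[str]:
    """``n_genes`` distinct synthetic symbols G000001…; deterministic."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return [f"G{i:06d}" for i in range(1, n_genes + 1)]


def gen_network(
    universe: Sequence[str],
    model: str = "scale_free",
    seed: int = 0,
    m: int = 3,
    p: float = 0.01,
    connect: Sequence[str] | None = None,
) -> nx.Graph:
    """Random simple undirected interactome over ``universe``.

    ``scale_free`` uses Barabási–Albert preferential attachment with ``m``
    edges per incoming node (exactly m·(n−m) edges); ``erdos_renyi`` uses
    G(n, p). If ``connect`` is given, those nodes are additionally joined by a
    random spanning path so the planted module is connected regardless of the
    random topology.
    """
    n = len(universe)
    if model == "scale_free":
        if not 1 <= m < n:
            raise ValueError(f"scale_free requires 1 <= m < n, got m={m}, n={n}")
        g0 = nx.barabasi_albert_graph(n, m, seed=seed)
    elif model == "erdos_renyi":
        if not 0 <= p <= 1:
            raise ValueError("erdos_renyi requires 0 <= p <= 1")
        g0 = nx.gnp_random_graph(n, p, seed=seed)
    else:
        raise ValueError(f"unknown network model {model!r}")
    relabel = dict(enumerate(universe))
    g = nx.relabel_nodes(g0, relabel)
    for a, b in g.edges:
        g.edges[a, b]["sources"] = {"synthetic"}
    if connect:
        rng = np.random.default_rng(seed)
        order = list(connect)
        rng.shuffle(order)
        for a, b in zip(order, order[1:]):  # spanning path = spanning tree
            if not g.has_edge(a, b):
                g.add_edge(a, b, sources={"synthetic"})
    return g


def gen_pathway_db(
    universe: Sequence[str],
    n_terms: int,
    size_range: tuple[int, int],
    seed: int = 0,
    module_genes: Sequence[str] = (),
    n_planted: int = 0,
    planted_fraction: float = 0.5,
) -> tuple[PathwayDB, set[str]]:
    """Random pathway catalogue with ``n_planted`` terms over-representing the
    module.

    Non-planted terms sample their genes uniformly from the universe; each
    planted term draws ``round(planted_fraction * size)`` genes from the
    module and the rest from outside it. Returns (db, planted term ids).
    """
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError(f"size_range {size_range} infeasible for universe of {len(universe)}")
    if n_planted > n_terms:
        raise ValueError("n_planted cannot exceed n_terms")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    module = list(module_genes)
    non_module = [g for g in universe if g not in set(module)]
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted_ids: set[str] = set()
    for i in range(n_terms):
        term_id = f"T{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_planted:
            n_from_module = int(round(planted_fraction * size))
            if n_from_module > len(module):
                raise ValueError(
                    f"planted spec infeasible: {n_from_module} module genes needed for "
                    f"term of size {size}, module has {len(module)}"
                )
            picked = list(rng.choice(module, size=n_from_module, replace=False))
            picked += list(rng.choice(non_module, size=size - n_from_module, replace=False))
            planted_ids.add(term_id)
        else:
            picked = list(rng.choice(universe, size=size, replace=False))
        terms[term_id] = (term_id, frozenset(picked))
    return PathwayDB(terms=terms), planted_ids


def gen_disease_studies(
    universe: Sequence[str],
    module_genes: Sequence[str],
    n_studies: int,
    signal_fraction: float,
    noise_rate: float,
    seed: int = 0,
    min_sample_size: int = 50,
    max_sample_size: int = 200,
) -> tuple[list[StudyRecord], dict[str, list[RawFeature]]]:
    """Per-study raw feature lists with Bernoulli reporting.

    Each study reports each module gene with probability π and each
    non-module gene with probability ρ. Reported genes in profiling layers
    get |fold change| > 2 so design screening retains the study; literature
    studies carry the {molecular, biomarker} keywords. Raw identifiers are
    ``raw_<SYMBOL>`` (resolved by the identity-style mapping table the bundle
    writer emits).
    """
    rng = np.random.default_rng(seed)
    module = set(module_genes)
    background = [g for g in universe if g not in module]
    studies: list[StudyRecord] = []
    tables: dict[str, list[RawFeature]] = {}
    for i in range(n_studies):
        omics = _OMICS_CYCLE[i % len(_OMICS_CYCLE)]
        study_id = f"S{i + 1:03d}"
        reported = [g for g in sorted(module) if rng.random() < signal_fraction]
        reported += [g for g in background if rng.random() < noise_rate]
        feats = []
        max_fold = None
        for g in reported:
            if omics in ("literature", "dna_mutation"):
                feats.append(RawFeature(f"raw_{g}", study_id, direction="present"))
            else:
                fold = float(rng.uniform(2.5, 8.0))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                feats.append(
                    RawFeature(f"raw_{g}", study_id, direction="up" if sign > 0 else "down",
                               fold_change=sign * fold)
                )
                max_fold = fold if max_fold is None else max(max_fold, fold)
        studies.append(
            StudyRecord(
                study_id=study_id,
                omics_type=omics,
                sample_size=int(rng.integers(min_sample_size, max_sample_size + 1)),
                max_abs_fold_change=max_fold,
                keywords=frozenset({"molecular", "biomarker"}) if omics == "literature" else frozenset(),
                stages=frozenset({"T2a", "T3b"}),
            )
        )
        tables[study_id] = feats
    return studies, tables


def gen_gene2pubmed(
    universe: Sequence[str],
    module_genes: Sequence[str],
    seed: int = 0,
    pubs_per_module_gene: float = 3.0,
    module_pub_prob: float = 0.9,
    background_pub_rate: float = 0.01,
) -> tuple[list[tuple[str, str, str]], dict[str, str], frozenset[str]]:
    """Synthetic gene→publication links in gene2pubmed dialect.

    Module genes get 1 + Poisson(λ−1) phenotype-relevant publications with
    probability ``module_pub_prob``; background genes get one with probability
    ``background_pub_rate``. Every gene additionally gets one irrelevant
    publication so relevance restriction is non-trivial.

    Returns (rows of (tax_id, gene_id, pmid), gene_id→symbol map, relevant PMIDs).
    """
    rng = np.random.default_rng(seed)
    module = set(module_genes)
    id_map = {str(100000 + i): sym for i, sym in enumerate(universe)}
    sym_to_id = {v: k for k, v in id_map.items()}
    rows: list[tuple[str, str, str]] = []
    relevant: set[str] = set()
    next_pmid = 9_000_001
    for sym in universe:
        gid = sym_to_id[sym]
        # one irrelevant publication per gene
        rows.append(("9606", gid, str(next_pmid)))
        next_pmid += 1
        if sym in module:
            if rng.random() < module_pub_prob:
                n_pubs = 1 + int(rng.poisson(max(pubs_per_module_gene - 1.0, 0.0)))
                for _ in range(n_pubs):
                    pmid = str(next_pmid)
                    next_pmid += 1
                    rows.append(("9606", gid, pmid))
                    relevant.add(pmid)
        elif rng.random() < background_pub_rate:
            pmid = str(next_pmid)
            next_pmid += 1
            rows.append(("9606", gid, pmid))
            relevant.add(pmid)
    return rows, id_map, frozenset(relevant)


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------


def generate_bundle(
    outdir: str | Path, params: SyntheticParams | None = None, seed: int = 0
) -> SyntheticTruth:
    """Write a complete synthetic input bundle (all pipeline dialects) plus
    ground-truth JSON to ``outdir``; returns the truth object.

    Files: studies.tsv, features_<study>.tsv, id_mapping.tsv, edges.tsv,
    pathways.gmt, blacklist.txt, literature_terms.txt, gene2pubmed.tsv,
    gene_id_map.tsv, relevant_pmids.txt, truth.json.
    """
    params = params or SyntheticParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    universe = gen_universe(params.n_genes, seed)
    module = sorted(rng.choice(universe, size=params.module_size, replace=False))
    net = gen_network(
        universe, model=params.network_model, seed=seed,
        m=params.ba_m, p=params.er_p, connect=module,
    )
    db, planted = gen_pathway_db(
        universe, params.n_terms, params.term_size_range, seed=seed,
        module_genes=module, n_planted=params.n_planted_terms,
        planted_fraction=params.planted_fraction,
    )
    studies, tables = gen_disease_studies(
        universe, module, params.n_studies, params.signal_fraction, params.noise_rate,
        seed=seed, min_sample_size=params.min_sample_size,
        max_sample_size=params.max_sample_size,
    )
    g2p_rows, id_map, relevant = gen_gene2pubmed(
        universe, module, seed=seed,
        pubs_per_module_gene=params.pubs_per_module_gene,
        module_pub_prob=params.module_pub_prob,
        background_pub_rate=params.background_pub_rate,
    )

    # studies + per-study feature tables
    with open(outdir / "studies.tsv", "w") as fh:
        fh.write("study_id\tomics_type\tsample_size\tmax_abs_fold_change\tkeywords\tstages\n")
        for s in studies:
            fold = "" if s.max_abs_fold_change is None else f"{s.max_abs_fold_change:.6g}"
            fh.write(
                f"{s.study_id}\t{s.omics_type}\t{s.sample_size}\t{fold}\t"
                f"{';'.join(sorted(s.keywords))}\t{';'.join(sorted(s.stages))}\n"
            )
    for study_id, feats in tables.items():
        with open(outdir / f"features_{study_id}.tsv", "w") as fh:
            fh.write("raw_id\tdirection\tfold_change\n")
            for f in feats:
                fc = "" if f.fold_change is None else f"{f.fold_change:.6g}"
                fh.write(f"{f.raw_id}\t{f.direction}\t{fc}\n")
    with open(outdir / "id_mapping.tsv", "w") as fh:
        fh.write("raw_id\tsymbol\n")
        for sym in universe:
            fh.write(f"raw_{sym}\t{sym}\n")

    # interactome
    with open(outdir / "edges.tsv", "w") as fh:
        fh.write("interactor_a\tinteractor_b\tsource_db\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\tsynthetic\n")

    # pathways; planted terms double as the "literature-known" list
    with open(outdir / "pathways.gmt", "w") as fh:
        for term_id in sorted(db.terms):
            name, genes = db.terms[term_id]
            fh.write("\t".join([term_id, "synthetic"] + sorted(genes)) + "\n")
    (outdir / "blacklist.txt").write_text("")
    with open(outdir / "literature_terms.txt", "w") as fh:
        for t in sorted(planted):
            fh.write(t + "\n")

    # literature evidence
    with open(outdir / "gene2pubmed.tsv", "w") as fh:
        fh.write("#tax_id\tGeneID\tPubMed_ID\n")
        for row in g2p_rows:
            fh.write("\t".join(row) + "\n")
    with open(outdir / "gene_id_map.tsv", "w") as fh:
        fh.write("gene_id\tsymbol\n")
        for gid in sorted(id_map):
            fh.write(f"{gid}\t{id_map[gid]}\n")
    with open(outdir / "relevant_pmids.txt", "w") as fh:
        for pmid in sorted(relevant):
            fh.write(pmid + "\n")

    truth = SyntheticTruth(
        module_genes=set(module), planted_terms=planted, seed=seed, params=params
    )
    (outdir / "truth.json").write_text(truth.to_json())
    return truth
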