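"""Literature-evidence ranking of genes and pathways.

NCBI's gene2pubmed table links genes to the publications that mention them.
Intersecting those links with a curated set of phenotype-relevant PubMed IDs
(here: urinary bladder neoplasm / muscle-invasion publications) yields, per
gene, its annotation depth (number of distinct relevant publications) and, per
pathway, the literature relevance ratio

    r = |{genes in the pathway linked to >= 1 relevant publication}| / |pathway genes|,

both of which drive the relevance ranking of enriched pathways and their
member genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)


@dataclass
class LiteratureIndex:
    """Gene symbol → set of publication IDs (optionally restricted to a
    phenotype-relevant publication set)."""

    links: dict[str, set[str]] = field(default_factory=dict)
    relevant_pubs: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.links)

    def pub_count(self, symbol: str) -> int:
        return len(self.links.get(symbol.upper(), ()))

    def is_linked(self, symbol: str) -> bool:
        return bool(self.links.get(symbol.upper()))


@dataclass(frozen=True)
class RelevanceScore:
    pathway_ratio: float
    n_linked: int
    n_genes: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pathway_ratio <= 1.0:
            raise ValueError("pathway_ratio must lie in [0, 1]")


def load_gene2pubmed(
    path: str | Path,
    id_to_symbol: Mapping[str, str],
    taxon: str = "9606",
) -> LiteratureIndex:
    """Parse a gene2pubmed-dialect TSV (tax_id, GeneID, PubMed_ID).

    Rows of other taxa are dropped (default keeps human, 9606); rows with a
    GeneID absent from the mapping are counted and skipped. Duplicate
    (gene, pmid) rows collapse to set semantics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene2pubmed table not found: {path}")
    links: dict[str, set[str]] = {}
    n_unmapped = n_other_taxon = n_malformed = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                n_malformed += 1
                continue
            tax, gene_id, pmid = (f.strip() for f in fields[:3])
            if tax != taxon:
                n_other_taxon += 1
                continue
            symbol = id_to_symbol.get(gene_id)
            if symbol is None:
                n_unmapped += 1
                continue
            links.setdefault(symbol.upper(), set()).add(pmid)
    if n_unmapped or n_other_taxon or n_malformed:
        logger.info(
            "gene2pubmed: %d unmappable GeneIDs, %d non-taxon rows, %d malformed rows skipped",
            n_unmapped, n_other_taxon, n_malformed,
        )
    return LiteratureIndex(links=links)


def load_id_mapping(path: str | Path) -> dict[str, str]:
    """GeneID → symbol mapping TSV (two columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if {"gene_id", "symbol"} <= set(df.columns):
        a, b = "gene_id", "symbol"
    else:
        a, b = df.columns[:2]
    return {
        str(r[a]).strip(): str(r[b]).strip().upper()
        for _, r in df.iterrows()
        if pd.notna(r[a]) and pd.notna(r[b])
    }


def load_pmid_list(path: str | Path) -> frozenset[str]:
    """One PubMed ID per line."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def restrict_to_relevant(index: LiteratureIndex, relevant_pubs: Iterable[str]) -> LiteratureIndex:
    """Keep only links to phenotype-relevant publications; genes left with no
    relevant link are removed."""
    relevant = frozenset(str(p) for p in relevant_pubs)
    if not relevant:
        raise ValueError("relevant_pubs must be non-empty")
    links = {}
    for sym, pubs in index.links.items():
        kept = pubs & relevant
        if kept:
            links[sym] = kept
    return LiteratureIndex(links=links, relevant_pubs=relevant)


def pathway_relevance_ratio(pathway_genes: Iterable[str], index: LiteratureIndex) -> RelevanceScore:
    """Fraction of pathway members linked to at least one relevant publication."""
    genes = {g.upper() for g in pathway_genes}
    if not genes:
        raise ValueError("pathway_genes must be non-empty (ratio undefined)")
    n_linked = sum(1 for g in genes if index.is_linked(g))
    return RelevanceScore(
        pathway_ratio=n_linked / len(genes), n_linked=n_linked, n_genes=len(genes)
    )


def rank_candidates(
    results: Sequence[EnrichmentResult],
    index: LiteratureIndex,
    literature_candidates: Iterable[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[int, int]]:
    """Relevance ranking of significant pathways and their member genes.

    Pathways are ordered by (relevance ratio desc, k desc, term_id asc); genes
    within the union of significant pathways by (publication count desc,
    symbol asc). Also reports how many of the supplied literature candidate
    genes are covered by the significant pathways' query overlaps.

    Returns (pathway table, gene table, (n_covered, n_candidates)).
    """
    sig = [r for r in results if r.significant]
    path_rows = []
    covered_genes: set[str] = set()
    for r in sig:
        score = pathway_relevance_ratio(r.overlap_genes, index) if r.overlap_genes else None
        covered_genes |= r.overlap_genes
        path_rows.append(
            {
                "term_id": r.term_id,
                "name": r.name,
                "ratio": score.pathway_ratio if score else 0.0,
                "n_linked": score.n_linked if score else 0,
                "k": r.k,
                "p_adj": r.p_adj,
                "status": r.status,
            }
        )
    pathway_df = pd.DataFrame(
        path_rows, columns=["term_id", "name", "ratio", "n_linked", "k", "p_adj", "status"]
    )
    if not pathway_df.empty:
        pathway_df = pathway_df.sort_values(
            by=["ratio", "k", "term_id"], ascending=[False, False, True], kind="mergesort"
        ).reset_index(drop=True)

    gene_rows = [
        {
            "symbol": g,
            "pub_count": index.pub_count(g),
            "pmids": ";".join(sorted(index.links.get(g, ()))),
        }
        for g in sorted(covered_genes)
    ]
    gene_df = pd.DataFrame(gene_rows, columns=["symbol", "pub_count", "pmids"])
    if not gene_df.empty:
        gene_df = gene_df.sort_values(
            by=["pub_count", "symbol"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)

    candidates = {c.upper() for c in literature_candidates}
    n_covered = len(candidates & covered_genes)
    if candidates:
        logger.info("%d of %d literature candidates covered by significant pathways",
                    n_covered, len(candidates))
    return pathway_df, gene_df, (n_covered, len(candidates))
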