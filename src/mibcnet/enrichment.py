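"""Pathway over-representation analysis with an exact two-sided hypergeometric test.

Given a query gene set (here: the disease features retained on the induced
subgraph) and a pathway catalogue (GMT gene sets), each term is tested for
over-representation with the exact two-sided hypergeometric test in its
minimum-likelihood form: with X ~ Hypergeometric(N, K, n) the p-value is the
total probability of every achievable overlap count x whose point probability
does not exceed that of the observed count k,

    p = sum_{x : P(X=x) <= P(X=k)} P(X=x).

Family-wise error is controlled by Bonferroni correction over the tested
family. General disease terms (e.g. "pathways in cancer") can be blacklisted
before testing, significant terms are classified as literature-known or novel
against a supplied list of term names, and significant terms are connected
into a pathway-overlap network whose edges carry the genes shared between the
terms' query overlaps.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

#: relative tolerance for the pmf(x) <= pmf(k) tie comparison. Point
#: probabilities are integer multiples of 1/C(N,n); exact ties (symmetric
#: support points) survive float rounding under this tolerance, while a
#: non-tie landing within 1e-9 of the observed pmf has measure zero.
_TIE_RTOL = 1e-9


class EmptyQueryError(ValueError):
    """Raised when the query set has no overlap with the background."""


@dataclass
class PathwayDB:
    """Named gene sets (GMT semantics) with an optional name blacklist."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    blacklist: frozenset[str] = frozenset()

    @property
    def universe(self) -> set[str]:
        """All symbols annotated to at least one term."""
        u: set[str] = set()
        for _, genes in self.terms.values():
            u |= genes
        return u

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]


@dataclass(frozen=True)
class EnrichmentConfig:
    alpha: float = 0.05
    background_mode: str = "pathway_universe"  # or "interactome_restricted", "custom"
    min_overlap: int = 3
    min_term_size: int | None = None
    max_term_size: int | None = None
    two_sided_method: str = "minlike"  # or "doubling"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_overlap < 0:
            raise ValueError("min_overlap must be >= 0")
        if self.two_sided_method not in {"minlike", "doubling"}:
            raise ValueError("two_sided_method must be 'minlike' or 'doubling'")


@dataclass
class EnrichmentResult:
    """Per-term test outcome: overlap k out of term size K, query size n,
    background size N; raw and Bonferroni-adjusted p over m tested terms."""

    term_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    m: int
    direction: str  # enriched | depleted
    significant: bool
    overlap_genes: frozenset[str]
    status: str = "unclassified"  # known | novel | unclassified


# ---------------------------------------------------------------------------
# GMT I/O and term filtering
# ---------------------------------------------------------------------------


def load_gmt(path: str | Path, blacklist: Iterable[str] = ()) -> PathwayDB:
    """Parse a GMT file (term, description, genes...; tab-separated).

    Duplicate genes within a line collapse to set semantics; lines with fewer
    than three fields or no non-empty genes are skipped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                n_rejected += 1
                continue
            term_id, _desc = fields[0], fields[1]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                n_rejected += 1
                continue
            # GMT convention: field 1 is the set name; it serves as both id and name
            terms[term_id] = (term_id, genes)
    if n_rejected:
        logger.info("%s: rejected %d malformed/empty GMT lines", path, n_rejected)
    if not terms:
        logger.warning("%s: empty pathway database", path)
    return PathwayDB(terms=terms, blacklist=frozenset(b.lower() for b in blacklist))


def load_blacklist(path: str | Path) -> frozenset[str]:
    """One case-insensitive substring pattern per line; '#' starts a comment."""
    patterns = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                patterns.add(line.lower())
    return frozenset(patterns)


def filter_terms(db: PathwayDB, config: EnrichmentConfig | None = None) -> PathwayDB:
    """Drop blacklisted terms (case-insensitive substring match on the name)
    and terms outside the configured size bounds."""
    config = config or EnrichmentConfig()
    kept: dict[str, tuple[str, frozenset[str]]] = {}
    for term_id, (name, genes) in db.terms.items():
        low = name.lower()
        hit = next((p for p in db.blacklist if p in low), None)
        if hit is not None:
            logger.info("term %r removed: blacklist pattern %r", name, hit)
            continue
        if config.min_term_size is not None and len(genes) < config.min_term_size:
            continue
        if config.max_term_size is not None and len(genes) > config.max_term_size:
            continue
        kept[term_id] = (name, genes)
    return PathwayDB(terms=kept, blacklist=db.blacklist)


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------


def _check_bounds(k: int, K: int, n: int, N: int) -> None:
    if N <= 0:
        raise ValueError("N must be > 0")
    if not 0 <= K <= N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    lo, hi = max(0, n - (N - K)), min(n, K)
    if not lo <= k <= hi:
        raise ValueError(f"require max(0, n-(N-K)) <= k <= min(n, K): {lo} <= {k} <= {hi} violated")


def hypergeom_two_sided(k: int, K: int, n: int, N: int, method: str = "minlike") -> float:
    """Exact two-sided hypergeometric p-value.

    ``minlike`` (default) sums P(X=x) over every achievable x at most as
    likely as the observed k (the conventional exact two-sided test, as used
    by Fisher's exact test). ``doubling`` returns min(1, 2 * min(lower tail,
    upper tail)) as a sensitivity alternative. Computed in log space with
    log-factorial (gammaln) arithmetic; always in (0, 1].
    """
    _check_bounds(k, K, n, N)
    lo, hi = max(0, n - (N - K)), min(n, K)
    x = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(x, N, K, n)
    obs = logpmf[k - lo]
    if method == "minlike":
        mask = logpmf <= obs + np.log1p(_TIE_RTOL)
        if mask.all():
            return 1.0  # whole support no more likely than k (sums to 1 exactly)
        p = float(np.exp(logsumexp(logpmf[mask])))
    elif method == "doubling":
        lower = float(np.exp(logsumexp(logpmf[x <= k])))
        upper = float(np.exp(logsumexp(logpmf[x >= k])))
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(1.0, p)


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment over a family of ``m`` tests: min(1, m*p)."""
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than number of p-values {len(p_values)}")
    for p in p_values:
        if not 0 < p <= 1:
            raise ValueError(f"p-value {p} outside (0, 1]")
    return [min(1.0, m * p) for p in p_values]


def enrich(
    query: Iterable[str],
    db: PathwayDB,
    config: EnrichmentConfig | None = None,
    background: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Test every pathway for over-representation of the query set.

    The background defaults to the pathway universe; pass ``background`` to
    restrict it (e.g. to interactome nodes). The Bonferroni family size m
    counts every candidate term (post-blacklist, post-size-filter, non-empty
    within the background) — NOT only the terms that reach ``min_overlap``.
    Counting only high-overlap terms would make the family data-dependent
    (terms selected because their overlap is large, then corrected over that
    small family alone) and demonstrably inflates the family-wise error rate;
    ``min_overlap`` therefore governs reporting only. Results are sorted by
    (p_adj, -k, term_id).
    """
    config = config or EnrichmentConfig()
    db = filter_terms(db, config)
    bg = set(background) if background is not None else db.universe
    query = set(query)  # callers/loaders normalize symbol case
    q = query & bg
    if not q:
        raise EmptyQueryError(
            f"query ({len(query)} symbols) has no overlap with the background ({len(bg)} symbols)"
        )
    n, N = len(q), len(bg)

    m = 0  # family size: every candidate term, tested or not
    tested: list[tuple[str, str, int, int, frozenset[str]]] = []
    for term_id in sorted(db.terms):
        name, genes = db.terms[term_id]
        genes_bg = genes & bg
        if not genes_bg:
            continue
        m += 1
        overlap = frozenset(q & genes_bg)
        if len(overlap) < config.min_overlap:
            continue
        tested.append((term_id, name, len(overlap), len(genes_bg), overlap))
    if not tested:
        logger.info(
            "no term reached min_overlap=%d (family size m=%d); empty report",
            config.min_overlap, m,
        )
        return []

    results = []
    raw = [
        hypergeom_two_sided(k, K, n, N, method=config.two_sided_method)
        for (_tid, _name, k, K, _ov) in tested
    ]
    adj = bonferroni(raw, m)
    for (term_id, name, k, K, overlap), p_raw, p_adj in zip(tested, raw, adj):
        enriched = k > n * K / N
        direction = "enriched" if enriched else "depleted"
        results.append(
            EnrichmentResult(
                term_id=term_id,
                name=name,
                k=k,
                K=K,
                n=n,
                N=N,
                p_raw=p_raw,
                p_adj=p_adj,
                m=m,
                direction=direction,
                significant=bool(p_adj <= config.alpha and enriched),
                overlap_genes=overlap,
            )
        )
    results.sort(key=lambda r: (r.p_adj, -r.k, r.term_id))
    return results


# ---------------------------------------------------------------------------
# known/novel classification and the term-overlap network
# ---------------------------------------------------------------------------

_PUNCT_RE = re.compile(r"[^a-z0-9 ]+")


def normalize_term_name(name: str) -> str:
    """Case-, punctuation- and whitespace-insensitive term-name key; also
    harmonizes the British/American 'signalling'/'signaling' spellings, which
    pathway sources mix freely."""
    s = _PUNCT_RE.sub(" ", name.lower())
    s = " ".join(s.split())
    return s.replace("signalling", "signaling")


def classify_known_novel(
    results: Sequence[EnrichmentResult], literature_terms: Iterable[str]
) -> list[EnrichmentResult]:
    """Label each result 'known' if its name appears in the literature term
    list (normalized matching), else 'novel'. Returns new result objects."""
    lit = {normalize_term_name(t) for t in literature_terms}
    out = [
        replace(r, status="known" if normalize_term_name(r.name) in lit else "novel")
        for r in results
    ]
    n_known = sum(r.status == "known" for r in out)
    logger.info("classified %d known / %d novel terms", n_known, len(out) - n_known)
    return out


def term_overlap_network(results: Sequence[EnrichmentResult]) -> nx.Graph:
    """Pathway-overlap network over significant terms.

    Node weight is the query overlap k; an edge joins two terms iff their
    query-overlap gene sets share at least one gene, annotated with the shared
    symbols and their count (the paper-style approximation of cross-pathway
    biological interaction).
    """
    g = nx.Graph()
    sig = [r for r in results if r.significant]
    for r in sig:
        g.add_node(r.term_id, name=r.name, weight=r.k, status=r.status)
    for i, r1 in enumerate(sig):
        for r2 in sig[i + 1:]:
            shared = r1.overlap_genes & r2.overlap_genes
            if shared:
                g.add_edge(r1.term_id, r2.term_id, shared=frozenset(shared), weight=len(shared))
    return g


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term_id,
            "name": r.name,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "m": r.m,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "direction": r.direction,
            "significant": r.significant,
            "status": r.status,
            "overlap_genes": ";".join(sorted(r.overlap_genes)),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "term_id", "name", "k", "K", "n", "N", "m", "p_raw", "p_adj",
            "direction", "significant", "status", "overlap_genes",
        ],
    )
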