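"""Consolidation of multi-study molecular feature lists into a unique gene catalogue.

Disease phenotypes such as muscle-invasive bladder cancer (MIBC) are characterized
by many independent studies — literature reports, mRNA and miRNA transcriptomics,
proteomics, DNA methylation and mutation screens, metabolomics — each yielding a
list of molecular features under its own identifier scheme. This module ingests
per-study feature tables, screens studies by design quality (sample size and
fold-change magnitude), maps raw identifiers to official gene symbols, and merges
everything into a catalogue keyed by unique gene symbol, retaining per-symbol
provenance (which study, which omics layer, and whether the link was direct or
indirect via metabolite→enzyme or miRNA→target mapping).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed enumeration of omics layers / evidence types.
OMICS_TYPES = frozenset(
    {
        "literature",
        "transcriptomics_mrna",
        "transcriptomics_mirna",
        "proteomics",
        "dna_methylation",
        "dna_mutation",
        "metabolomics",
    }
)

#: Layers whose evidence has no fold-change semantics; the >2-fold screening
#: rule applies to profiling experiments only.
FOLD_CHANGE_EXEMPT = frozenset({"literature", "dna_mutation"})

#: Omics layer → identifier mapping route.
_ROUTE_BY_OMICS = {
    "metabolomics": "metabolite_enzyme",
    "transcriptomics_mirna": "mirna_target",
}

MAPPING_ROUTES = frozenset({"direct", "metabolite_enzyme", "mirna_target"})

DIRECTIONS = frozenset({"up", "down", "present", "unknown"})


class SchemaError(ValueError):
    """An input table lacks a required column."""


@dataclass(frozen=True)
class StudyRecord:
    """Metadata of one source study (one publication / screen)."""

    study_id: str
    omics_type: str
    sample_size: int = 0
    max_abs_fold_change: float | None = None
    keywords: frozenset[str] = frozenset()
    stages: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if self.omics_type not in OMICS_TYPES:
            raise ValueError(
                f"unknown omics_type {self.omics_type!r}; expected one of {sorted(OMICS_TYPES)}"
            )
        if self.sample_size < 0:
            raise ValueError("sample_size must be >= 0")
        object.__setattr__(self, "keywords", frozenset(k.lower() for k in self.keywords))
        object.__setattr__(self, "stages", frozenset(self.stages))


@dataclass(frozen=True)
class RawFeature:
    """One identifier row of a study's feature table, before symbol mapping."""

    raw_id: str
    study_id: str
    direction: str = "unknown"
    fold_change: float | None = None

    def __post_init__(self) -> None:
        if not self.raw_id:
            raise ValueError("raw_id must be non-empty")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


#: provenance triple: (study_id, omics_type, mapping_route)
Provenance = tuple[str, str, str]


@dataclass
class MolecularFeature:
    """A gene symbol with the full set of (study, omics layer, route) provenance."""

    symbol: str
    provenance: set[Provenance] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.symbol or self.symbol != self.symbol.upper():
            raise ValueError("symbol must be non-empty and uppercase")

    @property
    def omics_types(self) -> frozenset[str]:
        return frozenset(p[1] for p in self.provenance)

    @property
    def mapping_routes(self) -> frozenset[str]:
        return frozenset(p[2] for p in self.provenance)

    @property
    def study_ids(self) -> frozenset[str]:
        return frozenset(p[0] for p in self.provenance)

    def has_direct_route(self) -> bool:
        return "direct" in self.mapping_routes


@dataclass(frozen=True)
class ScreeningConfig:
    """Study-screening thresholds: sample size is inclusive ("at least 50"),
    fold change is strict (">2-fold")."""

    min_sample_size: int = 50
    min_fold_change: float = 2.0
    required_keywords: frozenset[str] = frozenset({"molecular", "biomarker"})

    def __post_init__(self) -> None:
        if self.min_sample_size < 0 or self.min_fold_change < 0:
            raise ValueError("screening thresholds must be nonnegative")
        object.__setattr__(
            self, "required_keywords", frozenset(k.lower() for k in self.required_keywords)
        )


@dataclass
class FeatureCatalog:
    """Unique-symbol catalogue; uniqueness of keys is the defining property."""

    features: dict[str, MolecularFeature] = field(default_factory=dict)
    screening_config: ScreeningConfig = field(default_factory=ScreeningConfig)
    n_input_features: int = 0

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.features

    def symbols(self) -> set[str]:
        return set(self.features)

    def to_frame(self) -> pd.DataFrame:
        """Catalogue as a tidy table (one row per symbol)."""
        rows = []
        for sym in sorted(self.features):
            f = self.features[sym]
            rows.append(
                {
                    "symbol": sym,
                    "omics_types": ";".join(sorted(f.omics_types)),
                    "studies": ";".join(sorted(f.study_ids)),
                    "mapping_routes": ";".join(sorted(f.mapping_routes)),
                    "n_study_types": len(f.omics_types),
                    "provenance": ";".join(
                        "|".join(p) for p in sorted(f.provenance)
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "symbol", "omics_types", "studies", "mapping_routes",
                "n_study_types", "provenance",
            ],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureCatalog":
        """Reconstruct a catalogue from its tidy-table serialization."""
        features = {}
        for _, row in df.iterrows():
            sym = str(row["symbol"])
            prov = {
                tuple(t.split("|"))
                for t in str(row.get("provenance", "")).split(";")
                if t and t != "nan"
            }
            features[sym] = MolecularFeature(sym, {p for p in prov if len(p) == 3})
        return cls(features=features)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {"raw_id": "raw_id", "direction": "direction", "fold_change": "fold_change"}


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".xls", ".xlsx"}:
        return pd.read_excel(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def load_feature_table(
    path: str | Path,
    study_meta: StudyRecord,
    columns: Mapping[str, str] | None = None,
) -> list[RawFeature]:
    """Read one study's feature table into :class:`RawFeature` rows.

    ``columns`` maps the logical names {raw_id, direction, fold_change} to the
    file's column headers; only ``raw_id`` is mandatory. Rows with a blank
    identifier are skipped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = _read_table(path)
    id_col = colmap["raw_id"]
    if id_col not in df.columns:
        raise SchemaError(
            f"{path}: missing identifier column {id_col!r}; found {list(df.columns)}"
        )
    dir_col = colmap.get("direction")
    fc_col = colmap.get("fold_change")

    out: list[RawFeature] = []
    n_skipped = 0
    for _, row in df.iterrows():
        raw_id = row[id_col]
        if pd.isna(raw_id) or not str(raw_id).strip():
            n_skipped += 1
            continue
        direction = "unknown"
        if dir_col and dir_col in df.columns and pd.notna(row[dir_col]):
            d = str(row[dir_col]).strip().lower()
            direction = d if d in DIRECTIONS else "unknown"
        fold: float | None = None
        if fc_col and fc_col in df.columns and pd.notna(row[fc_col]) and str(row[fc_col]).strip():
            try:
                fold = float(row[fc_col])
            except ValueError:
                n_skipped += 1
                continue
        out.append(
            RawFeature(
                raw_id=str(raw_id).strip(),
                study_id=study_meta.study_id,
                direction=direction,
                fold_change=fold,
            )
        )
    if n_skipped:
        logger.info("%s: skipped %d malformed/blank rows", path, n_skipped)
    return out


def load_studies_table(path: str | Path) -> list[StudyRecord]:
    """Read a study-metadata table (study_id, omics_type, sample_size,
    max_abs_fold_change, keywords, stages; the last three optional)."""
    df = _read_table(Path(path))
    required = {"study_id", "omics_type"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing study columns {sorted(missing)}")
    studies = []
    for _, row in df.iterrows():
        fc = row.get("max_abs_fold_change")
        fold = None if (fc is None or pd.isna(fc) or str(fc).strip() == "") else float(fc)
        kw = row.get("keywords")
        keywords = frozenset(
            t.strip().lower() for t in str(kw).split(";") if t.strip()
        ) if (kw is not None and pd.notna(kw)) else frozenset()
        st = row.get("stages")
        stages = frozenset(
            t.strip() for t in str(st).split(";") if t.strip()
        ) if (st is not None and pd.notna(st)) else frozenset()
        studies.append(
            StudyRecord(
                study_id=str(row["study_id"]).strip(),
                omics_type=str(row["omics_type"]).strip(),
                sample_size=int(float(row.get("sample_size", 0) or 0)),
                max_abs_fold_change=fold,
                keywords=keywords,
                stages=stages,
            )
        )
    return studies


def load_mapping_table(path: str | Path) -> dict[str, str]:
    """Read a raw_id → official symbol mapping (two-column TSV)."""
    df = _read_table(Path(path))
    if {"raw_id", "symbol"} <= set(df.columns):
        a, b = "raw_id", "symbol"
    elif len(df.columns) >= 2:
        a, b = df.columns[:2]
    else:
        raise SchemaError(f"{path}: mapping table needs two columns (raw_id, symbol)")
    return {
        str(r[a]).strip(): str(r[b]).strip().upper()
        for _, r in df.iterrows()
        if pd.notna(r[a]) and pd.notna(r[b])
    }


# ---------------------------------------------------------------------------
# screening and normalization
# ---------------------------------------------------------------------------


def screen_studies(
    studies: Sequence[StudyRecord], config: ScreeningConfig | None = None
) -> list[StudyRecord]:
    """Retain studies meeting the design-quality thresholds.

    A study passes iff ``sample_size >= min_sample_size`` and, for profiling
    layers, ``max_abs_fold_change > min_fold_change`` (strict). Layers without
    fold-change semantics (literature, DNA mutation) are exempt from the fold
    rule. Order is preserved; rejections are logged with the violated rule.
    """
    config = config or ScreeningConfig()
    retained = []
    for s in studies:
        if s.sample_size < config.min_sample_size:
            logger.info("study %s rejected: sample_size %d < %d", s.study_id, s.sample_size, config.min_sample_size)
            continue
        if s.omics_type not in FOLD_CHANGE_EXEMPT:
            if s.max_abs_fold_change is None or s.max_abs_fold_change <= config.min_fold_change:
                logger.info(
                    "study %s rejected: fold change %s not > %g",
                    s.study_id, s.max_abs_fold_change, config.min_fold_change,
                )
                continue
        retained.append(s)
    return retained


def normalize_symbols(
    raw: Sequence[RawFeature],
    mapping: Mapping[str, str],
    studies: Mapping[str, StudyRecord],
) -> tuple[list[MolecularFeature], list[str]]:
    """Map raw identifiers to official (uppercase) gene symbols.

    The mapping route is dictated by the study's omics layer: metabolomics
    features arrive as enzyme symbols (metabolite_enzyme route), miRNA
    transcriptomics as target symbols (mirna_target), everything else direct.
    Unmappable identifiers are returned in a report, never silently dropped.
    """
    if raw and not mapping:
        logger.warning("mapping table empty: all %d raw features unmapped", len(raw))
    features: list[MolecularFeature] = []
    unmapped: list[str] = []
    for r in raw:
        sym = mapping.get(r.raw_id)
        if sym is None:
            unmapped.append(r.raw_id)
            continue
        sym = sym.strip().upper()
        study = studies[r.study_id]
        route = _ROUTE_BY_OMICS.get(study.omics_type, "direct")
        features.append(
            MolecularFeature(symbol=sym, provenance={(r.study_id, study.omics_type, route)})
        )
    if unmapped:
        logger.info("%d raw identifiers could not be mapped to symbols", len(unmapped))
    return features, unmapped


# ---------------------------------------------------------------------------
# consolidation and filters
# ---------------------------------------------------------------------------


def consolidate(
    feature_lists: Iterable[Sequence[MolecularFeature]],
    screening_config: ScreeningConfig | None = None,
) -> FeatureCatalog:
    """Merge normalized feature lists into a unique-symbol catalogue.

    Provenance triples are unioned per symbol. Both the total input count and
    the unique count are recorded (the redundancy funnel).
    """
    catalog = FeatureCatalog(screening_config=screening_config or ScreeningConfig())
    n_inputs = 0
    for flist in feature_lists:
        for f in flist:
            n_inputs += 1
            entry = catalog.features.get(f.symbol)
            if entry is None:
                catalog.features[f.symbol] = MolecularFeature(f.symbol, set(f.provenance))
            else:
                entry.provenance |= f.provenance
    catalog.n_input_features = n_inputs
    logger.info("consolidated %d input features into %d unique symbols", n_inputs, len(catalog))
    return catalog


def overlap_matrix(catalog: FeatureCatalog, grouping: str = "omics_type") -> pd.DataFrame:
    """Symmetric symbol-overlap count table between provenance groups.

    ``grouping='omics_type'`` crosses every omics layer; ``'literature_vs_omics'``
    crosses the literature layer against the union of all omics layers.
    Cell (g1, g2) counts symbols with provenance in both groups; the diagonal
    is the group cardinality.
    """
    if grouping == "omics_type":
        group_of: dict[str, set[str]] = {}
        for sym, f in catalog.features.items():
            for t in f.omics_types:
                group_of.setdefault(t, set()).add(sym)
        groups = {g: group_of[g] for g in sorted(group_of)}
    elif grouping == "literature_vs_omics":
        lit, omics = set(), set()
        for sym, f in catalog.features.items():
            types = f.omics_types
            if "literature" in types:
                lit.add(sym)
            if types - {"literature"}:
                omics.add(sym)
        groups = {"literature": lit, "omics": omics}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    names = list(groups)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for g1 in names:
        for g2 in names:
            mat.loc[g1, g2] = len(groups[g1] & groups[g2])
    return mat


def exclude_indirect(catalog: FeatureCatalog) -> FeatureCatalog:
    """Drop symbols supported ONLY by indirect mapping routes.

    Genes reached solely via metabolite→enzyme or miRNA→target mapping carry
    weak evidence of involvement and are excluded from network analysis; any
    symbol with at least one direct route is retained.
    """
    kept = {
        sym: MolecularFeature(sym, set(f.provenance))
        for sym, f in catalog.features.items()
        if f.has_direct_route()
    }
    n_removed = len(catalog.features) - len(kept)
    if n_removed:
        logger.info("exclude_indirect removed %d indirect-only symbols", n_removed)
    return FeatureCatalog(
        features=kept,
        screening_config=catalog.screening_config,
        n_input_features=catalog.n_input_features,
    )


def multi_study_filter(catalog: FeatureCatalog, min_types: int = 2) -> set[str]:
    """Symbols whose provenance spans at least ``min_types`` distinct study
    types (omics layers; literature counts as a type)."""
    if min_types < 1:
        raise ValueError("min_types must be >= 1")
    return {sym for sym, f in catalog.features.items() if len(f.omics_types) >= min_types}


def biomarker_filter(
    catalog: FeatureCatalog,
    studies: Mapping[str, StudyRecord],
    required_keywords: Iterable[str] | None = None,
) -> set[str]:
    """Literature-derived symbols whose supporting article carries all of the
    required keywords (default: {"molecular", "biomarker"})."""
    req = frozenset(
        k.lower() for k in (required_keywords or catalog.screening_config.required_keywords)
    )
    out = set()
    for sym, f in catalog.features.items():
        for study_id, omics, _route in f.provenance:
            if omics != "literature":
                continue
            study = studies.get(study_id)
            if study is not None and req <= study.keywords:
                out.add(sym)
                break
    return out
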