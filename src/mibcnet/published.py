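"""Reported KEGG pathway memberships for muscle-invasive bladder cancer.

A compact real-data example bundled with the package: the KEGG pathway terms
reported in the MIBC interactome literature as significantly enriched, with
their printed member-gene lists. Two analyses are covered — the enrichment of
the 286-gene induced-subgraph feature set (four pathways printed with full
membership) and the enrichment of the 72 genes recurring in more than one
study type (seven pathways).

Note on data quality: the printed per-pathway feature COUNTS disagree with
the printed member lists for several rows (e.g. Endocytosis counted as 16 but
listing 13 symbols). Both are kept verbatim; all derived quantities in this
package are computed from the member lists.
"""

from __future__ import annotations

#: Induced-subgraph analysis (286-gene feature set): pathway → printed member list.
SUBGRAPH_PATHWAYS: dict[str, frozenset[str]] = {
    "Regulation of actin cytoskeleton": frozenset(
        "PDGFA FGF1 RAF1 EGFR ACTN4 FGFR1 ITGB4 FGFR3 MYLK HRAS ACTN1 FGF2 "
        "ITGA5 ARAF FN1 MAPK1 ACTB ITGA6".split()
    ),
    "Endocytosis": frozenset(
        "EGFR MDM2 TGFBR2 FGFR3 HRAS ERBB3 TGFB3 TGFBR1 ERBB4 CAV1 MET PRKCZ KDR".split()
    ),
    "Neurotrophin signalling pathway": frozenset(
        "BDNF RAF1 BAD HRAS ABL1 GAB1 BCL2 TP53 BAX YWHAZ JUN MAPK1".split()
    ),
    "Serotonergic synapse": frozenset(
        "RAF1 GNAI3 PRKCG ITPR3 HRAS CASP3 PTGS2 DUSP1 ARAF MAPK1 PRKCA".split()
    ),
}

#: Printed per-pathway feature counts for the same rows (kept verbatim; they
#: disagree with the list lengths for three of the four rows).
SUBGRAPH_PRINTED_COUNTS: dict[str, int] = {
    "Regulation of actin cytoskeleton": 18,
    "Endocytosis": 16,
    "Neurotrophin signalling pathway": 13,
    "Serotonergic synapse": 12,
}

#: Multi-study analysis (72-gene set): pathway → printed member list.
MULTISTUDY_PATHWAYS: dict[str, frozenset[str]] = {
    "Focal adhesion": frozenset(
        "COL3A1 HRAS CCND1 COL11A1 FN1 THBS1 JUN COL5A1 RAF1 EGFR COL1A2".split()
    ),
    "Cell cycle": frozenset("CCND1 TP53 CDK4 CDKN2A CDKN1A".split()),
    "p53 signaling pathway": frozenset("CCND1 THBS1 TP53 CDK4 CDKN2A CDKN1A".split()),
    "ErbB signalling pathway": frozenset("HRAS JUN RAF1 CDKN1A EGFR".split()),
    "ECM-receptor interaction": frozenset("COL3A1 COL11A1 FN1 THBS1 COL5A1 COL1A2".split()),
    "GnRH signalling pathway": frozenset("HRAS JUN RAF1 EGFR".split()),
    "T cell receptor signalling pathway": frozenset("HRAS JUN CDK4 RAF1".split()),
}

MULTISTUDY_PRINTED_COUNTS: dict[str, int] = {
    "Focal adhesion": 16,
    "Cell cycle": 7,
    "p53 signaling pathway": 6,
    "ErbB signalling pathway": 6,
    "ECM-receptor interaction": 6,
    "GnRH signalling pathway": 5,
    "T cell receptor signalling pathway": 5,
}

#: The 15 pathway terms reported significant for the induced-subgraph feature
#: set, and the 11 of them described as previously known from the bladder
#: cancer literature (the remaining 4 were reported as novel).
LITERATURE_KNOWN_PATHWAYS: tuple[str, ...] = (
    "Focal adhesion",
    "MAPK signalling pathway",
    "ECM-receptor interaction",
    "Cell cycle",
    "p53 signalling pathway",
    "Tight junction",
    "Adherens junction",
    "Leukocyte transendothelial migration",
    "VEGF signalling pathway",
    "Gap junction",
    "ErbB signalling pathway",
)

NOVEL_PATHWAYS: tuple[str, ...] = (
    "Regulation of actin cytoskeleton",
    "Endocytosis",
    "Neurotrophin signalling pathway",
    "Serotonergic synapse",
)

ENRICHED_PATHWAYS_SUBGRAPH: tuple[str, ...] = LITERATURE_KNOWN_PATHWAYS + NOVEL_PATHWAYS
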