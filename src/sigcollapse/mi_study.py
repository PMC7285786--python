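"""Curated reference data from the myocardial-infarction PBMC study.

These are the printed inputs of the MI case/control transcriptome study the
pipeline re-implements (discovery cohort GSE141512; validation cohorts
GSE59867 and GSE62646): the Reactome enrichment rows, the MirTarBase-derived
miRNA target lists, STRING-style interaction edges among the enriched DEGs,
the five published signatures, and the cross-cohort replication table
(shipped verbatim as ``data/table3.tsv``).  They serve as worked-example
fixtures; gene-set member lists outside the DEG overlap are padded with
clearly synthetic filler symbols up to the published set sizes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import (GeneSet, GeneSetCollection, InteractionNetwork, TargetMap)
from .signatures import Signature, SignatureSet

# (direction, set name, published set size, DEG members, published FDR)
TABLE2_ROWS: tuple[tuple[str, str, int, tuple[str, ...], float], ...] = (
    ("up", "Immune system", 2663,
     ("BCL6", "BST1", "C3AR1", "CCR1", "CD14", "CLEC4D", "CLEC6A", "CR1",
      "FCGR1A", "FCGR1B", "FLT3", "FPR1", "FPR2", "GRN", "HLA-DQB1", "PADI2",
      "PYGL", "S100A12", "SLC11A1", "SOCS3", "TLR2", "TLR8"), 0.023),
    ("up", "Neutrophil degranulation", 480,
     ("BST1", "C3AR1", "CD14", "CLEC4D", "CR1", "FPR1", "FPR2", "GRN",
      "PADI2", "PYGL", "S100A12", "SLC11A1", "TLR2"), 0.0035),
    ("up", "Cytokine Signaling in immune system", 1055,
     ("BCL6", "CCR1", "FCGR1A", "FCGR1B", "FLT3", "FPR1", "HLA-DQB1",
      "S100A12", "SOCS3"), 0.015),
    ("up", "Interferon gamma signaling", 250,
     ("FCGR1A", "FCGR1B", "HLA-DQB1", "SOCS3"), 0.015),
    ("up", "Signaling by non-receptor tyrosine kinases", 70, ("NRG1", "SOCS3"), 0.033),
    ("up", "Signaling by PTK6", 70, ("NRG1", "SOCS3"), 0.033),
    ("up", "PTK6 Activates STAT3", 7, ("SOCS3",), 0.033),
    ("up", "GRB7 events in ERBB2 signaling", 6, ("NRG1",), 0.031),
    ("up", "Transport of glycerol from adipocytes to the liver by Aquaporins", 3,
     ("AQP9",), 0.015),
    ("down", "Immunoregulatory interactions between a Lymphoid and a non-Lymphoid cell",
     297, ("KLRB1", "KLRC1", "KLRD1", "KLRF1", "KIR2DL1", "KIR2DL3"), 0.021),
    ("down", "DAP12 signaling", 29, ("KLRC1", "KLRC2", "KLRC3", "KLRD1"), 0.021),
)

N_UP_DEGS = 48   # upregulated protein-coding DEGs (plus MIR21, MIR223)
N_DOWN_DEGS = 34

PARENT_MAP = {
    "Neutrophil degranulation": "Immune system",
    "Cytokine Signaling in immune system": "Immune system",
}

FDR_PASSING_GENES = ("ADAP2", "KLRB1")  # survived BH correction in discovery

TARGET_MAP = TargetMap({
    "MIR21": frozenset({"BCL6", "CCR1", "PDGFD", "SGK1", "TGFBR3"}),
    "MIR223": frozenset({"MAFB"}),
})

NEUTROPHIL_DEGS = ("BST1", "C3AR1", "CD14", "CLEC4D", "CR1", "FPR1", "FPR2",
                   "GRN", "PADI2", "PYGL", "S100A12", "SLC11A1", "TLR2")
NEUTROPHIL_ISOLATED = ("GRN", "PADI2", "PYGL")

# STRING-style edges among the interacting neutrophil-degranulation DEGs;
# GRN, PADI2, PYGL have no edges to the rest.
NEUTROPHIL_EDGES: tuple[tuple[str, str], ...] = (
    ("C3AR1", "FPR1"), ("C3AR1", "FPR2"), ("FPR1", "FPR2"),
    ("FPR1", "S100A12"), ("FPR2", "S100A12"), ("CD14", "TLR2"),
    ("CD14", "S100A12"), ("CD14", "CR1"), ("TLR2", "S100A12"),
    ("BST1", "CD14"), ("SLC11A1", "CD14"), ("SLC11A1", "S100A12"),
    ("CLEC4D", "CD14"), ("CR1", "C3AR1"), ("TLR2", "FPR2"),
)

IMMUNOREGULATORY_EDGES: tuple[tuple[str, str], ...] = (
    ("KLRB1", "KLRD1"), ("KLRB1", "KLRF1"), ("KLRC1", "KLRD1"),
    ("KLRD1", "KLRF1"), ("KIR2DL1", "KLRD1"), ("KIR2DL3", "KLRD1"),
    ("KIR2DL1", "KIR2DL3"),
)

CYTOKINE_EDGES: tuple[tuple[str, str], ...] = (
    ("CCR1", "FPR1"), ("CCR1", "S100A12"), ("FCGR1A", "FCGR1B"),
    ("FCGR1A", "S100A12"), ("FPR1", "S100A12"), ("FCGR1B", "HLA-DQB1"),
)


def interaction_network() -> InteractionNetwork:
    """All curated interaction edges in one network."""
    return InteractionNetwork.from_pairs(
        NEUTROPHIL_EDGES + IMMUNOREGULATORY_EDGES + CYTOKINE_EDGES)


def table2_collection(pad_to_published_size: bool = True) -> GeneSetCollection:
    """The eleven enriched gene sets as a :class:`GeneSetCollection`.

    Only the DEG members are known by name; with ``pad_to_published_size``
    each set is padded with synthetic ``<SET>_FILLERnnn`` symbols up to its
    published total size, so set sizes match the printed table.
    """
    sets = {}
    for i, (_, name, size, members, _) in enumerate(TABLE2_ROWS):
        padded = list(members)
        if pad_to_published_size:
            stem = f"SET{i:02d}_FILLER"
            padded += [f"{stem}{j:04d}" for j in range(size - len(members))]
        sets[name] = GeneSet(f"reference set ({size} genes)", tuple(padded))
    return GeneSetCollection(sets, dict(PARENT_MAP))


def enrichment_table() -> pd.DataFrame:
    """The published enrichment rows as an enrichment table (published FDR,
    published coverage denominators 48 up / 34 down)."""
    rows = []
    for direction, name, size, members, fdr in TABLE2_ROWS:
        n = N_UP_DEGS if direction == "up" else N_DOWN_DEGS
        rows.append({"direction": direction, "set_name": name, "K": size,
                     "k": len(members), "genes": tuple(sorted(members)),
                     "p_hyper": float("nan"), "fdr": fdr,
                     "coverage": len(members) / n})
    return pd.DataFrame(rows)


# The five published signatures (29 member slots before validation).
def initial_signatures() -> SignatureSet:
    return SignatureSet((
        Signature("ADAP2", "individual", ("ADAP2",), anchor="ADAP2"),
        Signature("KLRB1", "pathway_network",
                  ("KLRB1", "KLRC1", "KLRD1", "KLRF1", "KIR2DL1", "KIR2DL3"),
                  anchor="KLRB1"),
        Signature("MIR21", "mirna",
                  ("MIR21", "BCL6", "CCR1", "PDGFD", "SGK1", "TGFBR3",
                   "FCGR1A", "FCGR1B", "FPR1", "S100A12"), anchor="MIR21"),
        Signature("MIR223", "mirna", ("MIR223", "MAFB"), anchor="MIR223"),
        Signature("NeutrophilDegranulation", "pathway_network",
                  ("BST1", "C3AR1", "CD14", "CLEC4D", "CR1", "FPR1", "FPR2",
                   "S100A12", "SLC11A1", "TLR2")),
    ))


# The signatures after platform filtering + replication pruning (18 slots).
def validated_signatures() -> SignatureSet:
    return SignatureSet((
        Signature("ADAP2", "individual", ("ADAP2",), anchor="ADAP2"),
        Signature("KLRB1", "pathway_network",
                  ("KLRB1", "KLRC1", "KLRD1", "KLRF1"), anchor="KLRB1"),
        Signature("MIR21", "mirna",
                  ("MIR21", "BCL6", "CCR1", "PDGFD", "TGFBR3", "S100A12"),
                  anchor="MIR21"),
        Signature("MIR223", "mirna", ("MIR223", "MAFB"), anchor="MIR223"),
        Signature("NeutrophilDegranulation", "pathway_network",
                  ("C3AR1", "CD14", "CR1", "S100A12", "SLC11A1")),
    ))


# Genes absent from the validation platform (GeneChip Human Gene 1.0 ST).
PLATFORM_MISSING = ("KIR2DL1", "KIR2DL3", "FCGR1A", "FCGR1B")

L1_SELECTED_GENES = ("ADAP2", "KLRC1", "MIR21", "PDGFD", "CD14")


def load_table3() -> tuple[pd.DataFrame, list[pd.DataFrame], list[str]]:
    """The cross-cohort replication table.

    Returns ``(discovery, [gse62646, gse59867], cohort_names)``; each frame
    is gene-indexed with ``log2FC`` and ``p`` columns.  Genes listed under
    two signatures (FPR1, S100A12) appear once.
    """
    with resources.files("sigcollapse.data").joinpath("table3.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t")
    raw = raw.drop_duplicates(subset="gene").set_index("gene")
    discovery = raw[["log2FC_discovery", "p_discovery"]].rename(
        columns={"log2FC_discovery": "log2FC", "p_discovery": "p"})
    gse62646 = raw[["log2FC_GSE62646", "p_GSE62646"]].rename(
        columns={"log2FC_GSE62646": "log2FC", "p_GSE62646": "p"})
    gse59867 = raw[["log2FC_GSE59867", "p_GSE59867"]].rename(
        columns={"log2FC_GSE59867": "log2FC", "p_GSE59867": "p"})
    return discovery, [gse62646, gse59867], ["GSE62646", "GSE59867"]


def platform_genes() -> list[str]:
    """Genes measurable on the validation platform: the replication-table
    genes (the published signature genes minus :data:`PLATFORM_MISSING`)."""
    discovery, _, _ = load_table3()
    return sorted(discovery.index)
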