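"""Collapse DEGs into transcriptional signatures.

Three kinds of signature are built from a DEG list:

* ``individual`` — a single gene whose differential expression survives the
  multiple-comparisons correction;
* ``mirna`` — a differentially expressed miRNA gene together with the DEG
  targets whose expression is co-expressed with it (Spearman rank
  correlation, either sign), optionally extended with correlated genes from
  informative pathway sets;
* ``pathway_network`` — the largest interaction-connected component of a
  pathway's DEGs, restricted to genes with at least one significant
  within-component co-expression.

Signatures are serialized as GMT lines (anchor gene first) plus a JSON
provenance sidecar recording the correlations that admitted each member.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, FormatError, InteractionNetwork

logger = logging.getLogger(__name__)

SIGNATURE_KINDS = ("individual", "mirna", "pathway_network")


@dataclass(frozen=True)
class CorrelationRecord:
    """One Spearman rank correlation between two expression vectors."""

    gene_a: str | None
    gene_b: str | None
    rho: float
    p: float


@dataclass
class Signature:
    """A named group of co-dysregulated genes treated as one diagnostic unit."""

    name: str
    kind: str
    members: tuple[str, ...]
    anchor: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SIGNATURE_KINDS:
            raise ValueError(f"unknown signature kind {self.kind!r}")
        self.members = tuple(self.members)
        if not self.members:
            raise ValueError(f"signature {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"signature {self.name!r} has duplicate members")
        if self.anchor is not None and self.anchor not in self.members:
            raise ValueError(f"anchor {self.anchor!r} not a member of {self.name!r}")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SignatureSet:
    """Ordered collection of signatures; genes may repeat across signatures
    but never within one."""

    signatures: tuple[Signature, ...]

    def __post_init__(self) -> None:
        self.signatures = tuple(self.signatures)
        names = [s.name for s in self.signatures]
        if len(set(names)) != len(names):
            raise ValueError("duplicate signature names")

    def __iter__(self):
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    @property
    def n_slots(self) -> int:
        """Total member-slot count (a gene in two signatures counts twice)."""
        return sum(len(s) for s in self.signatures)

    @property
    def unique_genes(self) -> list[str]:
        return sorted({g for s in self.signatures for g in s.members})

    def get(self, name: str) -> Signature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(name)

    def slot_counts(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.signatures)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float],
             gene_a: str | None = None, gene_b: str | None = None) -> CorrelationRecord:
    """Spearman rank correlation with the two-sided t-approximation p-value.

    Ranks are average ranks; ``|rho| = 1`` yields ``p = 0``.  Constant
    vectors have undefined ranks and raise an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    if abs(rho) >= 1.0 - 1e-15:
        rho = float(np.sign(rho))
        p = 0.0
    return CorrelationRecord(gene_a=gene_a, gene_b=gene_b, rho=float(rho), p=float(p))


# ---------------------------------------------------------------------------
# miRNA signatures
# ---------------------------------------------------------------------------


def mirna_signatures(degs: pd.DataFrame, targets, m: ExpressionMatrix,
                     alpha_coexpr: float = 0.05) -> list[Signature]:
    """Build one signature per differentially expressed miRNA gene.

    For each miRNA in the DEG table that has mapped targets, candidate
    members are the DEGs among its targets; a target joins the signature iff
    its Spearman correlation with the miRNA across all samples has
    ``p < alpha_coexpr`` (either sign).  A miRNA with no passing target
    yields no signature; a miRNA absent from the expression matrix is
    skipped with a warning.
    """
    sigs: list[Signature] = []
    deg_genes = set(degs.index)
    for mirna in sorted(set(targets.pairs) & deg_genes):
        if mirna not in m.values.index:
            logger.warning("miRNA %s not in expression matrix; skipped", mirna)
            continue
        candidates = sorted((set(targets.targets(mirna)) & deg_genes) - {mirna})
        anchor_expr = m.expression(mirna)
        passing: list[CorrelationRecord] = []
        for gene in candidates:
            if gene not in m.values.index:
                logger.warning("target %s of %s not in expression matrix; skipped", gene, mirna)
                continue
            rec = spearman(anchor_expr, m.expression(gene), gene_a=mirna, gene_b=gene)
            if rec.p < alpha_coexpr:
                passing.append(rec)
        if not passing:
            continue
        sigs.append(Signature(
            name=mirna, kind="mirna",
            members=(mirna, *[r.gene_b for r in passing]), anchor=mirna,
            provenance={"correlations": {r.gene_b: {"rho": r.rho, "p": r.p} for r in passing}},
        ))
    return sigs


def extend_mirna_signature(sig: Signature, candidate_genes: Iterable[str],
                           m: ExpressionMatrix, alpha_coexpr: float = 0.05) -> Signature:
    """Append candidate genes co-expressed with the signature's anchor miRNA.

    Candidates already in the signature are ignored (idempotent); the rest
    join iff their Spearman correlation with the anchor has
    ``p < alpha_coexpr``.
    """
    if sig.kind != "mirna":
        raise ValueError("can only extend a mirna signature")
    anchor_expr = m.expression(sig.anchor)
    added: dict[str, dict] = {}
    for gene in sorted(set(candidate_genes) - set(sig.members)):
        if gene not in m.values.index:
            logger.warning("extension candidate %s not in expression matrix; skipped", gene)
            continue
        rec = spearman(anchor_expr, m.expression(gene), gene_a=sig.anchor, gene_b=gene)
        if rec.p < alpha_coexpr:
            added[gene] = {"rho": rec.rho, "p": rec.p}
    if not added:
        return sig
    provenance = dict(sig.provenance)
    provenance["extended"] = {**provenance.get("extended", {}), **added}
    return Signature(name=sig.name, kind=sig.kind,
                     members=sig.members + tuple(added), anchor=sig.anchor,
                     provenance=provenance)


# ---------------------------------------------------------------------------
# Pathway-network signatures
# ---------------------------------------------------------------------------


def network_correlated_component(set_degs: Sequence[str], net: InteractionNetwork,
                                 m: ExpressionMatrix, alpha_coexpr: float = 0.05,
                                 name: str = "pathway") -> Signature | None:
    """Largest interaction-connected, co-expressed subset of a pathway's DEGs.

    The network is restricted to ``set_degs``; isolated genes are dropped;
    of the remaining connected components the largest is kept (ties broken
    by lexicographically smallest member), and within it only genes with at
    least one significant Spearman correlation (``p < alpha_coexpr``) to
    another component gene remain.  Returns ``None`` when nothing survives.
    """
    missing = sorted(set(set_degs) - set(m.values.index))
    if missing:
        raise FormatError(f"genes absent from expression matrix: {missing}")
    sub = net.subnetwork(set_degs).to_networkx()
    components = [sorted(c) for c in nx.connected_components(sub)]
    if not components:
        return None
    components.sort(key=lambda c: (-len(c), c[0]))
    component = components[0]
    isolated = sorted(set(set_degs) - set(sub.nodes))

    expr = {g: m.expression(g) for g in component}
    members: list[str] = []
    correlations: dict[str, dict] = {}
    for g in component:
        partners = {}
        for h in component:
            if h == g:
                continue
            rec = spearman(expr[g], expr[h], gene_a=g, gene_b=h)
            if rec.p < alpha_coexpr:
                partners[h] = {"rho": rec.rho, "p": rec.p}
        if partners:
            members.append(g)
            correlations[g] = partners
    if not members:
        return None
    return Signature(
        name=name, kind="pathway_network", members=tuple(sorted(members)),
        provenance={"component": component, "isolated": isolated,
                    "correlations": correlations},
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_signatures(individual: Iterable[str],
                        mirna_sigs: Sequence[Signature],
                        pathway_sigs: Sequence[Signature],
                        merge_rule: str = "absorb",
                        deg_universe: Iterable[str] | None = None) -> SignatureSet:
    """Assemble the final signature set.

    Each FDR-passing gene either anchors the first pathway signature that
    contains it, or stands alone as an individual signature.  With
    ``merge_rule="absorb"`` a pathway signature whose members are all
    contained in one (extended) miRNA signature is dropped as redundant.
    Output order: individual, FDR-anchored pathway, miRNA, remaining pathway
    signatures.  Duplicate genes across signatures are allowed (the
    classifier's feature builder de-duplicates); ``deg_universe``, when
    given, asserts every member is a known DEG or extension gene.
    """
    if merge_rule not in ("absorb", "none"):
        raise ValueError(f"unknown merge_rule {merge_rule!r}")
    pathway = list(pathway_sigs)
    if merge_rule == "absorb":
        absorbed = [p for p in pathway
                    if any(set(p.members) <= set(ms.members) for ms in mirna_sigs)]
        for p in absorbed:
            logger.info("pathway signature %s absorbed into a miRNA signature", p.name)
        pathway = [p for p in pathway if p not in absorbed]

    individuals: list[Signature] = []
    anchored: list[Signature] = []
    remaining = list(pathway)
    mirna_anchors = {s.anchor for s in mirna_sigs}
    for gene in sorted(set(individual)):
        if gene in mirna_anchors:
            continue  # already heads its own miRNA signature
        host = next((p for p in remaining if gene in p.members), None)
        if host is not None:
            remaining.remove(host)
            members = (gene, *[g for g in host.members if g != gene])
            anchored.append(Signature(name=host.name, kind=host.kind, members=members,
                                      anchor=gene, provenance=host.provenance))
        else:
            individuals.append(Signature(name=gene, kind="individual",
                                         members=(gene,), anchor=gene))

    ordered = (*individuals, *anchored, *mirna_sigs, *remaining)
    if deg_universe is not None:
        allowed = set(deg_universe)
        stray = sorted({g for s in ordered for g in s.members} - allowed)
        if stray:
            raise ValueError(f"signature members outside the DEG/extension universe: {stray}")
    return SignatureSet(ordered)


# ---------------------------------------------------------------------------
# Serialization: GMT + JSON provenance sidecar
# ---------------------------------------------------------------------------


def write_signature_set(sigs: SignatureSet, gmt_path: str | Path,
                        provenance_path: str | Path | None = None) -> None:
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for s in sigs:
            desc = f"kind={s.kind}" + (f";anchor={s.anchor}" if s.anchor else "")
            fh.write("\t".join([s.name, desc, *s.members]) + "\n")
    if provenance_path is not None:
        payload = {s.name: {"kind": s.kind, "anchor": s.anchor,
                            "members": list(s.members), "provenance": s.provenance}
                   for s in sigs}
        Path(provenance_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_signature_set(gmt_path: str | Path,
                       provenance_path: str | Path | None = None) -> SignatureSet:
    provenance = {}
    if provenance_path is not None and Path(provenance_path).exists():
        provenance = json.loads(Path(provenance_path).read_text())
    sigs = []
    with open(gmt_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            name, desc, *members = line.split("\t")
            attrs = dict(item.split("=", 1) for item in desc.split(";") if "=" in item)
            sigs.append(Signature(
                name=name, kind=attrs.get("kind", "pathway_network"),
                members=tuple(members), anchor=attrs.get("anchor"),
                provenance=provenance.get(name, {}).get("provenance", {}),
            ))
    return SignatureSet(tuple(sigs))
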