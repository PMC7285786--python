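"""Validated containers and readers/writers for every file the pipeline touches.

All resources (expression matrices, gene sets, miRNA target maps, interaction
networks) are joined on exact, case-sensitive gene symbols.  TSVs are
tab-separated UTF-8 with ``.`` decimal separator and no quoting, so numeric
round-trips are bit-exact; gene order on read is always lexicographic so that
downstream results do not depend on file row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LABELS = ("case", "control")


class FormatError(ValueError):
    """Raised when an input file or container violates a format invariant."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are unique gene symbols, columns unique sample names, entries
        finite log2 intensities.
    group : pandas.Series
        Per-sample label, ``"case"`` or ``"control"``; both labels must be
        present at least twice.
    timepoint : pandas.Series, optional
        Per-sample ordinal label (e.g. ``"admission"``, ``"day4-6"``).
    """

    values: pd.DataFrame
    group: pd.Series
    timepoint: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        try:
            arr = v.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:  # pragma: no cover - defensive
            raise FormatError(f"non-numeric expression values: {exc}") from exc
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        self.values = v.astype(float).sort_index()

        group = pd.Series(self.group).reindex(v.columns)
        if group.isna().any():
            missing = list(group.index[group.isna()])
            raise FormatError(f"samples missing group label: {missing}")
        bad = sorted(set(group) - set(GROUP_LABELS))
        if bad:
            raise FormatError(f"unknown group labels {bad}; expected {GROUP_LABELS}")
        counts = group.value_counts()
        for label in GROUP_LABELS:
            if counts.get(label, 0) < 2:
                raise FormatError(f"need at least 2 {label!r} samples, got {counts.get(label, 0)}")
        self.group = group
        if self.timepoint is not None:
            self.timepoint = pd.Series(self.timepoint).reindex(v.columns)

    # -- convenience accessors -------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_samples(self) -> list[str]:
        return list(self.group.index[self.group == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.group.index[self.group == "control"])

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = sorted(set(genes) - set(self.values.index))
        if missing:
            raise FormatError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[genes].copy(), self.group.copy(),
                                None if self.timepoint is None else self.timepoint.copy())

    def expression(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across all samples (column order)."""
        return self.values.loc[gene].to_numpy()


def read_expression_matrix(path: str | Path, group_map: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene symbol, header = sample ids)
    together with a sample-metadata TSV (columns ``sample_id``, ``group`` and
    optional ``timepoint``).

    Rows containing any non-numeric value are rejected with a logged warning.
    Duplicate gene ids and samples missing from the group map are hard errors.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"duplicate gene id: {dup!r} in {path}")
    probe = raw.apply(pd.to_numeric, errors="coerce")
    bad = probe.isna().any(axis=1)
    if bad.any():
        logger.warning("rejected %d non-numeric rows from %s: %s",
                       int(bad.sum()), path, list(probe.index[bad])[:10])
    # exact float parsing (pd.to_numeric's fast path is not round-trip safe)
    numeric = raw.loc[~bad].map(float)

    meta = pd.read_csv(group_map, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(meta.columns):
        raise FormatError(f"group map {group_map} must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    missing = sorted(set(numeric.columns) - set(meta.index))
    if missing:
        raise FormatError(f"samples missing from group map: {missing}")
    group = meta["group"].reindex(numeric.columns)
    timepoint = meta["timepoint"].reindex(numeric.columns) if "timepoint" in meta.columns else None
    return ExpressionMatrix(numeric, group, timepoint)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path,
                            group_path: str | Path | None = None) -> None:
    """Write the matrix (and optionally the sample metadata) as TSV.

    Values are serialized with Python float repr, so a read-after-write
    round-trip reproduces them at full double precision.
    """
    m.values.to_csv(path, sep="\t", index_label="gene")
    if group_path is not None:
        meta = pd.DataFrame({"sample_id": m.samples, "group": m.group.to_numpy()})
        if m.timepoint is not None:
            meta["timepoint"] = m.timepoint.to_numpy()
        meta.to_csv(group_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene set collections (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional child -> parent hierarchy map."""

    sets: dict[str, GeneSet]
    parent: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, GeneSet] = {}
        for name, gs in self.sets.items():
            members = tuple(dict.fromkeys(gs.members))
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            cleaned[name] = GeneSet(gs.description, members)
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name].members

    def intersect_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Restrict every set to ``universe``; sets left empty are dropped."""
        uni = set(universe)
        kept = {name: GeneSet(gs.description, tuple(g for g in gs.members if g in uni))
                for name, gs in self.sets.items()}
        kept = {n: gs for n, gs in kept.items() if gs.members}
        parent = {c: p for c, p in self.parent.items() if c in kept and p in kept}
        return GeneSetCollection(kept, parent)


def read_gene_sets(path: str | Path, parent_map: str | Path | None = None) -> GeneSetCollection:
    """Parse a standard GMT file: ``name TAB description TAB member...``.

    Members duplicated within one line are de-duplicated with a logged
    warning; a line with no members is a hard error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: gene set {fields[0]!r} has no members")
            name, description = fields[0], fields[1]
            members = [g for g in fields[2:] if g]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            deduped = tuple(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning("%s:%d: %d duplicate members de-duplicated in set %r",
                               path, lineno, len(members) - len(deduped), name)
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = GeneSet(description, deduped)
    parent: dict[str, str] = {}
    if parent_map is not None:
        parent = read_parent_map(parent_map)
    return GeneSetCollection(sets, parent)


def read_parent_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (child set name, parent set name), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"], dtype=str)
    return dict(zip(df["child"], df["parent"]))


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            gs = collection.sets[name]
            fh.write("\t".join([name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# miRNA target maps and interaction networks
# ---------------------------------------------------------------------------


@dataclass
class TargetMap:
    """miRNA gene symbol -> experimentally validated target gene symbols."""

    pairs: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mirna, targets in self.pairs.items():
            if not targets:
                raise FormatError(f"miRNA {mirna!r} has no targets")
        self.pairs = {m: frozenset(t) for m, t in self.pairs.items()}

    def targets(self, mirna: str) -> frozenset[str]:
        return self.pairs.get(mirna, frozenset())

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.pairs


def read_target_map(path: str | Path) -> TargetMap:
    """Two-column TSV (miRNA symbol, target symbol), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["mirna", "target"], dtype=str)
    pairs: dict[str, set[str]] = {}
    for mirna, target in zip(df["mirna"], df["target"]):
        pairs.setdefault(mirna, set()).add(target)
    return TargetMap({m: frozenset(t) for m, t in pairs.items()})


def write_target_map(tm: TargetMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in sorted(tm.pairs):
            for target in sorted(tm.pairs[mirna]):
                fh.write(f"{mirna}\t{target}\n")


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected gene-gene interaction edges (STRING-style, unweighted).

    Edges are stored as sorted tuples, so (A, B) and (B, A) collapse to one
    edge; self-loops are rejected.
    """

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        edges = set()
        for a, b in pairs:
            if a == b:
                raise FormatError(f"self-loop edge on gene {a!r}")
            edges.add((a, b) if a < b else (b, a))
        return cls(frozenset(edges))

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g

    def subnetwork(self, genes: Iterable[str]) -> "InteractionNetwork":
        keep = set(genes)
        return InteractionNetwork(frozenset(e for e in self.edges
                                            if e[0] in keep and e[1] in keep))


def read_network(path: str | Path) -> InteractionNetwork:
    """Two-column TSV (geneA, geneB), no header; duplicate edges collapse."""
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
    return InteractionNetwork.from_pairs(zip(df["a"], df["b"]))


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")
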