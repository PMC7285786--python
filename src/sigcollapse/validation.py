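"""Prune signatures against independent validation cohorts.

Two filters, applied in order:

1. :func:`drop_unmeasured` — genes not represented on the validation
   platform are removed (array content differs between platforms);
2. :func:`prune_by_replication` — a signature member is kept only if its
   differential expression replicates (``p < alpha`` with the discovery
   direction) in *every* validation cohort.

A signature whose anchor is pruned keeps its remaining members as a
headless ``pathway_network`` signature only when at least two members
survive; otherwise the whole signature is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .signatures import Signature, SignatureSet

logger = logging.getLogger(__name__)

MIN_HEADLESS_SURVIVORS = 2


@dataclass
class ValidationReport:
    """Replication outcome per gene and the pruned signature set.

    Attributes
    ----------
    records : pandas.DataFrame
        One row per (gene, cohort): ``log2FC``, ``p``, ``replicated``.
    verdicts : dict
        Gene -> ``"kept"`` | ``"dropped_replication"``.
    pruned : SignatureSet
        Signatures after pruning.
    dropped_signatures : dict
        Signature name -> reason, for signatures removed entirely.
    """

    records: pd.DataFrame
    verdicts: dict[str, str]
    pruned: SignatureSet
    dropped_signatures: dict[str, str] = field(default_factory=dict)

    def kept_genes(self) -> list[str]:
        return sorted(g for g, v in self.verdicts.items() if v == "kept")


def drop_unmeasured(sigs: SignatureSet, platform_genes: Sequence[str]) -> SignatureSet:
    """Remove signature members absent from the validation platform.

    Signatures emptied by the removal are dropped entirely; an all-empty
    result is returned with a warning rather than raising.
    """
    platform = set(platform_genes)
    if not platform:
        raise ValueError("platform gene list is empty")
    pruned: list[Signature] = []
    for s in sigs:
        members = tuple(g for g in s.members if g in platform)
        removed = sorted(set(s.members) - platform)
        if not members:
            logger.warning("signature %s entirely unmeasured on platform; dropped", s.name)
            continue
        anchor = s.anchor if (s.anchor in members) else None
        provenance = dict(s.provenance)
        if removed:
            provenance["dropped_platform"] = removed
        pruned.append(Signature(name=s.name, kind=s.kind, members=members,
                                anchor=anchor, provenance=provenance))
    if not pruned:
        logger.warning("no signatures survive the platform filter")
    return SignatureSet(tuple(pruned))


def prune_by_replication(sigs: SignatureSet, discovery: pd.DataFrame,
                         cohorts: Sequence[pd.DataFrame], alpha: float = 0.05,
                         cohort_names: Sequence[str] | None = None) -> ValidationReport:
    """Keep a member iff it replicates in every validation cohort.

    Replication in a cohort means ``p < alpha`` *and* the cohort ``log2FC``
    has the discovery sign.  Anchors are prunable like any member; see the
    module docstring for the headless rule.

    ``discovery`` and each cohort table are gene-indexed with ``log2FC`` and
    ``p`` columns; every signature member must be present in every cohort
    (run :func:`drop_unmeasured` first).
    """
    if cohort_names is None:
        cohort_names = [f"cohort{i + 1}" for i in range(len(cohorts))]
    all_members = sorted({g for s in sigs for g in s.members})
    missing_disc = sorted(set(all_members) - set(discovery.index))
    if missing_disc:
        raise KeyError(f"members missing from discovery table: {missing_disc}; "
                       "run drop_unmeasured against the platform first")
    for name, cohort in zip(cohort_names, cohorts):
        missing = sorted(set(all_members) - set(cohort.index))
        if missing:
            raise KeyError(f"members missing from {name}: {missing}; "
                           "run drop_unmeasured against the platform first")

    rows = []
    verdicts: dict[str, str] = {}
    for gene in all_members:
        disc_sign = np.sign(discovery.loc[gene, "log2FC"])
        replicated_everywhere = True
        for name, cohort in zip(cohort_names, cohorts):
            lfc = float(cohort.loc[gene, "log2FC"])
            p = float(cohort.loc[gene, "p"])
            replicated = bool(p < alpha and np.sign(lfc) == disc_sign)
            replicated_everywhere &= replicated
            rows.append({"gene": gene, "cohort": name, "log2FC": lfc,
                         "p": p, "replicated": replicated})
        verdicts[gene] = "kept" if replicated_everywhere else "dropped_replication"

    pruned: list[Signature] = []
    dropped: dict[str, str] = {}
    for s in sigs:
        survivors = tuple(g for g in s.members if verdicts[g] == "kept")
        removed = sorted(set(s.members) - set(survivors))
        provenance = dict(s.provenance)
        if removed:
            provenance["dropped_replication"] = removed
        if not survivors:
            dropped[s.name] = "no member replicated"
            continue
        if s.anchor is not None and s.anchor not in survivors:
            if len(survivors) < MIN_HEADLESS_SURVIVORS:
                dropped[s.name] = (f"anchor {s.anchor} not replicated and fewer than "
                                   f"{MIN_HEADLESS_SURVIVORS} members survive")
                continue
            pruned.append(Signature(name=s.name, kind="pathway_network",
                                    members=survivors, anchor=None, provenance=provenance))
        else:
            pruned.append(Signature(name=s.name, kind=s.kind, members=survivors,
                                    anchor=s.anchor, provenance=provenance))

    return ValidationReport(records=pd.DataFrame(rows), verdicts=verdicts,
                            pruned=SignatureSet(tuple(pruned)),
                            dropped_signatures=dropped)


def write_validation_report(report: ValidationReport, records_path, verdicts_path) -> None:
    import json
    report.records.to_csv(records_path, sep="\t", index=False)
    payload = {"verdicts": report.verdicts,
               "dropped_signatures": report.dropped_signatures}
    with open(verdicts_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
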