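"""End-to-end orchestration: DEG selection -> signature collapse ->
cross-cohort validation -> diagnostic classifier.

:func:`run_pipeline` executes the stages in order from a single config
mapping (usually loaded from YAML), writing one numbered artifact per stage
plus a ``run.log`` into the run directory.  Stages read their input files
lazily, so a missing late input (e.g. the network edge list) fails at its
own stage and leaves earlier artifacts intact.  All randomness comes from
the config seed; re-running with the same config reproduces every artifact
byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import classify, diffexpr, enrichment, signatures as sigmod, validation
from .io_formats import (read_expression_matrix, read_gene_sets, read_network,
                         read_parent_map, read_target_map,
                         write_expression_matrix)

STAGES = ("collapse", "de", "degs", "mirna", "enrichment", "network",
          "assemble", "platform", "replication", "features", "train",
          "select", "timepoints")

DEFAULT_THRESHOLDS = {
    "lfc": 0.5, "alpha": 0.05, "fdr_alpha": 0.05, "coverage_min": 0.10,
    "alpha_coexpr": 0.05, "replication_alpha": 0.05,
}


class PipelineError(RuntimeError):
    """A stage failed; earlier artifacts are left in place."""


def _resolve(base: Path, value: str) -> Path:
    path = Path(value)
    return path if path.is_absolute() else base / path


def _read_cohort(base: Path, spec: Mapping[str, str]):
    return read_expression_matrix(_resolve(base, spec["matrix"]),
                                  _resolve(base, spec["groups"]))


def load_config(path: str | Path) -> dict:
    import yaml
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    config.setdefault("_base_dir", str(Path(path).resolve().parent))
    return config


def run_pipeline(config: Mapping[str, Any], outdir: str | Path,
                 stop_after: str | None = None) -> dict[str, Any]:
    """Run the full pipeline; returns the in-memory stage artifacts.

    ``stop_after`` names a stage (see :data:`STAGES`) after which execution
    halts; later artifacts are simply not produced.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; stages: {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(config.get("_base_dir", "."))
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    seed = int(config.get("seed", 0))
    log_path = outdir / "run.log"
    log_path.write_text("")

    def log(stage: str, message: str) -> None:
        with open(log_path, "a", encoding="utf-8") as fh:
            fh.write(f"[{stage}] {message}\n")

    def stage_guard(stage: str, fn):
        try:
            return fn()
        except Exception as exc:
            log(stage, f"ERROR: {exc}")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    artifacts: dict[str, Any] = {}

    # -- collapse ---------------------------------------------------------
    def _collapse():
        m = _read_cohort(base, config["discovery"])
        annotation_path = config["discovery"].get("annotation")
        if annotation_path:
            ann_df = pd.read_csv(_resolve(base, annotation_path), sep="\t",
                                 header=None, names=["transcript", "gene"], dtype=str)
            annotation = {t: g.split(",") for t, g in zip(ann_df["transcript"], ann_df["gene"])}
            m = diffexpr.collapse_transcripts(m, annotation)
            write_expression_matrix(m, outdir / "01_collapsed.tsv")
            log("collapse", f"collapsed to {len(m.genes)} genes")
        else:
            log("collapse", "no annotation provided; matrix already gene-level")
        return m

    matrix = stage_guard("collapse", _collapse)
    artifacts["matrix"] = matrix
    if stop_after == "collapse":
        return artifacts

    # -- differential expression -----------------------------------------
    def _de():
        results = diffexpr.TwoGroupDE(matrix, prior_df_mode="moments").fit()
        diffexpr.write_deg_table(results.table, outdir / "02_de.tsv")
        log("de", f"{len(results.table)} genes; prior df {results.prior_df:.3g}")
        return results

    de_results = stage_guard("de", _de)
    artifacts["de"] = de_results
    if stop_after == "de":
        return artifacts

    def _degs():
        degs = de_results.select_degs(lfc_threshold=thresholds["lfc"],
                                      alpha=thresholds["alpha"])
        diffexpr.write_deg_table(degs, outdir / "03_degs.tsv")
        log("degs", f"{len(degs)} DEGs, {int(degs['fdr_passing'].sum())} FDR-passing")
        return degs

    degs = stage_guard("degs", _degs)
    artifacts["degs"] = degs
    if stop_after == "degs":
        return artifacts

    # -- miRNA signatures -------------------------------------------------
    def _mirna():
        targets = read_target_map(_resolve(base, config["targets"]))
        sigs = sigmod.mirna_signatures(degs, targets, matrix,
                                       alpha_coexpr=thresholds["alpha_coexpr"])
        sigmod.write_signature_set(sigmod.SignatureSet(tuple(sigs)),
                                   outdir / "04_mirna_signatures.gmt",
                                   outdir / "04_mirna_signatures.json")
        log("mirna", f"{len(sigs)} miRNA signatures")
        return sigs

    mirna_sigs = stage_guard("mirna", _mirna)
    artifacts["mirna_sigs"] = mirna_sigs
    if stop_after == "mirna":
        return artifacts

    # -- over-representation ----------------------------------------------
    def _enrichment():
        parent = None
        if config.get("parent_map"):
            parent = read_parent_map(_resolve(base, config["parent_map"]))
        sets = read_gene_sets(_resolve(base, config["gene_sets"]))
        table = enrichment.overrepresentation(degs, sets, universe=matrix.genes)
        fdr_passing = set(degs.index[degs["fdr_passing"]])
        informative = enrichment.select_informative_sets(
            table, fdr_passing=fdr_passing, parent=parent,
            fdr_alpha=thresholds["fdr_alpha"], coverage_min=thresholds["coverage_min"])
        enrichment.write_enrichment_table(table, outdir / "05_enrichment.tsv")
        (outdir / "05_informative.txt").write_text("".join(f"{n}\n" for n in informative))
        log("enrichment", f"{len(table)} enriched rows; informative: {informative}")
        return table, informative, sets

    enrich_table, informative, gene_sets = stage_guard("enrichment", _enrichment)
    artifacts["enrichment"] = enrich_table
    artifacts["informative"] = informative
    if stop_after == "enrichment":
        return artifacts

    # -- network components + miRNA extension -----------------------------
    def _network():
        net = read_network(_resolve(base, config["network"]))
        pathway_sigs = []
        for name in informative:
            set_degs = sorted(set(gene_sets.members(name)) & set(degs.index))
            sig = sigmod.network_correlated_component(
                set_degs, net, matrix, alpha_coexpr=thresholds["alpha_coexpr"],
                name=name)
            if sig is not None:
                pathway_sigs.append(sig)
        candidates = sorted({g for s in pathway_sigs for g in s.members})
        extended = [sigmod.extend_mirna_signature(s, candidates, matrix,
                                                  alpha_coexpr=thresholds["alpha_coexpr"])
                    for s in mirna_sigs]
        sigmod.write_signature_set(sigmod.SignatureSet(tuple(pathway_sigs)),
                                   outdir / "06_network_signatures.gmt",
                                   outdir / "06_network_signatures.json")
        log("network", f"{len(pathway_sigs)} pathway-network signatures; "
                       f"miRNA signatures extended with {len(candidates)} candidates")
        return pathway_sigs, extended

    pathway_sigs, extended_mirna = stage_guard("network", _network)
    artifacts["pathway_sigs"] = pathway_sigs
    if stop_after == "network":
        return artifacts

    # -- assembly ----------------------------------------------------------
    def _assemble():
        fdr_passing = sorted(degs.index[degs["fdr_passing"]])
        universe = set(degs.index) | {g for s in pathway_sigs for g in s.members} \
            | {g for s in extended_mirna for g in s.members}
        sigs = sigmod.assemble_signatures(fdr_passing, extended_mirna, pathway_sigs,
                                          deg_universe=universe)
        sigmod.write_signature_set(sigs, outdir / "07_signatures.gmt",
                                   outdir / "07_signatures.json")
        log("assemble", f"{len(sigs)} signatures, {sigs.n_slots} member slots")
        return sigs

    assembled = stage_guard("assemble", _assemble)
    artifacts["signatures"] = assembled
    if stop_after == "assemble":
        return artifacts

    # -- validation cohorts ------------------------------------------------
    def _platform():
        cohorts = [_read_cohort(base, spec) for spec in config["validation"]]
        names = [spec.get("name", f"cohort{i + 1}")
                 for i, spec in enumerate(config["validation"])]
        if config.get("platform_genes"):
            platform = [line.strip() for line
                        in Path(_resolve(base, config["platform_genes"])).read_text().splitlines()
                        if line.strip()]
        else:
            platform = set(cohorts[0].genes)
            for cohort in cohorts[1:]:
                platform &= set(cohort.genes)
            platform = sorted(platform)
        sigs = validation.drop_unmeasured(assembled, platform)
        sigmod.write_signature_set(sigs, outdir / "08_platform_signatures.gmt")
        log("platform", f"{assembled.n_slots} -> {sigs.n_slots} member slots on platform")
        return sigs, cohorts, names

    platform_sigs, val_cohorts, val_names = stage_guard("platform", _platform)
    artifacts["platform_sigs"] = platform_sigs
    if stop_after == "platform":
        return artifacts

    def _replication():
        cohort_tables = [diffexpr.differential_expression(c) for c in val_cohorts]
        report = validation.prune_by_replication(
            platform_sigs, de_results.table, cohort_tables,
            alpha=thresholds["replication_alpha"], cohort_names=val_names)
        validation.write_validation_report(report, outdir / "09_validation_records.tsv",
                                           outdir / "09_verdicts.json")
        sigmod.write_signature_set(report.pruned, outdir / "09_signatures.gmt")
        log("replication", f"{platform_sigs.n_slots} -> {report.pruned.n_slots} member slots")
        return report

    report = stage_guard("replication", _replication)
    artifacts["validation_report"] = report
    if stop_after == "replication":
        return artifacts

    # -- classifier --------------------------------------------------------
    def _features():
        train_spec = config.get("train") or config["validation"][0]
        test_spec = config.get("test") or config["validation"][-1]
        train = _read_cohort(base, train_spec)
        test = _read_cohort(base, test_spec)
        X, y = classify.build_features(report.pruned, train)
        X.to_csv(outdir / "10_features.tsv", sep="\t", index_label="sample")
        log("features", f"{X.shape[0]} samples x {X.shape[1]} features")
        return train, test

    train_m, test_m = stage_guard("features", _features)
    if stop_after == "features":
        return artifacts

    clf_cfg = config.get("classifier", {})
    folds = int(clf_cfg.get("folds", 10))
    c_grid = clf_cfg.get("c_grid", classify.DEFAULT_C_GRID)

    def _train():
        model = classify.SignatureClassifier(report.pruned, penalty="l2",
                                             C_grid=c_grid, folds=folds, seed=seed)
        result = model.fit(train_m)
        X_test, y_test = classify.build_features(report.pruned, test_m)
        result.evaluate(X_test, y_test)
        result.to_json(outdir / "11_model_l2.json")
        log("train", f"L2 model C={result.C:g} train AUC {result.train_auc:.3f} "
                     f"test AUC {result.test_auc:.3f}")
        return result

    l2_result = stage_guard("train", _train)
    artifacts["l2"] = l2_result
    if stop_after == "train":
        return artifacts

    def _select():
        model = classify.SignatureClassifier(report.pruned, penalty="l1",
                                             C_grid=c_grid, folds=folds, seed=seed)
        result = model.fit(train_m)
        X_test, y_test = classify.build_features(report.pruned, test_m)
        result.evaluate(X_test, y_test)
        selected = classify.select_features_l1(result)
        result.to_json(outdir / "12_model_l1.json")
        (outdir / "12_selected.txt").write_text("".join(f"{g}\n" for g in selected))
        log("select", f"L1 model selects {len(selected)} genes: {selected}; "
                      f"test AUC {result.test_auc:.3f}")
        return result, selected

    l1_result, selected = stage_guard("select", _select)
    artifacts["l1"] = l1_result
    artifacts["selected"] = selected
    if stop_after == "select":
        return artifacts

    def _timepoints():
        if not config.get("timecourse"):
            log("timepoints", "no time-course cohorts configured; skipped")
            return {}
        cohorts = {tp: _read_cohort(base, spec)
                   for tp, spec in config["timecourse"].items()}
        aucs = classify.evaluate_timepoints(l2_result, cohorts)
        (outdir / "13_timepoint_auc.json").write_text(
            json.dumps(aucs, indent=2, sort_keys=True))
        log("timepoints", f"per-timepoint AUC: {aucs}")
        return aucs

    artifacts["timepoint_auc"] = stage_guard("timepoints", _timepoints)
    return artifacts
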