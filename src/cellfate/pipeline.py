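"""End-to-end orchestration: generate/ingest -> ... -> biomarker, with manifest.

``run_all`` executes the full stage sequence — cohort generation or
ingestion, gene filtering, TPM conversion, differential expression between
consecutive stages, PCoA ordination with a PERMANOVA group test, gene-set
over-representation, deconvolution, the stage-wise Mantel interaction
network, dynamics summaries, NOS/necroptosis correlations, and the marker
ROC — writing one TSV/JSON per stage output plus a run manifest.

Determinism contract: a fixed config (including seed) yields byte-identical
output tables on rerun.  The global seed fans out to per-stage child seeds
by a stable hash of the stage name, so adding a stage never perturbs the
random streams of earlier stages.  Every output table carries a header
comment naming the producing stage and the config digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarker import marker_roc
from .deconvolution import estimate_proportions
from .dynamics import classify_changes, count_interactions, strength_trajectory
from .expression import (
    count_degs,
    differential_expression,
    filter_genes,
    ora_enrichment,
    pcoa,
    permutation_group_test,
)
from .interactions import build_interaction_network, spearman_mode_type_matrix
from .io import (
    PipelineConfig,
    ValidationError,
    counts_to_tpm,
    read_expression_table,
    read_gene_annotation,
    read_gmt,
    read_sample_metadata,
    write_expression_table,
    write_gene_annotation,
    write_gmt,
    write_proportions,
    write_sample_metadata,
)
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

__all__ = ["run_all", "stage_seed", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def stage_seed(base_seed: int, stage_name: str) -> int:
    """Stable per-stage child seed derived from the global seed."""
    digest = hashlib.sha256(f"{base_seed}:{stage_name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _config_digest(config: PipelineConfig, cohort_config: CohortConfig | None) -> str:
    payload = {"pipeline": config.to_dict()}
    if cohort_config is not None:
        payload["cohort"] = dataclasses.asdict(cohort_config)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_df(df: pd.DataFrame, path: Path, stage: str, digest: str,
              index: bool = True, index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config_sha={digest}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(inputs: dict, config: PipelineConfig) -> SyntheticCohort:
    from .io import GeneSetCatalog  # noqa: F401  (typing only)

    required = ("counts", "metadata", "annotation", "gmt")
    missing = [k for k in required if k not in inputs or not Path(inputs[k]).exists()]
    if missing:
        raise PipelineError(f"stage=ingest missing input file(s): {missing}")
    counts = read_expression_table(inputs["counts"], unit_kind="counts")
    metadata = read_sample_metadata(inputs["metadata"], stage_order=config.stage_order)
    annotation = read_gene_annotation(inputs["annotation"])
    catalog = read_gmt(inputs["gmt"])
    return SyntheticCohort(counts=counts, metadata=metadata,
                           annotation=annotation, catalog=catalog, truth=None)


def run_all(config: PipelineConfig, outdir: str | Path,
            cohort_config: CohortConfig | None = None,
            inputs: dict | None = None,
            filter_params: dict | None = None) -> Path:
    """Run the full pipeline into ``outdir``; returns the output directory.

    Exactly one of ``cohort_config`` (simulate) or ``inputs`` (paths with
    keys counts/metadata/annotation/gmt) must be provided.
    """
    if (cohort_config is None) == (inputs is None):
        raise PipelineError("stage=setup provide either cohort_config or inputs")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = _config_digest(config, cohort_config)
    manifest: dict = {
        "tool": "cellfate",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha": digest,
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
        "seeds": {"global": config.rng_seed},
        "input_digests": {},
    }

    def _stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(f"stage={name} failed: {exc}") from exc
        return wrap

    # ---- generate / ingest -------------------------------------------------
    if cohort_config is not None:
        cohort_config = dataclasses.replace(
            cohort_config, rng_seed=stage_seed(config.rng_seed, "generate"))
        manifest["seeds"]["generate"] = cohort_config.rng_seed
        manifest["cohort_config"] = dataclasses.asdict(cohort_config)
        cohort = _stage("generate")(generate_cohort, cohort_config)
        write_expression_table(cohort.counts, outdir / "counts.tsv",
                               header_comment=f"stage=generate config_sha={digest}")
        write_sample_metadata(cohort.metadata, outdir / "metadata.tsv")
        write_gene_annotation(cohort.annotation, outdir / "annotation.tsv")
        write_gmt(cohort.catalog, outdir / "gene_sets.gmt")
        _write_df(cohort.truth.signature_matrix, outdir / "signature.tsv",
                  "generate", digest, index_label="gene_id")
        write_proportions(cohort.truth.true_proportions,
                          outdir / "true_proportions.tsv",
                          header_comment=f"stage=generate config_sha={digest}")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"couplings": [dataclasses.asdict(c) for c in
                                     cohort.truth.couplings],
                       "rng_seed": cohort.truth.rng_seed}, fh, indent=2)
    else:
        cohort = _load_inputs(inputs, config)
        for key, value in inputs.items():
            manifest["input_digests"][key] = _sha256(Path(value))
    manifest["stages"]["ingest"] = {
        "n_genes": cohort.counts.shape[0], "n_samples": cohort.counts.shape[1]}

    # ---- filter + TPM ------------------------------------------------------
    filter_params = filter_params or {}
    filtered = _stage("filter")(filter_genes, cohort.counts, cohort.annotation,
                                **filter_params)
    tpm = _stage("tpm")(counts_to_tpm, filtered, cohort.annotation)
    write_expression_table(tpm, outdir / "tpm.tsv",
                           header_comment=f"stage=tpm config_sha={digest}")
    manifest["stages"]["filter"] = {"n_genes": filtered.shape[0]}

    # ---- differential expression between consecutive stages ---------------
    stages = cohort.metadata.stages_present()
    deg_counts = {}
    contrasts = list(zip(stages[:-1], stages[1:]))
    if len(stages) > 2:
        contrasts.append((stages[0], stages[-1]))
    deg_tables = {}
    for group_a, group_b in contrasts:
        deg = _stage("deg")(differential_expression, tpm, cohort.metadata,
                            group_a, group_b, config)
        name = f"deg_{group_b}_vs_{group_a}"
        _write_df(deg, outdir / f"{name}.tsv", "deg", digest, index=False)
        n_up, n_down = count_degs(deg)
        deg_counts[name] = {"n_up": n_up, "n_down": n_down}
        deg_tables[(group_a, group_b)] = deg
    manifest["stages"]["deg"] = deg_counts

    # ---- ordination of the first-vs-last DEG profile -----------------------
    first, last = stages[0], stages[-1]
    deg_fl = deg_tables[(first, last)]
    deg_genes = deg_fl.loc[deg_fl["direction"] != "ns", "gene_id"].tolist()
    ord_genes = deg_genes if len(deg_genes) >= 2 else tpm.gene_ids
    ord_samples = [s for s in cohort.metadata.sample_ids
                   if s in set(tpm.sample_ids)
                   and str(cohort.metadata.data.loc[s, "stage"]) in (first, last)]
    tpm_ord = tpm.subset_genes(ord_genes).subset_samples(ord_samples)
    ordination = _stage("pcoa")(pcoa, tpm_ord, 2)
    perm_seed = stage_seed(config.rng_seed, "permanova")
    manifest["seeds"]["permanova"] = perm_seed
    group_p = _stage("pcoa")(
        permutation_group_test, tpm_ord,
        [str(cohort.metadata.data.loc[s, "stage"]) for s in ord_samples],
        config.n_permutations, perm_seed)
    ordination.group_p_value = group_p
    coords = ordination.coordinates.copy()
    coords["stage"] = [str(cohort.metadata.data.loc[s, "stage"]) for s in ord_samples]
    _write_df(coords, outdir / "pcoa.tsv", "pcoa", digest, index_label="sample_id")
    manifest["stages"]["pcoa"] = {"group_p_value": group_p,
                                  "n_deg_genes": len(ord_genes)}

    # ---- ORA of first-vs-last DEGs against the catalog ---------------------
    ora = _stage("ora")(ora_enrichment, deg_genes, cohort.catalog, tpm.gene_ids) \
        if deg_genes else pd.DataFrame(
            columns=["set_name", "n_set", "overlap", "p_value", "q_value"])
    _write_df(ora, outdir / "ora.tsv", "ora", digest, index=False)

    # ---- deconvolution -----------------------------------------------------
    if cohort_config is not None:
        signature = cohort.truth.signature_matrix
    elif "signature" in (inputs or {}):
        # gene x cell-type reference, read as a plain numeric table
        signature = read_expression_table(inputs["signature"], "counts").data
    else:
        raise PipelineError("stage=deconvolve no signature matrix available")
    proportions = _stage("deconvolve")(estimate_proportions, tpm, signature)
    write_proportions(proportions, outdir / "proportions.tsv",
                      header_comment=f"stage=deconvolve config_sha={digest}")
    manifest["stages"]["deconvolve"] = {"n_cell_types": len(proportions.cell_types)}

    # ---- interaction network ----------------------------------------------
    records = _stage("interactions")(build_interaction_network, tpm, proportions,
                                     cohort.catalog, cohort.metadata, config)
    _write_df(records, outdir / "interactions.tsv", "interactions", digest,
              index=False)
    manifest["stages"]["interactions"] = {"n_records": len(records)}

    # ---- dynamics ----------------------------------------------------------
    summary = _stage("dynamics")(count_interactions, records, stages)
    changes = _stage("dynamics")(classify_changes, summary, stages)
    _write_df(summary, outdir / "stage_summary.tsv", "dynamics", digest)
    _write_df(changes, outdir / "changes.tsv", "dynamics", digest, index=False)
    for mode in ("necroptosis", "ferroptosis"):
        if mode in set(records["death_mode"]):
            traj = strength_trajectory(records, mode, stages)
            _write_df(traj, outdir / f"trajectory_{mode}.tsv", "dynamics", digest)
    spearman_frames = []
    for stage in stages:
        rho, _p = _stage("dynamics")(spearman_mode_type_matrix, tpm, proportions,
                                     cohort.catalog, cohort.metadata, stage)
        rho.insert(0, "stage", stage)
        spearman_frames.append(rho)
    _write_df(pd.concat(spearman_frames), outdir / "spearman_heatmap.tsv",
              "dynamics", digest, index_label="death_mode")
    manifest["stages"]["dynamics"] = {
        "totals": {s: int(summary.loc[s, "total"]) for s in summary.index}}

    # ---- NOS association ---------------------------------------------------
    from .nos import count_signed_significant, nos_correlation_matrix

    nos_genes = []
    for name in cohort.catalog.names_with_role("nos"):
        nos_genes.extend(cohort.catalog[name])
    necro_genes = cohort.catalog["necroptosis"] \
        if "necroptosis" in cohort.catalog else []
    if nos_genes and necro_genes:
        nos_frames = [
            _stage("nos")(nos_correlation_matrix, tpm, cohort.metadata,
                          nos_genes, necro_genes, stage)
            for stage in stages
        ]
        nos_table = pd.concat(nos_frames, ignore_index=True)
        signed = count_signed_significant(nos_table)
        _write_df(nos_table, outdir / "nos_correlations.tsv", "nos", digest,
                  index=False)
        _write_df(signed, outdir / "nos_signed_counts.tsv", "nos", digest)
        manifest["stages"]["nos"] = {"n_pairs": len(nos_table)}

    # ---- biomarker ROC -----------------------------------------------------
    marker_genes = []
    for name in cohort.catalog.names_with_role("marker"):
        marker_genes.extend(cohort.catalog[name])
    if marker_genes and "group" in cohort.metadata.data.columns:
        roc = _stage("biomarker")(marker_roc, tpm, cohort.metadata, marker_genes)
        _write_df(pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr,
                                "tpr": roc.tpr}),
                  outdir / "roc_points.tsv", "biomarker", digest, index=False)
        _write_df(roc.coefficients.rename("coefficient").to_frame(),
                  outdir / "biomarker_coefficients.tsv", "biomarker", digest,
                  index_label="term")
        with open(outdir / "biomarker_summary.json", "w") as fh:
            json.dump({"auc": roc.auc, "sensitivity": roc.sensitivity,
                       "specificity": roc.specificity,
                       "youden_threshold": roc.youden_threshold}, fh, indent=2)
        manifest["stages"]["biomarker"] = {"auc": roc.auc}

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    manifest["output_digests"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.suffix in (".tsv", ".gmt") or p.name == "truth.json"}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %s", outdir)
    return outdir
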