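"""End-to-end orchestration: synthetic screens in memory and file-based runs.

:func:`run_screen` executes the whole analysis chain on a synthetic
configuration without touching disk (the workhorse for calibration and
recovery studies); :func:`simulate_to_dir` materializes a synthetic run
directory; :func:`run_pipeline` drives the same stages from files per a
:class:`~perturbscreen.io.RunConfig`, writing each stage's outputs and a
checksummed manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ps_io
from .concordance import (
    BiodomainAnnotation,
    ReferenceSignature,
    pearson_protein_concordance,
    score_term_concordance,
)
from .gsea import GeneSetCollection, preranked_gsea
from .integration import build_scorecards, correlate_assay_terms
from .phenotypes import batch_log2fc, fit_effect_model, summarize_hits
from .proteomics import anova_tukey, count_significant, qc_filter_samples
from .simulate import (
    GroundTruth,
    SimulationConfig,
    gen_assay_data,
    gen_biodomain_annotation,
    gen_ct_table,
    gen_knockdown_proteomes,
    gen_reference_signature,
    ground_truth,
)

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "run_screen", "simulate_to_dir", "run_pipeline", "write_report"]

_KEY_KNOCKDOWN_GSEA = 201


@dataclass
class ScreenResult:
    """Every table produced by one end-to-end screen analysis."""

    config: SimulationConfig | None
    truth: GroundTruth | None
    estimates: pd.DataFrame
    hit_summary: object
    de: pd.DataFrame
    de_counts: pd.DataFrame
    enrichments: dict
    reference: ReferenceSignature
    collection: GeneSetCollection
    annotation: BiodomainAnnotation
    concordance: pd.DataFrame
    protein_concordance: pd.DataFrame
    integration: pd.DataFrame
    scorecards: pd.DataFrame


def _knockdown_enrichments(
    de: pd.DataFrame,
    collection: GeneSetCollection,
    seed: int,
    n_perm: int,
    min_size: int,
    max_size: int,
) -> dict:
    """Per-(target, cell line) preranked enrichment of the DE log2FC ranking."""
    enrichments = {}
    keys = sorted(set(zip(de["sirna"], de["cell_line"])))
    for i, (target, line) in enumerate(keys):
        sub = de.loc[(de["sirna"] == target) & (de["cell_line"] == line) & de["testable"]]
        ranking = sub.set_index("protein")["log2fc"].astype(float)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), _KEY_KNOCKDOWN_GSEA, i)))
        enrichments[(target, line)] = preranked_gsea(
            ranking, collection, n_perm=n_perm, seed=rng, min_size=min_size, max_size=max_size
        )
    return enrichments


def run_screen(
    cfg: SimulationConfig,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_size: int = 10,
    max_size: int = 500,
    min_terms: int = 5,
    min_points: int = 8,
    min_proteins_corr: int = 10,
    qc_min_proteins: int = 0,
    separate_lines: bool = False,
) -> ScreenResult:
    """Generate a synthetic screen and run the full analysis chain on it.

    ``qc_min_proteins`` defaults to 0 because synthetic matrices are
    complete; file-based runs keep the standard 6100-protein QC threshold.
    """
    collection, annotation = gen_biodomain_annotation(cfg)
    reference = gen_reference_signature(cfg, collection, annotation, n_perm=n_perm,
                                        min_size=min_size, max_size=max_size, alpha=alpha)

    assay = gen_assay_data(cfg)
    fcs = batch_log2fc(assay, cfg.control_label)
    estimates = fit_effect_model(fcs, cfg.control_label, alpha=alpha, separate_lines=separate_lines)
    hit_summary = summarize_hits(estimates)

    matrix, meta = gen_knockdown_proteomes(cfg, reference, annotation)
    qc = qc_filter_samples(matrix, meta, min_proteins=qc_min_proteins)
    de = anova_tukey(qc.matrix, qc.sample_meta, control=cfg.control_label)
    de_counts = count_significant(de, alpha=alpha)

    enrichments = _knockdown_enrichments(de, collection, cfg.seed, n_perm, min_size, max_size)
    concord = score_term_concordance(enrichments, reference, annotation,
                                     alpha=alpha, min_terms=min_terms)
    prot_concord = pearson_protein_concordance(de, reference, annotation, collection,
                                               alpha=alpha, min_proteins_corr=min_proteins_corr)
    integration = correlate_assay_terms(estimates, enrichments,
                                        min_points=min_points, alpha=alpha)
    combined = pd.concat([concord, prot_concord], ignore_index=True)
    scorecards = build_scorecards(estimates, combined, integration, enrichments, alpha=alpha)
    return ScreenResult(
        config=cfg, truth=ground_truth(cfg), estimates=estimates, hit_summary=hit_summary,
        de=de, de_counts=de_counts, enrichments=enrichments, reference=reference,
        collection=collection, annotation=annotation, concordance=concord,
        protein_concordance=prot_concord, integration=integration, scorecards=scorecards,
    )


def simulate_to_dir(cfg: SimulationConfig, outdir, n_perm: int = 1000) -> ps_io.RunConfig:
    """Write a complete synthetic input set plus ground truth to ``outdir``.

    Returns a :class:`RunConfig` pointing at the written files (also saved
    as ``run_config.yaml``), directly consumable by :func:`run_pipeline`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection, annotation = gen_biodomain_annotation(cfg)
    reference = gen_reference_signature(cfg, collection, annotation, n_perm=n_perm)
    assay = gen_assay_data(cfg)
    matrix, meta = gen_knockdown_proteomes(cfg, reference, annotation)
    ct = gen_ct_table(cfg)

    ps_io.write_tsv(assay, outdir / "assays.tsv")
    out_matrix = matrix.reset_index()
    ps_io.write_tsv(out_matrix, outdir / "abundance.tsv")
    ps_io.write_tsv(meta, outdir / "sample_meta.tsv")
    ps_io.write_gmt(collection, outdir / "gene_sets.gmt")
    ps_io.write_biodomain_annotation(annotation, outdir / "biodomains.tsv")
    ps_io.write_reference_signature(reference, outdir / "reference_terms.tsv",
                                    outdir / "reference_proteins.tsv")
    ps_io.write_tsv(ct, outdir / "ct_values.tsv")
    with open(outdir / "ground_truth.json", "wt", encoding="utf-8") as fh:
        json.dump(ground_truth(cfg).to_json_dict(), fh, indent=1, sort_keys=True)

    run_cfg = ps_io.RunConfig(
        assays=str(outdir / "assays.tsv"),
        matrix=str(outdir / "abundance.tsv"),
        sample_meta=str(outdir / "sample_meta.tsv"),
        gene_sets=str(outdir / "gene_sets.gmt"),
        biodomains=str(outdir / "biodomains.tsv"),
        reference_terms=str(outdir / "reference_terms.tsv"),
        reference_proteins=str(outdir / "reference_proteins.tsv"),
        control=cfg.control_label,
        min_proteins=0,  # synthetic matrices are complete
        n_perm=n_perm,
        seed=cfg.seed,
    )
    run_cfg.to_yaml(outdir / "run_config.yaml")
    return run_cfg


STAGES = ("phenotypes", "proteome", "gsea", "concordance", "integrate", "report")


def run_pipeline(config: ps_io.RunConfig, outdir, stages=STAGES) -> Path:
    """Run the file-based pipeline stage by stage into ``outdir``.

    Each stage's outputs are on disk before the next starts; a manifest
    records the configuration and SHA-256 checksums of every output.  A
    stage failure raises with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": [], "checksums": {}}
    state: dict = {}

    def _checkpoint(stage: str, files: dict) -> None:
        manifest["stages"].append(stage)
        for name, path in files.items():
            manifest["checksums"][name] = ps_io.file_checksum(path)
        with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    def _require(path: str, what: str) -> str:
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing input for {what}: {path!r}")
        return path

    try:
        if "phenotypes" in stages:
            stage = "phenotypes"
            assay = ps_io.read_tsv(_require(config.assays, "assay measurements"))
            fcs = batch_log2fc(assay, config.control)
            estimates = fit_effect_model(fcs, config.control, alpha=config.alpha,
                                         separate_lines=config.separate_lines)
            summary = summarize_hits(estimates)
            ps_io.write_tsv(fcs, outdir / "batch_log2fc.tsv")
            ps_io.write_tsv(estimates, outdir / "effect_estimates.tsv")
            ps_io.write_tsv(summary.per_assay, outdir / "hit_summary.tsv")
            state["estimates"] = estimates
            _checkpoint(stage, {"batch_log2fc.tsv": outdir / "batch_log2fc.tsv",
                                "effect_estimates.tsv": outdir / "effect_estimates.tsv",
                                "hit_summary.tsv": outdir / "hit_summary.tsv"})

        if "proteome" in stages:
            stage = "proteome"
            matrix = ps_io.read_tsv(_require(config.matrix, "abundance matrix")).set_index("protein")
            meta = ps_io.read_tsv(_require(config.sample_meta, "sample metadata"))
            qc = qc_filter_samples(matrix, meta, min_proteins=config.min_proteins)
            de = anova_tukey(qc.matrix, qc.sample_meta, control=config.control)
            counts = count_significant(de, alpha=config.alpha)
            ps_io.write_tsv(qc.report, outdir / "qc_report.tsv")
            ps_io.write_tsv(de, outdir / "differential_abundance.tsv")
            ps_io.write_tsv(counts, outdir / "de_counts.tsv")
            state["de"] = de
            _checkpoint(stage, {"qc_report.tsv": outdir / "qc_report.tsv",
                                "differential_abundance.tsv": outdir / "differential_abundance.tsv",
                                "de_counts.tsv": outdir / "de_counts.tsv"})

        if "gsea" in stages:
            stage = "gsea"
            collection = ps_io.read_gmt(_require(config.gene_sets, "gene sets"))
            de = state.get("de")
            if de is None:
                de = ps_io.read_tsv(outdir / "differential_abundance.tsv")
            enrichments = _knockdown_enrichments(de, collection, config.seed, config.n_perm,
                                                 config.min_size, config.max_size)
            files = {}
            for (target, line), table in enrichments.items():
                out = table.copy()
                out["leading_edge"] = out["leading_edge"].map(lambda g: ",".join(g))
                name = f"gsea_{target}_{line}.tsv"
                ps_io.write_tsv(out, outdir / name)
                files[name] = outdir / name
            state["collection"] = collection
            state["enrichments"] = enrichments
            _checkpoint(stage, files)

        if "concordance" in stages:
            stage = "concordance"
            annotation = ps_io.read_biodomain_annotation(_require(config.biodomains, "biodomain table"))
            reference = ps_io.read_reference_signature(
                _require(config.reference_terms, "reference term signature"),
                _require(config.reference_proteins, "reference protein effects"),
            )
            mapping = None
            if config.orthologs:
                mapping = ps_io.read_tsv(config.orthologs, dtype=str)
            concord = score_term_concordance(state["enrichments"], reference, annotation,
                                             alpha=config.alpha, min_terms=config.min_terms,
                                             universe=config.universe)
            prot = pearson_protein_concordance(state["de"], reference, annotation,
                                               state["collection"], mapping=mapping,
                                               alpha=config.alpha,
                                               min_proteins_corr=config.min_proteins_corr)
            ps_io.write_tsv(concord, outdir / "term_concordance.tsv")
            ps_io.write_tsv(prot, outdir / "protein_concordance.tsv")
            state["concordance"] = concord
            state["protein_concordance"] = prot
            state["reference"] = reference
            state["annotation"] = annotation
            _checkpoint(stage, {"term_concordance.tsv": outdir / "term_concordance.tsv",
                                "protein_concordance.tsv": outdir / "protein_concordance.tsv"})

        if "integrate" in stages:
            stage = "integrate"
            integration = correlate_assay_terms(state["estimates"], state["enrichments"],
                                                min_points=config.min_points, alpha=config.alpha,
                                                per_line=config.per_line_integration)
            combined = pd.concat([state["concordance"], state["protein_concordance"]],
                                 ignore_index=True)
            scorecards = build_scorecards(state["estimates"], combined, integration,
                                          state["enrichments"], alpha=config.alpha)
            ps_io.write_tsv(integration, outdir / "integration.tsv")
            cards = scorecards.copy()
            for col in ("phenotype_hits", "reversal_domains", "coupled_terms"):
                cards[col] = cards[col].map(lambda items: ";".join("|".join(map(str, t)) for t in items))
            ps_io.write_tsv(cards, outdir / "scorecards.tsv")
            state["integration"] = integration
            state["scorecards"] = scorecards
            _checkpoint(stage, {"integration.tsv": outdir / "integration.tsv",
                                "scorecards.tsv": outdir / "scorecards.tsv"})

        if "report" in stages:
            stage = "report"
            path = write_report(state, outdir)
            _checkpoint(stage, {"report.md": path})
    except Exception as exc:
        record = {"stage": stage, "error": f"{type(exc).__name__}: {exc}"}
        with open(outdir / "error.json", "wt", encoding="utf-8") as fh:
            json.dump(record, fh, indent=1)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def write_report(state: dict, outdir) -> Path:
    """Human-readable markdown summary of whatever stages have run."""
    outdir = Path(outdir)
    lines = ["# Screen analysis report", ""]
    est = state.get("estimates")
    if est is not None and len(est):
        summary = summarize_hits(est)
        lines += [
            "## Phenotype hits",
            "",
            f"- targets tested: {summary.n_targets}",
            f"- targets with >= 1 significant assay hit: {summary.n_targets_with_hit}",
            "",
        ]
        for _, row in summary.per_assay.iterrows():
            dose = f" ({row['dose']})" if row["dose"] else ""
            lines.append(f"- {row['assay']}{dose}: {row['n_hit_targets']} hit targets")
        lines.append("")
    else:
        lines += ["## Phenotype hits", "", "_stage not run or no estimates_", ""]
    de = state.get("de")
    if de is not None and len(de):
        counts = count_significant(de)
        lines += ["## Proteomic differential abundance", "",
                  f"- contrasts tested: {len(counts)}",
                  f"- median significant proteins per contrast: {counts['n_significant'].median():.0f}", ""]
    conc = state.get("concordance")
    if conc is not None and len(conc):
        n_rev = int((conc["call"] == "anti_correlated").sum())
        lines += ["## Signature concordance", "",
                  f"- term-level domain correlations: {len(conc)}",
                  f"- reversal (anti-correlated) calls: {n_rev}", ""]
    cards = state.get("scorecards")
    if cards is not None and len(cards):
        lines += ["## Target tiers", "",
                  "Tier predicate: top = phenotype hit AND signature reversal AND "
                  "phenotype-coupled term; supported = hit AND reversal.", ""]
        for tier in ("top", "supported", "phenotype_only", "proteome_only", "none"):
            members = cards.loc[cards["tier"] == tier, "target"].tolist()
            lines.append(f"- {tier}: {', '.join(members) if members else '(none)'}")
        lines.append("")
    path = outdir / "report.md"
    path.write_text("\n".join(lines), encoding="utf-8")
    return path
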