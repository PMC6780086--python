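"""End-to-end orchestration: simulate/load -> DE -> reciprocal ->
enrichment -> concordance -> lipidomics, with a machine-readable report.

Every stage writes its TSV outputs under the run directory; the report
collects row counts, filter survivors and the key statistics.  The
lipidomic branch is optional: a run without a lipid table completes the
transcriptomic branch and logs a warning.  All randomness flows from the
single seed in the configuration, and the report's numeric content is
reproducible bit for bit under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .concordance import ConcordanceConfig, pathway_concordance
from .de import DECallConfig, call_de, contrast
from .enrichment import enrich
from .errors import ConfigError
from .io import (
    load_annotation,
    load_design,
    load_expression_matrix,
    write_annotation,
    write_design,
    write_expression_matrix,
    write_table,
)
from .lipidomics import (
    LipidTestConfig,
    class_levels,
    fatty_acid_totals,
    load_lipid_table,
    origin_stratified_levels,
    write_lipid_table,
)
from .reciprocal import classify_direction, common_de, kmeans_groups
from .simulate import (
    GroundTruth,
    LipidomeSimConfig,
    TranscriptomeSimConfig,
    generate_lipidome,
    generate_transcriptome,
)

logger = logging.getLogger("phosremodel")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of {simulated, file-based} inputs per data type: give a
    ``transcriptome_sim`` config or (``matrix_path``, ``design_path``,
    ``annotation_path``); give a ``lipidome_sim`` config, or a
    ``lipid_path`` (optionally with ``cell_counts_path``), or neither to
    skip the lipid branch.
    """

    outdir: str | Path = "phosremodel_run"
    seed: int = 0
    transcriptome_sim: TranscriptomeSimConfig | None = None
    matrix_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    lipidome_sim: LipidomeSimConfig | None = None
    lipid_path: str | None = None
    cell_counts_path: str | None = None
    contrasts: tuple[tuple[str, str], ...] = (("PR", "PD"), ("PD", "PDR"))
    # The reciprocal responder identification gates each contrast on the
    # 2-fold cutoff with the unadjusted p < 0.05 (the published selection
    # rule for the common DE set); set use_fdr=True to gate on BH FDR.
    de: DECallConfig = field(default_factory=lambda: DECallConfig(use_fdr=False))
    kmeans_k: int = 10
    kmeans_restarts: int = 50
    enrichment_min_genes: int = 5
    enrichment_fe_threshold: float = 2.0
    enrichment_alpha: float = 0.05
    concordance: ConcordanceConfig = field(default_factory=ConcordanceConfig)
    lipid_test: LipidTestConfig = field(default_factory=LipidTestConfig)

    def validate(self) -> None:
        sim = self.transcriptome_sim is not None
        files = any([self.matrix_path, self.design_path, self.annotation_path])
        if sim and files:
            raise ConfigError("give either a transcriptome sim config or file paths, not both")
        if not sim and not all([self.matrix_path, self.design_path, self.annotation_path]):
            raise ConfigError(
                "file-based runs need matrix_path, design_path and annotation_path"
            )
        if self.lipidome_sim is not None and self.lipid_path is not None:
            raise ConfigError("give either a lipidome sim config or a lipid_path, not both")
        if len(self.contrasts) != 2:
            raise ConfigError("exactly two contrasts are required (depletion, restoration)")
        if self.kmeans_k < 1:
            raise ConfigError("kmeans_k must be >= 1")


@dataclass
class _ClassificationRow:
    gene_id: str
    direction_a: str
    direction_b: str
    classification: str


@dataclass
class _GroupRow:
    group_id: int
    correlation_label: str
    phosphate_correlation: float
    n_genes: int
    member_genes: tuple[str, ...]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": {},
    }

    # --- data stage -------------------------------------------------------
    t0 = time.perf_counter()
    truth: GroundTruth | None = None
    if config.transcriptome_sim is not None:
        sim = dataclasses.replace(config.transcriptome_sim, seed=config.seed)
        matrix, annotation, truth = generate_transcriptome(sim)
        write_expression_matrix(matrix, outdir / "matrix.tsv")
        write_design(matrix.samples, outdir / "design.tsv")
        write_annotation(annotation, outdir / "annotation.tsv")
        _write_truth(truth, outdir / "truth_genes.tsv")
    else:
        design = load_design(config.design_path)
        matrix = load_expression_matrix(config.matrix_path, design)
        annotation = load_annotation(config.annotation_path)
    _stage(report, "data", t0, n_genes=matrix.n_genes, n_samples=len(matrix.samples))

    # --- differential expression ------------------------------------------
    t0 = time.perf_counter()
    (a1, b1), (a2, b2) = config.contrasts
    res_a = contrast(matrix, a1, b1, config.de)
    res_b = contrast(matrix, a2, b2, config.de)
    label_a, label_b = f"{b1}/{a1}", f"{b2}/{a2}"
    write_table(res_a, outdir / f"contrast_{b1}_{a1}.tsv")
    write_table(res_b, outdir / f"contrast_{b2}_{a2}.tsv")
    de_a = call_de(res_a, config.de)
    de_b = call_de(res_b, config.de)
    _stage(
        report, "differential_expression", t0,
        contrasts={label_a: len(de_a), label_b: len(de_b)},
    )

    # --- reciprocal response ------------------------------------------------
    t0 = time.perf_counter()
    overlap = common_de(de_a, de_b, matrix.n_genes)
    idx_a = {r.gene_id: r for r in res_a}
    idx_b = {r.gene_id: r for r in res_b}
    rows = [
        _ClassificationRow(g, da, db, classify_direction(g, idx_a, idx_b))
        for g, da, db in overlap.common_genes
    ]
    write_table(
        rows, outdir / "common_de.tsv",
        fields=["gene_id", "direction_a", "direction_b", "classification"],
    )
    classified = {r.gene_id: r.classification for r in rows}
    common_genes = [r.gene_id for r in rows]
    groups = []
    if common_genes:
        k = min(config.kmeans_k, len(common_genes))
        if k < config.kmeans_k:
            logger.warning("only %d common genes; reducing k to %d", len(common_genes), k)
        groups = kmeans_groups(
            matrix.subset(common_genes), k=k, seed=config.seed,
            n_restarts=config.kmeans_restarts,
        )
        write_table(
            [
                _GroupRow(g.group_id, g.correlation_label,
                          g.phosphate_correlation, len(g.member_genes), g.member_genes)
                for g in groups
            ],
            outdir / "groups.tsv",
        )
    else:
        logger.warning("no common DE genes; skipping clustering")
    _stage(
        report, "reciprocal", t0,
        overlap={
            "set_a_size": overlap.set_a_size, "set_b_size": overlap.set_b_size,
            "universe_size": overlap.universe_size, "overlap_size": overlap.overlap_size,
            "overlap_p": overlap.overlap_p, "overlap_log10_p": overlap.overlap_log10_p,
        },
        classification_counts=_counts(classified.values()),
        n_groups=len(groups),
        inverse_groups=sum(1 for g in groups if g.correlation_label == "inverse"),
    )

    # --- enrichment ---------------------------------------------------------
    t0 = time.perf_counter()
    universe = set(matrix.genes)
    enrichment_counts = {}
    for label in ("inverse", "positive"):
        subset = {g for g, c in classified.items() if c == label}
        if not subset:
            logger.warning("no %s-classified genes; skipping enrichment", label)
            enrichment_counts[label] = {"tested": 0, "passing": 0}
            continue
        results = enrich(
            subset, annotation, universe,
            min_pathway_genes=config.enrichment_min_genes,
            fe_threshold=config.enrichment_fe_threshold,
            alpha=config.enrichment_alpha,
        )
        write_table(results, outdir / f"enrichment_{label}.tsv")
        enrichment_counts[label] = {
            "tested": len(results),
            "passing": sum(r.passes_filter for r in results),
        }
    _stage(report, "enrichment", t0, subsets=enrichment_counts)

    # --- pathway concordance -------------------------------------------------
    t0 = time.perf_counter()
    tiers, conc = pathway_concordance(
        matrix, annotation, contrasts=config.contrasts, config=config.concordance
    )
    write_table(tiers, outdir / "enzyme_tiers.tsv")
    write_table(conc, outdir / "concordance.tsv")
    _stage(
        report, "concordance", t0,
        n_enzymes=len({t.ec_number for t in tiers}),
        n_tests=len(conc),
        significant={
            f"{c.pathway_id}:{c.contrast}": c.p_value for c in conc if c.p_value < 0.05
        },
    )

    # --- lipidomics ----------------------------------------------------------
    t0 = time.perf_counter()
    table = None
    if config.lipidome_sim is not None:
        lsim = dataclasses.replace(config.lipidome_sim, seed=config.seed + 1)
        table, ltruth = generate_lipidome(lsim)
        write_lipid_table(table, outdir / "lipids.tsv")
        if truth is None:
            truth = ltruth
        else:
            truth.class_folds = ltruth.class_folds
            truth.species_origins = ltruth.species_origins
    elif config.lipid_path is not None:
        design = matrix.samples
        table = load_lipid_table(config.lipid_path, design, config.cell_counts_path)
    if table is None:
        logger.warning("no lipid table configured; skipping lipidomic branch")
        report["stages"]["lipidomics"] = {"skipped": True}
    else:
        classes = class_levels(table, config.lipid_test)
        strata = origin_stratified_levels(table, config.lipid_test)
        totals, percent = fatty_acid_totals(table)
        _write_class_stats(classes, outdir / "class_stats.tsv")
        _write_stratum_stats(strata, outdir / "origin_stats.tsv")
        totals.to_csv(outdir / "fa_totals.tsv", sep="\t", float_format="%.9g")
        percent.to_csv(outdir / "fa_percent.tsv", sep="\t", float_format="%.9g")
        _stage(
            report, "lipidomics", t0,
            n_species=len(table.species),
            n_classes=len(classes),
            class_tiers={
                c.class_token: {
                    label: {"tier_2x": s.tier_2x, "tier_1p5x": s.tier_1p5x,
                            "fold_change": s.fold_change}
                    for label, s in c.stats.items()
                }
                for c in classes
            },
        )

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def recovery_metrics(
    classified: dict[str, str], truth: GroundTruth
) -> dict[str, float]:
    """Sensitivity and false-discovery of responder recovery.

    ``classified`` maps common-DE genes to ``inverse``/``positive``/
    ``discordant``; a planted responder counts as recovered when its
    class matches its planted label.
    """
    planted = {g: lab for g, lab in truth.gene_labels.items() if lab in ("inverse", "positive")}
    predicted = {g: c for g, c in classified.items() if c in ("inverse", "positive")}
    correct = sum(1 for g, c in predicted.items() if planted.get(g) == c)
    sensitivity = correct / len(planted) if planted else float("nan")
    fdr = (len(predicted) - correct) / len(predicted) if predicted else 0.0
    return {
        "n_planted": len(planted),
        "n_predicted": len(predicted),
        "n_correct": correct,
        "sensitivity": sensitivity,
        "false_discovery": fdr,
    }


def _stage(report: dict, name: str, t0: float, **stats) -> None:
    logger.info("stage %-24s %6.2f s", name, time.perf_counter() - t0)
    report["stages"][name] = stats  # timings stay out: report must be reproducible


def _counts(values) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return dict(sorted(out.items()))


def _config_echo(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return convert(config)


def _write_truth(truth: GroundTruth, path: Path) -> None:
    lines = ["gene_id\tlabel"]
    lines += [f"{g}\t{lab}" for g, lab in truth.gene_labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class _ClassStatRow:
    class_token: str
    contrast: str
    n_species: int
    fold_change: float
    p_value: float
    tier_2x: str
    tier_1p5x: str


@dataclass
class _StratumStatRow:
    class_token: str
    origin: str
    contrast: str
    n_species: int
    fold_change: float
    p_value: float
    tier_2x: str
    tier_1p5x: str


def _write_class_stats(classes, path: Path) -> None:
    rows = [
        _ClassStatRow(c.class_token, s.contrast, c.n_species,
                      s.fold_change, s.p_value, s.tier_2x, s.tier_1p5x)
        for c in classes
        for s in c.stats.values()
    ]
    write_table(rows, path)


def _write_stratum_stats(strata, path: Path) -> None:
    rows = [
        _StratumStatRow(c.class_token, c.origin, s.contrast, c.n_species,
                        s.fold_change, s.p_value, s.tier_2x, s.tier_1p5x)
        for c in strata
        for s in c.stats.values()
    ]
    write_table(rows, path)
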