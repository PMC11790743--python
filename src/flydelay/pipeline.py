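"""End-to-end orchestration: QC -> DE battery -> delay detection ->
enrichment -> machine-readable report.

A single :class:`PipelineConfig` drives the run.  All output tables are
TSV with a header, UTF-8, '.' decimals, and reals formatted with six
significant digits so that identical config + seed reproduces outputs byte
for byte.  The per-stage child seeds derive from the global seed by a
stage-name CRC, so stages are individually reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    ExpressionMatrix,
    GeneAnnotation,
    SampleDesign,
    read_annotation,
    read_counts,
    read_design,
    read_gene_sets,
    read_ontology,
)
from .de import DEResult, estimate_dispersion, normalize, run_battery, size_factors_median_of_ratios
from .delay import (
    build_profiles,
    calls_frame,
    detect_delayed,
    direction_concordance,
    lfc_correlation,
    mode_gap_cutoff,
)
from .enrich import cluster_terms, enrichment_frame, ora, similarity_matrix, x_enrichment
from .errors import ConfigError, StageError
from .qc import flag_outliers, pca_samples, remove_samples

log = logging.getLogger("flydelay")

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    counts: str | None = None
    design: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    ontology: str | None = None
    outdir: str = "flydelay_out"
    alpha_raw: float = 0.05
    alpha_adj: float = 0.1
    slope_cutoff: float = 0.05
    k_mad: float = 5.0
    k_clusters: int = 9
    universe: str = "intersect"
    normalize_scope: str = "joint"
    cutoff_mode: str = "fixed"
    alternative: str = "greater"
    min_count_filter: float = 0.0
    top_n_variable: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, alpha in (("alpha_raw", self.alpha_raw), ("alpha_adj", self.alpha_adj)):
            if not 0.0 <= alpha <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {alpha}")
        if self.slope_cutoff < 0:
            raise ConfigError("slope_cutoff must be >= 0")
        if self.k_mad <= 0 or self.k_clusters < 1:
            raise ConfigError("k_mad must be > 0 and k_clusters >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def child_seed(seed: int, stage: str) -> int:
    """Stage seed derived from the global seed by a stage-name CRC."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _write(df: pd.DataFrame, path: Path, index: bool = False, index_label=None) -> Path:
    df.to_csv(path, sep="\t", index=index, index_label=index_label, float_format=FLOAT_FORMAT)
    return path


def summarize_battery(
    results: dict[str, DEResult], alpha_raw: float = 0.05, alpha_adj: float = 0.1
) -> pd.DataFrame:
    """DEG counts per comparison at both thresholds, split by direction."""
    rows = []
    for name, res in results.items():
        for threshold, kwargs in (
            (f"p_raw<{alpha_raw:g}", {"alpha_raw": alpha_raw, "alpha_adj": None}),
            (f"p_adj<{alpha_adj:g}", {"alpha_raw": None, "alpha_adj": alpha_adj}),
        ):
            up = len(res.degs(direction="up", **kwargs))
            down = len(res.degs(direction="down", **kwargs))
            rows.append(
                {
                    "comparison": name,
                    "orientation": res.orientation,
                    "threshold": threshold,
                    "up": up,
                    "down": down,
                    "total": up + down,
                }
            )
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis and return the machine-readable report.

    Stage order: load -> QC/outlier removal -> size factors -> dispersions
    -> comparison battery -> delay detection -> enrichment (when inputs are
    provided) -> report.  Any stage failure raises :class:`StageError`
    naming the stage; outputs written so far stay on disk next to a
    ``failed`` marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # outdir is omitted from the recorded parameters: the report lives inside
    # it, and identical analyses into different directories should produce
    # byte-identical reports
    params = {k: v for k, v in asdict(config).items() if k != "outdir"}
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": params,
        "stages": {},
        "outputs": [],
    }
    try:
        return _run_stages(config, outdir, report)
    except Exception as exc:
        (outdir / "failed").write_text(str(exc), encoding="utf-8")
        if isinstance(exc, StageError):
            raise
        raise StageError("unknown", str(exc)) from exc


def _run_stages(config: PipelineConfig, outdir: Path, report: dict) -> dict:
    outputs: list[Path] = []

    # --- load -------------------------------------------------------------
    stage = "load"
    try:
        if config.counts is None or config.design is None:
            raise ConfigError("counts and design paths are required")
        matrix = read_counts(config.counts)
        design = read_design(config.design)
        design.check_against(matrix)
        matrix = matrix.subset_samples(design.sample_ids)
        annotation = read_annotation(config.annotation) if config.annotation else None
        gene_sets = read_gene_sets(config.gene_sets) if config.gene_sets else None
        dag = read_ontology(config.ontology) if config.ontology else None
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    log.info("loaded %d genes x %d samples", matrix.n_genes, matrix.n_samples)
    report["stages"][stage] = {"n_genes": matrix.n_genes, "n_samples": matrix.n_samples}

    if config.min_count_filter > 0:
        keep = matrix.counts.mean(axis=1) >= config.min_count_filter
        matrix = ExpressionMatrix(matrix.counts[keep])
        report["stages"][stage]["genes_after_filter"] = matrix.n_genes

    # --- QC ---------------------------------------------------------------
    stage = "qc"
    try:
        factors0 = size_factors_median_of_ratios(matrix)
        pca = pca_samples(matrix, factors0, n_components=2, top_n_variable=config.top_n_variable)
        flags = flag_outliers(pca, design, k=config.k_mad)
        flagged = sorted(flags.loc[flags["flagged"], "sample"]) if len(flags) else []
        outputs.append(_write(pca.scores.reset_index(), outdir / "qc_scores.tsv"))
        outputs.append(
            _write(
                pd.DataFrame(
                    {
                        "component": [f"PC{i + 1}" for i in range(len(pca.variance_fraction))],
                        "variance_fraction": pca.variance_fraction,
                    }
                ),
                outdir / "qc_variance.tsv",
            )
        )
        outputs.append(_write(flags, outdir / "qc_outlier_flags.tsv"))
        if flagged:
            matrix, design = remove_samples(matrix, design, flagged)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    log.info("QC removed %d outlier sample(s): %s", len(flagged), flagged)
    report["stages"][stage] = {
        "variance_fraction": [round(float(v), 6) for v in pca.variance_fraction],
        "samples_removed": flagged,
        "samples_retained": matrix.n_samples,
    }

    # --- normalization + dispersion ---------------------------------------
    stage = "normalize"
    try:
        factors = size_factors_median_of_ratios(matrix)
        normalized = normalize(matrix, factors)
        dispersions = estimate_dispersion(matrix, design, factors)
        outputs.append(
            _write(
                factors.rename_axis("sample").reset_index(), outdir / "size_factors.tsv"
            )
        )
        outputs.append(
            _write(
                dispersions.rename_axis("gene_id").reset_index(), outdir / "dispersions.tsv"
            )
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    report["stages"][stage] = {
        "size_factor_range": [float(factors.min()), float(factors.max())],
        "median_dispersion": float(dispersions.median()),
    }

    # --- DE battery --------------------------------------------------------
    stage = "de"
    try:
        results = run_battery(matrix, design, factors, dispersions)
        for name, res in results.items():
            outputs.append(
                _write(res.table.reset_index(), outdir / f"de_{name}.tsv")
            )
        summary = summarize_battery(results, config.alpha_raw, config.alpha_adj)
        outputs.append(_write(summary, outdir / "de_summary.tsv"))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    deg_counts = {
        row["comparison"] + "@" + row["threshold"]: int(row["total"])
        for _, row in summary.iterrows()
    }
    report["stages"][stage] = {"comparisons": sorted(results), "deg_counts": deg_counts}

    # --- delay detection ---------------------------------------------------
    stage = "delay"
    try:
        ages = design.ages
        f_early = f"F{ages[0]}v{ages[1]}"
        m_late = f"M{ages[1]}v{ages[2]}"
        cutoff = config.slope_cutoff
        profiles = build_profiles(
            normalized.loc[matrix.gene_ids, design.sample_ids],
            design,
            cutoff=cutoff,
            normalize_scope=config.normalize_scope,
        )
        if config.cutoff_mode == "mode-gap":
            cutoff = mode_gap_cutoff(profiles, fallback=config.slope_cutoff)
            profiles = build_profiles(
                normalized.loc[matrix.gene_ids, design.sample_ids],
                design,
                cutoff=cutoff,
                normalize_scope=config.normalize_scope,
            )
        elif config.cutoff_mode != "fixed":
            raise ConfigError(f"unknown cutoff_mode {config.cutoff_mode!r}")
        deg_f = results[f_early].degs(alpha_raw=config.alpha_raw, alpha_adj=None)
        deg_m = results[m_late].degs(alpha_raw=config.alpha_raw, alpha_adj=None)
        calls = detect_delayed(profiles, deg_f, deg_m, universe=config.universe)
        cframe = calls_frame(calls)
        outputs.append(_write(cframe, outdir / "delay_calls.tsv"))
        slope_rows = []
        for gene, prof in profiles.items():
            for sex in ("F", "M"):
                for i in range(2):
                    slope_rows.append(
                        {
                            "gene_id": gene,
                            "sex": sex,
                            "interval": f"{ages[i]}-{ages[i + 1]}",
                            "raw_slope": prof.raw_slopes[sex][i],
                            "corrected_slope": prof.corrected_slopes[sex][i],
                            "pattern": prof.patterns[sex][i],
                        }
                    )
        outputs.append(_write(pd.DataFrame(slope_rows), outdir / "delay_slopes.tsv"))
        candidates = sorted(deg_f & deg_m)
        corr = None
        if len(candidates) >= 3:
            corr = lfc_correlation(results[f_early], results[m_late], candidates)
            concord = direction_concordance(results[f_early], results[m_late], candidates)
            outputs.append(
                _write(
                    pd.DataFrame(
                        [
                            {
                                "comparison_a": f_early,
                                "comparison_b": m_late,
                                "r": corr.r,
                                "p_value": corr.p_value,
                                "n": corr.n,
                                **concord,
                            }
                        ]
                    ),
                    outdir / "delay_correlation.tsv",
                )
            )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    up_calls = [c.gene_id for c in calls if c.called and c.direction == "up"]
    down_calls = [c.gene_id for c in calls if c.called and c.direction == "down"]
    report["stages"][stage] = {
        "cutoff": cutoff,
        "candidate_universe": len(calls),
        "delayed_up": len(up_calls),
        "delayed_down": len(down_calls),
        "lfc_correlation_r": None if corr is None else round(corr.r, 6),
    }

    # --- enrichment --------------------------------------------------------
    stage = "enrichment"
    try:
        enrichment_report = {}
        if annotation is not None:
            background = annotation.background() & set(matrix.gene_ids)
            xrows = []
            for name, res in sorted(results.items()):
                for direction in ("up", "down"):
                    degs = res.degs(alpha_raw=config.alpha_raw, alpha_adj=None, direction=direction)
                    er = x_enrichment(degs, annotation, background, config.alternative)
                    xrows.append(
                        {
                            "comparison": name,
                            "direction": direction,
                            **{k: v for k, v in er.__dict__.items() if k != "p_adj"},
                        }
                    )
            outputs.append(_write(pd.DataFrame(xrows), outdir / "x_enrichment.tsv"))
            enrichment_report["x_tests"] = len(xrows)
            enrichment_report["x_significant"] = int(
                sum(1 for r in xrows if r["p_raw"] < 0.05)
            )
        if gene_sets is not None and annotation is not None:
            for label, genes in (("delayed_up", up_calls), ("delayed_down", down_calls)):
                if not genes:
                    continue
                res_list = ora(set(genes), gene_sets, background, config.alternative)
                outputs.append(
                    _write(enrichment_frame(res_list), outdir / f"ora_{label}.tsv")
                )
                enrichment_report[f"ora_{label}_hits"] = int(
                    sum(1 for r in res_list if r.p_adj < 0.05)
                )
                if dag is not None:
                    sig_terms = [r.set_id for r in res_list if r.p_raw < 0.05 and r.set_id in dag]
                    if len(sig_terms) >= max(2, config.k_clusters):
                        sim = similarity_matrix(dag, sig_terms)
                        clusters = cluster_terms(sim, k=config.k_clusters)
                        outputs.append(
                            _write(
                                clusters.rename_axis("term").reset_index(),
                                outdir / f"term_clusters_{label}.tsv",
                            )
                        )
                        enrichment_report[f"term_clusters_{label}"] = int(clusters.nunique())
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    report["stages"][stage] = enrichment_report or {"skipped": True}

    # --- report ------------------------------------------------------------
    report["outputs"] = sorted(str(p.relative_to(outdir)) for p in outputs)
    report_path = outdir / "report.json"
    report_path.write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8"
    )
    marker = outdir / "failed"
    if marker.exists():
        marker.unlink()
    return report
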