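"""End-to-end orchestration: detect -> localize -> enrich -> express ->
disease -> network over a flat TOML config, with deterministic per-stage
seeds derived from one master seed."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import (annotation_enrichment, disease_association, network_analysis,
               prld_detection, prld_localization, tissue_expression)
from ._validation import ValidationError, check

logger = logging.getLogger("prionscape.pipeline")

STAGES = ["detect", "localize", "enrich", "express", "disease", "network"]


@dataclass
class PipelineConfig:
    fasta: Path
    annotations: Path | None
    expression: Path | None
    disease: Path | None
    edges: Path | None
    mapping: Path | None
    outdir: Path
    cutoff: float = prld_detection.DEFAULT_CUTOFF
    n_fraction: float = 0.25
    c_fraction: float = 0.25
    k_min: int = 3
    k_max: int = 10
    n_disease_samples: int = 100
    n_network_samples: int = 1000
    bins: int = 20
    seed: int = 0
    exclude_evidence: tuple[str, ...] = ("IEA",)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        base = Path(path).parent

        def _path(key, required=False):
            if key not in raw:
                check(not required, f"config: missing required key '{key}'")
                return None
            p = Path(raw[key])
            return p if p.is_absolute() else base / p

        cfg = cls(
            fasta=_path("fasta", required=True),
            annotations=_path("annotations"),
            expression=_path("expression"),
            disease=_path("disease"),
            edges=_path("edges"),
            mapping=_path("mapping"),
            outdir=_path("outdir", required=True),
            cutoff=float(raw.get("cutoff", prld_detection.DEFAULT_CUTOFF)),
            n_fraction=float(raw.get("n_fraction", 0.25)),
            c_fraction=float(raw.get("c_fraction", 0.25)),
            k_min=int(raw.get("k_min", 3)),
            k_max=int(raw.get("k_max", 10)),
            n_disease_samples=int(raw.get("n_disease_samples", 100)),
            n_network_samples=int(raw.get("n_network_samples", 1000)),
            bins=int(raw.get("bins", 20)),
            seed=int(raw.get("seed", 0)),
            exclude_evidence=tuple(raw.get("exclude_evidence", ["IEA"])),
        )
        for key, p in (("fasta", cfg.fasta),):
            if p is not None and not p.exists():
                raise ValidationError(f"config: {key} path {p} does not exist")
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Fixed counter scheme: seed for a stage is independent of
        execution order."""
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage, writing each artifact under
    ``config.outdir`` and returning the consolidated report (also written
    as ``report.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    def _stage(name):
        logger.info("stage %s: starting", name)
        return report["stages"].setdefault(name, {})

    # --- detect ---------------------------------------------------------
    try:
        stage = _stage("detect")
        records = prld_detection.read_fasta(config.fasta)
        sequences = {p: s for p, _, s in records}
        gene_of = {p: g for p, g, _ in records}
        calls = prld_detection.call_prionlike(
            list(sequences.items()), cutoff=config.cutoff
        )
        prld_detection.write_calls_tsv(calls, out / "calls.tsv")
        prld_detection.write_calls_json(calls, out / "calls.json")
        candidates = [c for c in calls if c.passes_composition]
        positives = [c for c in calls if c.positive]
        stage.update(
            n_proteins=len(records),
            n_candidates=len(candidates),
            n_positive=len(positives),
        )
        logger.info("stage detect: %d proteins -> %d candidates -> %d positives",
                    len(records), len(candidates), len(positives))
    except Exception as exc:
        _write_report(report, out)
        raise ValidationError(f"stage detect failed: {exc}") from exc

    set_proteins = [c.protein_id for c in positives]
    set_genes = sorted({gene_of[p] for p in set_proteins})
    all_genes = sorted({g for g in gene_of.values()})

    # --- localize -------------------------------------------------------
    try:
        stage = _stage("localize")
        scheme = prld_localization.SegmentScheme(config.n_fraction,
                                                config.c_fraction)
        lengths = {p: len(s) for p, s in sequences.items()}
        loc = prld_localization.localize_calls(calls, lengths, scheme)
        prld_localization.write_localization_tsv(loc, out / "localization.tsv")
        prld_localization.write_localization_summary(
            loc, out / "localization_summary.json"
        )
        starts, ends = prld_localization.position_histogram(
            positives, lengths, n_bins=config.bins
        )
        pd.DataFrame({
            "bin": range(config.bins), "starts": starts, "ends": ends,
        }).to_csv(out / "position_histogram.tsv", sep="\t", index=False)
        stage.update(
            n_terminal=loc.n_terminal, internal=loc.internal,
            c_terminal=loc.c_terminal,
            c_to_n_ratio=_nan_none(loc.c_to_n_ratio),
            z=_nan_none(loc.z_statistic), p=_nan_none(loc.p_value),
        )
        logger.info("stage localize: N=%d internal=%d C=%d",
                    loc.n_terminal, loc.internal, loc.c_terminal)
    except Exception as exc:
        _write_report(report, out)
        raise ValidationError(f"stage localize failed: {exc}") from exc

    # --- enrich ---------------------------------------------------------
    if config.annotations is not None and set_proteins:
        try:
            stage = _stage("enrich")
            table = annotation_enrichment.load_annotations(config.annotations)
            table = annotation_enrichment.filter_annotations(
                table, excluded_evidence=config.exclude_evidence
            )
            top_terms = {}
            for namespace in sorted(table["namespace"].unique()):
                rows = annotation_enrichment.term_enrichment(
                    set_proteins, list(sequences), table, namespace
                )
                annotation_enrichment.write_enrichment_tsv(
                    rows, out / f"enrichment_{namespace}.tsv"
                )
                top_terms[namespace] = [
                    {"term_id": r.term_id, "adjusted_p": r.adjusted_p,
                     "direction": r.direction}
                    for r in rows[:5]
                ]
            stage.update(n_rows=len(table), top_terms=top_terms)
            logger.info("stage enrich: %d annotation rows after filtering",
                        len(table))
        except Exception as exc:
            _write_report(report, out)
            raise ValidationError(f"stage enrich failed: {exc}") from exc

    # --- express --------------------------------------------------------
    if config.expression is not None and len(set_genes) >= config.k_min + 1:
        try:
            stage = _stage("express")
            expr = tissue_expression.load_expression(config.expression)
            profile = tissue_expression.set_tissue_profile(set_genes, expr)
            profile.rename("mean_expression").to_csv(
                out / "tissue_profile.tsv", sep="\t", float_format="%.6f"
            )
            vectors = tissue_expression.deviation_vectors(set_genes, expr, expr)
            clusters = tissue_expression.cluster_genes(
                vectors, k_min=config.k_min, k_max=config.k_max,
                seed=config.stage_seed("express"),
            )
            tissue_expression.write_clusters_tsv(clusters, out / "clusters.tsv")
            tissue_expression.write_silhouette_tsv(
                clusters, out / "silhouette.tsv"
            )
            stage.update(chosen_k=clusters.chosen_k,
                         silhouette_by_k=clusters.silhouette_by_k)
            logger.info("stage express: chose k=%d", clusters.chosen_k)
        except Exception as exc:
            _write_report(report, out)
            raise ValidationError(f"stage express failed: {exc}") from exc

    # --- disease --------------------------------------------------------
    if config.disease is not None and set_genes:
        try:
            stage = _stage("disease")
            table = disease_association.load_disease_table(config.disease)
            sources = (sorted(table["source"].unique())
                       if "source" in table.columns else [None])
            for source in sources:
                sub = (table[table["source"] == source]
                       if source is not None else table)
                result = disease_association.disease_resampling(
                    set_genes, all_genes, sub,
                    n_samples=config.n_disease_samples,
                    seed=config.stage_seed("disease"),
                )
                key = source or "all"
                stage[key] = {
                    "observed": result.observed,
                    "null_mean": result.null_mean,
                    "z": _nan_none(result.z),
                    "empirical_p": result.empirical_p,
                    "above_95th": bool(result.above_95th),
                    "ratio": _nan_none(disease_association.enrichment_ratio(
                        set_genes, all_genes, sub)),
                }
                with open(out / f"disease_{key}.json", "w") as fh:
                    json.dump(_jsonify(result.to_dict()), fh, indent=1)
                    fh.write("\n")
            logger.info("stage disease: sources=%s", [s or "all" for s in sources])
        except Exception as exc:
            _write_report(report, out)
            raise ValidationError(f"stage disease failed: {exc}") from exc

    # --- network --------------------------------------------------------
    if config.edges is not None and len(set_genes) >= 2:
        try:
            stage = _stage("network")
            graph = network_analysis.load_edge_list(config.edges)
            net = network_analysis.analyze_set(
                graph, set_genes, n_samples=config.n_network_samples,
                seed=config.stage_seed("network"),
            )
            network_analysis.write_stats_json(net, out / "network_stats.json")
            pd.DataFrame({
                name: pd.Series(res.null_samples)
                for name, res in net.resampling.items()
            }).to_csv(out / "network_null.tsv", sep="\t", index=False,
                      float_format="%.6f")
            stage.update(
                n_in_graph=net.n_in_graph,
                mean_degree=net.mean_degree,
                intra_edges=net.intra_edges,
                lcc_size=net.lcc_size,
                msd=_nan_none(net.msd),
                z={k: _nan_none(v.z) for k, v in net.resampling.items()},
            )
            logger.info("stage network: lcc=%d msd=%s", net.lcc_size, net.msd)
        except Exception as exc:
            _write_report(report, out)
            raise ValidationError(f"stage network failed: {exc}") from exc

    _write_report(report, out)
    return report


def _nan_none(x):
    if isinstance(x, float) and (np.isnan(x) or np.isinf(x)):
        return None
    return x


def _jsonify(obj):
    """Recursively replace NaN/inf with null and numpy scalars with Python."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return _nan_none(float(obj))
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonify(report), fh, indent=1, sort_keys=True)
        fh.write("\n")
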