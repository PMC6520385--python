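"""End-to-end pipeline: simulate -> normalize/filter -> rank -> screen -> methylation.

Each stage writes its artifacts under the output directory and contributes a
section to a machine-readable run report (parameters, seed, per-stage
counts, package version).  Deterministic stages reproduce bit-identically
from the report's parameters.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as psio
from .errors import ConfigError, PropensityScreenError
from .filtering import filter_probes, global_scale
from .methylation import (
    annotation_filter,
    detection_filter,
    differential_methylation,
    region_distribution,
    summarize_fractions,
)
from .ranking import build_ranking, interlineage_rank_correlation
from .screen import inverse_correlation_intersection, screen_markers, top_k_table
from .synthetic import SimulationConfig, simulate_inputs

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs: sources, thresholds, toggles, seed."""

    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # stage toggles
    run_filter: bool = True
    run_rank: bool = True
    run_screen: bool = True
    run_methylation: bool = True
    # normalization / filter thresholds
    normalize: bool = True
    target_intensity: float = 500.0
    trim: float = 0.02
    min_present: int = 4
    alpha: float = 0.05
    min_fold: float = 5.0
    # screen
    top_k: int = 5
    # methylation thresholds
    detection_threshold: float = 0.01
    q_threshold: float = 0.05
    lfc_threshold: float = 0.6
    ttest: str = "student"
    # input paths, used when simulate is false
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha", "q_threshold", "detection_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.run_screen and not (self.run_filter and self.run_rank):
            raise ConfigError("screen stage requires filter and rank stages")
        if not self.simulate:
            needed = ["expression_intensity", "expression_calls"]
            if self.run_rank:
                needed += ["ct_table", "panels"]
            if self.run_methylation:
                needed += ["beta", "detection_p", "manifest"]
            missing = [k for k in needed if k not in self.inputs]
            if missing:
                raise ConfigError(f"simulate=false but input paths missing: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        try:
            sim = SimulationConfig(**sim_raw)
        except TypeError as exc:
            raise ConfigError(f"bad simulation config: {exc}") from exc
        try:
            cfg = cls(simulation=sim, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config: {exc}") from exc
        if "seed" in raw:
            cfg.simulation = dataclasses.replace(sim, seed=raw["seed"])
        return cfg


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the configured stages; return the run report (also written).

    A stage failure aborts the run with the stage name attached; artifacts
    of completed stages are left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("simulation", "inputs")
        },
        "stages": {},
    }
    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            sim = simulate_inputs(config.simulation)
            expression, gene_map = sim.expression, sim.gene_map
            ct_table, panels, methylation = sim.ct_table, sim.panels, sim.methylation
            psio.write_expression(
                expression, out / "expression_intensity.tsv", out / "expression_calls.tsv"
            )
            psio.write_ct_table(ct_table, out / "ct_table.tsv")
            psio.write_panels(panels, out / "panels.csv")
            psio.write_gene_map(gene_map, out / "gene_map.tsv")
            psio.write_methylation(
                methylation, out / "beta.tsv", out / "detection_p.tsv", out / "manifest.csv"
            )
            report["stages"]["simulate"] = {
                "n_probes": expression.n_probes,
                "n_lines": expression.n_lines,
                "n_replicates": expression.n_replicates,
                "n_meth_probes": methylation.n_probes,
                "beta_clip_count": methylation.clip_count,
                "simulation": dataclasses.asdict(config.simulation)
                | {"planted_markers": [m.probe_id for m in config.simulation.planted_markers]},
            }
        else:
            stage = "load"
            inp = config.inputs
            expression = psio.read_expression(
                inp["expression_intensity"], inp["expression_calls"]
            )
            gene_map = psio.read_gene_map(inp["gene_map"]) if "gene_map" in inp else {}
            ct_table = panels = methylation = None
            if config.run_rank:
                ct_table = psio.read_ct_table(
                    inp["ct_table"],
                    housekeeping=inp.get("housekeeping", "GAPDH"),
                    reference_line=inp.get("reference_line", "201B7"),
                )
                panels = psio.read_panels(inp["panels"])
            if config.run_methylation:
                methylation = psio.read_methylation(
                    inp["beta"], inp["detection_p"], inp["manifest"]
                )

        survivors = None
        if config.run_filter:
            stage = "filter"
            if config.normalize:
                expression = global_scale(
                    expression, target=config.target_intensity, trim=config.trim
                )
            filt = filter_probes(
                expression,
                min_present=config.min_present,
                alpha=config.alpha,
                min_ratio=config.min_fold,
            )
            survivors = filt.final
            psio.write_json(filt.to_dict(), out / "filter_report.json")
            (out / "surviving_probes.tsv").write_text(
                "probe_id\n" + "".join(p + "\n" for p in survivors)
            )
            report["stages"]["filter"] = filt.to_dict()

        ranking = None
        if config.run_rank:
            stage = "rank"
            ranking = build_ranking(ct_table, panels)
            psio.write_ranking(ranking, out / "propensity_ranking.tsv")
            pair = interlineage_rank_correlation(ranking)
            pair.to_csv(out / "interlineage_correlation.tsv", sep="\t", index=False)
            report["stages"]["rank"] = {
                "explained_variance": ranking.explained_variance,
                "interlineage": pair.to_dict(orient="records"),
            }

        if config.run_screen:
            stage = "screen"
            assert ranking is not None and survivors is not None
            result = screen_markers(
                expression,
                survivors,
                ranking,
                alpha=config.alpha,
                probe_to_gene=gene_map,
            )
            result.table.to_csv(out / "marker_screen.tsv", sep="\t", index=False)
            inter = inverse_correlation_intersection(result)
            psio.write_json(
                {k: sorted(v) for k, v in inter.items()}, out / "intersections.json"
            )
            topk = top_k_table(result, k=config.top_k)
            topk.to_csv(out / "top_candidates.tsv", sep="\t", index=False)
            report["stages"]["screen"] = {
                "critical_value": result.null.critical_value,
                "candidates": result.candidate_counts().to_dict(orient="records"),
                "intersections": {k: sorted(v) for k, v in inter.items()},
                "n_unannotated_probes": result.n_unannotated,
            }

        if config.run_methylation:
            stage = "methylation"
            assert methylation is not None
            detected = detection_filter(methylation, threshold=config.detection_threshold)
            annotated, n_missing = annotation_filter(detected, methylation.manifest)
            dm = differential_methylation(
                methylation,
                annotated,
                q_threshold=config.q_threshold,
                lfc_threshold=config.lfc_threshold,
                ttest=config.ttest,
            )
            dm.table.to_csv(out / "differential_methylation.tsv", sep="\t")
            summary = summarize_fractions(dm)
            counts = dm.class_counts()
            meth_report = {
                "n_total": methylation.n_probes,
                "n_detected": len(detected),
                "n_annotated": len(annotated),
                "n_missing_from_manifest": n_missing,
                "class_counts": counts,
                "summary": summary,
            }
            if counts["hyper"]:
                meth_report["hyper_region_pct"] = region_distribution(
                    dm, methylation.manifest, cls="hyper"
                ).to_dict()
            psio.write_json(meth_report, out / "methylation_summary.json")
            report["stages"]["methylation"] = meth_report

    except PropensityScreenError as exc:
        exc.args = (f"stage {stage!r} failed: {exc}",)
        psio.write_json(report, out / "run_report.json")  # partial outputs retained
        raise

    psio.write_json(report, out / "run_report.json")
    return report
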