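"""End-to-end orchestration: preprocess -> detect -> profiles -> network -> benchmark.

A single master seed deterministically derives one child seed per
stochastic stage (imputation, detection bootstrap, correlation bootstrap,
K-means), so re-running with the same configuration is bit-identical and
individual stages can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corecruit, detect, io as cio, netstats, preprocess, synth
from .model import (IntensityTable, NormalizedTable, ReferenceInteractions,
                    SampleDesign)

logger = logging.getLogger(__name__)


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Per-stage child seeds derived deterministically from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(4)
    names = ("impute", "detect", "correlation", "kmeans")
    return {n: int(s % (2 ** 31)) for n, s in zip(names, state)}


@dataclass
class PipelineConfig:
    """Paths, thresholds and the master seed for one full analysis."""

    intensities: str | None = None
    design: str | None = None
    reference: str | None = None
    outdir: str = "corecnet_out"
    spike_ids: tuple[str, ...] = ()
    percentile: float = 5.0
    p_threshold: float = 0.001
    fold_threshold: float = 2.0
    n_boot_detect: int = 200
    detect_frac: float = 0.9
    p_adjust: str = "none"
    profile_points: str = "per-run"
    n_boot_corr: int = 1000
    alpha: float = 5e-5
    hc_r: float = 0.8
    kmeans_k: int | None = None
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "spike_ids" in raw and raw["spike_ids"] is not None:
            raw["spike_ids"] = tuple(raw["spike_ids"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    normalized: NormalizedTable
    detection: detect.DetectionResult
    profiles: corecruit.RecruitmentProfiles | None
    matrix: corecruit.CorrelationMatrix | None
    clusters: pd.Series | None
    network: object | None
    report: netstats.BenchmarkReport | None
    manifest: dict


def _load_inputs(config: PipelineConfig
                 ) -> tuple[IntensityTable, SampleDesign,
                            ReferenceInteractions | None]:
    if config.intensities is None or config.design is None:
        raise ValueError("pipeline needs intensities and design paths")
    table = cio.read_protein_groups(config.intensities)
    design = cio.read_design(config.design)
    reference = (cio.read_reference(config.reference)
                 if config.reference else None)
    return table, design, reference


def run_all(config: PipelineConfig,
            table: IntensityTable | None = None,
            design: SampleDesign | None = None,
            reference: ReferenceInteractions | None = None,
            write: bool = True) -> PipelineResult:
    """Run every stage and (optionally) write the artifact bundle.

    Inputs may be passed in memory; otherwise they are read from the
    configured paths. Outputs: detection TSV, profile TSV, correlation
    matrix TSV, cluster TSV, GraphML + edge TSV, benchmark JSON, and a
    manifest of every parameter and derived seed actually applied.
    """
    if table is None or design is None:
        table, design, reference = _load_inputs(config)
    design.check_matches(table)
    seeds = derive_seeds(config.seed)
    manifest: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(config).items()},
                      "seeds": seeds, "stages": {}}

    stage = "preprocess"
    try:
        norm = preprocess.preprocess(table, design, seed=seeds["impute"],
                                     spike_ids=list(config.spike_ids) or None,
                                     percentile=config.percentile)
        manifest["stages"][stage] = {
            "n_proteins": int(norm.log_data.shape[0]),
            "n_runs": int(norm.log_data.shape[1]),
            "n_imputed": int(norm.imputed.to_numpy().sum()),
            "imputation": norm.audit.get("imputation", {}),
        }

        stage = "detect"
        dconf = detect.DetectionConfig(
            p_threshold=config.p_threshold,
            fold_threshold=config.fold_threshold,
            n_boot=config.n_boot_detect, detect_frac=config.detect_frac,
            seed=seeds["detect"], p_adjust=config.p_adjust)
        result = detect.bootstrap_detection(norm, design, dconf)
        interactors = result.interactors()
        manifest["stages"][stage] = {
            "p_threshold": dconf.p_threshold,
            "fold_threshold": dconf.fold_threshold,
            "n_boot": dconf.n_boot, "detect_frac": dconf.detect_frac,
            "n_specific_interactors": len(interactors),
        }

        profiles = matrix = clusters = network = report = None
        if len(interactors) >= 2:
            stage = "profiles"
            bnorm = corecruit.bait_normalize(norm, design)
            profiles = corecruit.build_profiles(
                bnorm, design, interactors, points=config.profile_points)

            stage = "network"
            matrix = corecruit.correlation_matrix(
                profiles, n_boot=config.n_boot_corr,
                seed=seeds["correlation"])
            network = corecruit.build_network(matrix, alpha=config.alpha,
                                              hc_r=config.hc_r)
            manifest["stages"][stage] = {
                "alpha": config.alpha, "p_star": network.p_star,
                "hc_r": config.hc_r, "n_nodes": len(network.nodes),
                "n_edges": len(network.edges),
                "n_boot": config.n_boot_corr,
            }
            if config.kmeans_k and matrix.n >= config.kmeans_k >= 2:
                stage = "clusters"
                clusters = corecruit.kmeans_partition(
                    matrix, config.kmeans_k, seed=seeds["kmeans"])

            if reference is not None:
                stage = "benchmark"
                report = netstats.benchmark(network, reference)
                manifest["stages"][stage] = report.to_dict()
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    out = PipelineResult(normalized=norm, detection=result,
                         profiles=profiles, matrix=matrix, clusters=clusters,
                         network=network, report=report, manifest=manifest)
    if write:
        _write_bundle(config, out)
    return out


def _write_bundle(config: PipelineConfig, result: PipelineResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.detection.to_frame().to_csv(outdir / "detection.tsv", sep="\t",
                                       index=False, float_format="%.10g")
    if result.profiles is not None:
        flat = result.profiles.tech_mean.copy()
        flat.to_csv(outdir / "profiles.tsv", sep="\t", float_format="%.10g")
    if result.matrix is not None:
        cio.write_matrix(result.matrix.R, outdir / "correlation_R.tsv")
        cio.write_matrix(result.matrix.P, outdir / "correlation_P.tsv")
    if result.clusters is not None:
        result.clusters.rename_axis("protein").to_frame().to_csv(
            outdir / "clusters.tsv", sep="\t")
    if result.network is not None:
        cio.write_network(result.network, outdir / "network.graphml")
        cio.write_edge_table(result.network, outdir / "edges.tsv")
    if result.report is not None:
        with open(outdir / "benchmark.json", "w") as fh:
            json.dump(result.report.to_dict(), fh, indent=2, sort_keys=True)
        (outdir / "benchmark.txt").write_text(result.report.summary() + "\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)


def simulate(config: synth.SimulationConfig, outdir: str | Path,
             reference_recall: float = 1.0) -> dict[str, Path]:
    """Write a synthetic experiment's fixture files (delegates to synth)."""
    return synth.write_fixtures(config, outdir,
                                reference_recall=reference_recall)
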