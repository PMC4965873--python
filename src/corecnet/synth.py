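"""Synthetic time-resolved AP-MS experiments with known ground truth.

The generator emulates a pulldown time course: a tagged bait purified from
stimulated cells at several time points, with matched wild-type control
pulldowns, technical and biological replicates, log-normal intensity
noise, planted specific interactors whose recruitment follows module-wise
kinetic profiles, non-specific contaminant background, and
intensity-dependent missingness.

Intensity model (log10 scale). Every protein ``p`` has a baseline
abundance ``b_p`` drawn once from a normal distribution; contaminants show
this baseline in both backgrounds. A planted specific prey in a bait run
at time ``t`` has expectation ``b_p + log10(fold * profile_p(t))`` plus a
module-level recruitment fluctuation shared by all members of its module
within a (biological replicate, time) stratum — complex members are
captured stoichiometrically, so their recruitment co-fluctuates, and this
shared term is the planted co-recruitment signal. Measurement noise
decomposes into a run-level component common to all proteins of a run
(sample-loading variation, which the normalization stages are designed to
remove) and an independent protein-level residual; ``noise_sd_log`` is the
total marginal SD of the two. Cells below the detection floor, plus a
uniform Bernoulli draw, are set missing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .model import BAIT, CONTROL, IntensityTable, ReferenceInteractions, SampleDesign

#: Named kinetic presets over the five stimulation times (max = 1).
PROFILE_SHAPES: dict[str, tuple[float, ...]] = {
    # chosen to be mutually near-orthogonal so that module membership and
    # correlation structure coincide (max pairwise |r| = 0.40)
    "early-peak": (0.05, 1.0, 0.31, 0.18, 0.09),
    "late-peak": (0.05, 0.11, 0.13, 0.44, 1.0),
    "sustained": (0.08, 0.69, 1.0, 1.0, 0.84),
    "biphasic": (0.62, 1.0, 0.09, 0.18, 0.92),
    "constitutive": (1.0, 1.0, 1.0, 1.0, 1.0),
}

DEFAULT_TIMES = (0.0, 30.0, 120.0, 300.0, 600.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise model for one simulated bait experiment.

    Defaults mirror a CBL-like design: 5 stimulation conditions
    (unstimulated plus 30/120/300/600 s), 3 biological x 3 technical
    replicates per condition and background, 200 contaminant proteins and
    40 planted preys in four kinetic modules at eightfold peak enrichment.
    """

    bait_name: str = "BAIT1"
    times: tuple[float, ...] = DEFAULT_TIMES
    n_bio: int = 3
    n_tech: int = 3
    n_background_proteins: int = 200
    n_specific: int = 40
    modules: tuple[tuple[str, int, str], ...] = (
        ("M1", 10, "early-peak"),
        ("M2", 10, "late-peak"),
        ("M3", 10, "sustained"),
        ("M4", 10, "biphasic"),
    )
    enrichment_fold: float = 8.0
    #: total marginal SD of log10 intensity noise per cell
    noise_sd_log: float = 0.15
    #: independent per-protein component of ``noise_sd_log`` (None: 8/15 of it)
    protein_noise_sd_log: float | None = None
    #: SD of the recruitment fluctuation shared within (module, bio rep, time)
    module_kinetic_sd_log: float = 0.25
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 0.6
    bait_log_intensity: float = 9.5
    missing_rate: float = 0.02
    detection_floor: float = 10 ** 5.5
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_bio", "n_tech", "n_specific"):
            if getattr(self, name) < (0 if name == "n_specific" else 1):
                raise ValueError(f"{name} must be >= 1")
        if self.n_background_proteins < 1:
            raise ValueError("n_background_proteins must be >= 1")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.n_specific > 0 and self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1 for planted preys")
        if self.noise_sd_log < 0 or self.module_kinetic_sd_log < 0:
            raise ValueError("noise SDs must be non-negative")
        member_total = sum(m[1] for m in self.modules)
        if member_total > self.n_specific:
            raise ValueError(
                f"module member counts ({member_total}) exceed n_specific "
                f"({self.n_specific})")
        for _, count, shape in self.modules:
            if count < 1:
                raise ValueError("module member_count must be >= 1")
            if shape not in PROFILE_SHAPES:
                raise ValueError(f"unknown profile shape {shape!r}; "
                                 f"choose from {sorted(PROFILE_SHAPES)}")
        for _, _, shape in self.modules:
            if len(PROFILE_SHAPES[shape]) != len(self.times):
                raise ValueError("profile shapes must match number of times")

    @property
    def protein_sd(self) -> float:
        if self.protein_noise_sd_log is not None:
            if self.protein_noise_sd_log > self.noise_sd_log:
                raise ValueError("protein_noise_sd_log cannot exceed noise_sd_log")
            return self.protein_noise_sd_log
        return self.noise_sd_log * 8.0 / 15.0

    @property
    def run_sd(self) -> float:
        return float(np.sqrt(max(self.noise_sd_log ** 2 - self.protein_sd ** 2,
                                 0.0)))


def default_modules(n_specific: int) -> tuple[tuple[str, int, str], ...]:
    """Split ``n_specific`` preys into up to four balanced kinetic modules."""
    shapes = ("early-peak", "late-peak", "sustained", "biphasic")
    n_modules = min(4, n_specific)
    if n_modules == 0:
        return ()
    sizes = [n_specific // n_modules] * n_modules
    for i in range(n_specific % n_modules):
        sizes[i] += 1
    return tuple((f"M{i + 1}", size, shapes[i])
                 for i, size in enumerate(sizes) if size > 0)


def cbl_like_config(**overrides) -> SimulationConfig:
    """3 biological x 3 technical replicates (CBL-like design)."""
    defaults = dict(bait_name="BAIT1", n_bio=3, n_tech=3)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def cblb_like_config(**overrides) -> SimulationConfig:
    """3 biological x 2 technical replicates (CBLB-like design)."""
    defaults = dict(bait_name="BAIT2", n_bio=3, n_tech=2)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class GroundTruth:
    """What was planted: specific preys, their kinetics, modules, edges."""

    specific_ids: set[str]
    profile_of: dict[str, np.ndarray]
    module_of: dict[str, str]
    true_edges: set[tuple[str, str]]
    bait_name: str = "BAIT1"

    def __post_init__(self) -> None:
        for p, prof in self.profile_of.items():
            if p not in self.specific_ids:
                raise ValueError(f"profile for non-specific protein {p}")
        for a, b in self.true_edges:
            if a not in self.specific_ids or b not in self.specific_ids:
                raise ValueError("true edges must connect specific proteins")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in sorted(self.specific_ids):
            rows.append({
                "protein": p,
                "module": self.module_of.get(p, ""),
                "profile": ";".join(f"{v:.6g}" for v in self.profile_of[p]),
            })
        return pd.DataFrame(rows)


def _protein_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    specific = [f"PREY{i + 1:03d}" for i in range(config.n_specific)]
    contaminants = [f"CONT{i + 1:03d}" for i in range(config.n_background_proteins)]
    return specific, contaminants


def _assign_modules(config: SimulationConfig,
                    specific: list[str]) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    module_of: dict[str, str] = {}
    profile_of: dict[str, np.ndarray] = {}
    cursor = 0
    for module_id, count, shape in config.modules:
        prof = np.asarray(PROFILE_SHAPES[shape], dtype=float)
        prof = prof / prof.max()
        for p in specific[cursor:cursor + count]:
            module_of[p] = module_id
            profile_of[p] = prof
        cursor += count
    # preys not claimed by any module get a constitutive profile, no module
    for p in specific[cursor:]:
        profile_of[p] = np.ones(len(config.times))
    return module_of, profile_of


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[IntensityTable, SampleDesign, GroundTruth]:
    """Simulate one bait time course with matched wild-type controls.

    Returns the (linear-scale) intensity table with missing cells, the run
    design, and the planted ground truth. Bit-identical for identical
    ``(config, seed)``.
    """
    rng = np.random.default_rng(config.seed)
    specific, contaminants = _protein_names(config)
    module_of, profile_of = _assign_modules(config, specific)
    proteins = [config.bait_name] + specific + contaminants
    n_times = len(config.times)

    runs = []
    design_rows = []
    for background in (BAIT, CONTROL):
        tag = "B" if background == BAIT else "WT"
        for ti, t in enumerate(config.times):
            for bio in range(1, config.n_bio + 1):
                for tech in range(1, config.n_tech + 1):
                    run = f"{config.bait_name}_{tag}_t{int(t)}_b{bio}_r{tech}"
                    runs.append(run)
                    design_rows.append({
                        "run": run, "background": background,
                        "bait_name": config.bait_name, "time_s": float(t),
                        "bio_rep": bio, "tech_rep": tech,
                    })
    design = SampleDesign(pd.DataFrame(design_rows).set_index("run"))

    baselines = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                           len(proteins) - 1)
    baseline_of = dict(zip(specific + contaminants, baselines))

    module_ids = [m[0] for m in config.modules]
    # shared recruitment deviation per (module, bio rep, time)
    mod_dev = {
        m: rng.normal(0.0, config.module_kinetic_sd_log,
                      (config.n_bio, n_times))
        for m in module_ids
    }

    run_shift = rng.normal(0.0, config.run_sd, len(runs))
    log_mat = np.full((len(proteins), len(runs)), np.nan)
    prot_sd = config.protein_sd

    for j, run in enumerate(runs):
        row = design.table.loc[run]
        is_bait_run = row["background"] == BAIT
        ti = config.times.index(row["time_s"])
        bio = int(row["bio_rep"]) - 1
        for i, p in enumerate(proteins):
            if p == config.bait_name:
                if not is_bait_run:
                    continue  # bait absent from wild-type pulldowns
                mu = config.bait_log_intensity
            else:
                mu = baseline_of[p]
                if is_bait_run and p in profile_of:
                    rel = config.enrichment_fold * profile_of[p][ti]
                    if rel <= 0:
                        continue
                    mu = mu + np.log10(rel)
                    if p in module_of:
                        mu = mu + mod_dev[module_of[p]][bio, ti]
            log_mat[i, j] = mu + run_shift[j] + rng.normal(0.0, prot_sd)

    intensities = np.power(10.0, log_mat)
    # censor below the detection floor, then missing-completely-at-random
    intensities[intensities < config.detection_floor] = np.nan
    mcar = rng.random(intensities.shape) < config.missing_rate
    intensities[mcar] = np.nan

    table = IntensityTable(pd.DataFrame(intensities, index=pd.Index(
        proteins, name="protein"), columns=runs))
    members_by_module: dict[str, list[str]] = {}
    for p, m in module_of.items():
        members_by_module.setdefault(m, []).append(p)
    true_edges = set()
    for members in members_by_module.values():
        for a, b in itertools.combinations(sorted(members), 2):
            true_edges.add((a, b))
    truth = GroundTruth(specific_ids=set(specific), profile_of=profile_of,
                        module_of=module_of, true_edges=true_edges,
                        bait_name=config.bait_name)
    return table, design, truth


def truth_reference_list(truth: GroundTruth, recall: float,
                         seed: int) -> ReferenceInteractions:
    """Random subset of the planted edges with expected size recall x |edges|.

    Stands in for an external curated interaction list with incomplete
    coverage; deterministic given ``seed``.
    """
    if not 0 <= recall <= 1:
        raise ValueError("recall must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = sorted(truth.true_edges)
    keep = rng.random(len(edges)) < recall if edges else []
    return ReferenceInteractions.from_pairs(
        e for e, k in zip(edges, keep) if k)


def write_fixtures(config: SimulationConfig, outdir: str | Path,
                   reference_recall: float = 1.0) -> dict[str, Path]:
    """Write the simulated experiment as the pipeline's input file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, design, truth = simulate_experiment(config)
    ref = truth_reference_list(truth, reference_recall, seed=config.seed + 1)
    paths = {
        "intensities": outdir / "protein_groups.tsv",
        "design": outdir / "design.tsv",
        "reference": outdir / "reference.tsv",
        "truth": outdir / "ground_truth.tsv",
    }
    cio.write_protein_groups(table, paths["intensities"])
    cio.write_design(design, paths["design"])
    cio.write_reference(ref, paths["reference"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
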