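"""Specific-interactor calling: enrichment + one-way ANOVA with bootstrap.

For each protein and stimulation time the bait-background and control
log10 intensities are compared: the enrichment ``r(t)`` is the fold change
``10^(mean log bait - mean log control)`` and ``P(t)`` the one-way ANOVA
(two-group F-test) p-value. The whole selection (``P(t) < P*`` and
``r(t) > r*``) is repeated over bootstrap resamples of each group's run
values; a protein's ``P(Detection)`` at a time is the fraction of
iterations in which it was selected, and it is called a specific
interactor when some time reaches the detection fraction threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import BAIT, CONTROL, NormalizedTable, SampleDesign

_TINY_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for interactor selection.

    ``p_threshold`` defaults to 0.001 (a triplicate-technical-replicate
    design; use 0.005 for duplicate designs), ``fold_threshold`` to 2,
    with 200 bootstrap iterations and a 90% detection-fraction rule.
    ``p_adjust`` may be ``"none"`` or ``"bh"`` (per-time Benjamini-
    Hochberg within each iteration).
    """

    p_threshold: float = 0.001
    fold_threshold: float = 2.0
    n_boot: int = 200
    detect_frac: float = 0.9
    seed: int = 0
    p_adjust: str = "none"

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.detect_frac <= 1:
            raise ValueError("detect_frac must lie in (0, 1]")
        if self.p_adjust not in ("none", "bh"):
            raise ValueError("p_adjust must be 'none' or 'bh'")


def anova_enrichment(bait: np.ndarray, control: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group enrichment and one-way ANOVA p-value.

    ``bait``/``control`` have group observations on the last axis; returns
    linear-scale fold enrichment and the F-test p-value with (1, n1+n2-2)
    degrees of freedom. Groups with zero pooled within-group variance get
    P = 1 when the means agree (fully degenerate) and a machine-tiny P
    when they differ (perfect separation).
    """
    bait = np.asarray(bait, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = bait.shape[-1], control.shape[-1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two runs per group")
    m1 = bait.mean(axis=-1)
    m2 = control.mean(axis=-1)
    r = np.power(10.0, m1 - m2)
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = ((bait - m1[..., None]) ** 2).sum(axis=-1) + \
          ((control - m2[..., None]) ** 2).sum(axis=-1)
    df2 = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / 1.0) / (ssw / df2)
        p = stats.f.sf(f, 1, df2)
    degenerate = ssw == 0
    p = np.where(degenerate & (ssb == 0), 1.0, p)
    p = np.where(degenerate & (ssb > 0), _TINY_P, p)
    p = np.clip(p, _TINY_P, 1.0)
    return r, p


def enrichment_and_pvalue(norm: NormalizedTable, design: SampleDesign,
                          protein: str, time_s: float) -> tuple[float, float]:
    """Single (protein, time) enrichment r and ANOVA p-value P."""
    bait_runs = design.runs(background=BAIT, time_s=time_s)
    ctrl_runs = design.runs(background=CONTROL, time_s=time_s)
    bait = norm.log_data.loc[protein, bait_runs].to_numpy(dtype=float)
    ctrl = norm.log_data.loc[protein, ctrl_runs].to_numpy(dtype=float)
    r, p = anova_enrichment(bait, ctrl)
    return float(r), float(p)


@dataclass
class DetectionResult:
    """Per-(protein, time) bootstrap statistics and the specific calls.

    ``r_mean``, ``p_mean`` and ``detection_fraction`` are protein x time
    DataFrames of bootstrap means; ``specific`` flags proteins whose
    detection fraction reaches the threshold at some time. The bait is
    flagged separately and excluded from :meth:`interactors`.
    """

    r_mean: pd.DataFrame
    p_mean: pd.DataFrame
    detection_fraction: pd.DataFrame
    specific: pd.Series
    bait_name: str
    config: DetectionConfig
    times: list[float] = field(default_factory=list)

    @property
    def max_mean_enrichment(self) -> pd.Series:
        """Maximum over times of the bootstrap-mean enrichment, per protein."""
        return self.r_mean.max(axis=1)

    def times_specific(self, protein: str) -> list[float]:
        frac = self.detection_fraction.loc[protein]
        return [t for t in self.times
                if frac[t] >= self.config.detect_frac]

    def interactors(self) -> list[str]:
        """Specific interactors excluding the bait, ranked by <r>_max."""
        flagged = self.specific[self.specific].index
        flagged = [p for p in flagged if p != self.bait_name]
        return sorted(flagged, key=lambda p: -self.max_mean_enrichment[p])

    def volcano_table(self, time_s: float) -> pd.DataFrame:
        """Mean enrichment vs mean p-value at one time, selection flagged."""
        if time_s not in self.times:
            raise KeyError(f"unknown time point {time_s!r}")
        df = pd.DataFrame({
            "protein": self.r_mean.index,
            "r_mean": self.r_mean[time_s].to_numpy(),
            "p_mean": self.p_mean[time_s].to_numpy(),
            "detection_fraction": self.detection_fraction[time_s].to_numpy(),
        })
        df["selected"] = df["detection_fraction"] >= self.config.detect_frac
        return df.sort_values("r_mean", ascending=False).reset_index(drop=True)

    def interactors_per_time(self) -> pd.Series:
        """Number of specific interactors (bait excluded) per time point."""
        frac = self.detection_fraction.drop(index=self.bait_name,
                                            errors="ignore")
        counts = (frac >= self.config.detect_frac).sum(axis=0)
        counts.name = "n_interactors"
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.r_mean.index:
            for t in self.times:
                rows.append({
                    "protein": p, "time_s": t,
                    "r_mean": self.r_mean.at[p, t],
                    "p_mean": self.p_mean.at[p, t],
                    "detection_fraction": self.detection_fraction.at[p, t],
                    "specific": bool(self.specific[p]),
                    "is_bait": p == self.bait_name,
                })
        return pd.DataFrame(rows)


def bootstrap_detection(norm: NormalizedTable, design: SampleDesign,
                        config: DetectionConfig) -> DetectionResult:
    """Bootstrap-stabilized interactor selection.

    Each iteration resamples every (protein, time, group) run set with
    replacement (imputed values are resampled along with observed ones),
    recomputes (r, P), and applies the joint threshold. Deterministic
    given ``config.seed``.
    """
    if not norm.is_complete:
        raise ValueError("normalized table must be imputed before detection")
    times = design.times
    proteins = list(norm.log_data.index)
    n_prot = len(proteins)
    rng = np.random.default_rng(config.seed)

    bait_blocks, ctrl_blocks = [], []
    for t in times:
        bait_runs = design.runs(background=BAIT, time_s=t)
        ctrl_runs = design.runs(background=CONTROL, time_s=t)
        if len(bait_runs) < 2 or len(ctrl_runs) < 2:
            raise ValueError(f"need >=2 bait and control runs at t={t}")
        bait_blocks.append(norm.log_data[bait_runs].to_numpy(dtype=float))
        ctrl_blocks.append(norm.log_data[ctrl_runs].to_numpy(dtype=float))

    shape = (n_prot, len(times))
    r_sum = np.zeros(shape)
    p_sum = np.zeros(shape)
    sel_count = np.zeros(shape)
    for _ in range(config.n_boot):
        r_it = np.empty(shape)
        p_it = np.empty(shape)
        for ti in range(len(times)):
            b, c = bait_blocks[ti], ctrl_blocks[ti]
            bi = rng.integers(0, b.shape[1], size=b.shape)
            ci = rng.integers(0, c.shape[1], size=c.shape)
            r, p = anova_enrichment(np.take_along_axis(b, bi, axis=1),
                                    np.take_along_axis(c, ci, axis=1))
            r_it[:, ti] = r
            p_it[:, ti] = p
        if config.p_adjust == "bh":
            for ti in range(len(times)):
                p_it[:, ti] = multipletests(p_it[:, ti], method="fdr_bh")[1]
        r_sum += r_it
        p_sum += p_it
        sel_count += (p_it < config.p_threshold) & \
                     (r_it > config.fold_threshold)

    frac = sel_count / config.n_boot
    r_mean = pd.DataFrame(r_sum / config.n_boot, index=proteins, columns=times)
    p_mean = pd.DataFrame(p_sum / config.n_boot, index=proteins, columns=times)
    detection = pd.DataFrame(frac, index=proteins, columns=times)
    specific = pd.Series((frac >= config.detect_frac).any(axis=1),
                         index=proteins)
    return DetectionResult(r_mean=r_mean, p_mean=p_mean,
                           detection_fraction=detection, specific=specific,
                           bait_name=design.bait_name, config=config,
                           times=times)
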