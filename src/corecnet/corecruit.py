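"""Recruitment kinetics, bootstrap Pearson correlation, and the network.

Each specific interactor's intensities in the bait-background runs are
first normalized to the bait (making the bait constant across runs), then
each biological replicate's series is divided by its maximum-over-time of
technical-replicate means, giving recruitment profiles in [0, 1]. Pairs of
interactors are correlated across the concatenated normalized points of
all runs; Pearson R and its p-value are averaged over bootstrap resamples
of the paired points. Edges of the co-recruitment network are pairs whose
bootstrap-mean p-value beats a Bonferroni-corrected threshold; edges with
R > 0.8 form the high-confidence subnetwork.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .model import (BAIT, CorrelationNetwork, NormalizedTable, SampleDesign,
                    canonical_edge)

logger = logging.getLogger(__name__)

_TINY_P = float(np.finfo(float).tiny)


def bait_normalize(norm: NormalizedTable, design: SampleDesign,
                   bait: str | None = None) -> NormalizedTable:
    """Scale every bait-background run so the bait's intensity is constant.

    On the log10 scale each bait run is shifted by the difference between
    the bait's value in that run and its mean across bait runs. Control
    runs are left untouched (recruitment profiles use bait runs only).
    """
    if bait is None:
        bait = design.bait_name
    if bait not in norm.log_data.index:
        raise ValueError(f"bait {bait!r} not present in the table")
    bait_runs = design.runs(background=BAIT)
    bait_row = norm.log_data.loc[bait, bait_runs]
    if bait_row.isna().any():
        missing = list(bait_row.index[bait_row.isna()])
        raise ValueError(f"bait {bait!r} missing in bait runs: {missing}")
    const = float(bait_row.mean())
    log_data = norm.log_data.copy()
    offsets = const - bait_row
    log_data[bait_runs] = log_data[bait_runs].add(offsets, axis=1)
    audit = dict(norm.audit)
    audit["bait_offsets"] = offsets.to_dict()
    return NormalizedTable(log_data, norm.imputed.copy(), audit)


@dataclass
class RecruitmentProfiles:
    """Bait- and max-normalized recruitment kinetics of the interactors.

    ``obs`` holds the observation matrix used for correlation: one row per
    protein, columns multi-indexed by (bio_rep, time_s, tech_rep) for the
    default per-run pairing or (bio_rep, time_s) for the tech-mean
    pairing. ``tech_mean`` always holds the per-(protein, bio rep)
    profiles of technical-replicate means, max-normalized per bio rep.
    """

    obs: pd.DataFrame
    tech_mean: pd.DataFrame  # MultiIndex rows (protein, bio_rep) x times
    points: str
    flagged_zero: list[str] = field(default_factory=list)

    @property
    def proteins(self) -> list[str]:
        return list(self.obs.index)

    def pair_values(self, i: str, j: str) -> tuple[np.ndarray, np.ndarray]:
        x = self.obs.loc[i].to_numpy(dtype=float)
        y = self.obs.loc[j].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        return x[keep], y[keep]

    def mean_profile(self, protein: str) -> pd.Series:
        """Average over biological replicates of the normalized profiles."""
        return self.tech_mean.loc[protein].mean(axis=0)


def build_profiles(norm: NormalizedTable, design: SampleDesign,
                   interactors: list[str],
                   points: str = "per-run") -> RecruitmentProfiles:
    """Normalized recruitment profiles for the given interactors.

    ``points="per-run"`` keeps every technical run as an observation
    (each bio rep's block divided by its max-over-time of tech means);
    ``points="tech-mean"`` averages technical replicates first.

    Imputed cells are masked out of the profiles: an imputed value is a
    draw from the background distribution and carries no recruitment
    information, so the downstream correlation pairs only the points
    actually quantified for both proteins.
    """
    if points not in ("per-run", "tech-mean"):
        raise ValueError("points must be 'per-run' or 'tech-mean'")
    missing = [p for p in interactors if p not in norm.log_data.index]
    if missing:
        raise ValueError(f"interactors not in the table: {missing}")
    bait_runs = design.runs(background=BAIT)
    linear = np.power(10.0, norm.log_data.loc[interactors, bait_runs])
    linear = linear.mask(norm.imputed.loc[interactors, bait_runs])
    sub = design.table.loc[bait_runs]
    bios = sorted(sub["bio_rep"].unique())
    times = design.times

    flagged: list[str] = []
    tech_mean_rows = {}
    obs_cols: dict[tuple, pd.Series] = {}
    for b in bios:
        cols_by_time = {t: [r for r in bait_runs
                            if sub.at[r, "bio_rep"] == b
                            and sub.at[r, "time_s"] == t]
                        for t in times}
        tmean = pd.DataFrame(
            {t: linear[cols].mean(axis=1) for t, cols in cols_by_time.items()})
        factor = tmean.max(axis=1)
        zero = factor.fillna(0.0) <= 0  # nothing quantified in this bio rep
        factor = factor.mask(zero, 1.0)
        norm_tmean = tmean.divide(factor, axis=0)
        report_tmean = norm_tmean.copy()
        report_tmean[zero] = 0.0  # all-missing bio rep reported as zeros
        for p in interactors:
            tech_mean_rows[(p, b)] = report_tmean.loc[p]
        if points == "tech-mean":
            for t in times:
                obs_cols[(b, t)] = norm_tmean[t]
        else:
            for t in times:
                for r in cols_by_time[t]:
                    tech = int(sub.at[r, "tech_rep"])
                    obs_cols[(b, t, tech)] = linear[r].divide(factor)
    obs = pd.DataFrame(obs_cols).loc[interactors]
    empty = obs.isna().all(axis=1) | (obs.fillna(0.0) == 0).all(axis=1)
    flagged = list(obs.index[empty])
    if flagged:
        logger.warning("no usable recruitment series for: %s", flagged)
    obs.columns = pd.MultiIndex.from_tuples(
        obs.columns,
        names=["bio_rep", "time_s"] + (["tech_rep"] if points == "per-run"
                                       else []))
    tech_mean = pd.DataFrame(tech_mean_rows).T.loc[
        [(p, b) for p in interactors for b in bios]]
    tech_mean.index = pd.MultiIndex.from_tuples(tech_mean.index,
                                                names=["protein", "bio_rep"])
    return RecruitmentProfiles(obs=obs, tech_mean=tech_mean, points=points,
                               flagged_zero=flagged)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p-value from the t-distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((xm * ym).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, _TINY_P
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return r, max(p, _TINY_P)


def bootstrap_pearson(x: np.ndarray, y: np.ndarray, n_boot: int = 1000,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None
                      ) -> tuple[float, float]:
    """Bootstrap-mean Pearson coefficient and p-value for one pair.

    Paired points are resampled with replacement ``n_boot`` times; each
    sample's r and two-sided p (t-distribution, n-2 df) are averaged.
    Zero-variance samples are skipped (their count is logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xm = xb - xb.mean(axis=1, keepdims=True)
    ym = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xm ** 2).sum(axis=1) * (ym ** 2).sum(axis=1))
    valid = denom > 0
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.debug("skipped %d zero-variance bootstrap samples", n_skipped)
    if not valid.any():
        return float("nan"), float("nan")
    r = np.clip((xm * ym).sum(axis=1)[valid] / denom[valid], -1.0, 1.0)
    near_one = np.isclose(np.abs(r), 1.0)
    t = np.zeros_like(r)
    t[~near_one] = r[~near_one] * np.sqrt(
        (n - 2) / (1 - r[~near_one] ** 2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[near_one] = _TINY_P
    p = np.clip(p, _TINY_P, 1.0)
    return float(r.mean()), float(p.mean())


@dataclass
class CorrelationMatrix:
    """Symmetric bootstrap-mean Pearson R and P matrices over interactors."""

    R: pd.DataFrame
    P: pd.DataFrame
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not self.R.index.equals(self.R.columns):
            raise ValueError("R must be square with matching labels")

    @property
    def proteins(self) -> list[str]:
        return list(self.R.index)

    @property
    def n(self) -> int:
        return self.R.shape[0]


def correlation_matrix(profiles: RecruitmentProfiles, n_boot: int = 1000,
                       seed: int = 0,
                       exclude: list[str] | None = None) -> CorrelationMatrix:
    """Bootstrap-mean Pearson matrix over all interactor pairs.

    Proteins are processed in sorted order with one spawned random stream
    per pair, so the result is invariant to the input ordering. Flagged
    all-zero profiles and anything in ``exclude`` (e.g. the bait) are left
    out of the matrix.
    """
    drop = set(exclude or []) | set(profiles.flagged_zero)
    prots = sorted(p for p in profiles.proteins if p not in drop)
    n = len(prots)
    R = pd.DataFrame(np.eye(n), index=prots, columns=prots)
    P = pd.DataFrame(np.full((n, n), _TINY_P), index=prots, columns=prots)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    for (i, j), ss in zip(pairs, streams):
        x, y = profiles.pair_values(prots[i], prots[j])
        if len(x) < 3:  # too few commonly quantified points to correlate
            r, p = float("nan"), float("nan")
        else:
            r, p = bootstrap_pearson(x, y, n_boot=n_boot,
                                     rng=np.random.default_rng(ss))
        R.iat[i, j] = R.iat[j, i] = r
        P.iat[i, j] = P.iat[j, i] = p
    return CorrelationMatrix(R=R, P=P, n_boot=n_boot, seed=seed)


def kmeans_partition(matrix: CorrelationMatrix, k: int, n_init: int = 10,
                     seed: int = 0) -> pd.Series:
    """K-means partition of interactors using rows of R as features."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.n:
        raise ValueError(f"k={k} exceeds the number of interactors {matrix.n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2 ** 31))
    # uncorrelatable pairs (too few common points) contribute 0 to the features
    labels = km.fit_predict(matrix.R.fillna(0.0).to_numpy())
    return pd.Series(labels, index=matrix.proteins, name="cluster")


def suggest_k(matrix: CorrelationMatrix, k_min: int = 2, k_max: int = 10,
              n_init: int = 10, seed: int = 0) -> pd.Series:
    """Mean silhouette score for each candidate k (higher is better)."""
    scores = {}
    feats = matrix.R.to_numpy()
    for k in range(k_min, min(k_max, matrix.n - 1) + 1):
        labels = kmeans_partition(matrix, k, n_init=n_init, seed=seed)
        scores[k] = float(silhouette_score(feats, labels.to_numpy()))
    return pd.Series(scores, name="silhouette")


def bonferroni_threshold(alpha: float, n: int) -> float:
    """Per-pair p-value threshold: alpha over the N(N-1)/2 tested pairs."""
    if n < 2:
        raise ValueError("need at least two interactors")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / (n * (n - 1) / 2)


def build_network(matrix: CorrelationMatrix, alpha: float = 5e-5,
                  hc_r: float = 0.8) -> CorrelationNetwork:
    """Threshold the P matrix into the co-recruitment network.

    An edge (i, j) exists iff P_ij < alpha / (N(N-1)/2); the
    high-confidence flag marks edges with R > ``hc_r``.
    """
    n = matrix.n
    g = nx.Graph()
    g.add_nodes_from(matrix.proteins)
    if n < 2:
        return CorrelationNetwork(g, alpha=alpha, p_star=float("nan"),
                                  hc_r=hc_r)
    p_star = bonferroni_threshold(alpha, n)
    prots = matrix.proteins
    for i in range(n):
        for j in range(i + 1, n):
            p = float(matrix.P.iat[i, j])
            if p < p_star:
                r = float(matrix.R.iat[i, j])
                g.add_edge(prots[i], prots[j], R=r, P=p,
                           high_confidence=bool(r > hc_r))
    g.graph.update({"alpha": alpha, "p_star": p_star, "hc_r": hc_r})
    return CorrelationNetwork(g, alpha=alpha, p_star=p_star, hc_r=hc_r)
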