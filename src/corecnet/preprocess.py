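"""Run normalization and control-based imputation of missing intensities.

Order of operations: optional spike-in normalization on the linear scale,
global mean normalization on log10 intensities anchored on the proteins
detected in every run, imputation of missing cells from the wild-type
background model, then per-condition mean normalization across each
stimulation time's bait and control runs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import CONTROL, IntensityTable, NormalizedTable, SampleDesign

logger = logging.getLogger(__name__)

LOG_BASE = 10  # fixed; any fixed base yields identical decisions downstream
DEFAULT_PERCENTILE = 5.0


def spikein_normalize(table: IntensityTable,
                      spike_ids: list[str]) -> IntensityTable:
    """Scale each run by its total spike-in standard intensity.

    Factors are rescaled so their grand mean is 1; a run in which every
    spike-in is missing keeps factor 1 (with a warning).
    """
    if not spike_ids:
        raise ValueError("spike_ids must be non-empty")
    present = [s for s in spike_ids if s in table.data.index]
    if not present:
        raise ValueError("no spike-in identifiers found in the table")
    totals = table.data.loc[present].sum(axis=0, min_count=1)
    if totals.isna().any():
        bad = list(totals.index[totals.isna()])
        logger.warning("runs with no spike-in signal get factor 1: %s", bad)
    factors = totals / totals.dropna().mean()
    factors = factors.fillna(1.0)
    return IntensityTable(table.data.divide(factors, axis=1))


def _as_log(table: IntensityTable) -> pd.DataFrame:
    return np.log10(table.data)


def global_mean_normalize(table: IntensityTable,
                          design: SampleDesign) -> NormalizedTable:
    """Per-run additive log10 offsets anchored on always-detected proteins.

    The anchor set is every protein quantified in all runs; each run is
    shifted so its mean log intensity over the anchor set equals the grand
    mean of that set.
    """
    design.check_matches(table)
    log_data = _as_log(table)
    anchor = log_data.dropna(axis=0).index
    if len(anchor) == 0:
        raise ValueError("no protein is detected in every run; cannot anchor "
                         "global normalization")
    anchor_block = log_data.loc[anchor]
    run_means = anchor_block.mean(axis=0)
    offsets = float(anchor_block.to_numpy().mean()) - run_means
    normalized = log_data.add(offsets, axis=1)
    audit = {"global_offsets": offsets.to_dict(),
             "anchor_proteins": list(anchor)}
    mask = pd.DataFrame(False, index=log_data.index, columns=log_data.columns)
    return NormalizedTable(normalized, mask, audit)


def background_model(norm: NormalizedTable, design: SampleDesign,
                     percentile: float = DEFAULT_PERCENTILE) -> tuple[float, float]:
    """Location and scale of the imputation distribution.

    Over proteins observed in control runs, compute each protein's mean
    and SD of log control intensities; return the given percentile of the
    means (linear interpolation) and the mean of the SDs.
    """
    control_runs = design.runs(background=CONTROL)
    if not control_runs:
        raise ValueError("no control runs in the design")
    ctrl = norm.log_data[control_runs]
    observed = ctrl.notna()
    means = ctrl.mean(axis=1)[observed.any(axis=1)]
    sds = ctrl.std(axis=1, ddof=1)[observed.sum(axis=1) >= 2]
    if means.empty or sds.dropna().empty:
        # degenerate control coverage: fall back to the global distribution
        logger.warning("control background underdetermined; falling back to "
                       "global observed intensities")
        all_obs = norm.log_data.stack()
        mu0 = float(np.percentile(all_obs, percentile))
        sigma0 = float(norm.log_data.std(axis=1, ddof=1).dropna().mean())
        return mu0, sigma0
    mu0 = float(np.percentile(means.to_numpy(), percentile))
    sigma0 = float(sds.dropna().mean())
    return mu0, sigma0


def impute_missing(norm: NormalizedTable, design: SampleDesign, seed: int,
                   percentile: float = DEFAULT_PERCENTILE) -> NormalizedTable:
    """Fill missing cells from the wild-type background distribution.

    Missing values are drawn independently from Normal(mu0, sigma0) on the
    log10 scale, where mu0 is the 5th percentile of per-protein mean log
    control intensities and sigma0 the mean of the per-protein SDs.
    Observed values are never overwritten; deterministic given ``seed``.
    """
    mu0, sigma0 = background_model(norm, design, percentile)
    rng = np.random.default_rng(seed)
    log_data = norm.log_data.copy()
    missing = log_data.isna()
    n_missing = int(missing.to_numpy().sum())
    if n_missing:
        # draws assigned in canonical (protein, run) label order so the
        # result is invariant to row/column permutations of the input
        ii, jj = np.nonzero(missing.to_numpy())
        labels = sorted(range(n_missing),
                        key=lambda k: (log_data.index[ii[k]],
                                       log_data.columns[jj[k]]))
        draws = rng.normal(mu0, sigma0, n_missing)
        vals = log_data.to_numpy()
        for draw, k in zip(draws, labels):
            vals[ii[k], jj[k]] = draw
        log_data = pd.DataFrame(vals, index=log_data.index,
                                columns=log_data.columns)
    audit = dict(norm.audit)
    audit["imputation"] = {"mu0": mu0, "sigma0": sigma0, "seed": seed,
                           "percentile": percentile, "n_imputed": n_missing}
    return NormalizedTable(log_data, norm.imputed | missing, audit)


def per_condition_normalize(norm: NormalizedTable,
                            design: SampleDesign) -> NormalizedTable:
    """Equalize mean log intensity across each time point's runs.

    Within each stimulation condition, bait and control runs are shifted
    so every run's mean log intensity (over all proteins) matches the
    condition mean.
    """
    log_data = norm.log_data.copy()
    offsets: dict[str, float] = {}
    for t in design.times:
        runs = design.runs(time_s=t)
        runs = [r for r in runs if r in log_data.columns]
        if not runs:
            continue
        block = log_data[runs]
        run_means = block.mean(axis=0)
        target = float(np.nanmean(block.to_numpy()))
        shift = target - run_means
        log_data[runs] = block.add(shift, axis=1)
        offsets.update(shift.to_dict())
    audit = dict(norm.audit)
    audit["per_condition_offsets"] = offsets
    return NormalizedTable(log_data, norm.imputed.copy(), audit)


def preprocess(table: IntensityTable, design: SampleDesign, seed: int,
               spike_ids: list[str] | None = None,
               percentile: float = DEFAULT_PERCENTILE) -> NormalizedTable:
    """Full preprocessing chain: [spike-in] -> global -> impute -> per-condition."""
    if spike_ids:
        table = spikein_normalize(table, spike_ids)
        table = IntensityTable(table.data.drop(
            index=[s for s in spike_ids if s in table.data.index]))
    norm = global_mean_normalize(table, design)
    norm = impute_missing(norm, design, seed, percentile)
    return per_condition_normalize(norm, design)
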