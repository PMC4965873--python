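"""Parameter-recovery evaluation of the pipeline on synthetic ground truth.

Runs the full chain (simulate -> preprocess -> detect -> profiles ->
correlation network -> clustering) against the generator's planted truth
and scores detection sensitivity, false discovery proportion, recovery of
planted within-module edges, and module-partition agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import corecruit, detect, preprocess, synth


@dataclass
class RecoveryMetrics:
    """Scores of one simulated experiment against its planted truth."""

    sensitivity: float
    false_discovery_proportion: float
    edge_recall: float
    n_extra_edges: int
    adjusted_rand: float
    n_interactors: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "false_discovery_proportion": self.false_discovery_proportion,
            "edge_recall": self.edge_recall,
            "n_extra_edges": self.n_extra_edges,
            "adjusted_rand": self.adjusted_rand,
            "n_interactors": self.n_interactors,
        }


def evaluate_recovery(config: synth.SimulationConfig, p_threshold: float,
                      seed: int, n_boot_detect: int = 200,
                      n_boot_corr: int = 1000,
                      alpha: float = 5e-5) -> RecoveryMetrics:
    """Score one simulated experiment end to end.

    ``seed`` drives the analysis-side randomness (imputation, bootstraps,
    K-means); the generator's own seed lives in ``config``.
    """
    table, design, truth = synth.simulate_experiment(config)
    state = np.random.SeedSequence(seed).generate_state(4)
    s_imp, s_det, s_corr, s_km = (int(s % (2 ** 31)) for s in state)

    norm = preprocess.preprocess(table, design, seed=s_imp)
    result = detect.bootstrap_detection(
        norm, design, detect.DetectionConfig(p_threshold=p_threshold,
                                             seed=s_det,
                                             n_boot=n_boot_detect))
    interactors = set(result.interactors())
    tp = len(interactors & truth.specific_ids)
    sens = tp / len(truth.specific_ids) if truth.specific_ids else float("nan")
    fdp = (len(interactors) - tp) / len(interactors) if interactors else 0.0

    edge_recall = float("nan")
    extra = 0
    ari = float("nan")
    if len(interactors) >= 2:
        bnorm = corecruit.bait_normalize(norm, design)
        profiles = corecruit.build_profiles(bnorm, design, sorted(interactors))
        matrix = corecruit.correlation_matrix(profiles, n_boot=n_boot_corr,
                                              seed=s_corr)
        net = corecruit.build_network(matrix, alpha=alpha)
        predicted = set(net.edges)
        true_among = {e for e in truth.true_edges
                      if e[0] in interactors and e[1] in interactors}
        if true_among:
            edge_recall = len(predicted & true_among) / len(true_among)
        extra = len(predicted - true_among)
        n_modules = len({m for m in truth.module_of.values()})
        members = [p for p in matrix.proteins if p in truth.module_of]
        if n_modules >= 2 and len(members) > n_modules:
            sub = corecruit.CorrelationMatrix(
                R=matrix.R.loc[members, members],
                P=matrix.P.loc[members, members],
                n_boot=matrix.n_boot, seed=matrix.seed)
            labels = corecruit.kmeans_partition(sub, n_modules, seed=s_km)
            want = [truth.module_of[p] for p in members]
            ari = float(adjusted_rand_score(want, labels.to_numpy()))
    return RecoveryMetrics(sensitivity=sens,
                           false_discovery_proportion=fdp,
                           edge_recall=edge_recall, n_extra_edges=extra,
                           adjusted_rand=ari,
                           n_interactors=len(interactors))


def recovery_battery(seeds, design_kind: str = "cbl-like",
                     **kwargs) -> pd.DataFrame:
    """Recovery metrics across generator seeds for one replicate design."""
    maker = (synth.cbl_like_config if design_kind == "cbl-like"
             else synth.cblb_like_config)
    p_threshold = 0.001 if design_kind == "cbl-like" else 0.005
    rows = []
    for s in seeds:
        config = maker(seed=int(s))
        metrics = evaluate_recovery(config, p_threshold=p_threshold,
                                    seed=int(s) + 1000, **kwargs)
        rows.append({"seed": int(s), **metrics.as_dict()})
    return pd.DataFrame(rows).set_index("seed")
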