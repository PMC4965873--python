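"""Benchmark predicted networks against a reference interaction list.

Headline quantities: precision (validated / predicted edges), the random-
network baseline 2K / (N(N-1)) for K reference edges among N nodes,
first-neighbor validation of an anchor node, and validation stratified by
unweighted graph distance from the anchor. Probabilities are reported to
2 decimals and percentages/folds to 1 decimal, mirroring common reporting
conventions; raw values are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .model import CorrelationNetwork, ReferenceInteractions, canonical_edge


def precision(n_validated: int, n_predicted: int) -> float:
    """Fraction of predicted edges present in the reference."""
    if n_predicted < 1:
        raise ValueError("precision undefined for zero predicted edges")
    if n_validated > n_predicted:
        raise ValueError("validated edges cannot exceed predicted edges")
    return n_validated / n_predicted


def random_baseline(k_reference: int, n_nodes: int) -> float:
    """Chance that a uniformly random edge hits one of K reference edges."""
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    if k_reference < 0:
        raise ValueError("reference edge count cannot be negative")
    return 2 * k_reference / (n_nodes * (n_nodes - 1))


def expected_random_neighbor_rate(n_targets: int, n_candidates: int) -> float:
    """Percentage of candidates that are targets (random-edge expectation)."""
    if n_candidates < 1:
        raise ValueError("need at least one candidate node")
    return 100.0 * n_targets / n_candidates


def enrichment_ratio(r_max_a: float, r_max_b: float) -> float:
    """Fold difference between two maximum mean enrichments."""
    if r_max_a <= 0 or r_max_b <= 0:
        raise ValueError("enrichments must be positive")
    return r_max_a / r_max_b


def first_neighbors(net: CorrelationNetwork, node: str) -> set[str]:
    """Nodes at unweighted graph distance 1 from ``node``."""
    if node not in net.graph:
        raise KeyError(f"{node!r} is not a network node")
    return set(net.graph.neighbors(node))


def neighbor_validation(net: CorrelationNetwork, node: str,
                        target_set: Iterable[str]
                        ) -> tuple[int, int, float | None]:
    """(hits, n_neighbors, percentage of neighbors in the target set).

    The fraction is ``None`` for an isolated node.
    """
    neighbors = first_neighbors(net, node)
    targets = {str(t).upper() for t in target_set}
    hits = sum(1 for n in neighbors if str(n).upper() in targets)
    if not neighbors:
        return 0, 0, None
    return hits, len(neighbors), 100.0 * hits / len(neighbors)


def distance_stratified_validation(net: CorrelationNetwork, anchor: str,
                                   target_set: Iterable[str]) -> pd.DataFrame:
    """Validation rate per unweighted shortest-path distance from the anchor.

    Unreachable nodes are binned at distance ``inf``. At distance 1 the
    rate equals :func:`neighbor_validation`.
    """
    if anchor not in net.graph:
        raise KeyError(f"{anchor!r} is not a network node")
    targets = {str(t).upper() for t in target_set}
    dist = nx.single_source_shortest_path_length(net.graph, anchor)
    rows = []
    others = [n for n in net.graph.nodes if n != anchor]
    all_d = sorted({dist.get(n, np.inf) for n in others})
    for d in all_d:
        at_d = [n for n in others if dist.get(n, np.inf) == d]
        hits = sum(1 for n in at_d if str(n).upper() in targets)
        rows.append({"distance": d, "n_nodes": len(at_d), "hits": hits,
                     "fraction_pct": 100.0 * hits / len(at_d)})
    return pd.DataFrame(rows, columns=["distance", "n_nodes", "hits",
                                       "fraction_pct"])


@dataclass
class BenchmarkReport:
    """Precision of a predicted network against reference interactions."""

    n_nodes: int
    n_predicted_edges: int
    n_validated: int
    n_reference_edges_among_nodes: int
    precision: float | None
    random_baseline: float
    hc_n_predicted_edges: int
    hc_n_validated: int
    hc_precision: float | None
    extras: dict = field(default_factory=dict)

    def rounded(self) -> dict:
        def r2(x):
            return None if x is None else round(x, 2)
        return {
            "precision": r2(self.precision),
            "random_baseline": r2(self.random_baseline),
            "hc_precision": r2(self.hc_precision),
        }

    def to_dict(self) -> dict:
        out = {
            "n_nodes": self.n_nodes,
            "n_predicted_edges": self.n_predicted_edges,
            "n_validated": self.n_validated,
            "n_reference_edges_among_nodes":
                self.n_reference_edges_among_nodes,
            "precision": self.precision,
            "random_baseline": self.random_baseline,
            "hc_n_predicted_edges": self.hc_n_predicted_edges,
            "hc_n_validated": self.hc_n_validated,
            "hc_precision": self.hc_precision,
        }
        out.update({"rounded": self.rounded()})
        out.update(self.extras)
        return out

    def summary(self) -> str:
        lines = [
            f"nodes: {self.n_nodes}",
            f"predicted edges: {self.n_predicted_edges} "
            f"(validated: {self.n_validated})",
            f"precision: "
            + ("undefined" if self.precision is None
               else f"{self.precision:.2f}"),
            f"random baseline: {self.random_baseline:.2f} "
            f"({self.n_reference_edges_among_nodes} reference edges among "
            f"nodes)",
            f"high-confidence edges: {self.hc_n_predicted_edges} "
            f"(validated: {self.hc_n_validated}; precision: "
            + ("undefined" if self.hc_precision is None
               else f"{self.hc_precision:.2f}") + ")",
        ]
        return "\n".join(lines)


def benchmark(net: CorrelationNetwork,
              reference: ReferenceInteractions) -> BenchmarkReport:
    """Compare a co-recruitment network's edges with the reference list."""
    nodes = net.nodes
    predicted = [canonical_edge(a, b) for a, b in net.edges]
    validated = [e for e in predicted if e in reference.edges]
    k = len(reference.among(nodes))
    hc = net.high_confidence_subnetwork()
    hc_predicted = [canonical_edge(a, b) for a, b in hc.edges]
    hc_validated = [e for e in hc_predicted if e in reference.edges]
    return BenchmarkReport(
        n_nodes=len(nodes),
        n_predicted_edges=len(predicted),
        n_validated=len(validated),
        n_reference_edges_among_nodes=k,
        precision=(len(validated) / len(predicted)) if predicted else None,
        random_baseline=random_baseline(k, len(nodes)) if len(nodes) >= 2
        else 0.0,
        hc_n_predicted_edges=len(hc_predicted),
        hc_n_validated=len(hc_validated),
        hc_precision=(len(hc_validated) / len(hc_predicted))
        if hc_predicted else None,
    )
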