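"""Shared in-memory containers for the AP-MS analysis pipeline.

The pipeline works on three external inputs — a protein-group intensity
matrix, a sample-design table describing each LC-MS run, and a reference
list of known physical protein-protein interactions — plus the normalized
table produced by preprocessing. All tabular state is held in pandas
objects; a cell that was not quantified is ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

BAIT = "bait"
CONTROL = "control"

DESIGN_COLUMNS = ("background", "bait_name", "time_s", "bio_rep", "tech_rep")


@dataclass
class IntensityTable:
    """Protein x run matrix of label-free intensities (linear scale).

    ``data`` is indexed by protein identifier (gene-symbol level after
    aggregation) with one column per LC-MS run. Missing quantifications
    are ``NaN``; zeros are converted to ``NaN`` on read.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise ValueError("intensity table needs at least one run")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein identifiers: {dupes}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate run identifiers")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("intensities must be finite or missing")
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SampleDesign:
    """Run annotations: background (bait/control), time point and replicate.

    ``table`` is indexed by run id with columns ``background`` (``"bait"``
    or ``"control"``), ``bait_name``, ``time_s``, ``bio_rep``, ``tech_rep``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate run ids in design table")
        bad = set(self.table["background"]) - {BAIT, CONTROL}
        if bad:
            raise ValueError(f"unknown background labels: {sorted(bad)}")

    @property
    def run_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def times(self) -> list[float]:
        return sorted(self.table["time_s"].unique())

    @property
    def bait_name(self) -> str:
        names = self.table["bait_name"].unique()
        if len(names) != 1:
            raise ValueError(f"expected a single bait per design, got {list(names)}")
        return str(names[0])

    def runs(self, background: str | None = None, time_s: float | None = None,
             bio_rep: int | None = None) -> list[str]:
        """Run ids matching the given stratum (all if unrestricted)."""
        mask = pd.Series(True, index=self.table.index)
        if background is not None:
            mask &= self.table["background"] == background
        if time_s is not None:
            mask &= self.table["time_s"] == time_s
        if bio_rep is not None:
            mask &= self.table["bio_rep"] == bio_rep
        return list(self.table.index[mask])

    def check_matches(self, table: IntensityTable) -> None:
        """Every intensity run must have exactly one design row."""
        missing = set(table.run_ids) - set(self.run_ids)
        if missing:
            raise ValueError(f"runs without design rows: {sorted(missing)}")


@dataclass
class NormalizedTable:
    """Log10 intensity matrix plus imputation mask and normalization audit.

    Before imputation ``log_data`` may contain ``NaN``; afterwards it is
    complete and ``imputed`` marks the filled cells. ``audit`` accumulates
    the per-run offsets and imputation parameters actually applied.
    """

    log_data: pd.DataFrame
    imputed: pd.DataFrame
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.imputed.shape != self.log_data.shape:
            raise ValueError("imputed mask shape must match log_data")
        obs = ~self.log_data.isna()
        if bool((self.imputed & ~obs).to_numpy().any()):
            raise ValueError("imputed mask marks cells that are still missing")

    def copy(self) -> "NormalizedTable":
        return NormalizedTable(self.log_data.copy(), self.imputed.copy(),
                               dict(self.audit))

    @property
    def is_complete(self) -> bool:
        return not bool(self.log_data.isna().to_numpy().any())


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Unordered symbol pair, case-normalized to upper case."""
    a, b = str(a).upper(), str(b).upper()
    return (a, b) if a <= b else (b, a)


@dataclass
class ReferenceInteractions:
    """Undirected set of known physical interactions keyed by gene symbol."""

    edges: set = field(default_factory=set)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ReferenceInteractions":
        edges = set()
        for a, b in pairs:
            e = canonical_edge(a, b)
            if e[0] != e[1]:  # no self-loops
                edges.add(e)
        return cls(edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.edges)

    def has(self, a: str, b: str) -> bool:
        return canonical_edge(a, b) in self.edges

    def among(self, nodes: Iterable[str]) -> "ReferenceInteractions":
        """Subset of edges whose both endpoints lie in ``nodes``."""
        keep = {str(n).upper() for n in nodes}
        return ReferenceInteractions(
            {e for e in self.edges if e[0] in keep and e[1] in keep})


@dataclass
class CorrelationNetwork:
    """Co-recruitment network: nodes are interactors, edges carry (R, P).

    Edges exist where the bootstrap-mean Pearson p-value beats the stored
    Bonferroni threshold ``p_star``; ``high_confidence`` flags R > ``hc_r``.
    """

    graph: nx.Graph
    alpha: float
    p_star: float
    hc_r: float = 0.8

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [canonical_edge(a, b) for a, b in self.graph.edges]

    def edge_data(self) -> pd.DataFrame:
        rows = []
        for a, b, d in self.graph.edges(data=True):
            a, b = canonical_edge(a, b)
            rows.append({"node_a": a, "node_b": b, "R": d["R"], "P": d["P"],
                         "high_confidence": bool(d["high_confidence"])})
        df = pd.DataFrame(rows, columns=["node_a", "node_b", "R", "P",
                                         "high_confidence"])
        return df.sort_values(["node_a", "node_b"]).reset_index(drop=True)

    def high_confidence_subnetwork(self) -> "CorrelationNetwork":
        sub = nx.Graph()
        sub.add_nodes_from(self.graph.nodes)
        for a, b, d in self.graph.edges(data=True):
            if d["high_confidence"]:
                sub.add_edge(a, b, **d)
        sub.graph.update(self.graph.graph)
        return CorrelationNetwork(sub, self.alpha, self.p_star, self.hc_r)
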