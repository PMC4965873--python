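"""Readers and writers for the pipeline's external formats.

Supported formats: MaxQuant ``proteinGroups``-style tab-separated tables
(columns ``Majority protein IDs``, ``Gene names``, ``Intensity <run>``,
``Reverse``, ``Potential contaminant``), a run-design TSV, reference
interaction lists (two-column or BioGRID tab-delimited), and network
output as GraphML plus a flat edge table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .model import (CorrelationNetwork, DESIGN_COLUMNS, IntensityTable,
                    ReferenceInteractions, SampleDesign, canonical_edge)

logger = logging.getLogger(__name__)

ID_COLUMN = "Majority protein IDs"
GENE_COLUMN = "Gene names"
INTENSITY_PREFIX = "Intensity "
REVERSE_COLUMN = "Reverse"
CONTAMINANT_COLUMN = "Potential contaminant"
BIOGRID_A = "Official Symbol Interactor A"
BIOGRID_B = "Official Symbol Interactor B"

# Ubiquitin is encoded by four genes (two as ribosomal fusions); peptide
# evidence is indexed under a single ubiquitin entry, so the default alias
# map collapses all four precursors to UB.
DEFAULT_ALIASES: dict[str, str] = {
    "UBA52": "UB", "RPS27A": "UB", "UBB": "UB", "UBC": "UB",
}


def _display_id(majority_ids: str, gene_names: str, id_policy: str) -> str:
    """Map a protein group to one display symbol.

    ``id_policy="gene-first"`` (default): first gene name if any, else the
    first accession. ``id_policy="accession"``: always the first accession.
    """
    accessions = [a for a in str(majority_ids).split(";") if a and a != "nan"]
    genes = [g for g in str(gene_names).split(";") if g and g != "nan"]
    if id_policy == "accession":
        chosen = accessions[0] if accessions else ""
    elif id_policy == "gene-first":
        chosen = genes[0] if genes else (accessions[0] if accessions else "")
    else:
        raise ValueError(f"unknown id_policy: {id_policy!r}")
    if not chosen:
        raise ValueError("protein group with neither gene name nor accession")
    return chosen.upper()


def read_protein_groups(path: str | Path, id_policy: str = "gene-first",
                        aliases: dict[str, str] | None = None) -> IntensityTable:
    """Read a MaxQuant proteinGroups-style TSV into an :class:`IntensityTable`.

    Reverse-decoy and contaminant-flagged rows are dropped, zeros become
    missing values, and protein groups sharing a display symbol (after
    alias mapping) are merged by summing intensities per run.
    """
    if aliases is None:
        aliases = DEFAULT_ALIASES
    df = pd.read_csv(path, sep="\t", dtype=str)
    if ID_COLUMN not in df.columns:
        raise ValueError(f"missing required column {ID_COLUMN!r}")
    intensity_cols = [c for c in df.columns if c.startswith(INTENSITY_PREFIX)
                      and c != INTENSITY_PREFIX.strip()]
    if not intensity_cols:
        raise ValueError("no 'Intensity <run>' columns found")
    run_ids = [c[len(INTENSITY_PREFIX):] for c in intensity_cols]
    if len(set(run_ids)) != len(run_ids):
        raise ValueError("duplicate run ids among intensity columns")

    for marker in (REVERSE_COLUMN, CONTAMINANT_COLUMN):
        if marker in df.columns:
            flagged = df[marker].fillna("").str.strip() == "+"
            if flagged.any():
                logger.info("dropping %d rows flagged in %r", int(flagged.sum()),
                            marker)
            df = df[~flagged]

    genes = df[GENE_COLUMN] if GENE_COLUMN in df.columns else pd.Series(
        "", index=df.index)
    symbols = [
        _display_id(m, g, id_policy) for m, g in zip(df[ID_COLUMN], genes)
    ]
    alias_upper = {k.upper(): v.upper() for k, v in aliases.items()}
    symbols = [alias_upper.get(s, s) for s in symbols]

    mat = df[intensity_cols].apply(pd.to_numeric, errors="coerce")
    mat.columns = run_ids
    mat = mat.mask(mat == 0.0)  # zero means "not quantified"
    mat.index = pd.Index(symbols, name="protein")
    # merge protein groups sharing a symbol by summing per run
    mat = mat.groupby(level=0, sort=True).sum(min_count=1)
    logger.info("read %d protein groups x %d runs from %s",
                mat.shape[0], mat.shape[1], path)
    return IntensityTable(mat)


def write_protein_groups(table: IntensityTable, path: str | Path) -> None:
    """Write an intensity table back out in proteinGroups-style TSV."""
    out = pd.DataFrame({
        ID_COLUMN: table.protein_ids,
        GENE_COLUMN: table.protein_ids,
        REVERSE_COLUMN: "",
        CONTAMINANT_COLUMN: "",
    })
    data = table.data.fillna(0.0)
    for run in table.run_ids:
        out[INTENSITY_PREFIX + run] = data[run].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"run": str})
    if "run" not in df.columns:
        raise ValueError("design table needs a 'run' column")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    df = df.set_index("run")
    df["time_s"] = df["time_s"].astype(float)
    df["bio_rep"] = df["bio_rep"].astype(int)
    df["tech_rep"] = df["tech_rep"].astype(int)
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.rename_axis("run").reset_index().to_csv(path, sep="\t",
                                                         index=False)


def read_reference(path: str | Path,
                   aliases: dict[str, str] | None = None) -> ReferenceInteractions:
    """Read a reference interaction list.

    Accepts either BioGRID tab-delimited files (using the official-symbol
    interactor columns) or a plain two-column symbol-pair TSV with or
    without a header. Pairs are case-normalized, alias-mapped, symmetry
    deduplicated, and self-loops dropped. An empty file yields an empty set.
    """
    if aliases is None:
        aliases = DEFAULT_ALIASES
    try:
        head = pd.read_csv(path, sep="\t", nrows=1)
    except pd.errors.EmptyDataError:
        return ReferenceInteractions(set())
    if BIOGRID_A in head.columns and BIOGRID_B in head.columns:
        df = pd.read_csv(path, sep="\t", dtype=str)
        a, b = df[BIOGRID_A], df[BIOGRID_B]
    else:
        header_tokens = {str(c).lower() for c in head.columns}
        has_header = bool(header_tokens & {"symbol_a", "symbol_b", "node_a",
                                           "node_b"})
        df = pd.read_csv(path, sep="\t", dtype=str,
                         header=0 if has_header else None)
        if df.shape[1] < 2:
            raise ValueError("reference file needs at least two columns")
        a, b = df.iloc[:, 0], df.iloc[:, 1]
    alias_upper = {k.upper(): v.upper() for k, v in aliases.items()}

    def _map(s: pd.Series) -> pd.Series:
        s = s.astype(str).str.upper()
        return s.map(lambda x: alias_upper.get(x, x))

    return ReferenceInteractions.from_pairs(zip(_map(a), _map(b)))


def write_reference(ref: ReferenceInteractions, path: str | Path) -> None:
    df = pd.DataFrame(sorted(ref.edges), columns=["symbol_a", "symbol_b"])
    df.to_csv(path, sep="\t", index=False)


def write_network(net: CorrelationNetwork, path: str | Path) -> None:
    """Serialize a correlation network as GraphML."""
    g = net.graph.copy()
    g.graph["alpha"] = float(net.alpha)
    g.graph["p_star"] = float(net.p_star)
    g.graph["hc_r"] = float(net.hc_r)
    for _, _, d in g.edges(data=True):
        d["R"] = float(d["R"])
        d["P"] = float(d["P"])
        d["high_confidence"] = bool(d["high_confidence"])
    nx.write_graphml(g, path)


def read_network(path: str | Path) -> CorrelationNetwork:
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, str)
    meta = g.graph
    return CorrelationNetwork(g, alpha=float(meta["alpha"]),
                              p_star=float(meta["p_star"]),
                              hc_r=float(meta.get("hc_r", 0.8)))


def write_edge_table(net: CorrelationNetwork, path: str | Path) -> None:
    net.edge_data().to_csv(path, sep="\t", index=False,
                           float_format="%.10g")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.10g")
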