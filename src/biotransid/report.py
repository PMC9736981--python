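"""Tabular reports, per-matrix summaries, and the metabolic pathway graph."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Sequence

import networkx as nx
import pandas as pd

from .annotate import AnnotatedMetabolite, AnnotationResult
from .formula import ElementalFormula
from .spectra import MATRICES, PLASMA_MATRICES

REPORT_COLUMNS = (
    "metabolite_id", "rt_min", "ion_formula", "theoretical_mz", "experimental_mz",
    "rdb", "ppm_error", "reaction_path", "ms2_evidence", "confidence", *MATRICES,
)


def write_report(result: AnnotationResult, path: str | Path) -> pd.DataFrame:
    """Write the metabolite report as TSV (m/z at 5 decimals, ppm at 3, RT at
    2; one row per annotated metabolite, ordered by RT then formula) and
    return the frame written. Two runs on identical inputs produce
    byte-identical files."""
    frame = result.to_frame()
    if frame.empty:
        frame = pd.DataFrame(columns=list(REPORT_COLUMNS))
    else:
        frame = frame[list(REPORT_COLUMNS)]
    frame.to_csv(path, sep="\t", index=False, float_format="%.5f")
    return frame


def read_report(path: str | Path) -> pd.DataFrame:
    """Re-read a report written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t")


def summarize_matrices(annotations: Sequence[AnnotatedMetabolite]) -> Dict[str, int]:
    """Distinct metabolites per matrix, plus the plasma union and the total."""
    counts = {m: 0 for m in MATRICES}
    plasma = 0
    for a in annotations:
        for m in MATRICES:
            counts[m] += a.matrix_presence[m]
        plasma += any(a.matrix_presence[m] for m in PLASMA_MATRICES)
    counts["plasma"] = plasma
    counts["total"] = len(annotations)
    return counts


def build_pathway_graph(
    annotations: Sequence[AnnotatedMetabolite],
    parent: ElementalFormula | None = None,
) -> nx.DiGraph:
    """Directed metabolic-pathway graph.

    Nodes are Hill formulas — the parent plus every intermediate and terminal
    formula on any annotated candidate's stored reaction path; each edge is
    one reaction step, labelled with the reaction name and multiplicity. The
    parent is the unique source.
    """
    graph = nx.DiGraph()
    if parent is None and annotations:
        parent = annotations[0].candidate.parent
    if parent is not None:
        graph.add_node(parent.hill(), role="parent")
    for a in annotations:
        current = a.candidate.parent
        for reaction, mult in a.candidate.path:
            product = current + reaction.add * mult - reaction.remove * mult
            graph.add_node(product.hill())
            graph.add_edge(
                current.hill(), product.hill(),
                reaction=reaction.name, multiplicity=mult, label=reaction.label,
            )
            current = product
        if current.hill() in graph.nodes:
            graph.nodes[current.hill()]["metabolite_id"] = a.metabolite_id
    return graph


def write_pathway_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    """Export the pathway graph as GraphML (lossless labelled edges)."""
    nx.write_graphml(graph, str(path))
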