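"""Trajectory graph composition and counting.

Significant directional pairs form a directed graph (nodes = concepts with
patient counts, edges = E1 -> E2 with RR and pair count). Longer candidate
trajectories are all simple directed paths of 2..max_len nodes; each is then
counted against the data: a unit realizes a trajectory when its first
occurrences follow the listed order with every adjacent gap inside the study
gap window, intermediate events being allowed.
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .io import SequencePanel
from .params import StudyParams


def build_graph(
    results: pd.DataFrame,
    panel: SequencePanel,
    min_edge_count: int = 0,
) -> nx.DiGraph:
    """Directed graph of pairs flagged ``significant_direction``.

    ``min_edge_count`` optionally hides less frequent pairs (display filter).
    Node attributes: ``patient_count``, ``name``; edge attributes: ``rr``,
    ``n_pair``.
    """
    g = nx.DiGraph()
    sig = results[results["significant_direction"]]
    for row in sig.itertuples():
        if row.n_pair < min_edge_count:
            continue
        for c in (row.e1, row.e2):
            if not g.has_node(int(c)):
                g.add_node(
                    int(c),
                    patient_count=panel.patient_count(int(c)),
                    name=panel.name_of(int(c)),
                )
        g.add_edge(int(row.e1), int(row.e2), rr=float(row.rr), n_pair=int(row.n_pair))
    return g


def compose_trajectories(g: nx.DiGraph, max_len: int = 5) -> list[tuple[int, ...]]:
    """All simple directed paths of 2..max_len nodes, in deterministic
    lexicographic (concept-id) order. Cycles are never traversed twice."""
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    paths: list[tuple[int, ...]] = []

    def extend(path: list[int]) -> None:
        if len(path) >= 2:
            paths.append(tuple(path))
        if len(path) == max_len:
            return
        for nxt in sorted(g.successors(path[-1])):
            if nxt not in path:  # simple-path rule: no repeated concept
                path.append(nxt)
                extend(path)
                path.pop()

    for start in sorted(g.nodes):
        extend([start])
    return sorted(paths)


def count_trajectory(
    concepts: Iterable[int], panel: SequencePanel, params: StudyParams
) -> int:
    """Units whose first occurrences realize the ordered concept chain.

    Every adjacent gap must lie in ``[min_gap_days, max_gap_days]``; other
    events between the listed concepts do not block a match. Each unit is
    counted at most once.
    """
    concepts = [int(c) for c in concepts]
    if len(concepts) < 2:
        raise ValueError("a trajectory needs at least 2 concepts")
    cols = np.stack([panel.col(c) for c in concepts], axis=1)
    gaps = np.diff(cols, axis=1)
    with np.errstate(invalid="ignore"):
        ok = (gaps >= params.min_gap_days) & (gaps <= params.gap_upper)
    return int(np.all(ok, axis=1).sum())


def count_all_trajectories(
    g: nx.DiGraph,
    panel: SequencePanel,
    params: StudyParams,
    include_unrealized: bool = False,
) -> pd.DataFrame:
    """Compose and count every candidate trajectory of the graph.

    Returns the ranked report: columns ``trajectory`` (tuple of concept
    ids), ``length``, ``n_patients``, sorted by descending count then
    lexicographic concept list. Composable but unrealized trajectories
    (count 0) are suppressed unless ``include_unrealized``.
    """
    rows = []
    for path in compose_trajectories(g, params.max_trajectory_len):
        n = count_trajectory(path, panel, params)
        if n > 0 or include_unrealized:
            rows.append({"trajectory": path, "length": len(path), "n_patients": n})
    df = pd.DataFrame(rows, columns=["trajectory", "length", "n_patients"])
    return rank_trajectories(df)


def rank_trajectories(
    counts: pd.DataFrame, prefix: Optional[tuple[int, ...]] = None
) -> pd.DataFrame:
    """Sort by descending patient count, ties by lexicographic concept list;
    optionally keep only trajectories starting with ``prefix``."""
    if len(counts) == 0:
        return counts.reset_index(drop=True)
    df = counts.copy()
    if prefix is not None:
        prefix = tuple(int(c) for c in prefix)
        df = df[df["trajectory"].map(lambda t: t[: len(prefix)] == prefix)]
    order = sorted(
        range(len(df)),
        key=lambda i: (-df["n_patients"].iloc[i], df["trajectory"].iloc[i]),
    )
    return df.iloc[order].reset_index(drop=True)


def mask_count(n: int, privacy_min_count: int) -> str:
    """Privacy mask: counts below the threshold print as ``<k``."""
    return str(int(n)) if n >= privacy_min_count or n == 0 else f"<{privacy_min_count}"


def export_graphml(g: nx.DiGraph, path) -> None:
    nx.write_graphml(g, path)


def export_dot(g: nx.DiGraph, path) -> None:
    """GraphViz DOT export; node size reflects the patient count and edge
    labels carry the relative risk."""
    counts = [d.get("patient_count", 1) for _, d in g.nodes(data=True)] or [1]
    cmax = max(max(counts), 1)
    lines = ["digraph trajectories {"]
    for n, d in sorted(g.nodes(data=True)):
        size = 0.5 + 1.5 * (d.get("patient_count", 1) / cmax)
        label = str(d.get("name", n)).replace('"', "'")
        lines.append(
            f'  "{n}" [label="{label}\\n(n={d.get("patient_count", "?")})", '
            f"width={size:.2f}, fixedsize=false];"
        )
    for u, v, d in sorted(g.edges(data=True)):
        lines.append(f'  "{u}" -> "{v}" [label="RR={d.get("rr", float("nan")):.2f}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
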