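"""Transformation graph and delta-pair chart tables.

The transformation graph has one node per fragment and one directed edge
per significant transformation, oriented toward the direction of increasing
property (or increasing active fraction for binary endpoints).  The
delta-pair table compares experimental against predicted per-pair effects;
sign-discordant pairs with large magnitude are mispredicted activity
cliffs.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .index import MatchedPair
from .stats import TransformationStats

__all__ = ["build_graph", "export_dot", "export_graphml", "delta_pair_table", "plot_delta_pairs"]


def _parse_id(transformation_id: str) -> tuple[str, str]:
    left, _, right = transformation_id.partition(">>")
    if not right:
        raise ValueError(f"malformed transformation id {transformation_id!r}")
    return left, right


def build_graph(stats: list[TransformationStats]) -> nx.DiGraph:
    """Directed fragment graph of one endpoint's significant transformations.

    Edges point toward the higher-property fragment: a positive mean delta
    in the canonical left -> right direction gives an edge left -> right,
    a negative one reverses it.  Binary endpoints orient toward the larger
    after-active fraction.  Mixed endpoints raise.
    """
    endpoints = {s.endpoint for s in stats}
    if len(endpoints) > 1:
        raise ValueError(f"graph must be built per endpoint, got {sorted(endpoints)}")
    graph = nx.DiGraph()
    if stats:
        graph.graph["endpoint"] = stats[0].endpoint
    for s in stats:
        left, right = _parse_id(s.transformation_id)
        if s.kind == "continuous":
            effect = s.mean_delta or 0.0
            forward = effect >= 0
        else:
            forward = (s.after_pos or 0) >= s.n_pos
            n_tot = max(s.N, 1)
            effect = ((s.after_pos or 0) - s.n_pos) / n_tot
        src, dst = (left, right) if forward else (right, left)
        graph.add_node(src)
        graph.add_node(dst)
        graph.add_edge(
            src,
            dst,
            endpoint=s.endpoint,
            effect=abs(effect),
            mean_delta=s.mean_delta if s.mean_delta is not None else "",
            significance_level=s.sig_level if s.sig_level is not None else 0.0,
            n_pairs=s.N,
            provenance_class=s.provenance_class,
        )
    return graph


def _dot_quote(s: str) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def export_dot(graph: nx.DiGraph, path: str | Path) -> None:
    """Write the graph in DOT format (node label = fragment notation)."""
    lines = ["digraph transformations {"]
    for node in graph.nodes:
        lines.append(f"  {_dot_quote(node)};")
    for src, dst, data in graph.edges(data=True):
        attrs = ", ".join(f"{k}={_dot_quote(v)}" for k, v in sorted(data.items()))
        lines.append(f"  {_dot_quote(src)} -> {_dot_quote(dst)} [{attrs}];")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def _quadrant(exp: float, pred: float) -> tuple[int, bool]:
    """Quadrant of the (experimental, predicted) sign pattern:
    (+,+)=1, (-,+)=2, (-,-)=3, (+,-)=4.  A zero delta is assigned the
    axis-adjacent quadrant with the lower index and flagged."""
    on_axis = exp == 0 or pred == 0
    if exp == 0 and pred == 0:
        return 1, True
    if exp == 0:
        return (1, True) if pred > 0 else (3, True)
    if pred == 0:
        return (1, True) if exp > 0 else (2, True)
    if exp > 0:
        return (1, False) if pred > 0 else (4, False)
    return (2, False) if pred > 0 else (3, False)


def delta_pair_table(
    pairs: list[MatchedPair], endpoint: str, cliff_threshold: float = 1.0
) -> pd.DataFrame:
    """Experimental vs predicted delta per pair, with quadrant assignment.

    Pairs missing either delta are skipped; the number skipped is stored in
    ``frame.attrs["n_skipped"]``.  A pair in quadrants 2 or 4 whose larger
    |delta| reaches ``cliff_threshold`` is a mispredicted activity cliff.
    """
    rows = []
    skipped = 0
    for pair in pairs:
        data = pair.deltas.get(endpoint)
        exp = data.experimental() if data is not None else None
        pred = data.predicted() if data is not None else None
        if exp is None or pred is None or exp.kind != "continuous":
            skipped += 1
            continue
        quadrant, on_axis = _quadrant(exp.delta, pred.delta)
        rows.append(
            {
                "pair_id": f"{pair.mol_a}|{pair.mol_b}|{pair.scaffold.notation}",
                "mol_a": pair.mol_a,
                "mol_b": pair.mol_b,
                "experimental_delta": exp.delta,
                "predicted_delta": pred.delta,
                "quadrant": quadrant,
                "on_axis": on_axis,
                "is_mispredicted_cliff": quadrant in (2, 4)
                and max(abs(exp.delta), abs(pred.delta)) >= cliff_threshold,
                "cliff_threshold": cliff_threshold,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "mol_a",
            "mol_b",
            "experimental_delta",
            "predicted_delta",
            "quadrant",
            "on_axis",
            "is_mispredicted_cliff",
            "cliff_threshold",
        ],
    )
    frame.attrs["n_skipped"] = skipped
    if not frame.empty:
        frame = frame.sort_values(
            "experimental_delta", key=lambda s: s.abs(), ascending=False
        ).reset_index(drop=True)
        frame.attrs["n_skipped"] = skipped
    return frame


def plot_delta_pairs(frame: pd.DataFrame, path: str | Path) -> None:
    """Static scatter of experimental vs predicted pair deltas."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    cliff = frame["is_mispredicted_cliff"]
    ax.scatter(
        frame.loc[~cliff, "experimental_delta"],
        frame.loc[~cliff, "predicted_delta"],
        s=12,
        alpha=0.6,
        label="concordant",
    )
    ax.scatter(
        frame.loc[cliff, "experimental_delta"],
        frame.loc[cliff, "predicted_delta"],
        s=16,
        color="crimson",
        label="mispredicted cliff",
    )
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("experimental pair delta")
    ax.set_ylabel("predicted pair delta")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
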