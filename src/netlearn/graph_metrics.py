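"""Percolation thresholding and weighted closeness centrality.

A session's connectivity matrix is first cleaned of its weakest edges by
percolation analysis: edges are removed in ascending weight order (ties
as one batch) until the graph would disconnect, and the last connected
state is kept.  The surviving minimum weight ``tau`` equals the maximin
bottleneck of the graph — the minimum edge weight on a maximum spanning
tree — which tests exploit as an independent oracle.

Node importance is then summarized by weighted closeness centrality

    C(i) = (N - 1) / sum_{j != i} l(i, j)

where the length of an edge is the reciprocal of its connectivity
weight (strong coupling = short path) and l(i, j) is the weighted
shortest-path distance, so multi-hop routes may beat direct edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .connectivity import CHANNELS_16, ConnectivityMatrix

logger = logging.getLogger(__name__)


@dataclass
class ThresholdedGraph:
    """A connectivity matrix with sub-threshold edges zeroed.

    ``tau`` is the smallest surviving edge weight; the graph restricted
    to edges >= tau is connected and removing the next-weakest weight
    class would disconnect it.
    """

    values: np.ndarray
    tau: float
    channel_labels: tuple[str, ...] = CHANNELS_16
    connected: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def _components(adj: np.ndarray) -> tuple[int, np.ndarray]:
    n, labels = connected_components(
        csr_matrix(adj > 0), directed=False, return_labels=True
    )
    return n, labels


def _component_members(
    labels: np.ndarray, names: Sequence[str]
) -> list[list[str]]:
    return [
        [names[i] for i in np.flatnonzero(labels == c)]
        for c in range(labels.max() + 1)
    ]


def percolation_threshold(
    m: ConnectivityMatrix | np.ndarray,
    channel_labels: Sequence[str] | None = None,
) -> ThresholdedGraph:
    """Remove the weakest edges while the graph stays connected.

    Edges are removed in ascending weight order, with equal-weight edges
    removed as a single batch so the result is order-independent; the
    last connected state is returned and ``tau`` is its minimum
    surviving weight.  An already-disconnected input is an error naming
    the components.
    """
    if isinstance(m, ConnectivityMatrix):
        A = m.values.copy()
        labels = m.channel_labels
    else:
        A = np.asarray(m, dtype=float).copy()
        labels = tuple(
            channel_labels
            if channel_labels is not None
            else [f"n{i}" for i in range(A.shape[0])]
        )
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    np.fill_diagonal(A, 0.0)
    n_comp, comp = _components(A)
    if n_comp > 1:
        raise ValueError(
            "input graph is disconnected; components: "
            f"{_component_members(comp, labels)}"
        )
    weights = np.unique(A[np.triu_indices_from(A, k=1)])
    weights = weights[weights > 0]
    # Connectivity of {edges >= t} is monotone decreasing in t: find the
    # largest weight class whose induced graph is still connected.
    tau = weights[0]
    for t in weights[1:]:
        if _components(np.where(A >= t, A, 0.0))[0] == 1:
            tau = t
        else:
            break
    values = np.where(A >= tau, A, 0.0)
    return ThresholdedGraph(
        values=values, tau=float(tau), channel_labels=labels, connected=True
    )


def closeness(g: ThresholdedGraph | np.ndarray) -> pd.Series:
    """Weighted closeness centrality per node.

    Edge lengths are reciprocal weights; distances come from Dijkstra's
    algorithm, so indirect routes through strong edges are used when
    they are shorter than a weak direct edge.  Raises on a disconnected
    graph (path lengths would be infinite).
    """
    if isinstance(g, ThresholdedGraph):
        A = g.values
        labels = g.channel_labels
    else:
        A = np.asarray(g, dtype=float)
        labels = tuple(f"n{i}" for i in range(A.shape[0]))
    n = A.shape[0]
    n_comp, comp = _components(A)
    if n_comp > 1:
        raise ValueError(
            "graph is disconnected; closeness undefined "
            f"(components: {_component_members(comp, labels)})"
        )
    with np.errstate(divide="ignore"):
        lengths = np.where(A > 0, 1.0 / A, 0.0)
    dist = dijkstra(csr_matrix(lengths), directed=False)
    C = (n - 1) / dist.sum(axis=1)
    return pd.Series(C, index=list(labels), name="closeness")


def node_closeness_table(
    mats: Iterable[ConnectivityMatrix],
    percolation: bool = True,
) -> pd.DataFrame:
    """Tidy closeness table over subject x session x band matrices.

    Each matrix is percolation-thresholded (unless ``percolation=False``,
    which computes closeness on the raw weights) and the per-node
    closeness is emitted as rows (subject, session, band, node,
    closeness, tau).
    """
    rows = []
    for m in mats:
        if percolation:
            g = percolation_threshold(m)
            tau = g.tau
            C = closeness(g)
        else:
            tau = np.nan
            C = closeness(
                ThresholdedGraph(
                    values=m.values, tau=np.nan,
                    channel_labels=m.channel_labels,
                )
            )
        for node, c in C.items():
            rows.append(
                {
                    "subject": m.subject,
                    "session": m.session,
                    "band": m.band,
                    "node": node,
                    "closeness": float(c),
                    "tau": tau,
                }
            )
    return pd.DataFrame(rows)
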