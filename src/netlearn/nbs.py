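"""Network-based statistic: edge-level session contrasts with
family-wise error control by permutation.

The NBS tests the null hypothesis that every edge's connectivity has
equal means across two sessions.  A paired t statistic is computed per
unique edge from the within-subject (post - pre) differences; edges
beyond a component-forming threshold T form a supra-threshold graph
whose connected components are the candidate subnetworks.  Family-wise
error over the 120 edges is controlled by permutation: sessions are
repeated measures of one cohort, so each permutation flips the sign of
every subject's difference matrix (within-subject relabeling), and the
maximal component extent (edge count) is recorded.  A component's
p-value is the fraction of the null reference at or above its extent;
the observed labeling is part of the reference, so p > 0 always.

When the sign-flip space is small (2^n <= k) it is enumerated exactly;
otherwise k flips are sampled from a seeded generator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .connectivity import CHANNELS_16, ConnectivityMatrix

logger = logging.getLogger(__name__)

_TAILS = ("increase", "decrease", "both")


@dataclass(frozen=True)
class NBSConfig:
    """Settings for one NBS run.

    T is the component-forming threshold on the paired t statistic, k
    the number of permutations, alpha the significance level and tail
    the direction of the session contrast ("decrease" flags post < pre).
    """

    T: float = 2.75
    k: int = 100_000
    alpha: float = 0.05
    tail: str = "decrease"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.k < 100:
            raise ValueError("k must be at least 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tail not in _TAILS:
            raise ValueError(f"tail must be one of {_TAILS}")


@dataclass
class NBSResult:
    """Observed statistics, supra-threshold components and their p-values."""

    t_matrix: np.ndarray
    components: list[list[tuple[str, str]]]
    extents: list[int]
    p_values: list[float]
    null_max_extents: np.ndarray
    significant: list[bool]
    exact: bool
    config: NBSConfig
    channel_labels: tuple[str, ...] = CHANNELS_16

    @property
    def any_significant(self) -> bool:
        return any(self.significant)


def _coerce_stack(
    stack,
) -> tuple[np.ndarray, list[str] | None, tuple[str, ...]]:
    """Accept a list of ConnectivityMatrix or an (n, c, c) array."""
    if isinstance(stack, np.ndarray):
        arr = np.asarray(stack, dtype=float)
        if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
            raise ValueError("array stack must have shape (n_subjects, c, c)")
        labels = tuple(f"n{i}" for i in range(arr.shape[1]))
        return arr, None, labels
    mats: Sequence[ConnectivityMatrix] = list(stack)
    if not mats:
        raise ValueError("empty stack")
    labels = mats[0].channel_labels
    arr = np.stack([m.values for m in mats])
    subjects = [m.subject for m in mats]
    return arr, subjects, labels


def _paired_t(d: np.ndarray) -> np.ndarray:
    """Paired t statistics per column of an (n, e) difference matrix.

    Columns with zero variance get t = 0 (logged); the mean difference
    alone carries no calibrated evidence there.
    """
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning(
            "paired t: %d edges with zero-variance differences set to 0",
            int(zero.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero, 0.0, mean / (sd / np.sqrt(n)))
    return t


def edge_stats(pre, post) -> np.ndarray:
    """Paired t statistic per edge of matched pre/post stacks.

    Differences are post - pre per subject; stacks must list the same
    subjects in the same order.  Returns a symmetric (c, c) matrix with
    zero diagonal.
    """
    pre_arr, pre_subj, labels = _coerce_stack(pre)
    post_arr, post_subj, _ = _coerce_stack(post)
    if pre_arr.shape != post_arr.shape:
        raise ValueError("pre and post stacks differ in shape")
    if pre_arr.shape[0] < 2:
        raise ValueError("need at least 2 subjects for a paired t statistic")
    if pre_subj is not None and post_subj is not None and pre_subj != post_subj:
        raise ValueError(
            f"subject mismatch between stacks: {pre_subj} vs {post_subj}"
        )
    c = pre_arr.shape[1]
    iu, ju = np.triu_indices(c, k=1)
    d = (post_arr - pre_arr)[:, iu, ju]
    t = _paired_t(d)
    t_matrix = np.zeros((c, c))
    t_matrix[iu, ju] = t
    t_matrix[ju, iu] = t
    return t_matrix


def _supra_mask(t: np.ndarray, T: float, tail: str) -> np.ndarray:
    if tail == "increase":
        return t >= T
    if tail == "decrease":
        return t <= -T
    return np.abs(t) >= T


def _max_component_extent(
    rows: np.ndarray, cols: np.ndarray, n_nodes: int
) -> int:
    """Largest edge count among connected components of an edge list
    (union-find; used in the permutation loop)."""
    parent = list(range(n_nodes))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in zip(rows, cols):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    counts: dict[int, int] = {}
    best = 0
    for i in rows:
        r = find(i)
        counts[r] = counts.get(r, 0) + 1
        if counts[r] > best:
            best = counts[r]
    return best


def _sign_matrix(n: int, cfg: NBSConfig) -> tuple[np.ndarray, bool]:
    """All 2^n sign-flip patterns when affordable, else k sampled ones."""
    if 2 ** n <= cfg.k:
        bits = np.arange(2 ** n, dtype=np.int64)
        signs = 1.0 - 2.0 * (
            (bits[:, None] >> np.arange(n)[None, :]) & 1
        ).astype(float)
        return signs, True
    rng = np.random.default_rng(cfg.seed)
    signs = rng.choice([-1.0, 1.0], size=(cfg.k, n))
    return signs, False


def nbs_test(pre, post, cfg: NBSConfig = NBSConfig()) -> NBSResult:
    """Run the network-based statistic on matched pre/post stacks.

    Steps: (1) paired t per edge; (2) supra-threshold graph in the
    configured tail and its connected components with extents;
    (3) within-subject sign-flip permutations recording the maximal
    null component extent; (4) p per component as the fraction of the
    null reference (observed labeling included) at or above its extent;
    components with p < alpha are flagged significant.
    """
    pre_arr, pre_subj, labels = _coerce_stack(pre)
    post_arr, post_subj, labels2 = _coerce_stack(post)
    if pre_subj is None:
        labels = labels2 if post_subj is not None else labels
    t_matrix = edge_stats(pre, post)
    n = pre_arr.shape[0]
    c = pre_arr.shape[1]
    if n < 5:
        warnings.warn(
            f"only {n} subjects: the sign-flip space has 2^{n} elements, "
            "limiting attainable p-values",
            stacklevel=2,
        )
    if 1.0 / (cfg.k + 1) > cfg.alpha:
        warnings.warn(
            f"k={cfg.k} cannot resolve alpha={cfg.alpha} "
            f"(smallest attainable p is {1 / (cfg.k + 1):.3g})",
            stacklevel=2,
        )

    iu, ju = np.triu_indices(c, k=1)
    d = (post_arr - pre_arr)[:, iu, ju]

    # Observed components via networkx on the supra-threshold graph.
    sup = _supra_mask(t_matrix[iu, ju], cfg.T, cfg.tail)
    G = nx.Graph()
    G.add_nodes_from(range(c))
    G.add_edges_from(zip(iu[sup], ju[sup]))
    components: list[list[tuple[str, str]]] = []
    extents: list[int] = []
    for nodes in nx.connected_components(G):
        if len(nodes) < 2:
            continue
        edges = [
            (labels[i], labels[j])
            for i, j in zip(iu[sup], ju[sup])
            if i in nodes and j in nodes
        ]
        components.append(sorted(edges))
        extents.append(len(edges))

    # Permutation null of maximal component extents.  Sign flips leave
    # each d_i^2 unchanged, so only the permuted mean must be recomputed.
    signs, exact = _sign_matrix(n, cfg)
    k_eff = signs.shape[0]
    sumsq = (d ** 2).sum(axis=0)
    mean_p = signs @ d / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var_p = (sumsq - n * mean_p ** 2) / (n - 1)
        t_p = np.where(var_p > 0, mean_p / np.sqrt(var_p / n), 0.0)
    sup_p = _supra_mask(t_p, cfg.T, cfg.tail)
    null_max = np.zeros(k_eff, dtype=int)
    counts = sup_p.sum(axis=1)
    for row in np.flatnonzero(counts):
        cnt = counts[row]
        if cnt == 1:
            null_max[row] = 1
        else:
            e = np.flatnonzero(sup_p[row])
            null_max[row] = _max_component_extent(iu[e], ju[e], c)

    p_values = []
    for ext in extents:
        exceed = int((null_max >= ext).sum())
        if exact:
            p = exceed / k_eff
        else:
            p = (1 + exceed) / (k_eff + 1)
        p_values.append(float(p))
    significant = [p < cfg.alpha for p in p_values]
    return NBSResult(
        t_matrix=t_matrix,
        components=components,
        extents=extents,
        p_values=p_values,
        null_max_extents=null_max,
        significant=significant,
        exact=exact,
        config=cfg,
        channel_labels=labels,
    )


def result_to_dict(res: NBSResult) -> dict:
    """JSON-serializable summary of an NBS result."""
    return {
        "T": res.config.T,
        "k": res.config.k,
        "alpha": res.config.alpha,
        "tail": res.config.tail,
        "exact": res.exact,
        "n_permutations": int(res.null_max_extents.shape[0]),
        "components": [
            {
                "edges": [list(e) for e in comp],
                "extent": ext,
                "p_value": p,
                "significant": sig,
            }
            for comp, ext, p, sig in zip(
                res.components, res.extents, res.p_values, res.significant
            )
        ],
        "any_significant": res.any_significant,
    }
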