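"""Neighbor-joining cluster trees, nonparametric bootstrap, Newick output.

Trees here are clustering visualisations of distance matrices, not
phylogenies: no rooting, no model-based inference.  The agglomeration is the
Saitou–Nei criterion with a fixed deterministic tie-break (row-major minimum
of the Q matrix, i.e. lower first index, then lower second index, over the
current node order where merged nodes are appended last).  Negative branch
lengths are clamped to zero with a log note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix, encode_rows, pairwise_matrix
from .errors import TreeError

logger = logging.getLogger(__name__)

_NEWICK_UNSAFE = set(" (){}[],:;'\t\n")


@dataclass
class Tree:
    """Unrooted tree over labelled leaves.

    Leaves are nodes ``0..n-1`` in label order; internal nodes follow.
    ``support`` maps a canonical bipartition (frozenset of leaf labels on the
    side not containing the first label) to a percentage in [0, 100].
    """

    labels: list[str]
    edges: list[tuple[int, int, float]]
    support: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for bp, s in self.support.items():
            if not 0.0 <= s <= 100.0:
                raise TreeError(f"support {s} outside [0, 100] for {sorted(bp)}")

    # -- topology queries ---------------------------------------------------

    def _adjacency(self) -> dict[int, list[tuple[int, int]]]:
        adj: dict[int, list[tuple[int, int]]] = {}
        for k, (u, v, _) in enumerate(self.edges):
            adj.setdefault(u, []).append((v, k))
            adj.setdefault(v, []).append((u, k))
        return adj

    def _leafset_below(self, adj, start: int, blocked_edge: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nxt, k in adj[node]:
                if k == blocked_edge or nxt in seen:
                    continue
                seen.add(nxt)
                stack.append(nxt)
        return {x for x in seen if x < len(self.labels)}

    def bipartitions(self, include_trivial: bool = False) -> dict[frozenset, int]:
        """Canonical bipartition → edge index for every (internal) edge."""
        n = len(self.labels)
        adj = self._adjacency()
        out: dict[frozenset, int] = {}
        for k, (u, v, _) in enumerate(self.edges):
            side = self._leafset_below(adj, u, k)
            if 0 in side:
                side = set(range(n)) - side
            if not include_trivial and min(len(side), n - len(side)) < 2:
                continue
            out[frozenset(self.labels[i] for i in side)] = k
        return out

    def is_exclusive(self, label_subset) -> bool:
        """True iff some edge bipartition isolates exactly this subset."""
        subset = frozenset(label_subset)
        if not subset:
            raise TreeError("empty label subset")
        unknown = subset - set(self.labels)
        if unknown:
            raise TreeError(f"unknown labels: {sorted(unknown)}")
        if len(subset) in (1, len(self.labels)):
            return True
        complement = frozenset(self.labels) - subset
        bps = self.bipartitions()
        return subset in bps or complement in bps

    # -- Newick -------------------------------------------------------------

    @staticmethod
    def _quote(label: str) -> str:
        if set(label) & _NEWICK_UNSAFE:
            return "'" + label.replace("'", "''") + "'"
        return label

    def to_newick(self) -> str:
        n = len(self.labels)
        adj = self._adjacency()
        root = max(adj)
        if root < n:  # degenerate: leaf-only tree
            root = 0
        bps = self.bipartitions()
        edge_support = {k: s for bp, k in bps.items() for s in [self.support.get(bp)]}

        def render(node: int, via_edge: int | None) -> str:
            children = [(nxt, k) for nxt, k in adj[node] if k != via_edge]
            if node < n and not children:
                length = self.edges[via_edge][2] if via_edge is not None else 0.0
                return f"{self._quote(self.labels[node])}:{length:.10g}"
            parts = ",".join(render(c, k) for c, k in sorted(children))
            label = ""
            if via_edge is not None:
                s = edge_support.get(via_edge)
                if s is not None:
                    label = f"{s:.10g}"
                length = self.edges[via_edge][2]
                return f"({parts}){label}:{length:.10g}"
            return f"({parts}){label}"

        return render(root, None) + ";"


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamp(length: float) -> float:
    if length < 0.0:
        logger.debug("negative NJ branch length %.6g clamped to 0", length)
        return 0.0
    return length


def _q_argmin(D: np.ndarray) -> tuple[int, int]:
    k = D.shape[0]
    r = D.sum(axis=1)
    Q = (k - 2) * D - r[:, None] - r[None, :]
    np.fill_diagonal(Q, np.inf)
    flat = int(np.argmin(Q))  # row-major => lower i, then lower j
    return flat // k, flat % k


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking."""
    n = len(matrix.labels)
    if n < 3:
        raise TreeError("nj_tree needs at least 3 labels")
    if np.isnan(matrix.values).any():
        raise TreeError("distance matrix contains undefined entries")

    D = matrix.values.astype(np.float64).copy()
    nodes = list(range(n))
    next_id = n
    edges: list[tuple[int, int, float]] = []

    while len(nodes) > 3:
        k = len(nodes)
        i, j = _q_argmin(D)
        r = D.sum(axis=1)
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        edges.append((nodes[i], next_id, _clamp(li)))
        edges.append((nodes[j], next_id, _clamp(lj)))
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(k) if x not in (i, j)]
        D2 = np.empty((k - 1, k - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row[keep]
        D2[:-1, -1] = new_row[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [next_id]
        next_id += 1

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    center = next_id
    edges.append((a, center, _clamp(0.5 * (dab + dac - dbc))))
    edges.append((b, center, _clamp(0.5 * (dab + dbc - dac))))
    edges.append((c, center, _clamp(0.5 * (dac + dbc - dab))))
    return Tree(labels=list(matrix.labels), edges=edges)


def nj_join_order(D: np.ndarray) -> list[tuple[int, int, int]]:
    """Pure agglomeration schedule of NJ, down to a single node.

    Returns ``(node_a, node_b, new_node)`` triples over ids where the first
    ``n`` ids are the input rows.  Used as the guide for progressive
    alignment.
    """
    n = D.shape[0]
    D = D.astype(np.float64).copy()
    nodes = list(range(n))
    next_id = n
    joins: list[tuple[int, int, int]] = []
    while len(nodes) > 1:
        if len(nodes) == 2:
            i, j = 0, 1
        else:
            i, j = _q_argmin(D)
        dij = D[i, j]
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(len(nodes)) if x not in (i, j)]
        joins.append((nodes[i], nodes[j], next_id))
        k = len(nodes)
        D2 = np.empty((k - 1, k - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row[keep]
        D2[:-1, -1] = new_row[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [next_id]
        next_id += 1
    return joins


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _matrix_from_encoded(enc: np.ndarray, labels: list[str], metric: str):
    from . import distances as _d

    if (enc == _d._EXCLUDED).any():
        ts, tv, compared = _d._pair_counts_loop(enc)
    else:
        ts, tv, compared = _d._pair_counts_dense(enc)
    ts = ts.astype(np.float64)
    tv = tv.astype(np.float64)
    compared = compared.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "p":
            values = np.where(compared > 0, (ts + tv) / compared, np.nan)
        else:
            P, Q = ts / compared, tv / compared
            w = (1.0 - 2.0 * P - Q) * np.sqrt(1.0 - 2.0 * Q)
            values = np.where((compared > 0) & (w > 0), -0.5 * np.log(w), np.nan)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=labels, values=values, metric=metric)


def bootstrap_support(
    alignment,
    metric: str,
    replicates: int,
    seed: int,
) -> tuple[Tree, int]:
    """Bootstrap support mapped onto the point-estimate NJ tree.

    Columns are resampled with replacement per replicate; support is the
    percentage of analysable replicate trees containing each non-trivial
    bipartition of the point tree.  Replicates whose resampled matrix has an
    undefined pair are skipped and counted.  Returns (tree, n_skipped).
    """
    if replicates < 1:
        raise TreeError("replicates must be >= 1")
    labels = [rid for rid, _ in alignment.rows]
    enc = encode_rows([r for _, r in alignment.rows])
    L = enc.shape[1]
    point = nj_tree(pairwise_matrix(alignment, metric))
    targets = set(point.bipartitions())
    counts = {bp: 0 for bp in targets}

    rng = np.random.default_rng(seed)
    skipped = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        sub = enc[:, cols]
        mat = _matrix_from_encoded(sub, labels, metric)
        if np.isnan(mat.values).any():
            skipped += 1
            continue
        rep_bps = set(nj_tree(mat).bipartitions())
        for bp in targets & rep_bps:
            counts[bp] += 1
    valid = replicates - skipped
    if skipped:
        logger.warning("bootstrap: %d of %d replicates skipped", skipped, replicates)
    if valid == 0:
        raise TreeError("all bootstrap replicates had undefined distances")
    point.support = {bp: 100.0 * c / valid for bp, c in counts.items()}
    return point, skipped
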