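"""Distance-based phylogenetics: p/JC distances, neighbor joining,
nonparametric bootstrap, midpoint rooting, and reference-based genome
constitution assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import align
from .records import ItsRecord, MsaBlock
from .trees import PhyloTree, TreeNode

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class DistanceError(ValueError):
    pass


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites, pairwise deletion of gap/N columns."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must be aligned")
    diffs = compared = 0
    for x, y in zip(row_a, row_b):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise DistanceError("zero compared sites")
    return diffs / compared


def jc_distance(p: float, saturation_ceiling: float | None = None) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3).

    p >= 0.75 is saturated: raises unless a `saturation_ceiling` distance
    is configured, which is then substituted.
    """
    if p < 0:
        raise DistanceError(f"negative p-distance {p}")
    if p >= 0.75:
        if saturation_ceiling is not None:
            return saturation_ceiling
        raise DistanceError(f"p-distance {p} >= 0.75: Jukes-Cantor saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray
    model: str  # "p" or "jc"

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite distances")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("nonzero diagonal")


def _encode(msa: MsaBlock) -> np.ndarray:
    codes = np.full((msa.n_rows, msa.n_cols), -1, dtype=np.int8)
    for i, row in enumerate(msa.rows):
        for j, ch in enumerate(row):
            codes[i, j] = _CODE.get(ch, -1)
    return codes


def _pairwise_p(codes: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        a = codes[i]
        for j in range(i + 1, n):
            b = codes[j]
            valid = (a >= 0) & (b >= 0)
            compared = int(valid.sum())
            if compared == 0:
                raise DistanceError(f"pair ({i},{j}) has zero compared sites")
            p = int(((a != b) & valid).sum()) / compared
            out[i, j] = out[j, i] = p
    return out


def distance_matrix(
    msa: MsaBlock, model: str = "jc", saturation_ceiling: float | None = None
) -> DistanceMatrix:
    if model not in ("p", "jc"):
        raise ValueError(f"unknown model {model!r}")
    p = _pairwise_p(_encode(msa))
    if model == "jc":
        n = p.shape[0]
        d = np.zeros_like(p)
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = jc_distance(p[i, j], saturation_ceiling)
    else:
        d = p
    return DistanceMatrix(labels=tuple(msa.labels), matrix=d, model=model)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei NJ with deterministic tie-breaking.

    Ties in the Q criterion break on the lexicographically smallest pair of
    subtree keys (a subtree's key is its smallest leaf label).  Negative
    branch lengths are clamped to zero with the deficit logged.  The result
    is unrooted: the root node has three children.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    D = dm.matrix.astype(float).copy()
    nodes = [TreeNode(label=lab) for lab in dm.labels]
    keys = [lab for lab in dm.labels]

    def clamp(x: float) -> float:
        if x < 0:
            logger.info("clamped negative branch length %.6g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] <= qmin + 1e-12:
                    pair_key = tuple(sorted((keys[i], keys[j])))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, i, j)
        _, i, j = best
        dij = D[i, j]
        li = clamp(0.5 * dij + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj

        new_row = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[m - 2, : m - 2] = D2[: m - 2, m - 2] = new_row[keep]
        D2[m - 2, m - 2] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final three-way join: l_a = (d_ab + d_ac - d_bc) / 2 etc.
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root=root, rooted=False)


def nj_from_msa(msa: MsaBlock, model: str = "jc",
                saturation_ceiling: float | None = None) -> PhyloTree:
    return neighbor_joining(distance_matrix(msa, model, saturation_ceiling))


def bootstrap_support(
    msa: MsaBlock,
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "jc",
    saturation_ceiling: float | None = 5.0,
) -> PhyloTree:
    """NJ tree with supports = percent of column-resampled replicates
    containing each original internal bipartition."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if msa.n_rows < 4:
        raise ValueError("bootstrap needs at least 4 rows")
    tree = nj_from_msa(msa, model, saturation_ceiling)
    labels = tuple(msa.labels)
    codes = _encode(msa)
    rng = np.random.default_rng(seed)

    counts: dict[frozenset[str], int] = {split: 0 for split in tree.bipartitions()}
    for _ in range(n_replicates):
        idx = rng.integers(0, msa.n_cols, size=msa.n_cols)
        p = _pairwise_p(codes[:, idx])
        if model == "jc":
            m = p.shape[0]
            d = np.zeros_like(p)
            for i in range(m):
                for j in range(i + 1, m):
                    d[i, j] = d[j, i] = jc_distance(p[i, j], saturation_ceiling)
        else:
            d = p
        rep_tree = neighbor_joining(DistanceMatrix(labels, d, model))
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1

    all_labels = frozenset(labels)
    anchor = min(all_labels)

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if node is not tree.root and 1 < len(below) < len(all_labels) - 1:
            side = below if anchor not in below else all_labels - below
            node.support = 100.0 * counts[side] / n_replicates
        return below

    annotate(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Midpoint rooting
# ---------------------------------------------------------------------------

def _adjacency(tree: PhyloTree):
    """Undirected view: node -> list of (neighbor, length, support_on_edge)."""
    adj: dict[int, list[tuple[TreeNode, float, float | None]]] = {}
    index: dict[int, TreeNode] = {}

    def add(u: TreeNode, v: TreeNode, length: float, support: float | None):
        adj.setdefault(id(u), []).append((v, length, support))
        adj.setdefault(id(v), []).append((u, length, support))
        index[id(u)] = u
        index[id(v)] = v

    def walk(node: TreeNode):
        for child in node.children:
            add(node, child, child.length, child.support)
            walk(child)

    walk(tree.root)
    return adj, index


def _farthest_leaf(start: TreeNode, adj) -> tuple[TreeNode, float, list]:
    """DFS: farthest leaf from `start`, its distance, and the path edges."""
    best = (start, 0.0, [])
    stack = [(start, None, 0.0, [])]
    while stack:
        node, parent, dist, path = stack.pop()
        if node.is_leaf and node is not start and dist > best[1]:
            best = (node, dist, path)
        for nb, length, support in adj[id(node)]:
            if nb is parent:
                continue
            stack.append((nb, node, dist + length, path + [(node, nb, length, support)]))
    return best


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    lengths = [n.length for n in tree.root.walk() if n is not tree.root]
    if not any(l > 0 for l in lengths):
        raise ValueError("cannot midpoint-root a tree with all-zero branch lengths")
    adj, _ = _adjacency(tree)
    leaves = tree.leaves()
    # two-sweep diameter search
    end_a, _, _ = _farthest_leaf(leaves[0], adj)
    end_b, diameter, path = _farthest_leaf(end_a, adj)
    half = diameter / 2.0

    # locate the edge on the path containing the midpoint
    acc = 0.0
    for u, v, length, support in path:
        if acc + length >= half - 1e-12:
            offset = half - acc  # distance from u along (u, v)
            return _reroot_on_edge(u, v, offset, length, support, adj)
        acc += length
    raise AssertionError("midpoint not found on diameter path")


def _build_subtree(node: TreeNode, parent: TreeNode, adj) -> TreeNode:
    new = TreeNode(label=node.label)
    for nb, length, support in adj[id(node)]:
        if nb is parent:
            continue
        child = _build_subtree(nb, node, adj)
        child.length = length
        child.support = support
        new.children.append(child)
    return new


def _reroot_on_edge(
    u: TreeNode, v: TreeNode, offset: float, length: float, support: float | None, adj
) -> PhyloTree:
    eps = 1e-12
    if offset <= eps and not u.is_leaf:
        root = _build_subtree(u, None, adj)
        return PhyloTree(root=root, rooted=True)
    if offset >= length - eps and not v.is_leaf:
        root = _build_subtree(v, None, adj)
        return PhyloTree(root=root, rooted=True)
    left = _build_subtree(u, v, adj)
    right = _build_subtree(v, u, adj)
    left.length = offset
    right.length = length - offset
    right.support = support
    left.support = support
    root = TreeNode(children=[left, right])
    return PhyloTree(root=root, rooted=True)


# ---------------------------------------------------------------------------
# Genome constitution assignment
# ---------------------------------------------------------------------------

@dataclass
class GenomeAssignment:
    query_id: str
    genome: str
    margin: float
    ambiguous: bool
    mean_distances: dict[str, float]


DEFAULT_MARGIN_FLOOR = 0.005


def assign_genome(
    query_types: list[ItsRecord],
    reference_msa: MsaBlock,
    reference_labels: dict[str, str],
    margin_floor: float = DEFAULT_MARGIN_FLOOR,
    saturation_ceiling: float | None = 5.0,
) -> list[GenomeAssignment]:
    """Assign each query the genome label of the reference group with the
    smallest mean JC distance; flag assignments with a thin margin."""
    missing = [lab for lab in reference_msa.labels if lab not in reference_labels]
    if missing:
        raise ValueError(f"references without genome label: {', '.join(missing)}")

    out: list[GenomeAssignment] = []
    for query in query_types:
        merged = align.align_to_msa(reference_msa, query)
        qrow = merged.rows[merged.labels.index(query.id)]
        by_genome: dict[str, list[float]] = {}
        for lab in reference_msa.labels:
            d = jc_distance(p_distance(merged.row(lab), qrow), saturation_ceiling)
            by_genome.setdefault(reference_labels[lab], []).append(d)
        means = {g: float(np.mean(ds)) for g, ds in by_genome.items()}
        ranked = sorted(means.items(), key=lambda kv: kv[1])
        best_genome, best_d = ranked[0]
        margin = (ranked[1][1] - best_d) if len(ranked) > 1 else math.inf
        out.append(
            GenomeAssignment(
                query_id=query.id,
                genome=best_genome,
                margin=margin,
                ambiguous=margin < margin_floor,
                mean_distances=means,
            )
        )
    return out
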