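"""Distance / neighbor-joining / bootstrap engine.

Implements p, Jukes-Cantor and Kimura 2-parameter distances with pairwise
deletion of gap/ambiguity columns, classic neighbor joining with a
deterministic tie rule, column-resampling bootstrap supports, monophyly
queries and Newick serialization.  Written from scratch so the tree stage
has no hidden dependency on an external inference package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, SaturationError
from .seqio import SpeciesAlignment, validate_dna

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "p_distance",
    "jc_distance",
    "k2p_distance",
    "build_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "is_monophyletic",
    "tree_to_newick",
    "write_newick",
    "write_distance_tsv",
]

MODELS = ("p", "jc", "k2p")

# base -> small int; anything ambiguous/gap -> -1 (pairwise-deleted)
_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_IS_PURINE = np.array([True, False, True, False])  # A C G T


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(validate_dna(seq).encode("ascii"), dtype=np.uint8)]


def _pq_counts(a: np.ndarray, b: np.ndarray) -> tuple:
    """(n_valid, n_transitions, n_transversions) under pairwise deletion."""
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise SaturationError("no comparable sites between the two sequences")
    av, bv = a[valid], b[valid]
    diff = av != bv
    same_class = _IS_PURINE[av] == _IS_PURINE[bv]
    ts = int((diff & same_class).sum())
    tv = int((diff & ~same_class).sum())
    return n, ts, tv


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among sites unambiguous in both."""
    ea, eb = _encode(a), _encode(b)
    if len(ea) != len(eb):
        raise ConfigurationError("sequences have unequal lengths")
    n, ts, tv = _pq_counts(ea, eb)
    return (ts + tv) / n


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor correction: -(3/4) ln(1 - 4p/3)."""
    p = p_distance(a, b)
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        raise SaturationError(f"JC distance undefined at p={p:.4f}")
    return -0.75 * math.log(arg)


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter: -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q)
    with P the transition and Q the transversion fraction."""
    ea, eb = _encode(a), _encode(b)
    if len(ea) != len(eb):
        raise ConfigurationError("sequences have unequal lengths")
    n, ts, tv = _pq_counts(ea, eb)
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P saturated (P={P:.4f}, Q={Q:.4f})")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    taxa: tuple
    d: np.ndarray
    model: str = "k2p"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ConfigurationError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ConfigurationError("matrix is not symmetric")
        if (np.diag(self.d) != 0).any() or (self.d < 0).any() or not np.isfinite(self.d).all():
            raise ConfigurationError("distances must be finite, non-negative, zero on the diagonal")


_PAIR_FNS = {"p": p_distance, "jc": jc_distance, "k2p": k2p_distance}


def build_distance_matrix(aln: SpeciesAlignment, model: str = "k2p") -> DistanceMatrix:
    """All pairwise distances under *model* (symmetric by construction)."""
    if model not in MODELS:
        raise ConfigurationError(f"unknown model {model!r}; choose from {MODELS}")
    if len(aln) < 3:
        raise ConfigurationError("need at least 3 records for a distance matrix")
    enc = [_encode(r.seq) for r in aln]
    n = len(enc)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            nv, ts, tv = _pq_counts(enc[i], enc[j])
            P, Q = ts / nv, tv / nv
            p = P + Q
            if model == "p":
                dist = p
            elif model == "jc":
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0.0:
                    raise SaturationError(
                        f"JC saturated for pair ({aln.records[i].id}, {aln.records[j].id})"
                    )
                dist = -0.75 * math.log(arg)
            else:
                w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
                if w1 <= 0.0 or w2 <= 0.0:
                    raise SaturationError(
                        f"K2P saturated for pair ({aln.records[i].id}, {aln.records[j].id})"
                    )
                dist = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=tuple(r.id for r in aln), d=d, model=model)


@dataclass(eq=False)  # identity semantics: nodes are dict keys
class TreeNode:
    name: str = ""
    length: float = 0.0  # edge length to parent (clamped; raw kept separately)
    raw_length: float = 0.0
    support: float = None
    children: list = field(default_factory=list)
    parent: "TreeNode" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary internal root of degree 3."""

    root: TreeNode

    def leaves(self) -> list:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def postorder(self):
        out = []

        def walk(node):
            for c in node.children:
                walk(c)
            out.append(node)

        walk(self.root)
        return out

    def _clade_sets(self) -> dict:
        sets = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[id(node)] = frozenset([node.name])
            else:
                s = frozenset()
                for c in node.children:
                    s |= sets[id(c)]
                sets[id(node)] = s
        return sets

    def bipartitions(self, include_trivial: bool = False) -> dict:
        """Map node -> canonical split side (the side not containing the
        reference leaf), for every edge below the root."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        sets = self._clade_sets()
        out = {}
        for node in self.postorder():
            if node is self.root:
                continue
            side = sets[id(node)]
            if ref in side:
                side = all_leaves - side
            if not include_trivial and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            out[node] = side
        return out

    def internal_splits(self) -> frozenset:
        return frozenset(self.bipartitions().values())


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> Tree:
    """Classic NJ.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; among ties the lexicographically smallest active index pair
    wins.  Negative branch lengths are clamped to zero (raw value kept on
    the node and the deficit logged) unless *clamp_negative* is false.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ConfigurationError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=t) for t in dm.taxa]
    D = dm.d.copy()
    active = list(range(n))

    def set_len(node, value):
        node.raw_length = float(value)
        if value < 0 and clamp_negative:
            logger.debug("clamped negative branch length %.6g to 0", value)
            node.length = 0.0
        else:
            node.length = float(value) + 0.0  # normalize -0.0

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                key = (q[ai, aj], ai, aj)
                if best is None or key < best:
                    best = key
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        new = TreeNode()
        set_len(nodes[i], li)
        set_len(nodes[j], lj)
        new.add(nodes[i])
        new.add(nodes[j])
        # grow matrix by one row/col for the joined node
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[u, k] = D[k, u] = duk
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    root = TreeNode()
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        set_len(nodes[idx], length)
        root.add(nodes[idx])
    return Tree(root=root)


def bootstrap_support(
    aln: SpeciesAlignment,
    model: str = "k2p",
    replicates: int = 1000,
    seed: int = 42,
) -> Tree:
    """NJ tree on the full data with bootstrap supports on internal edges.

    Columns are resampled with replacement (same alignment length) per
    replicate; support is the fraction of replicate trees containing each
    internal bipartition of the full-data tree.  Reproducible per *seed*.
    """
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    full = neighbor_joining(build_distance_matrix(aln, model))
    parts = full.bipartitions()
    counts = {node: 0 for node in parts}
    rng = np.random.default_rng(seed)
    enc = np.stack([_encode(r.seq) for r in aln])  # (n_rec, L)
    L = enc.shape[1]
    taxa = tuple(r.id for r in aln)
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        sample = enc[:, cols]
        d = _matrix_from_encoded(sample, model, taxa)
        rep_splits = neighbor_joining(DistanceMatrix(taxa=taxa, d=d, model=model)).internal_splits()
        for node, side in parts.items():
            if side in rep_splits:
                counts[node] += 1
    for node, c in counts.items():
        node.support = c / replicates
    return full


def _matrix_from_encoded(enc: np.ndarray, model: str, taxa) -> np.ndarray:
    n = enc.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            nv, ts, tv = _pq_counts(enc[i], enc[j])
            P, Q = ts / nv, tv / nv
            if model == "p":
                dist = P + Q
            elif model == "jc":
                p = P + Q
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0.0:
                    raise SaturationError(f"JC saturated for pair ({taxa[i]}, {taxa[j]})")
                dist = -0.75 * math.log(arg)
            else:
                w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
                if w1 <= 0.0 or w2 <= 0.0:
                    raise SaturationError(f"K2P saturated for pair ({taxa[i]}, {taxa[j]})")
                dist = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            d[i, j] = d[j, i] = dist
    return d


def is_monophyletic(tree: Tree, taxa_subset) -> bool:
    """True iff one edge of the unrooted tree separates exactly the subset."""
    subset = frozenset(taxa_subset)
    all_leaves = tree.leaf_names()
    if not subset <= all_leaves:
        raise ConfigurationError("subset contains unknown leaf names")
    if subset == all_leaves or len(subset) == 1:
        return True
    if not subset:
        return False
    ref = min(all_leaves)
    canon = subset if ref not in subset else all_leaves - subset
    splits = frozenset(tree.bipartitions(include_trivial=True).values())
    return canon in splits


def _newick_node(node: TreeNode, fmt: str, with_support: bool) -> str:
    if node.is_leaf:
        label = node.name
    else:
        inner = ",".join(_newick_node(c, fmt, with_support) for c in node.children)
        label = f"({inner})"
        if with_support and node.support is not None:
            label += str(int(round(node.support * 100)))
    if node.parent is not None:
        label += f":{node.length:{fmt}}"
    return label


def tree_to_newick(tree: Tree, fmt: str = ".6g") -> str:
    with_support = any(n.support is not None for n in tree.postorder())
    return _newick_node(tree.root, fmt, with_support) + ";"


def write_newick(tree: Tree, path) -> None:
    """Standard Newick with branch lengths; integer-percent supports are
    written as internal node labels when present."""
    Path(path).write_text(tree_to_newick(tree) + "\n", encoding="utf-8")


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    lines = ["\t" + "\t".join(dm.taxa)]
    for i, t in enumerate(dm.taxa):
        lines.append(t + "\t" + "\t".join(f"{x:.6g}" for x in dm.d[i]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
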