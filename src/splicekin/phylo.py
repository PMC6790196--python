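"""Distance-based phylogenetics: p/K2P distances, neighbour joining, bootstrap.

Distances use pairwise deletion — for each sequence pair, positions where
either member carries a gap or ambiguity are removed before counting. The
Kimura two-parameter (K2P) distance separates transitions (P) from
transversions (Q): d = −½·ln(1−2P−Q) − ¼·ln(1−2Q). Neighbour joining follows
the canonical Saitou–Nei agglomeration with a deterministic tie-break on the
smallest taxon-label pair; negative branch lengths are clamped to zero with
the deficit logged. Bootstrap support is the percentage of site-resampled
replicate trees containing each internal bipartition of the original tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SaturationError",
    "DistanceMatrix",
    "TreeNode",
    "TreeWithSupport",
    "pairwise_distances",
    "nj_tree",
    "bootstrap_support",
]

log = logging.getLogger(__name__)

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
VALID = {"A", "C", "G", "T"}


class SaturationError(ValueError):
    """K2P distance undefined (log argument <= 0) for a sequence pair."""


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def _as_items(alignment):
    if isinstance(alignment, dict):
        return list(alignment.items())
    return list(alignment)


def pairwise_distances(alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise p or K2P distances with pairwise deletion of ambiguous sites."""
    items = _as_items(alignment)
    labels = tuple(lab for lab, _ in items)
    seqs = [s.upper() for _, s in items]
    L = {len(s) for s in seqs}
    if len(L) != 1:
        raise ValueError("alignment sequences must have equal length")
    n = len(seqs)
    # encode: A,G -> 0,1 (purines); C,T -> 2,3; anything else -> 4 (excluded)
    lut = np.full(256, 4, dtype=np.int8)
    for b, v in zip("AGCT", (0, 1, 2, 3)):
        lut[ord(b)] = v
    enc = np.stack([lut[np.frombuffer(s.encode(), dtype=np.uint8)] for s in seqs])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[i], enc[j]
            ok = (a != 4) & (b != 4)
            valid = int(ok.sum())
            if valid == 0:
                raise ValueError(f"no comparable sites for {labels[i]}/{labels[j]}")
            neq = ok & (a != b)
            diff = int(neq.sum())
            same_class = (a < 2) == (b < 2)
            trans = int((neq & same_class).sum())
            if model == "p":
                d[i, j] = d[j, i] = diff / valid
            elif model in ("K2P", "k2p"):
                P, Q = trans / valid, (diff - trans) / valid
                a1, a2 = 1 - 2 * P - Q, 1 - 2 * Q
                if a1 <= 0 or a2 <= 0:
                    raise SaturationError(
                        f"K2P saturated for pair {labels[i]}/{labels[j]}"
                    )
                d[i, j] = d[j, i] = -0.5 * np.log(a1) - 0.25 * np.log(a2)
            else:
                raise ValueError(f"unknown distance model {model!r}")
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # (TreeNode, branch_length)

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset({self.name})
        out = set()
        for c, _ in self.children:
            out |= c.leaves()
        return frozenset(out)


@dataclass
class TreeWithSupport:
    """Unrooted tree (held as a degree-3 'root'), optional bootstrap supports
    keyed by canonical bipartition."""

    root: TreeNode
    taxa: tuple[str, ...]
    supports: dict = field(default_factory=dict)

    def _canon(self, side: frozenset) -> frozenset:
        ref = min(self.taxa)
        return side if ref not in side else frozenset(self.taxa) - side

    def bipartitions(self) -> set:
        """Canonical non-trivial bipartitions induced by internal edges."""
        out = set()

        def walk(node):
            for child, _ in node.children:
                side = child.leaves()
                if 2 <= len(side) <= len(self.taxa) - 2:
                    out.add(self._canon(side))
                walk(child)

        walk(self.root)
        return out

    def is_monophyletic(self, labels) -> bool:
        group = frozenset(labels)
        if len(group) in (1, len(self.taxa)):
            return True
        return self._canon(group) in {self._canon(b) for b in self.bipartitions()}

    def support_for(self, labels) -> float | None:
        return self.supports.get(self._canon(frozenset(labels)))

    def newick(self, with_supports: bool = True, precision: int = 10) -> str:
        def fmt(node, length=None):
            if not node.children:
                body = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = ""
                if with_supports and self.supports:
                    side = self._canon(node.leaves())
                    if side in self.supports:
                        label = f"{self.supports[side]:g}"
                body = f"({inner}){label}"
            if length is None:
                return body
            return f"{body}:{length:.{precision}f}"

        return fmt(self.root) + ";"


def nj_tree(dm: DistanceMatrix) -> TreeWithSupport:
    """Saitou–Nei neighbour joining with deterministic tie-breaks."""
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("need at least 3 taxa")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=lab) for i, lab in enumerate(dm.labels)
    }
    reps = {i: dm.labels[i] for i in range(n0)}  # smallest taxon label per cluster
    d = {
        (i, j): float(dm.values[i, j])
        for i in range(n0)
        for j in range(i + 1, n0)
    }

    def dist(i, j):
        return d[(i, j) if i < j else (j, i)]

    active = list(range(n0))
    next_id = n0
    clamp_deficit = 0.0
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((reps[i], reps[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[0] < best[0] - 1e-12 or (
                    abs(cand[0] - best[0]) <= 1e-12 and pair_key < best[1]
                ):
                    best = cand
        _, _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            clamp_deficit += -li
            li = 0.0
        if lj < 0:
            clamp_deficit += -lj
            lj = 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes[next_id] = new
        reps[next_id] = min(reps[i], reps[j])
        for k in active:
            if k in (i, j):
                continue
            d[(min(k, next_id), max(k, next_id))] = 0.5 * (
                dist(i, k) + dist(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    li = 0.5 * (dist(i, j) + dist(i, k) - dist(j, k))
    lj = 0.5 * (dist(i, j) + dist(j, k) - dist(i, k))
    lk = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
    lens = []
    for val in (li, lj, lk):
        if val < 0:
            clamp_deficit += -val
            val = 0.0
        lens.append(val)
    if clamp_deficit > 0:
        log.info("negative branch lengths clamped; total deficit %.3g", clamp_deficit)
    root = TreeNode(
        children=[(nodes[i], lens[0]), (nodes[j], lens[1]), (nodes[k], lens[2])]
    )
    return TreeWithSupport(root=root, taxa=dm.labels)


def bootstrap_support(
    alignment,
    reps: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> TreeWithSupport:
    """NJ tree of the full alignment with bootstrap supports (percent of
    site-resampled replicates containing each original bipartition)."""
    items = _as_items(alignment)
    labels = [lab for lab, _ in items]
    mat = np.array([list(s) for _, s in items])
    tree = nj_tree(pairwise_distances(items, model=model))
    target = tree.bipartitions()
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    L = mat.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        res = mat[:, cols]
        rep_aln = [(lab, "".join(res[i])) for i, lab in enumerate(labels)]
        try:
            rep_tree = nj_tree(pairwise_distances(rep_aln, model=model))
        except SaturationError:
            continue
        rep_bips = rep_tree.bipartitions()
        for b in target:
            if b in rep_bips:
                counts[b] += 1
    tree.supports = {b: 100.0 * c / reps for b, c in counts.items()}
    return tree
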