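"""Neighbour-joining trees with bootstrap support from protein alignments.

Distances are p-distances (mismatches over shared non-gap columns) so the
stage is closed-form testable; the agglomeration is the standard
Saitou-Nei algorithm with deterministic tie-breaking, exact on additive
matrices.  Bootstrap support resamples alignment columns with replacement,
rebuilds the tree per replicate and reports, for each internal split of the
full-data tree, the percentage of replicates containing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; leaves carry names, internal nodes support."""

    name: str | None = None
    branch_length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with leaf labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.matrix < -1e-12).any():
            raise ValueError("negative distances")


def p_distance(msa: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise p-distance: mismatches over shared non-gap columns.

    A pair with zero shared non-gap columns has no defined distance and
    raises.
    """
    labels = list(msa)
    if len(labels) < 2:
        raise ValueError("need at least 2 aligned sequences")
    length = len(msa[labels[0]])
    if any(len(msa[l]) != length for l in labels):
        raise ValueError("aligned sequences differ in length")
    arr = np.array([list(msa[l]) for l in labels])
    gap = arr == "-"
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            if not shared.any():
                raise ValueError(
                    f"no shared non-gap columns for {labels[i]!r}/{labels[j]!r}"
                )
            d[i, j] = d[j, i] = (arr[i, shared] != arr[j, shared]).mean()
    return DistanceMatrix(labels, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining; exact on additive matrices.

    Ties in the Q criterion resolve to the lexicographically lowest label
    pair.  Negative branch lengths are clamped to 0 with the deficit moved
    to the sibling branch.  The returned tree is unrooted, represented by a
    trifurcating root (n >= 3).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    # lexicographically minimal leaf label under each working node, for ties
    keys: list[str] = list(dm.labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best: tuple[float, str, str, int, int] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                ka, kb = keys[active[ai]], keys[active[aj]]
                lo, hi = (ka, kb) if ka <= kb else (kb, ka)
                cand = (q[ai, aj], lo, hi, ai, aj)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = li
        child_j.branch_length = lj
        new = TreeNode(children=[child_i, child_j])
        new_idx = d.shape[0]
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_idx, :-1] = new_row
        d[:-1, new_idx] = new_row
        d[new_idx, new_idx] = 0.0
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [a for a in active if a not in (i, j)] + [new_idx]

    if len(active) == 3:
        i, j, k = active
        x = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        y = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        z = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
        for node, bl in zip(root.children, (x, y, z)):
            node.branch_length = max(bl, 0.0)
        return root
    # n == 3 handled above; len(active) can also be 2 only if n == 2 (rejected)
    raise AssertionError("unreachable")


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the leaf set, one per internal edge.

    Each split is represented by the side not containing the
    lexicographically smallest leaf, so representation is canonical.
    """
    all_leaves = set(tree.leaf_names())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = set(node.leaf_names())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if anchor in side:
            side = all_leaves - side
        splits.add(frozenset(side))
    return splits


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric-difference (Robinson-Foulds) distance between two trees."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees have different leaf sets")
    return len(tree_splits(t1) ^ tree_splits(t2))


def path_length_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path lengths along the tree (additivity check)."""
    labels = sorted(tree.leaf_names())
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    def below(node: TreeNode) -> dict[str, float]:
        """Leaf name -> distance from node."""
        if node.is_leaf:
            return {node.name: 0.0}
        out: dict[str, float] = {}
        groups = []
        for c in node.children:
            sub = {k: v + c.branch_length for k, v in below(c).items()}
            groups.append(sub)
            out.update(sub)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a, da in groups[gi].items():
                    for b, db in groups[gj].items():
                        d[idx[a], idx[b]] = d[idx[b], idx[a]] = da + db
        return out

    below(tree)
    return DistanceMatrix(labels, d)


def bootstrap_support(
    msa: Mapping[str, str], n_boot: int = 1000, seed: int | None = None
) -> TreeNode:
    """Full-data NJ tree with per-split bootstrap support percentages.

    Alignment columns are resampled with replacement ``n_boot`` times; for
    each internal split of the full-data tree the support is the percentage
    of replicate trees containing it.  Deterministic given the seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    labels = list(msa)
    length = len(msa[labels[0]])
    if length < 2:
        raise ValueError("alignment needs at least 2 columns")
    full = nj_tree(p_distance(msa))
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(full)}
    rng = np.random.default_rng(seed)
    cols = np.array([list(msa[l]) for l in labels])
    for _ in range(n_boot):
        pick = rng.integers(0, length, size=length)
        rep = {l: "".join(cols[i, pick]) for i, l in enumerate(labels)}
        try:
            rep_splits = tree_splits(nj_tree(p_distance(rep)))
        except ValueError:
            continue  # replicate with an all-gap pair carries no information
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    all_leaves = set(full.leaf_names())
    anchor = min(all_leaves)
    for node in full.postorder():
        if node is full or node.is_leaf:
            continue
        side = set(node.leaf_names())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        key = frozenset(all_leaves - side if anchor in side else side)
        node.support = 100.0 * counts[key] / n_boot
    return full


def high_support_flags(tree: TreeNode, cutoff: float = 70.0) -> dict[frozenset[str], bool]:
    """Flag internal splits whose bootstrap support exceeds the cutoff.

    Mirrors the reporting convention of marking branches with greater than
    70% support with an asterisk.
    """
    out = {}
    all_leaves = set(tree.leaf_names())
    anchor = min(all_leaves)
    for node in tree.postorder():
        if node is tree or node.is_leaf or node.support is None:
            continue
        side = set(node.leaf_names())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        key = frozenset(all_leaves - side if anchor in side else side)
        out[key] = node.support > cutoff
    return out


def to_newick(tree: TreeNode) -> str:
    """Newick string with bootstrap supports as internal node labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.branch_length:.6g}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:g}"
        bl = "" if node is tree else f":{node.branch_length:.6g}"
        return f"({inner}){label}{bl}"

    return fmt(tree) + ";"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def parse_newick(text: str) -> TreeNode:
    """Minimal newick parser (names, branch lengths, internal labels)."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                elif text[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(text) and text[pos] not in ",():":
            pos += 1
        label = text[start:pos]
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            node.branch_length = float(text[start:pos])
        return node

    return parse_node()


def read_subgroups(path: str | Path) -> dict[str, str]:
    """Read a subgroup assignment TSV (columns id, subgroup)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "subgroup"}.issubset(df.columns):
        raise ValueError("subgroup table needs columns id, subgroup")
    if df["id"].duplicated().any():
        raise ValueError("duplicate protein ids in subgroup table")
    return dict(zip(df["id"], df["subgroup"]))


def write_subgroups(subgroups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsubgroup\n")
        for pid, sub in subgroups.items():
            fh.write(f"{pid}\t{sub}\n")
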