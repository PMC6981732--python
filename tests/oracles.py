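"""Independent brute-force oracles for the tree stage.

Topology enumeration by edge attachment plus least-squares additivity
fitting; used to verify neighbour joining without reference to it.
"""

import itertools

import numpy as np


def enumerate_topologies(labels):
    """All unrooted leaf-labelled binary topologies as canonical split sets.

    Brute force by edge attachment: every topology on n leaves arises by
    attaching the nth leaf onto one of the 2n-5 edges of a topology on n-1
    leaves.  Trees are explicit (nodes, edge list) graphs; topologies are
    canonicalised to their sets of non-trivial splits (anchored away from
    the first label), which identify them uniquely.
    """
    n = len(labels)
    # seed: star on the first three leaves; node ids: leaves 0..n-1,
    # internal nodes from n upward
    seed_edges = [(0, n), (1, n), (2, n)]
    trees = [(seed_edges, n + 1)]
    for new_leaf in range(3, n):
        grown = []
        for edges, next_id in trees:
            for k, (u, v) in enumerate(edges):
                e2 = edges[:k] + edges[k + 1:]
                e2 += [(u, next_id), (next_id, v), (next_id, new_leaf)]
                grown.append((e2, next_id + 1))
        trees = grown

    def splits_of(edges):
        adj = {}
        for u, v in edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        out = set()
        for u, v in edges:
            # leaves on v's side when edge (u, v) is cut
            seen, stack = {u, v}, [v]
            side = set()
            while stack:
                x = stack.pop()
                if x < n:
                    side.add(labels[x])
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if 2 <= len(side) <= n - 2:
                if labels[0] in side:
                    side = set(labels) - side
                out.add(frozenset(side))
        return frozenset(out)

    return {splits_of(edges) for edges, _ in trees}


def fits_additively(split_sets, labels, d):
    """Least-squares branch lengths for a topology; True if the fit is exact."""
    full = set(labels)
    # edges: one per leaf (terminal) + one per non-trivial split
    edges = [frozenset({l}) for l in labels] + [set(s) for s in split_sets]
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        li, lj = labels[i], labels[j]
        y[row] = d[i, j]
        for col, e in enumerate(edges):
            e = set(e)
            # the path i-j crosses edge e iff e separates them
            if (li in e) != (lj in e):
                A[row, col] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.allclose(A @ x, y, atol=1e-9) and (x > -1e-9).all()
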