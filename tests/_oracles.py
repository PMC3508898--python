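"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: trees are plain
edge lists with BFS path sums, repeats are found by exhaustive
enumeration, and lipidation rules are restated from first principles.
"""

from __future__ import annotations

from collections import Counter, deque
from itertools import product

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------- trees

def enumerate_topologies(labels):
    """All unrooted binary topologies over the labels (3, 15, 105 ... trees),
    as edge lists over leaf labels and internal nodes 'I0', 'I1', ..."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    trees = [[("I0", labels[0]), ("I0", labels[1]), ("I0", labels[2])]]
    for k, leaf in enumerate(labels[3:], start=1):
        grown = []
        for edges in trees:
            for edge in edges:
                rest = [e for e in edges if e != edge]
                u, v = edge
                node = f"I{k}"
                grown.append(rest + [(u, node), (node, v), (node, leaf)])
        trees = grown
    return trees


def edge_lengths(edges, base=0.3, step=0.07):
    """Deterministic, pairwise-distinct positive branch lengths."""
    return {e: base + step * i for i, e in enumerate(edges)}


def _adjacency(edges, lengths=None):
    adj = {}
    for e in edges:
        u, v = e
        w = 1.0 if lengths is None else lengths[e]
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    return adj


def path_distance_matrix(edges, lengths, labels):
    """Additive matrix of leaf-to-leaf path sums (BFS from each leaf)."""
    adj = _adjacency(edges, lengths)
    n = len(labels)
    out = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        queue = deque([src])
        while queue:
            node = queue.popleft()
            for nxt, w in adj[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + w
                    queue.append(nxt)
        for j, dst in enumerate(labels):
            out[i, j] = dist[dst]
    return out


def tree_bipartitions(edges, labels):
    """Non-trivial splits, each as the side not containing min(labels)."""
    labels = set(labels)
    ref = min(labels)
    out = set()
    for removed in edges:
        adj = _adjacency([e for e in edges if e != removed])
        start = removed[0]
        seen = {start}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            for nxt, _ in adj.get(node, []):
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        side = frozenset(seen & labels)
        if ref in side:
            side = frozenset(labels - side)
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out


# -------------------------------------------------------------- repeats

def _unit_identity(unit, consensus):
    return sum(a == b and a != "X" for a, b in zip(unit, consensus)) / len(unit)


def _majority(copies, col):
    votes = Counter(c[col] for c in copies)
    top = max(votes.values())
    tied = sorted(ch for ch, n in votes.items() if n == top)
    return copies[0][col] if copies[0][col] in tied else tied[0]


def brute_force_repeats(region, unit_range=(5, 10), min_identity=0.7):
    """Exhaustive scan over all starts × unit lengths × copy counts, with
    the same growth rule and greedy overlap policy as the detector, but
    written independently and without shortcuts."""
    lo, hi = unit_range
    candidates = []
    for unit_len in range(lo, hi + 1):
        for start in range(len(region)):
            copies = []
            consensus = None
            pos = start
            while pos + unit_len <= len(region):
                unit = region[pos:pos + unit_len]
                if consensus is not None and \
                        _unit_identity(unit, consensus) < min_identity:
                    break
                copies.append(unit)
                consensus = "".join(
                    _majority(copies, c) for c in range(unit_len))
                pos += unit_len
            if len(copies) >= 2:
                mean_id = sum(
                    _unit_identity(c, consensus) for c in copies
                ) / len(copies)
                if mean_id >= min_identity:
                    candidates.append(
                        (start + 1, unit_len, len(copies), mean_id, consensus))
    candidates.sort(key=lambda c: (-(c[1] * c[2]), c[0], c[1]))
    chosen = []
    for cand in candidates:
        s = cand[0]
        e = cand[0] + cand[1] * cand[2] - 1
        if all(e < cs or s > ce for cs, ce in
               ((c[0], c[0] + c[1] * c[2] - 1) for c in chosen)):
            chosen.append(cand)
    return chosen


# ------------------------------------------------------------ lipidation

def all_caax_suffixes():
    """Every 4-residue terminus with fixed 'C' at -4: 20^3 combinations."""
    return ["C" + "".join(p) for p in product(AA, repeat=3)]


def oracle_transferase(x_residue):
    if x_residue in "LI":
        return "PGGT-I"
    if x_residue in "MQACS":
        return "PFT"
    return "ambiguous"
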