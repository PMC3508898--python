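"""Central-domain phylogenetics: distances, neighbor-joining, bootstrap.

Because the N- and C-termini of Gγ subunits are too variable to align,
phylogenetic analysis is restricted to the conserved central domain,
extracted as a column window around the [D/E]PL[L/I] anchor.  Trees are
built by neighbor-joining (Saitou–Nei) on p- or Poisson-corrected
distances; support for the structural types is measured by column
bootstrap: the fraction of replicate trees in which a type's taxa form one
side of a bipartition of the unrooted tree (monophyly on an unrooted
tree).  A strict majority-rule consensus tree over any tree collection is
also provided.

All trees are ``dendropy.Tree`` objects sharing a taxon namespace, so they
round-trip through Newick via :func:`ggamma.seq_io.write_newick`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np

from .cterminal import find_anchor
from .seq_io import GAP, AlignedBlock

P_SATURATION_CAP = 0.95


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with ids; ``saturated`` lists pairs
    whose p-distance was capped before Poisson correction."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    model: str                               # "p-distance" | "poisson"
    saturated: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix has non-finite entries")


@dataclass(frozen=True)
class TreeWithSupport:
    """Point NJ tree with bootstrap annotations.

    ``group_support`` maps a group label to the fraction of replicates in
    which the group's taxa form a bipartition; groups too small or too
    large for a non-trivial bipartition are absent from the map."""

    tree: dendropy.Tree
    group_support: dict[str, float]
    n_replicates: int
    seed: int


def extract_central_domain(
    block: AlignedBlock,
    anchor_map: Mapping[str, tuple[int, int]] | None = None,
    upstream: int = 45,
    downstream: int = 2,
) -> tuple[AlignedBlock, list[str]]:
    """Slice the conserved central-domain column window from an alignment.

    The anchor columns are located per row (first [D/E]PL[L/I] match on the
    de-gapped sequence, mapped through the gaps), or supplied directly via
    ``anchor_map`` {id: (start_col, end_col)}.  The window spans
    [modal_anchor_start − upstream, modal_anchor_end + downstream], clipped
    to the alignment.  Rows without an anchor are dropped and returned as
    the second element.
    """
    spans: dict[str, tuple[int, int]] = {}
    dropped: list[str] = []
    for rid, row in block.records:
        if anchor_map is not None and rid in anchor_map:
            spans[rid] = anchor_map[rid]
            continue
        degapped = row.replace(GAP, "")
        hit = find_anchor(degapped) if degapped else None
        if hit is None:
            dropped.append(rid)
            continue
        # map residue indices to alignment columns
        cols = [i + 1 for i, ch in enumerate(row) if ch != GAP]
        spans[rid] = (cols[hit[0] - 1], cols[hit[1] - 1])
    if not spans:
        raise ValueError("no row carries the central-domain anchor")
    modal_span = Counter(spans.values()).most_common(1)[0][0]
    start = max(1, modal_span[0] - upstream)
    end = min(block.ncols, modal_span[1] + downstream)
    if end < start:
        raise ValueError("empty central-domain window")
    rows = [(rid, row[start - 1:end]) for rid, row in block.records
            if rid in spans]
    return AlignedBlock.from_rows(rows), dropped


def distances(block: AlignedBlock, model: str = "p-distance") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gapped column pairs.

    p-distance = mismatches / compared columns, where a column pair is
    compared when neither character is a gap and mismatches include any
    comparison involving 'X'.  The Poisson correction d = −ln(1−p) caps p
    at 0.95 (flagging the pair as saturated) to keep distances finite.
    """
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    ids = tuple(block.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 rows")
    arr = np.array([list(s) for _, s in block.records])
    n = len(ids)
    out = np.zeros((n, n))
    saturated = []
    gap = arr == GAP
    unknown = arr == "X"
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~gap[i] & ~gap[j]
            compared = int(mask.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            mism = ((arr[i] != arr[j]) | unknown[i] | unknown[j]) & mask
            p = mism.sum() / compared
            if model == "poisson":
                if p > P_SATURATION_CAP:
                    saturated.append((ids[i], ids[j]))
                    p = P_SATURATION_CAP
                d = -math.log(1.0 - p)
            else:
                d = p
            out[i, j] = out[j, i] = d
    return DistanceMatrix(ids=ids, matrix=out, model=model,
                          saturated=tuple(saturated))


def _new_tree(ids: Sequence[str]) -> tuple[dendropy.Tree, dict[str, dendropy.Node]]:
    tns = dendropy.TaxonNamespace(list(ids))
    tree = dendropy.Tree(taxon_namespace=tns)
    leaves = {}
    for rid in ids:
        node = dendropy.Node(taxon=tns.get_taxon(rid))
        leaves[rid] = node
    return tree, leaves


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining (Saitou–Nei) with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (representative, representative) id pair, where a cluster's
    representative is the smallest leaf id it contains.  Negative branch
    lengths are floored at zero with the deficit moved to the sister
    branch, preserving the pair's summed length.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    tree, leaf_nodes = _new_tree(ids)
    D = dm.matrix.astype(float).copy()
    nodes = [leaf_nodes[r] for r in ids]
    lengths: dict[dendropy.Node, float] = {}
    reps = list(ids)
    active = list(range(len(ids)))

    def pair_key(i: int, j: int) -> tuple[str, str]:
        a, b = reps[i], reps[j]
        return (a, b) if a <= b else (b, a)

    while len(active) > 3:
        n = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * D[i, j] - r[i] - r[j]
                key = (q, pair_key(i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # reuse slot i for the new cluster
        for k in active:
            if k not in (i, j):
                d = 0.5 * (D[i, k] + D[j, k] - D[i, j])
                D[i, k] = D[k, i] = max(d, 0.0)
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    i, j, k = active
    li = max(0.5 * (D[i, j] + D[i, k] - D[j, k]), 0.0)
    lj = max(0.5 * (D[i, j] + D[j, k] - D[i, k]), 0.0)
    lk = max(0.5 * (D[i, k] + D[j, k] - D[i, j]), 0.0)
    root = dendropy.Node()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = ln
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _canonical(side: frozenset[str], all_labels: frozenset[str]) -> frozenset[str]:
    ref = min(all_labels)
    return frozenset(all_labels - side) if ref in side else side


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized as
    the side not containing the lexicographically smallest leaf."""
    labels = leaf_labels(tree)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= len(labels) - 2:
            out.add(_canonical(side, labels))
    return out


def group_is_monophyletic(tree: dendropy.Tree, members: Iterable[str]) -> bool:
    """True when the group's taxa form one side of some bipartition."""
    labels = leaf_labels(tree)
    side = frozenset(members)
    if not 2 <= len(side) <= len(labels) - 2:
        raise ValueError("group size leaves no non-trivial bipartition")
    return _canonical(side, labels) in bipartitions(tree)


def _resample_block(block: AlignedBlock, cols: np.ndarray) -> AlignedBlock:
    rows = [(rid, "".join(s[c] for c in cols)) for rid, s in block.records]
    return AlignedBlock.from_rows(rows)


def bootstrap_support(
    block: AlignedBlock,
    groups: Mapping[str, str],
    n_replicates: int = 100,
    seed: int = 0,
    model: str = "poisson",
) -> TreeWithSupport:
    """Column bootstrap of the NJ tree with per-group monophyly support.

    ``groups`` maps every taxon id to its group label (e.g. structural
    type).  A single seeded generator drives all replicates in order:
    replicate r consumes draw r.  Internal nodes of the point tree are
    labelled with the percentage of replicates containing their
    bipartition.
    """
    ids = set(block.ids)
    missing = ids - set(groups)
    if missing:
        raise ValueError(f"taxa without group label: {sorted(missing)}")
    n = len(block.ids)
    if n < 4:
        raise ValueError("bootstrap needs at least 4 taxa")
    members: dict[str, frozenset[str]] = {}
    for rid in block.ids:
        members.setdefault(groups[rid], frozenset())
        members[groups[rid]] = members[groups[rid]] | {rid}
    testable = {
        g: m for g, m in members.items() if 2 <= len(m) <= n - 2
    }
    all_labels = frozenset(block.ids)
    rng = np.random.default_rng(seed)
    hits = Counter()
    bip_counts: Counter = Counter()
    for _ in range(n_replicates):
        cols = rng.integers(0, block.ncols, size=block.ncols)
        rep_tree = nj_tree(distances(_resample_block(block, cols), model))
        bips = bipartitions(rep_tree)
        bip_counts.update(bips)
        for g, m in testable.items():
            if _canonical(m, all_labels) in bips:
                hits[g] += 1
    point = nj_tree(distances(block, model))
    for node in point.preorder_node_iter():
        if node is point.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= n - 2:
            count = bip_counts.get(_canonical(side, all_labels), 0)
            node.label = f"{100.0 * count / n_replicates:g}"
    support = {g: hits[g] / n_replicates for g in testable}
    return TreeWithSupport(tree=point, group_support=support,
                           n_replicates=n_replicates, seed=seed)


def majority_consensus(
    trees: Sequence[dendropy.Tree], threshold: float = 0.5,
) -> dendropy.Tree:
    """Strict majority-rule consensus: keep bipartitions occurring in
    strictly more than ``threshold`` of the trees; no greedy completion.

    Internal nodes are labelled with the bipartition's percentage.  All
    trees must share one leaf set.
    """
    if not trees:
        raise ValueError("no trees")
    labels = leaf_labels(trees[0])
    for t in trees[1:]:
        if leaf_labels(t) != labels:
            raise ValueError("trees have different leaf sets")
    counts: Counter = Counter()
    for t in trees:
        counts.update(bipartitions(t))
    n = len(trees)
    retained = [(bip, c / n) for bip, c in counts.items() if c / n > threshold]
    # frequency-descending; below-majority thresholds could admit
    # incompatible splits, so later incompatible clusters are skipped
    retained.sort(key=lambda bf: (-bf[1], sorted(bf[0])))
    ref = min(labels)
    clusters: list[tuple[frozenset[str], float]] = []
    for bip, freq in retained:
        side = bip if ref not in bip else frozenset(labels - bip)
        if all(
            side <= c or c <= side or not (side & c)
            for c, _ in clusters
        ):
            clusters.append((side, freq))
    clusters.sort(key=lambda cf: -len(cf[0]))

    tns = dendropy.TaxonNamespace(sorted(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    root = dendropy.Node()
    cluster_nodes: list[tuple[frozenset[str], dendropy.Node]] = []
    for side, freq in clusters:
        node = dendropy.Node()
        node.label = f"{100.0 * freq:g}"
        parent = root
        for other, other_node in cluster_nodes:
            if side < other:
                parent = other_node  # smallest container wins (sorted big→small)
        parent.add_child(node)
        cluster_nodes.append((side, node))
    for label in sorted(labels):
        leaf = dendropy.Node(taxon=tns.get_taxon(label))
        parent = root
        best_size = None
        for side, node in cluster_nodes:
            if label in side and (best_size is None or len(side) < best_size):
                parent = node
                best_size = len(side)
        parent.add_child(leaf)
    tree.seed_node = root
    tree.is_rooted = False
    return tree
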