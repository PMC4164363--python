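"""Neighbour-joining trees, bootstrap support, and divergence clusters.

The tree is built with the classical neighbour-joining agglomeration
(Saitou & Nei) from the K2P matrix, with two reproducibility conventions:
Q-criterion ties are broken by the lexicographically smallest pair of leaf
ids, and a negative branch length arising at a join is clamped to zero with
the deficit transferred to its sibling branch so path lengths are preserved.

Clusters are the maximal clades (bipartition sides of the unrooted tree,
read off a midpoint rooting) whose within-clade maximum pairwise K2P
distance stays below a divergence threshold — 2% for the species screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skbio import TreeNode

from .distances import DistanceMatrix, k2p_matrix_encoded, encode
from .io import BarcodeLibrary

DEFAULT_CLUSTER_THRESHOLD = 0.02


def build_nj(matrix: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree from a fully defined distance matrix.

    The result is the standard unrooted NJ tree, represented with a
    trifurcating root.  Undefined (NaN) entries are refused: prune those
    specimens first.
    """
    ids = list(matrix.ids)
    if len(ids) < 3:
        raise ValueError("neighbour joining needs at least 3 leaves")
    if matrix.undefined_pairs:
        pair = sorted(next(iter(matrix.undefined_pairs)))
        raise ValueError(f"undefined distance between {pair[0]} and {pair[1]}")
    d = matrix.d.copy()
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN entries")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    # Sort key per active node: smallest leaf id underneath (for tie-breaks).
    keys: list[str] = list(ids)

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        best = min(
            (tuple(sorted((keys[i], keys[j]))), int(i), int(j))
            for i, j in cand if i < j
        )
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        lj = max(lj, 0.0)
        li = max(li, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])

        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.empty((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = new_row[keep]
        d_new[:-1, -1] = new_row[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # Final three-way join: closed-form three-point branch lengths.
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    order = np.argsort([keys[0], keys[1], keys[2]])
    children = [nodes[k] for k in order]
    root = TreeNode(children=children)
    root.length = None
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an (unrooted) tree, in canonical form.

    Each bipartition is the side *not* containing the lexicographically
    smallest leaf name.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    anchor = min(all_tips)
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            out.add(side)
    return out


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances along the tree."""
    dm = tree.tip_tip_distances()
    return DistanceMatrix(list(dm.ids), np.asarray(dm.data, dtype=float), set())


def bootstrap_support(library: BarcodeLibrary, tree: TreeNode,
                      n_reps: int = 1000, seed: Optional[int] = None,
                      min_overlap: int = 20) -> dict[frozenset, float]:
    """Column-resampling bootstrap support for a tree's bipartitions.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    replicate K2P matrix (out-of-domain entries clipped to keep it finite)
    is rebuilt with NJ, and support is the percentage of replicates whose
    tree contains the original bipartition.  Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    records = list(library)
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("bootstrap requires aligned, equal-length sequences")
    n_cols = lengths.pop()
    if n_cols < 2:
        raise ValueError("alignment must have at least 2 columns")
    ids = [r.specimen_id for r in records]
    enc = np.stack([encode(r.sequence) for r in records])

    targets = tree_bipartitions(tree)
    counts = {bp: 0 for bp in targets}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_d, _ = k2p_matrix_encoded(enc[:, cols], min_overlap=min_overlap,
                                      clip=True)
        rep_tree = build_nj(DistanceMatrix(ids, rep_d, set()))
        rep_bps = tree_bipartitions(rep_tree)
        for bp in targets:
            if bp in rep_bps:
                counts[bp] += 1
    return {bp: 100.0 * c / n_reps for bp, c in counts.items()}


def annotate_support(tree: TreeNode, support: dict[frozenset, float]) -> TreeNode:
    """Label internal nodes of ``tree`` with bootstrap percentages."""
    all_tips = frozenset(t.name for t in tree.tips())
    anchor = min(all_tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_tips - side
        if side in support:
            node.name = f"{support[side]:.0f}"
    return tree


@dataclass
class Cluster:
    """A maximal low-divergence clade of the tree."""

    cluster_id: str
    member_ids: list[str]
    max_within: float
    species_composition: dict[str, int] = field(default_factory=dict)

    @property
    def is_single_entry(self) -> bool:
        return len(self.member_ids) == 1

    @property
    def consensus_species(self) -> Optional[str]:
        named = {s for s in self.species_composition if s}
        if len(named) == 1 and set(self.species_composition) == named:
            return next(iter(named))
        return None


def _midpoint_rooted(tree: TreeNode) -> TreeNode:
    try:
        return tree.root_at_midpoint()
    except Exception:
        # Degenerate (e.g. zero-diameter) trees: any rooting is equivalent.
        return tree


def extract_clusters(tree: TreeNode, matrix: DistanceMatrix,
                     threshold: float = DEFAULT_CLUSTER_THRESHOLD,
                     species_map: Optional[dict[str, str]] = None
                     ) -> list[Cluster]:
    """Partition the leaves into maximal clades with max K2P < threshold.

    Clades are read off a midpoint rooting of the tree, so cluster
    boundaries fall on the deepest divergences; a clade qualifies when the
    maximum pairwise distance among its leaves is strictly below
    ``threshold``.  Leaves belonging to no qualifying multi-leaf clade
    become single-entry clusters.  The result is a partition of the leaf
    set, numbered in tree traversal order.
    """
    rooted = _midpoint_rooted(tree.copy())
    clusters: list[Cluster] = []

    def walk(node: TreeNode) -> None:
        leaves = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        if matrix.max_among(leaves) < threshold:
            comp: dict[str, int] = {}
            if species_map is not None:
                for leaf in leaves:
                    sp = species_map.get(leaf, "")
                    comp[sp] = comp.get(sp, 0) + 1
            clusters.append(Cluster(
                cluster_id="",
                member_ids=sorted(leaves),
                max_within=matrix.max_among(leaves),
                species_composition=comp,
            ))
            return
        for child in node.children:
            walk(child)

    walk(rooted)
    for k, cl in enumerate(clusters, start=1):
        cl.cluster_id = f"C{k:04d}"
    return clusters


def species_monophyly(tree: TreeNode,
                      species_map: dict[str, str]) -> dict[str, str]:
    """Classify each species as monophyletic / non_monophyletic / not_evaluable.

    A species is monophyletic when its specimen set is exactly one side of
    some bipartition of the unrooted tree (assessed without an outgroup).
    Species with a single specimen are not evaluable.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    clades: set[frozenset] = set()
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            clades.add(frozenset({node.name}))
        else:
            clades.add(frozenset(t.name for t in node.tips()))

    by_species: dict[str, set[str]] = {}
    for sid, sp in species_map.items():
        if sid in all_tips:
            by_species.setdefault(sp, set()).add(sid)

    result: dict[str, str] = {}
    for sp, members in by_species.items():
        if len(members) < 2:
            result[sp] = "not_evaluable"
            continue
        fs = frozenset(members)
        if fs in clades or (all_tips - fs) in clades:
            result[sp] = "monophyletic"
        else:
            result[sp] = "non_monophyletic"
    return result
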