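"""Distance-based tree building, bootstrap support, and clade tests.

A deliberately transparent stand-in for likelihood tree inference:
protein distances (p-distance or Kimura-corrected) feed Saitou–Nei
neighbor joining with a deterministic tie-break, and clade support
comes from column-resampling bootstrap. Neighbor joining recovers the
true topology exactly whenever the distance matrix is additive, which
is what the synthetic tests exploit.

Trees are :class:`dendropy.Tree` objects throughout, so newick I/O,
rooting, and MRCA queries use the standard library machinery.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .align import Alignment


def distance_matrix(msa: Alignment, correction: str = "p") -> pd.DataFrame:
    """Pairwise protein distances with pairwise gap deletion.

    ``p`` is the raw mismatch proportion; ``kimura_protein`` applies
    d = -ln(1 - p - 0.2 p^2), capped (with a warning) at p = 0.85 where
    the correction diverges.
    """
    if correction not in ("p", "kimura_protein"):
        raise ValueError(f"unknown correction {correction!r}")
    if len(msa.rows) < 3:
        raise ValueError("need >= 3 rows for a distance matrix")
    ids = [rid for rid, _ in msa.rows]
    seqs = [g for _, g in msa.rows]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairs = [(x, y) for x, y in zip(seqs[i], seqs[j])
                     if x != "-" and y != "-"]
            if not pairs:
                raise ValueError(
                    f"rows {ids[i]!r} and {ids[j]!r} share no ungapped columns")
            p = sum(x != y for x, y in pairs) / len(pairs)
            if correction == "kimura_protein":
                if p >= 0.85:
                    warnings.warn(
                        f"p-distance {p:.3f} >= 0.85 between {ids[i]!r} and "
                        f"{ids[j]!r}; capping")
                    p = 0.85
                dist = -math.log(1.0 - p - 0.2 * p * p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=ids, columns=ids)


def nj_tree(dm: pd.DataFrame) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaks.

    Among minimum-Q pairs, the tie-break orders candidates by the
    lexicographically smallest leaf label under each node, so the
    result is both deterministic and invariant to input row order.
    Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling branch. Returns an unrooted tree
    (trifurcating at the root node).
    """
    if dm.shape[0] != dm.shape[1] or dm.shape[0] < 3:
        raise ValueError("distance matrix must be square with >= 3 taxa")
    if not np.allclose(dm.values, dm.values.T):
        raise ValueError("distance matrix is not symmetric")
    labels = list(dm.index)
    taxa = dendropy.TaxonNamespace(labels)
    nodes = {lab: dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in labels}
    active = list(labels)
    rep = {lab: lab for lab in labels}   # smallest leaf label under node
    D = {(a, b): float(dm.loc[a, b]) for a in labels for b in labels}

    def dist(a, b):
        return 0.0 if a == b else D[(a, b)]

    new_idx = 0
    while len(active) > 3:
        n = len(active)
        ordered = sorted(active, key=lambda x: rep[x])
        r = {a: sum(dist(a, k) for k in active) for a in active}
        best = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = ordered[ii], ordered[jj]
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * dist(a, b) + (r[a] - r[b]) / (2 * (n - 2))
        lb = dist(a, b) - la
        if la < 0:
            lb, la = dist(a, b), 0.0
        if lb < 0:
            la, lb = dist(a, b), 0.0
        u = f"_nj{new_idx}"
        new_idx += 1
        rep[u] = min(rep[a], rep[b])
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        nodes[u] = parent
        for k in active:
            if k in (a, b):
                continue
            D[(u, k)] = D[(k, u)] = 0.5 * (dist(a, k) + dist(b, k)
                                           - dist(a, b))
        active = [k for k in active if k not in (a, b)] + [u]
    # star-join the final three
    a, b, c = active
    root = dendropy.Node()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        lx = 0.5 * (dist(x, y) + dist(x, z) - dist(y, z))
        nodes[x].edge.length = max(lx, 0.0)
        root.add_child(nodes[x])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def _leaf_labels(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each internal edge splits the leaves in two; the canonical form is
    the side *not* containing the lexicographically smallest label, so
    the encoding is invariant to rooting and leaf order.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = _leaf_labels(node)
        side = all_leaves - below if ref in below else below
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def bootstrap_support(msa: Alignment, n_reps: int = 100, seed: int = 0,
                      correction: str = "p",
                      ) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """NJ tree with column-resampling bootstrap support.

    Columns are resampled with replacement ``n_reps`` times; support for
    each bipartition of the full-data tree is the fraction of replicate
    trees containing it. Supports are also written to internal node
    labels of the returned tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = nj_tree(distance_matrix(msa, correction))
    target = bipartitions(tree)
    counts = {bp: 0 for bp in target}
    L = msa.length
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rows = [(rid, "".join(g[c] for c in cols)) for rid, g in msa.rows]
        rep = Alignment(rows=rows, matrix_name=msa.matrix_name,
                        gap_open=msa.gap_open, gap_extend=msa.gap_extend)
        try:
            rep_bps = bipartitions(nj_tree(distance_matrix(rep, correction)))
        except ValueError:
            continue
        for bp in target & rep_bps:
            counts[bp] += 1
    support = {bp: counts[bp] / n_reps for bp in target}
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = _leaf_labels(node)
        side = all_leaves - below if ref in below else below
        if side in support:
            node.label = f"{support[side]:.3f}"
    return tree, support


def root_on_outgroup(tree: dendropy.Tree,
                     outgroup_leaves: Sequence[str]) -> dendropy.Tree:
    """Return a clone rooted on the stem of the outgroup.

    With no outgroup given, falls back to midpoint rooting.
    """
    t = tree.clone(depth=1)
    if not outgroup_leaves:
        t.reroot_at_midpoint(update_bipartitions=False)
        return t
    taxa = [t.taxon_namespace.get_taxon(l) for l in outgroup_leaves]
    if any(tx is None for tx in taxa):
        missing = [l for l, tx in zip(outgroup_leaves, taxa) if tx is None]
        raise ValueError(f"outgroup leaves not in tree: {missing}")
    if len(taxa) == 1:
        node = t.find_node_with_taxon_label(outgroup_leaves[0])
    else:
        node = t.mrca(taxa=taxa)
        if node is t.seed_node:
            # outgroup spans the current root; root on the complement side
            others = [lf.taxon for lf in t.leaf_node_iter()
                      if lf.taxon not in taxa]
            node = t.mrca(taxa=others)
    edge = node.edge
    t.reroot_at_edge(edge, update_bipartitions=False,
                     length1=(edge.length or 0.0) / 2,
                     length2=(edge.length or 0.0) / 2)
    return t


def is_in_clade_with(tree: dendropy.Tree, query_leaf: str,
                     reference_leaves: Sequence[str],
                     outgroup_leaves: Sequence[str],
                     contrast_leaves: Optional[Sequence[str]] = None,
                     ) -> tuple[bool, frozenset]:
    """Clade-membership test after outgroup rooting.

    True iff the smallest clade containing the query and all reference
    leaves excludes every contrast leaf. By default the contrast set is
    all leaves outside query/reference/outgroup.
    """
    if query_leaf in outgroup_leaves:
        raise ValueError("query cannot be part of the outgroup")
    rooted = root_on_outgroup(tree, list(outgroup_leaves))
    all_labels = {lf.taxon.label for lf in rooted.leaf_node_iter()}
    wanted = {query_leaf, *reference_leaves}
    missing = wanted - all_labels
    if missing:
        raise ValueError(f"leaves not in tree: {sorted(missing)}")
    if contrast_leaves is None:
        contrast = all_labels - wanted - set(outgroup_leaves)
    else:
        contrast = set(contrast_leaves)
    mrca = rooted.mrca(taxa=[rooted.taxon_namespace.get_taxon(l)
                             for l in sorted(wanted)])
    clade = _leaf_labels(mrca)
    return not (clade & contrast), clade


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick",
                                suppress_rooting=True))


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
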