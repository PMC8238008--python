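"""Distance phylogenetics: p-distances, neighbor-joining, bootstrap support.

The agglomeration is the classic Saitou–Nei algorithm on the Q-criterion.
Determinism is part of the contract: ties in the Q matrix are broken by the
lexicographically smallest label pair (a cluster is labelled by the smallest
leaf label it contains), and negative branch-length estimates are clamped to
zero so that downstream patristic distances stay metric-like.  Trees are
returned as :class:`dendropy.Tree` objects and serialize to Newick.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import dendropy
import numpy as np

GAP_CHARS = frozenset("-.")


def _as_matrix(seqs: Mapping[str, str] | Sequence[tuple[str, str]]):
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.array([list(s.upper()) for _, s in items])
    return labels, arr


def p_distance_matrix(seqs) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances with pairwise gap deletion.

    ``d(i, j)`` is the fraction of mismatching columns among the columns
    where neither sequence carries a gap character.
    """
    labels, arr = _as_matrix(seqs)
    gap = np.isin(arr, list(GAP_CHARS))
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ~gap[i] & ~gap[j]
            n_comp = int(comp.sum())
            if n_comp == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} "
                    f"and {labels[j]!r}")
            mism = int((arr[i][comp] != arr[j][comp]).sum())
            D[i, j] = D[j, i] = mism / n_comp
    return labels, D


def _validate_distances(D: np.ndarray) -> None:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if (np.asarray(D) < 0).any():
        raise ValueError("distance matrix contains negative entries")


def nj_tree(labels: Sequence[str], D: np.ndarray,
            taxon_namespace: dendropy.TaxonNamespace | None = None
            ) -> dendropy.Tree:
    """Neighbor-joining tree for >= 3 taxa.

    Joined-pair ties are broken by the lexicographically smallest
    (cluster label, cluster label) pair; negative branch lengths are
    clamped to 0.
    """
    _validate_distances(D)
    n = len(labels)
    if n != np.asarray(D).shape[0]:
        raise ValueError("labels do not match matrix dimension")
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")

    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(sorted(labels))
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)

    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxon_namespace.get_taxon(lab)
        if node.taxon is None:
            raise ValueError(f"label {lab!r} missing from taxon namespace")
        nodes.append(node)
    clab = list(labels)  # cluster label = smallest contained leaf label
    d = np.asarray(D, dtype=float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = None
        for a, b in cand:
            if a >= b:
                continue
            i, j = active[a], active[b]
            key = tuple(sorted((clab[i], clab[j])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (R[a] - R[b]) / (2 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            parent.add_child(child)
            child.edge.length = max(length, 0.0)
        # distances from the new cluster to remaining clusters
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        clab[i] = min(clab[i], clab[j])
        active.remove(j)

    x, y, z = active
    root = dendropy.Node()
    bx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    by = 0.5 * (d[x, y] + d[y, z] - d[x, z])
    bz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
    for idx, length in ((x, bx), (y, by), (z, bz)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as normalized leaf-label sets.

    Each internal edge is represented by the side that does *not*
    contain the lexicographically smallest leaf label, so the encoding
    is rooting-invariant.
    """
    all_leaves = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    anchor = all_leaves[0]
    total = len(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(below) <= 1 or len(below) >= total - 1:
            continue
        if anchor in below:
            below = frozenset(all_leaves) - below
        out.add(below)
    return out


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path lengths, ordered by sorted leaf label."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]])
    return labels, D


def bootstrap_support(seqs, n_replicates: int = 1000,
                      seed: int | None = None) -> dendropy.Tree:
    """NJ tree with bootstrap support on internal nodes.

    Alignment columns are resampled with replacement ``n_replicates``
    times; the support of an internal edge is the percentage of
    replicate NJ trees containing the same bipartition, written as the
    internal node label.  For fewer than 4 taxa support is undefined and
    the plain NJ tree is returned.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels, arr = _as_matrix(seqs)
    items = (list(seqs.items()) if isinstance(seqs, Mapping)
             else list(seqs))
    main_labels, D = p_distance_matrix(items)
    tree = nj_tree(main_labels, D)
    if len(labels) < 4:
        return tree

    rng = np.random.default_rng(seed)
    L = arr.shape[1]
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        boot = [(lab, "".join(row)) for lab, row in
                zip(labels, arr[:, cols])]
        blabels, bD = p_distance_matrix(boot)
        btree = nj_tree(blabels, bD)
        for bip in tree_bipartitions(btree):
            counts[bip] = counts.get(bip, 0) + 1

    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        bips = tree_bipartitions(tree)
        # normalize exactly as tree_bipartitions does
        all_leaves = sorted(leaf.taxon.label
                            for leaf in tree.leaf_node_iter())
        if all_leaves[0] in below:
            below = frozenset(all_leaves) - below
        if below in bips:
            pct = 100.0 * counts.get(below, 0) / n_replicates
            node.label = f"{pct:g}"
    return tree
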