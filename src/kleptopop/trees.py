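"""Neighbor-joining, locus bootstrap, consensus trees and AFLP distances.

Trees are represented as :class:`skbio.TreeNode`; internal node names carry
bootstrap / consensus support percentages.  Neighbor-joining is implemented
directly (Saitou & Nei agglomeration with deterministic lowest-index
tie-breaking) so that bootstrap replicates and tests are bit-reproducible;
scikit-bio's ``nj`` serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .bruvo import matrix_from_stack, per_locus_matrices
from .model import AflpMatrix, Dataset, DistanceMatrix, KleptopopError


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lowest (i, j) label-index pair.
    Negative branch lengths (possible for non-additive input) are clamped to
    zero with a warning.  On additive input the tree reproduces the matrix
    exactly.
    """
    n = len(dm)
    if n < 3:
        raise KleptopopError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes = [TreeNode(name=str(label)) for label in dm.labels]
    active = list(range(n))
    clamped = False

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima
        qmin = q.min()
        ii, jj = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))[0]
        if ii > jj:
            ii, jj = jj, ii
        i, j = active[ii], active[jj]
        vi = 0.5 * sub[ii, jj] + (r[ii] - r[jj]) / (2 * (m - 2))
        vj = sub[ii, jj] - vi
        if clamp_negative and (vi < 0 or vj < 0):
            clamped = True
            vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = TreeNode()
        nodes[i].length = float(vi)
        nodes[j].length = float(vj)
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to the rest
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # final three nodes: three-point formulas
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = [la, lb, lc]
    if clamp_negative and any(v < 0 for v in lens):
        clamped = True
        lens = [max(v, 0.0) for v in lens]
    root = TreeNode()
    for node, length in zip((nodes[a], nodes[b], nodes[c]), lens):
        node.length = float(length)
        root.append(node)
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0", stacklevel=2)
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each canonicalized to one side.

    A bipartition is represented by the smaller side (ties broken by sorted
    tip names) so that trees rooted differently compare equal.
    """
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            out.add(_canon(side, tips))
    return out


def _canon(side: frozenset, tips: frozenset) -> frozenset:
    other = tips - side
    if (len(side), sorted(side)) <= (len(other), sorted(other)):
        return side
    return other


def bootstrap_support(
    dataset: Dataset,
    isoloci: list[str],
    n_reps: int = 1000,
    seed: int = 0,
    collapse_threshold: float = 50.0,
    freq_scope: str = "site",
    add: bool = True,
    loss: bool = True,
) -> TreeNode:
    """NJ tree with locus-bootstrap supports, low-support nodes collapsed.

    Loci are resampled with replacement ``n_reps`` times; each pseudoreplicate
    matrix is rebuilt from the cached per-locus distances and a new NJ tree
    computed.  Support for each internal edge of the full-data tree is the
    percentage of replicate trees containing the same bipartition; edges
    below ``collapse_threshold`` are collapsed to polytomies.
    """
    if len(isoloci) < 2:
        raise KleptopopError("locus bootstrap needs at least 2 loci")
    stack, labels = per_locus_matrices(
        dataset, isoloci, freq_scope=freq_scope, add=add, loss=loss
    )
    full = matrix_from_stack(stack, labels)
    tree = neighbor_joining(full)
    tips = frozenset(labels)
    counts = {bp: 0 for bp in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    nloc = stack.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            pick = rng.integers(0, nloc, size=nloc)
            rep = matrix_from_stack(stack[pick], labels)
            rep_bps = bipartitions(neighbor_joining(rep))
            for bp in counts:
                if bp in rep_bps:
                    counts[bp] += 1
    support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    annotate_support(tree, support, tips)
    if collapse_threshold > 0:
        collapse_low_support(tree, collapse_threshold)
    return tree


def annotate_support(tree: TreeNode, support: dict, tips: frozenset) -> None:
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        bp = _canon(side, tips)
        if bp in support:
            node.name = f"{support[bp]:g}"


def collapse_low_support(tree: TreeNode, threshold: float) -> TreeNode:
    """Collapse internal edges whose support label is below ``threshold``."""
    for node in list(tree.non_tips(include_self=False)):
        try:
            sup = float(node.name) if node.name is not None else None
        except ValueError:
            sup = None
        if sup is None or sup < threshold:
            parent = node.parent
            for child in list(node.children):
                # preserve root-to-tip path lengths through the polytomy
                if child.length is not None and node.length is not None:
                    child.length += node.length
                parent.append(child)
            parent.remove(node)
    return tree


def majority_consensus(trees: list[TreeNode], mode: str = "extended") -> TreeNode:
    """Majority-rule consensus, optionally extended with compatible minority
    bipartitions (added greedily by decreasing frequency, ties broken by the
    lexicographically smallest bipartition)."""
    if not trees:
        raise KleptopopError("no trees to merge")
    tip_sets = [frozenset(t.name for t in tree.tips()) for tree in trees]
    tips = tip_sets[0]
    if any(ts != tips for ts in tip_sets):
        raise KleptopopError("trees have mismatched leaf sets")
    counts: dict[frozenset, int] = {}
    for tree in trees:
        for bp in bipartitions(tree):
            counts[bp] = counts.get(bp, 0) + 1
    n = len(trees)
    chosen = [bp for bp, c in counts.items() if c / n > 0.5]
    if mode == "extended":
        rest = sorted(
            (bp for bp, c in counts.items() if c / n <= 0.5),
            key=lambda bp: (-counts[bp], sorted(bp)),
        )
        for bp in rest:
            if all(_compatible(bp, other, tips) for other in chosen):
                chosen.append(bp)
    elif mode != "strict":
        raise KleptopopError(f"unknown consensus mode {mode!r}")
    tree = tree_from_bipartitions(chosen, tips)
    annotate_support(tree, {bp: 100.0 * counts[bp] / n for bp in chosen}, tips)
    return tree


def _compatible(a: frozenset, b: frozenset, tips: frozenset) -> bool:
    return (
        not (a & b)
        or not (a - b)
        or not (b - a)
        or not (tips - (a | b))
    )


def tree_from_bipartitions(bps: list[frozenset], tips: frozenset) -> TreeNode:
    """Build a (possibly multifurcating) tree realizing compatible splits."""
    ref = min(tips)  # root the laminar family away from a reference tip
    clusters = [bp if ref not in bp else tips - bp for bp in bps]
    clusters = sorted(set(clusters), key=lambda c: (len(c), sorted(c)))
    root = TreeNode()
    node_of: dict[str, TreeNode] = {}
    for name in sorted(tips):
        node_of[name] = TreeNode(name=name, length=0.0)
        root.append(node_of[name])
    for cluster in clusters:  # smallest first: sub-clusters already grouped,
        group = TreeNode(length=0.0)  # so members are direct children of root
        for child in list(root.children):
            if _tipset(child) <= set(cluster):
                root.remove(child)
                group.append(child)
        root.append(group)
    return root


def _tipset(node: TreeNode) -> set:
    if node.is_tip():
        return {node.name}
    return {t.name for t in node.tips()}


def simple_match_distance(aflp: AflpMatrix) -> DistanceMatrix:
    """Simple-matching distance between AFLP band profiles.

    ``d(i, j)`` is the fraction of bands where presence/absence differs —
    the complement of the simple-match coefficient.
    """
    if len(aflp.bands) == 0:
        raise KleptopopError("AFLP matrix has zero bands")
    values = squareform(pdist(aflp.presence.astype(bool), metric="hamming"))
    return DistanceMatrix(aflp.individuals, values)
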