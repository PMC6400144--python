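"""Distance-based clustering of CTLD sequences with bootstrap support.

The candidate receptors' C-type lectin-like domains are clustered from an
existing multiple alignment by p-distance + neighbor-joining, with support
for internal bipartitions estimated by column bootstrap (default 500
replicates). This is a deliberately desk-scale procedure: it answers "which
CTLDs group together" reproducibly; it is not a maximum-likelihood
reconstruction and clustering claims on real CTLD sets are qualitative.

Numerical rules fixed for reproducibility:

* pairwise deletion — a site contributes to a pair's distance only when
  neither sequence has a gap or ``X`` there;
* NJ ties in the Q-criterion are broken by the lexicographically smallest
  (id, id) pair, where a cluster is identified by its smallest leaf id;
* negative NJ branch-length estimates are clamped to 0 and the deficit is
  logged.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable

import dendropy
import numpy as np
import pandas as pd

from .io_formats import GAP, Alignment

logger = logging.getLogger(__name__)

_EXCLUDED = {GAP, "X"}


# ---------------------------------------------------------------------------
# p-distance with pairwise deletion
# ---------------------------------------------------------------------------


def p_distance(alignment: Alignment) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise proportion of mismatches over comparable sites.

    Returns ``(distances, comparable_sites)`` as symmetric DataFrames. A
    site is comparable for a pair when neither sequence has a gap or ``X``
    there. A pair with zero comparable sites is an error naming the pair.
    """
    ids = alignment.ids
    if len(ids) < 2:
        raise ValueError("p_distance needs at least 2 sequences")
    seqs = [s.upper() for s in alignment.sequences]
    n = len(ids)
    dist = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        comp[i, i] = sum(1 for c in seqs[i] if c not in _EXCLUDED)
        for j in range(i + 1, n):
            comparable = 0
            mismatch = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in _EXCLUDED or b in _EXCLUDED:
                    continue
                comparable += 1
                if a != b:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"pair ('{ids[i]}', '{ids[j]}') has zero comparable sites"
                )
            dist[i, j] = dist[j, i] = mismatch / comparable
            comp[i, j] = comp[j, i] = comparable
    return (
        pd.DataFrame(dist, index=list(ids), columns=list(ids)),
        pd.DataFrame(comp, index=list(ids), columns=list(ids)),
    )


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------


def nj_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining on a symmetric distance matrix.

    Returns an unrooted dendropy tree (trifurcation at the seed node for
    >= 4 taxa). Requires >= 3 taxa.
    """
    if list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix rows and columns must agree")
    mat = dist.values.astype(float)
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    taxa = list(dist.index)
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")

    namespace = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=namespace)
    nodes: dict[str, dendropy.Node] = {}
    for t in taxa:
        node = dendropy.Node(taxon=namespace.get_taxon(t))
        nodes[t] = node

    # active clusters keyed by their smallest leaf id (used for tie-breaks)
    active = sorted(taxa)
    d: dict[frozenset[str], float] = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            d[frozenset((a, b))] = mat[taxa.index(a), taxa.index(b)]

    def dget(a: str, b: str) -> float:
        return 0.0 if a == b else d[frozenset((a, b))]

    def clamp(value: float, context: str) -> float:
        if value < 0:
            logger.info("clamped negative branch length %.6g to 0 at %s", value, context)
            return 0.0
        return value

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dget(a, b) for b in active) for a in active}
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * dget(a, b) - r[a] - r[b]
                key_pair = tuple(sorted((a, b)))
                if (
                    best is None
                    or q < best[0] - 1e-12
                    or (abs(q - best[0]) <= 1e-12 and key_pair < (best[1], best[2]))
                ):
                    best = (q, key_pair[0], key_pair[1])
        assert best is not None
        _, a, b = best
        dab = dget(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la = clamp(la, f"join({a},{b})")
        lb = clamp(lb, f"join({a},{b})")

        parent = dendropy.Node()
        child_a, child_b = nodes[a], nodes[b]
        child_a.edge.length = la
        child_b.edge.length = lb
        parent.add_child(child_a)
        parent.add_child(child_b)

        new_key = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_key, c))] = 0.5 * (dget(a, c) + dget(b, c) - dab)
        active = sorted([c for c in active if c not in (a, b)] + [new_key])
        nodes[new_key] = parent

    # closed-form three-point join for the last three clusters
    a, b, c = active
    la = clamp(0.5 * (dget(a, b) + dget(a, c) - dget(b, c)), "final")
    lb = clamp(0.5 * (dget(a, b) + dget(b, c) - dget(a, c)), "final")
    lc = clamp(0.5 * (dget(a, c) + dget(b, c) - dget(a, b)), "final")
    seed = dendropy.Node()
    for key, length in ((a, la), (b, lb), (c, lc)):
        node = nodes[key]
        node.edge.length = length
        seed.add_child(node)
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions and bootstrap support
# ---------------------------------------------------------------------------


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree.

    Each split is canonicalized as the leaf side *not* containing the
    alphabetically first leaf, so splits compare across trees on the same
    leaf set regardless of rooting.
    """
    all_leaves = leaf_labels(tree)
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if not (2 <= len(below) <= len(all_leaves) - 2):
            continue
        side = below if ref not in below else all_leaves - below
        splits.add(frozenset(side))
    return splits


def _default_builder(alignment: Alignment) -> dendropy.Tree:
    dist, _ = p_distance(alignment)
    return nj_tree(dist)


def bootstrap_support(
    alignment: Alignment,
    builder: Callable[[Alignment], dendropy.Tree] | None = None,
    n_reps: int = 500,
    seed: int | None = None,
) -> dendropy.Tree:
    """Attach column-bootstrap support (percent of replicates) to the tree.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal bipartition of the full-data tree is the
    percentage of replicate trees containing it, written to the internal
    node labels. Replicates on which the builder fails (e.g. a pair with
    zero comparable sites) are skipped and counted; a warning is issued when
    more than 10% are skipped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if alignment.n_sequences < 3:
        raise ValueError("tree building needs >= 3 sequences")
    builder = builder or _default_builder
    rng = np.random.default_rng(seed)

    full_tree = builder(alignment)
    counts: dict[frozenset[str], int] = {s: 0 for s in bipartitions(full_tree)}

    n_cols = alignment.n_columns
    skipped = 0
    used = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        resampled = Alignment(
            ids=alignment.ids,
            sequences=tuple("".join(s[i] for i in idx) for s in alignment.sequences),
        )
        try:
            rep_tree = builder(resampled)
        except ValueError:
            skipped += 1
            continue
        used += 1
        rep_splits = bipartitions(rep_tree)
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    if used == 0:
        raise ValueError("all bootstrap replicates failed")
    if skipped > 0.10 * n_reps:
        warnings.warn(
            f"{skipped}/{n_reps} bootstrap replicates skipped (builder failures)",
            stacklevel=2,
        )

    all_leaves = leaf_labels(full_tree)
    ref = min(all_leaves)
    for node in full_tree.preorder_node_iter():
        if node is full_tree.seed_node or node.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if not (2 <= len(below) <= len(all_leaves) - 2):
            continue
        side = frozenset(below if ref not in below else all_leaves - below)
        support = 100.0 * counts[side] / used
        node.label = f"{support:g}"
    return full_tree


def slice_ctld_sequences(proteins, domains, label: str = "CTLD") -> list[tuple[str, str]]:
    """Extract CTLD subsequences by domain-interval slicing.

    Multiple CTLDs on one protein are numbered from the N-terminus: the
    first is designated 1, the next 2, and so on (id "<protein>_<k>").
    """
    by_protein: dict[str, list] = {}
    for dom in domains:
        if dom.label == label:
            by_protein.setdefault(dom.protein_id, []).append(dom)
    seqs = {p.id: p.sequence for p in proteins}
    out: list[tuple[str, str]] = []
    for pid in sorted(by_protein):
        for k, dom in enumerate(sorted(by_protein[pid], key=lambda d: d.start), start=1):
            out.append((f"{pid}_{k}", seqs[pid][dom.start - 1 : dom.end]))
    return out
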