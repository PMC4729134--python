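"""Bootstrap consensus trees and clade assignment for family proteins.

Pairwise distances are maximum-likelihood estimates under the JTT empirical
amino-acid model (eigendecomposition of the rate matrix, one-dimensional
likelihood optimization per pair); trees are neighbor-joining (dendropy).
Branch support comes from bootstrap resampling of alignment columns and a
majority-rule-extended consensus; branches under a support cutoff are
collapsed to polytomies, and subfamily labels propagate from anchor leaves to
the smallest label-pure anchored clade.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from ._jtt import rate_matrix
from ._seq import AA_INDEX
from .msa import Msa

MAX_DISTANCE = 10.0
UNPLACED = "unplaced"


class UnreliableInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# JTT maximum-likelihood pairwise distances

_Q, _PI = rate_matrix()
_D_SQRT = np.sqrt(_PI)
_B = (_Q * _D_SQRT[:, None]) / _D_SQRT[None, :]
_W, _U = np.linalg.eigh((_B + _B.T) / 2.0)
_LEFT = _U / _D_SQRT[:, None]
_RIGHT = (_U * _D_SQRT[:, None]).T


def transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the JTT model."""
    return (_LEFT * np.exp(_W * t)) @ _RIGHT


def encode_msa(msa: Msa) -> np.ndarray:
    """(n, ncol) integer matrix; gaps/ambiguous residues encoded as -1."""
    mat = np.full((msa.n_sequences, msa.n_columns), -1, dtype=np.int16)
    for i, row in enumerate(msa.rows):
        for j, c in enumerate(row):
            mat[i, j] = AA_INDEX.get(c, -1)
    return mat


def _pair_counts(row_a: np.ndarray, row_b: np.ndarray) -> np.ndarray:
    ok = (row_a >= 0) & (row_b >= 0)
    counts = np.zeros((20, 20))
    np.add.at(counts, (row_a[ok], row_b[ok]), 1.0)
    return counts


def ml_distance(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """JTT maximum-likelihood distance between two encoded rows.

    Maximizes sum_ab C_ab * log(pi_a * P_ab(t)) over the divergence time t
    (expected substitutions per site).  Pairs with no shared sites, or whose
    optimum exceeds the search bound, return ``MAX_DISTANCE``.
    """
    counts = _pair_counts(row_a, row_b)
    total = counts.sum()
    if total == 0:
        return MAX_DISTANCE
    if np.trace(counts) == total:
        return 0.0

    def neg_ll(t):
        p = transition_matrix(t)
        return -float(np.sum(counts * np.log(np.maximum(p * _PI[:, None], 1e-300))))

    res = minimize_scalar(neg_ll, bounds=(1e-6, MAX_DISTANCE), method="bounded")
    return float(min(res.x, MAX_DISTANCE))


def distance_matrix(encoded: np.ndarray) -> np.ndarray:
    n = encoded.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ml_distance(encoded[i], encoded[j])
    return d


# ---------------------------------------------------------------------------
# trees


@dataclass
class CladeTree:
    """A (consensus) tree with per-internal-branch bootstrap support (0-100).

    Supports are stored as internal node labels on the dendropy tree.
    """

    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def internal_supports(self) -> list[float]:
        out = []
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            if node.label is not None:
                out.append(float(node.label))
        return out

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _nj_tree(labels: list[str], dmat: np.ndarray, namespace: dendropy.TaxonNamespace) -> dendropy.Tree:
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=_dmat_csv(labels, dmat),
        taxon_namespace=namespace,
        delimiter=",",
    )
    return pdm.nj_tree()


def _dmat_csv(labels, dmat):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{x:.10f}" for x in dmat[i]) + "\n")
    buf.seek(0)
    return buf


def _tree_splits(tree: dendropy.Tree, all_taxa: frozenset, ref: str) -> set[frozenset]:
    """Nontrivial splits, each normalized to the side not containing ``ref``."""
    n = len(all_taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        cluster = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = cluster if ref not in cluster else all_taxa - cluster
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def _compatible(c: frozenset, accepted: list[frozenset]) -> bool:
    for a in accepted:
        inter = c & a
        if inter and inter != c and inter != a:
            return False
    return True


def _consensus_from_splits(
    split_freqs: dict[frozenset, float],
    taxa: list[str],
    namespace: dendropy.TaxonNamespace,
) -> dendropy.Tree:
    """Majority-rule-extended consensus, built greedily from split frequencies."""
    ref = taxa[0]
    ranked = sorted(
        split_freqs.items(),
        key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0]))),
    )
    accepted: list[tuple[frozenset, float]] = []
    for side, freq in ranked:
        if _compatible(side, [s for s, _ in accepted]):
            accepted.append((side, freq))
    tree = dendropy.Tree(taxon_namespace=namespace)
    nodes: dict[frozenset, dendropy.Node] = {}
    for side, freq in accepted:
        node = dendropy.Node()
        node.label = f"{100.0 * freq:g}"
        nodes[side] = node
    # parent of each cluster: the smallest accepted strict superset, else root
    for side, _ in sorted(accepted, key=lambda kv: -len(kv[0])):
        supersets = [s for s, _ in accepted if side < s]
        parent = nodes[min(supersets, key=len)] if supersets else tree.seed_node
        parent.add_child(nodes[side])
    for label in taxa:
        leaf = dendropy.Node(taxon=namespace.get_taxon(label))
        if label == ref:
            tree.seed_node.add_child(leaf)
            continue
        containing = [s for s, _ in accepted if label in s]
        parent = nodes[min(containing, key=len)] if containing else tree.seed_node
        parent.add_child(leaf)
    return tree


def build_tree(
    msa: Msa,
    bootstrap_n: int = 100,
    seed: int = 0,
    min_columns: int = 10,
) -> CladeTree:
    """Bootstrap majority-rule-extended consensus of NJ/JTT trees.

    Branch support is the percentage of replicates reproducing the partition;
    the result is deterministic given the seed.
    """
    if msa.n_sequences < 4:
        raise ValueError("an informative unrooted tree needs at least 4 sequences")
    if msa.n_columns < min_columns:
        raise UnreliableInputError(f"fewer than {min_columns} alignment columns")
    encoded = encode_msa(msa)
    taxa = list(msa.ids)
    namespace = dendropy.TaxonNamespace(taxa)
    all_taxa = frozenset(taxa)
    rng = np.random.default_rng(seed)
    split_counts: dict[frozenset, int] = {}
    for _ in range(bootstrap_n):
        cols = rng.integers(0, msa.n_columns, size=msa.n_columns)
        dmat = distance_matrix(encoded[:, cols])
        rep = _nj_tree(taxa, dmat, namespace)
        for side in _tree_splits(rep, all_taxa, taxa[0]):
            split_counts[side] = split_counts.get(side, 0) + 1
    freqs = {s: c / bootstrap_n for s, c in split_counts.items()}
    tree = _consensus_from_splits(freqs, taxa, namespace)
    return CladeTree(tree=tree)


def collapse_branches(clade_tree: CladeTree, min_support: float = 30.0) -> CladeTree:
    """Collapse internal branches with support strictly below ``min_support``."""
    tree = clade_tree.tree.clone(depth=1)
    to_collapse = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        if node.label is not None and float(node.label) < min_support:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return CladeTree(tree=tree)


def assign_clades(clade_tree: CladeTree, anchors: dict[str, str]) -> dict[str, str]:
    """Propagate anchor subfamily labels to unlabeled leaves.

    Each unlabeled leaf takes the label of the smallest tree partition side
    (over all branches, both sides considered, so the rule is root-free) that
    contains the leaf and at least one anchor, provided that side is
    label-pure among its anchors; otherwise the leaf is ``unplaced``.
    """
    tree = clade_tree.tree
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    all_taxa = frozenset(leaves)
    sides: list[frozenset] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        cluster = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        for side in (cluster, all_taxa - cluster):
            if 0 < len(side) < len(all_taxa):
                sides.append(side)
    labels: dict[str, str] = {}
    for leaf in leaves:
        if leaf in anchors:
            labels[leaf] = anchors[leaf]
            continue
        best: frozenset | None = None
        for side in sides:
            if leaf in side and any(a in side for a in anchors):
                if best is None or len(side) < len(best):
                    best = side
        if best is None:
            labels[leaf] = UNPLACED
            continue
        anchor_labels = {anchors[a] for a in anchors if a in best}
        labels[leaf] = anchor_labels.pop() if len(anchor_labels) == 1 else UNPLACED
    return labels
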