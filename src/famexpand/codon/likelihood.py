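"""Phylogenetic likelihood of codon alignments by Felsenstein pruning.

Works on a flattened index of the rooted gene tree.  Site-class mixtures
(site, branch and branch-site models) are proportion-weighted sums of
per-class site likelihoods; branch partitions (outgroup / background /
foreground) select which omega applies on each branch within a class.

Missing states (gaps, ambiguity) contribute a partial likelihood of one.
Per-node rescaling keeps partials in floating range on large trees.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from ..family_data import FamilyDataError, RootedGeneTree, TreeNode
from .alignment import CodonAlignment
from .models import BACKGROUND, FOREGROUND, G_ROOT, RateMatrixCache

__all__ = ["TreeIndex", "mixture_log_likelihood", "log_likelihood", "find_clade"]

_MARK_TO_LABEL = {"1": FOREGROUND, "G": G_ROOT, "g": G_ROOT}


class TreeIndex:
    """Post-order arrays over a rooted tree, paired with alignment rows."""

    def __init__(self, tree: RootedGeneTree, aln: CodonAlignment):
        self.tree = tree
        nodes = list(tree.postorder())
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root_index = self.n_nodes - 1
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.children] for n in nodes
        ]
        self.lengths = np.array([n.length for n in nodes], dtype=float)
        self.is_leaf = np.array([n.is_leaf for n in nodes], dtype=bool)
        # branch partition labels from '#' marks; BACKGROUND by default
        self.labels: list[str] = [
            _MARK_TO_LABEL.get(n.branch_mark, n.branch_mark) or BACKGROUND for n in nodes
        ]
        taxa_index = {t: i for i, t in enumerate(aln.taxa)}
        missing = [n.label for n in nodes if n.is_leaf and n.label not in taxa_index]
        if missing:
            raise FamilyDataError(f"tree leaves absent from alignment: {missing}")
        if sum(self.is_leaf) != aln.n_taxa:
            extra = set(aln.taxa) - {n.label for n in nodes if n.is_leaf}
            raise FamilyDataError(f"alignment taxa absent from tree: {sorted(extra)}")
        self.leaf_row = np.full(self.n_nodes, -1, dtype=np.intp)
        for i, n in enumerate(nodes):
            if n.is_leaf:
                self.leaf_row[i] = taxa_index[n.label]

    def set_labels(self, label_of_node) -> None:
        """Override branch partition labels (callable node-index -> label)."""
        self.labels = [label_of_node(i) for i in range(self.n_nodes)]

    def relabel(self, mapping: dict[str, str]) -> list[str]:
        return [mapping.get(lab, lab) for lab in self.labels]

    def apply_lengths_to_tree(self) -> None:
        for node, t in zip(self.nodes, self.lengths):
            node.length = float(t)


def find_clade(tree: RootedGeneTree, spec: Union[TreeNode, str, frozenset, set, Sequence[str]]) -> TreeNode:
    """Resolve a branch specification to its subtending node.

    Accepts a node object, a node/leaf label, or a set of leaf labels
    (the branch above their smallest containing clade).
    """
    if isinstance(spec, TreeNode):
        return spec
    if isinstance(spec, str):
        for n in tree.preorder():
            if n.label == spec:
                return n
        raise FamilyDataError(f"no node labelled {spec!r}")
    want = frozenset(spec)
    best = None
    for n in tree.preorder():
        leaves = frozenset(lf.label for lf in RootedGeneTree.leaves(_wrap(n, tree)))
        if leaves == want:
            return n
        if want <= leaves and (best is None or len(leaves) < len(best[1])):
            best = (n, leaves)
    if best is None:
        raise FamilyDataError(f"no clade containing leaves {sorted(want)}")
    return best[0]


def _wrap(node: TreeNode, tree: RootedGeneTree) -> RootedGeneTree:
    w = RootedGeneTree.__new__(RootedGeneTree)
    w.root = node
    w.leaf_to_species = tree.leaf_to_species
    return w


def _class_site_logliks(
    ti: TreeIndex,
    patterns: np.ndarray,
    pi: np.ndarray,
    cache: RateMatrixCache,
    kappa: float,
    omega_map: dict[str, float],
    scale_map: dict[str, float],
    labels: Sequence[str],
) -> np.ndarray:
    """Per-pattern log-likelihood for one site class."""
    npat = patterns.shape[1]
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros(npat)
    for i in range(ti.n_nodes):
        if ti.is_leaf[i]:
            continue
        M = np.ones((pi.size, npat))
        for c in ti.children[i]:
            lab = labels[c] if labels[c] in omega_map else BACKGROUND
            P = cache.transition_matrix(kappa, omega_map[lab], ti.lengths[c], scale_map[lab])
            if ti.is_leaf[c]:
                states = patterns[ti.leaf_row[c]]
                obs = states >= 0
                contrib = np.ones((pi.size, npat))
                contrib[:, obs] = P[:, states[obs]]
            else:
                contrib = P @ partials.pop(c)
            M *= contrib
        mx = M.max(axis=0)
        bad = mx <= 0
        if bad.any():
            mx = np.where(bad, 1.0, mx)
            logscale[bad] = -np.inf
        M /= mx
        logscale += np.log(mx)
        partials[i] = M
    L = pi @ partials[ti.root_index]
    with np.errstate(divide="ignore"):
        return np.log(L) + logscale


def mixture_log_likelihood(
    ti: TreeIndex,
    patterns: np.ndarray,
    counts: np.ndarray,
    pi: np.ndarray,
    kappa: float,
    props: np.ndarray,
    class_maps: Sequence[dict[str, float]],
    cache: Optional[RateMatrixCache] = None,
    labels: Optional[Sequence[str]] = None,
    per_site: bool = False,
):
    """Mixture log-likelihood; optionally also per-pattern class terms.

    Scaling: within each branch partition, matrices share the partition's
    mixture-average rate, so one expected substitution per codon per unit
    branch length holds on every branch at the fitted mixture.
    """
    cache = cache or RateMatrixCache(pi)
    labels = list(labels) if labels is not None else ti.labels
    used = set(labels[i] for i in range(ti.n_nodes) if i != ti.root_index)
    # labels on the tree with no omega in the model fall back to background
    labels = [lab if lab in class_maps[0] else BACKGROUND for lab in labels]
    used = {lab if lab in class_maps[0] else BACKGROUND for lab in used}
    scale_map = {
        lab: float(sum(p * cache.rate(kappa, m[lab]) for p, m in zip(props, class_maps)))
        for lab in used
    }
    per_class = np.empty((len(class_maps), patterns.shape[1]))
    for k, omega_map in enumerate(class_maps):
        per_class[k] = _class_site_logliks(
            ti, patterns, pi, cache, kappa, omega_map, scale_map, labels
        )
    with np.errstate(divide="ignore"):
        logp = np.log(np.asarray(props, dtype=float))
    site_ll = logsumexp(per_class + logp[:, None], axis=0)
    total = float(site_ll @ counts)
    if not np.isfinite(total):
        raise FloatingPointError(
            f"non-finite log-likelihood at pattern {int(np.argmin(site_ll))}"
        )
    if per_site:
        return total, per_class, site_ll
    return total


def compress_patterns(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, their counts, and site -> pattern indices."""
    patterns, inverse, counts = np.unique(
        aln.codons, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(float), inverse


def log_likelihood(
    aln: CodonAlignment,
    tree: RootedGeneTree,
    model,
    kappa: Optional[float] = None,
    pi: Optional[np.ndarray] = None,
) -> float:
    """Log-likelihood of an alignment under any model type.

    ``model`` is a CodonSubstModel (single omega, carries its own kappa and
    pi), or any mixture model exposing ``classes()`` (site, branch,
    branch-site) — for these, ``kappa`` is required and ``pi`` defaults to
    F3x4 frequencies estimated from the alignment.  Branch partitions are
    taken from '#' marks on the tree.
    """
    from .models import BranchPartitionModel, CodonSubstModel, codon_frequencies

    ti = TreeIndex(tree, aln)
    patterns, counts, _ = compress_patterns(aln)
    if isinstance(model, CodonSubstModel):
        props, maps = BranchPartitionModel({BACKGROUND: model.omega}).classes()
        labels = [BACKGROUND] * ti.n_nodes
        return mixture_log_likelihood(
            ti, patterns, counts, model.pi, model.kappa, props, maps, labels=labels
        )
    if kappa is None:
        raise ValueError("mixture models need kappa passed explicitly")
    if pi is None:
        pi = codon_frequencies(aln.codons)
    props, maps = model.classes()
    return mixture_log_likelihood(ti, patterns, counts, pi, kappa, props, maps)
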