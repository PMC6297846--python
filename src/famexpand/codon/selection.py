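"""Positive-selection tests: site (M8 vs M8a), branch, and branch-site.

All three are likelihood-ratio tests between nested codon models:

* site test — do some codons of a paralog set evolve with omega > 1?
  M8 (beta + omega_s >= 1) against M8a (beta + omega_s = 1), df = 1.
* branch test — does one tested (foreground) branch have its own omega?
  Three-ratio model (outgroup G, background, foreground) against the
  two-ratio null (outgroup G, rest), df = 1, Bonferroni-corrected for the
  number of branch partitions tested.
* branch-site test — do some sites on the foreground branch have
  omega > 1?  Model A against model A with omega2 fixed at 1, df = 1;
  significant tests are followed by Bayes empirical Bayes site
  identification.

Branch lengths are re-optimized under each null and held fixed for its
alternative by default (``branch_lengths="null"``); ``"fixed"`` keeps the
input lengths and ``"joint"`` optimizes them under both models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import chi2

from ..family_data import FamilyDataError, RootedGeneTree, TreeNode
from .alignment import CodonAlignment
from .fit import BranchSiteSpec, BranchSpec, FitError, FitResult, M8aSpec, M8Spec, fit
from .likelihood import TreeIndex, find_clade
from .models import BACKGROUND, FOREGROUND, G_ROOT

__all__ = [
    "LRTResult",
    "lrt",
    "site_model_test",
    "branch_model_test",
    "branch_site_test",
    "partition_labels",
]

_NESTING_TOL = 1e-3


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested codon models against chi2(df)."""

    statistic: float
    df: int
    p: float
    p_corrected: float
    m: int


def lrt(lnL_null: float, lnL_alt: float, df: int, m: int = 1) -> LRTResult:
    """2*(lnL_alt − lnL_null) against chi2(df); Bonferroni over m tests.

    A statistic that is negative within numerical tolerance is clipped to
    zero; a clearly negative one means the fits are not nested (or the
    alternative fit failed) and raises.
    """
    if df < 1 or m < 1:
        raise ValueError("df and m must be >= 1")
    stat = 2.0 * (lnL_alt - lnL_null)
    if stat < -_NESTING_TOL:
        raise FitError(
            f"lnL_alt ({lnL_alt}) < lnL_null ({lnL_null}): models not nested or fit failed"
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(statistic=stat, df=df, p=p, p_corrected=min(1.0, m * p), m=m)


# ---------------------------------------------------------------------------
# branch partition labelling
# ---------------------------------------------------------------------------

BranchRef = Union[TreeNode, str, frozenset, set, Sequence[str]]


def partition_labels(
    ti: TreeIndex,
    foreground: Optional[BranchRef] = None,
    outgroup: Optional[Sequence[BranchRef]] = None,
    foreground_whole_clade: bool = False,
) -> list[str]:
    """Post-order branch partition labels for the branch(-site) models.

    The G group covers each outgroup clade's subtending branch and every
    branch inside it.  The foreground is the subtending branch of the
    tested clade only (the ancestral branch leading to an orthogroup),
    unless ``foreground_whole_clade`` is set.
    """
    labels = [BACKGROUND] * ti.n_nodes
    tree = ti.tree

    def clade_indices(node: TreeNode) -> list[int]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            out.append(ti.index[id(n)])
            stack.extend(n.children)
        return out

    g_indices: set[int] = set()
    for ref in outgroup or ():
        node = find_clade(tree, ref)
        for i in clade_indices(node):
            labels[i] = G_ROOT
            g_indices.add(i)
    if foreground is not None:
        node = find_clade(tree, foreground)
        fg = clade_indices(node) if foreground_whole_clade else [ti.index[id(node)]]
        if any(i in g_indices for i in fg):
            raise FamilyDataError("foreground branch lies inside the outgroup (G) partition")
        for i in fg:
            labels[i] = FOREGROUND
    return labels


def _null_lengths(aln, tree, fit_null: FitResult) -> RootedGeneTree:
    """Tree with branch lengths replaced by the null fit's estimates."""
    if fit_null.branch_lengths is None:
        return tree
    tree2 = tree.copy()
    ti = TreeIndex(tree2, aln)
    ti.lengths[:] = fit_null.branch_lengths
    ti.apply_lengths_to_tree()
    return tree2


# ---------------------------------------------------------------------------
# test drivers
# ---------------------------------------------------------------------------

def site_model_test(
    aln: CodonAlignment,
    tree: RootedGeneTree,
    K: int = 10,
    n_restarts: int = 3,
    seed: int = 0,
    branch_lengths: str = "null",
    freq_model: str = "F3x4",
) -> tuple[FitResult, FitResult, LRTResult]:
    """M8 against M8a on one set of sequences (e.g. a species' paralogs)."""
    if aln.n_taxa < 3:
        raise FamilyDataError("site test needs at least 3 sequences")
    opt_bl_null = branch_lengths in {"null", "joint"}
    fit_null = fit(
        aln, tree, M8aSpec(K), n_restarts=n_restarts, seed=seed,
        optimize_branch_lengths=opt_bl_null, freq_model=freq_model,
    )
    tree_alt = _null_lengths(aln, tree, fit_null) if branch_lengths == "null" else tree
    fit_alt = fit(
        aln, tree_alt, M8Spec(K), n_restarts=n_restarts, seed=seed + 1,
        optimize_branch_lengths=(branch_lengths == "joint"),
        freq_model=freq_model,
        warm_start={**fit_null.parameters, "omega_s": 1.0},
    )
    return fit_null, fit_alt, lrt(fit_null.lnL, fit_alt.lnL, df=1)


def branch_model_test(
    aln: CodonAlignment,
    tree: RootedGeneTree,
    foreground_branch: BranchRef,
    outgroup_branches: Sequence[BranchRef] = (),
    n_restarts: int = 3,
    seed: int = 0,
    m: int = 6,
    branch_lengths: str = "null",
    freq_model: str = "F3x4",
) -> tuple[FitResult, FitResult, LRTResult]:
    """Three-ratio (G, background, foreground) against two-ratio null."""
    ti = TreeIndex(tree, aln)
    labels_alt = partition_labels(ti, foreground=foreground_branch, outgroup=outgroup_branches)
    labels_null = [BACKGROUND if lab == FOREGROUND else lab for lab in labels_alt]
    null_partitions = (BACKGROUND, G_ROOT) if G_ROOT in labels_null else (BACKGROUND,)
    opt_bl_null = branch_lengths in {"null", "joint"}
    fit_null = fit(
        aln, tree, BranchSpec(null_partitions), n_restarts=n_restarts, seed=seed,
        optimize_branch_lengths=opt_bl_null, freq_model=freq_model, labels=labels_null,
    )
    tree_alt = _null_lengths(aln, tree, fit_null) if branch_lengths == "null" else tree
    warm = dict(fit_null.parameters)
    warm[f"omega_{FOREGROUND}"] = warm.get(f"omega_{BACKGROUND}", 0.2)
    fit_alt = fit(
        aln, tree_alt, BranchSpec(null_partitions + (FOREGROUND,)),
        n_restarts=n_restarts, seed=seed + 1,
        optimize_branch_lengths=(branch_lengths == "joint"),
        freq_model=freq_model, labels=labels_alt, warm_start=warm,
    )
    return fit_null, fit_alt, lrt(fit_null.lnL, fit_alt.lnL, df=1, m=m)


def branch_site_test(
    aln: CodonAlignment,
    tree: RootedGeneTree,
    foreground_branch: BranchRef,
    outgroup_branches: Sequence[BranchRef] = (),
    n_restarts: int = 3,
    seed: int = 0,
    m: int = 1,
    branch_lengths: str = "null",
    freq_model: str = "F3x4",
    beb_grid_size: int = 10,
    alpha: float = 0.05,
):
    """Branch-site model A against its omega2 = 1 null; BEB when significant.

    The outgroup branches share the background site classes here (the null
    assumes one selective regime over the whole tree); they are accepted so
    the same roster drives branch and branch-site tests.
    """
    from .beb import BEBResult, beb  # local import to avoid cycle

    ti = TreeIndex(tree, aln)
    labels = partition_labels(ti, foreground=foreground_branch, outgroup=outgroup_branches)
    labels = [BACKGROUND if lab == G_ROOT else lab for lab in labels]
    opt_bl_null = branch_lengths in {"null", "joint"}
    fit_null = fit(
        aln, tree, BranchSiteSpec(null=True), n_restarts=n_restarts, seed=seed,
        optimize_branch_lengths=opt_bl_null, freq_model=freq_model, labels=labels,
    )
    tree_alt = _null_lengths(aln, tree, fit_null) if branch_lengths == "null" else tree
    warm = dict(fit_null.parameters)
    warm["omega2"] = 1.0
    fit_alt = fit(
        aln, tree_alt, BranchSiteSpec(null=False), n_restarts=n_restarts, seed=seed + 1,
        optimize_branch_lengths=(branch_lengths == "joint"),
        freq_model=freq_model, labels=labels, warm_start=warm,
    )
    result = lrt(fit_null.lnL, fit_alt.lnL, df=1, m=m)
    beb_result: Optional[BEBResult] = None
    if result.p < alpha:
        beb_result = beb(
            aln, tree_alt, fit_alt, labels=labels, grid_size=beb_grid_size
        )
    return fit_null, fit_alt, result, beb_result
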