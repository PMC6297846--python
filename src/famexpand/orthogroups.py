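"""Orthogroup delineation on rooted gene trees by species overlap.

An orthogroup (OG) is the set of genes in a species sample descending from
a single gene in the sample's last common ancestor.  On a rooted gene tree
with a species taxonomy, an OG at a taxonomic split (e.g. monocots vs
dicots) is a clade mixing at least two of the split's sibling lineages —
such a clade must trace back to a gene older than the split.  A node whose
children THEMSELVES each mix two or more split lineages witnesses a
duplication that predates the split, so delineation recurses into it; any
other mixed node is emitted as one orthogroup (single-lineage children are
kept inside it rather than orphaned).  Single-lineage clades falling
between emitted OGs are reported unassigned.

OGs at a shallow split are refined at deeper splits (e.g. within
commelinids, then within Poaceae), and hierarchical names are assigned:
letters at the top level, digit suffixes below, lowercase letters below
that (A, A7, A7a, ...).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .family_data import FamilyDataError, RootedGeneTree, SpeciesTaxonomy, TreeNode

__all__ = ["Orthogroup", "ClassificationReport", "delineate", "refine", "assign_names"]


@dataclass
class Orthogroup:
    """A named clade of genes descending from one ancestral gene."""

    name: Optional[str]
    node: TreeNode
    members: list[str]
    split_level: tuple[str, ...]
    support: Optional[float]
    parent_og: Optional[str] = None
    # preorder position of the defining node; fixes naming order
    traversal_order: int = 0
    lineages: tuple[str, ...] = ()


@dataclass
class ClassificationReport:
    """Delineation outcome: orthogroups plus unassigned leaves with reasons."""

    orthogroups: list[Orthogroup]
    unassigned: list[tuple[str, str]]  # (gene_id, reason)
    log: list[str] = field(default_factory=list)

    def all_assigned(self) -> set[str]:
        return {g for og in self.orthogroups for g in og.members}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for og in self.orthogroups:
            for gid in og.members:
                rows.append(
                    {
                        "gene_id": gid,
                        "og_name": og.name,
                        "parent_og": og.parent_og,
                        "node_support": og.support,
                        "status": "assigned",
                    }
                )
        for gid, reason in self.unassigned:
            rows.append(
                {
                    "gene_id": gid,
                    "og_name": None,
                    "parent_og": None,
                    "node_support": None,
                    "status": f"unassigned: {reason}",
                }
            )
        return pd.DataFrame(rows, columns=["gene_id", "og_name", "parent_og", "node_support", "status"])


def _leaves_under(node: TreeNode) -> list[TreeNode]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(reversed(n.children))
    return out


def delineate(
    tree: RootedGeneTree,
    taxonomy: SpeciesTaxonomy,
    split: Iterable[str],
    min_support: Optional[float] = None,
    root: Optional[TreeNode] = None,
) -> ClassificationReport:
    """Delineate orthogroups at a taxonomic split on a rooted gene tree.

    ``split`` is a set of sibling lineage labels (e.g. {"monocots",
    "dicots"}).  Leaves whose species lie in none of the split lineages are
    outgroup evidence and never trigger nor join an OG.  With
    ``min_support`` set, a would-be OG node with lower support is recursed
    into instead of emitted (logged).
    """
    split = tuple(sorted(set(split)))
    if len(split) < 2:
        raise FamilyDataError("a split needs at least two sibling lineages")
    for lab in split:
        if not taxonomy.has_lineage(lab):
            raise FamilyDataError(f"split lineage {lab!r} not found in taxonomy")
    tree.validate_species(taxonomy)
    start = root if root is not None else tree.root

    # preorder numbering for deterministic naming order, independent of
    # child ordering in the source Newick: order by sorted leaf-label sets
    order: dict[int, int] = {}

    def _number(node: TreeNode, counter: list[int]) -> None:
        order[id(node)] = counter[0]
        counter[0] += 1
        for ch in sorted(node.children, key=lambda c: min(lf.label for lf in _leaves_under(c))):
            _number(ch, counter)

    _number(start, [0])

    lineage_of: dict[int, Optional[str]] = {}
    for lf in _leaves_under(start):
        lineage_of[id(lf)] = taxonomy.split_lineage(tree.species_of(lf), split)

    def lineages_under(node: TreeNode) -> set[str]:
        return {
            lineage_of[id(lf)]
            for lf in _leaves_under(node)
            if lineage_of[id(lf)] is not None
        }

    orthogroups: list[Orthogroup] = []
    unassigned: list[tuple[str, str]] = []
    log: list[str] = []

    def emit(node: TreeNode) -> None:
        members = [
            lf.label for lf in _leaves_under(node) if lineage_of[id(lf)] is not None
        ]
        for lf in _leaves_under(node):
            if lineage_of[id(lf)] is None:
                unassigned.append((lf.label, "outgroup species at this split"))
        orthogroups.append(
            Orthogroup(
                name=None,
                node=node,
                members=members,
                split_level=split,
                support=node.support,
                traversal_order=order[id(node)],
                lineages=tuple(sorted(lineages_under(node))),
            )
        )

    def mark_unassigned(node: TreeNode, reason: str) -> None:
        for lf in _leaves_under(node):
            if lineage_of[id(lf)] is None:
                unassigned.append((lf.label, "outgroup species at this split"))
            else:
                unassigned.append((lf.label, reason))

    def recurse(node: TreeNode) -> None:
        lins = lineages_under(node)
        if len(lins) < 2:
            reason = (
                "single-lineage clade outside any orthogroup"
                if lins
                else "outgroup species at this split"
            )
            mark_unassigned(node, reason)
            return
        # outgroup-only children are ignored for delineation: pass through
        # nodes with a single ingroup child (their placement is evidence,
        # not membership)
        effective = [ch for ch in node.children if lineages_under(ch)]
        if len(effective) == 1:
            for ch in node.children:
                if ch is not effective[0]:
                    mark_unassigned(ch, "outgroup species at this split")
            recurse(effective[0])
            return
        mixed_children = [ch for ch in effective if len(lineages_under(ch)) >= 2]
        if len(mixed_children) >= 2:
            # two or more children each mix split lineages: a duplication
            # predating the split — recurse
            for ch in node.children:
                recurse(ch)
            return
        if min_support is not None and node.support is not None and node.support < min_support:
            log.append(
                f"node (support {node.support:.3g} < {min_support:.3g}) not emitted; recursing"
            )
            if mixed_children:
                for ch in node.children:
                    recurse(ch)
                return
            mark_unassigned(node, f"low support ({node.support:.3g})")
            return
        emit(node)

    recurse(start)
    orthogroups.sort(key=lambda og: og.traversal_order)
    report = ClassificationReport(orthogroups=orthogroups, unassigned=unassigned, log=log)
    _check_partition(report, start, lineage_of)
    return report


def _check_partition(report: ClassificationReport, start: TreeNode, lineage_of) -> None:
    assigned = report.all_assigned()
    un = {g for g, _ in report.unassigned}
    if assigned & un:
        raise AssertionError(f"leaves both assigned and unassigned: {assigned & un}")
    everything = {lf.label for lf in _leaves_under(start)}
    if assigned | un != everything:
        raise AssertionError("partition property violated: some leaves unaccounted for")


def refine(
    og: Orthogroup,
    tree: RootedGeneTree,
    taxonomy: SpeciesTaxonomy,
    deeper_split: Iterable[str],
    min_support: Optional[float] = None,
) -> ClassificationReport:
    """Delineate sub-orthogroups of ``og`` at a strictly deeper split."""
    deeper = tuple(sorted(set(deeper_split)))
    if not taxonomy.is_strictly_deeper(deeper, og.split_level):
        raise FamilyDataError(
            f"split {deeper} is not strictly below {og.split_level}"
        )
    report = delineate(tree, taxonomy, deeper, min_support=min_support, root=og.node)
    member_set = set(og.members)
    for sub in report.orthogroups:
        sub.parent_og = og.name
        sub.members = [m for m in sub.members if m in member_set]
    return report


_TOP_LABELS = string.ascii_uppercase
_SUB_LABELS = string.ascii_lowercase


def assign_names(
    report: ClassificationReport,
    family_prefix: str,
    parent: Optional[Orthogroup] = None,
    letters: Optional[Sequence[str]] = None,
) -> ClassificationReport:
    """Assign hierarchical names in traversal order.

    Top-level OGs get uppercase letters (or the user-supplied ``letters``),
    children of a named OG get digit suffixes, grandchildren lowercase
    letters: ``PREFIX-A``, ``PREFIX-A7``, ``PREFIX-A7a``.
    """
    ogs = sorted(report.orthogroups, key=lambda og: og.traversal_order)
    n = len(ogs)
    if n == 0:
        return report
    if parent is None:
        pool = list(letters) if letters is not None else list(_TOP_LABELS)
        if n > len(pool):
            raise FamilyDataError(
                f"{n} orthogroups but only {len(pool)} labels; pass explicit letters"
            )
        for og, lab in zip(ogs, pool):
            og.name = f"{family_prefix}-{lab}"
        return report
    depth = _name_depth(parent.name, family_prefix)
    if depth == 0:  # children of a top-level OG: digits
        suffixes = [str(i + 1) for i in range(n)]
    elif depth == 1:  # grandchildren: lowercase letters
        if n > len(_SUB_LABELS):
            raise FamilyDataError(f"{n} sub-orthogroups exceed available lowercase labels")
        suffixes = list(_SUB_LABELS[:n])
    else:
        suffixes = [f".{i + 1}" for i in range(n)]
    for og, suf in zip(ogs, suffixes):
        og.name = f"{parent.name}{suf}"
        og.parent_og = parent.name
    return report


def _name_depth(name: str, family_prefix: str) -> int:
    tail = name[len(family_prefix) + 1 :]  # strip "PREFIX-"
    # depth 0: letters only; depth 1: letters+digits; deeper: trailing lowercase
    if tail.isalpha() and tail.isupper():
        return 0
    if tail[-1].isdigit():
        return 1
    return 2
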