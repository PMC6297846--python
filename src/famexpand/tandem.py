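"""Tandem clusters and cross-species collinearity of family loci.

Family genes on the same chromosome separated by no more than ``max_gap``
other (non-family) genes form a tandem cluster; clustering is the
transitive closure of that pairwise rule over gene-order ranks.  Clusters
from several species are then laid out as a collinearity matrix — one row
per cluster, one column per orthogroup label — and a consensus row gives,
per column, the fraction of loci carrying the orthogroup and the majority
gene orientation ('>', '<', 'mixed' or 'unknown') after normalizing
reversed loci to the shared column order.  The consensus reconstructs the
ancestral structure of a tandem locus from its fractionated descendants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .family_data import FamilyDataError, GeneRecord

__all__ = [
    "TandemCluster",
    "CollinearityMatrix",
    "detect_clusters",
    "build_matrix",
    "consensus",
    "count_loci",
]

PARTIAL = "Partial"  # rendering of a cluster member without an OG label


@dataclass
class TandemCluster:
    """An ordered run of family genes on one chromosome."""

    species_code: str
    chromosome: str
    members: list[tuple[str, int, str, Optional[str]]]  # (gene_id, rank, strand, og)

    def __post_init__(self) -> None:
        self.members = sorted(self.members, key=lambda m: m[1])

    @property
    def gene_ids(self) -> list[str]:
        return [m[0] for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


def detect_clusters(
    genes: Sequence[GeneRecord],
    max_gap: int = 5,
    keep_singletons: bool = False,
    og_assignment: Optional[dict[str, str]] = None,
) -> list[TandemCluster]:
    """Chain family genes into tandem clusters within (species, chromosome).

    Two consecutive family genes join the same cluster when the number of
    intervening genes (rank difference − 1) is at most ``max_gap``; the
    boundary is inclusive.  Clusters of size >= 2 are returned unless
    ``keep_singletons``.  Mixed-species input is grouped per species.
    """
    if max_gap < 0:
        raise FamilyDataError("max_gap must be >= 0")
    og_assignment = og_assignment or {}
    by_group: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_group.setdefault((g.species_code, g.chromosome), []).append(g)
    clusters: list[TandemCluster] = []
    for (species, chrom), group in sorted(by_group.items()):
        group = sorted(group, key=lambda g: g.order_rank)
        run: list[GeneRecord] = []
        for g in group:
            if run and (g.order_rank - run[-1].order_rank - 1) > max_gap:
                clusters.append(_make_cluster(species, chrom, run, og_assignment))
                run = []
            run.append(g)
        if run:
            clusters.append(_make_cluster(species, chrom, run, og_assignment))
    if not keep_singletons:
        clusters = [c for c in clusters if len(c) >= 2]
    return clusters


def _make_cluster(species, chrom, run, og_assignment) -> TandemCluster:
    return TandemCluster(
        species_code=species,
        chromosome=chrom,
        members=[
            (g.gene_id, g.order_rank, g.strand, og_assignment.get(g.gene_id))
            for g in run
        ],
    )


def count_loci(
    clusters: Sequence[TandemCluster], species_code: str, known_species: Optional[set] = None
) -> int:
    """Number of tandem loci (clusters) of one species.

    ``known_species`` (when given) makes unknown codes an error rather than
    a silent zero.
    """
    if known_species is not None and species_code not in known_species:
        raise FamilyDataError(f"unknown species code {species_code!r}")
    return sum(1 for c in clusters if c.species_code == species_code)


# ---------------------------------------------------------------------------
# collinearity matrix
# ---------------------------------------------------------------------------

@dataclass
class CollinearityMatrix:
    """Clusters laid out against a shared orthogroup column order."""

    column_order: list[str]
    clusters: list[TandemCluster]
    cells: list[dict[str, list[str]]]  # per row: og label -> gene ids
    reversed_rows: list[bool]

    def row_label(self, i: int) -> str:
        c = self.clusters[i]
        return f"{c.species_code}:{c.chromosome}"

    def render_cell(self, i: int, og: str) -> str:
        genes = self.cells[i].get(og, [])
        return ",".join(genes) if genes else ""

    def to_tsv(self, path: str) -> None:
        cons = consensus(self)
        with open(path, "w") as fh:
            fh.write("locus\t" + "\t".join(self.column_order) + "\n")
            for i in range(len(self.clusters)):
                row = [self.render_cell(i, og) for og in self.column_order]
                fh.write(self.row_label(i) + "\t" + "\t".join(row) + "\n")
            arrow = {">": ">", "<": "<", "mixed": "mixed", "unknown": "?"}
            fh.write(
                "Consensus\t"
                + "\t".join(arrow[cons[og][1]] for og in self.column_order)
                + "\n"
            )


def _majority_order(
    clusters: Sequence[TandemCluster], reverse_flags: Optional[Sequence[bool]] = None
) -> tuple[list[str], bool]:
    """Greedy topological order of the majority adjacency graph.

    Votes come from consecutive within-cluster label pairs (unlabelled
    members skipped); rows flagged reversed vote with their order flipped.
    For each unordered pair the majority direction wins; ties cancel.
    Returns (order, cyclic); a cyclic majority falls back to lexicographic
    order.
    """
    votes: dict[tuple[str, str], int] = {}
    labels: set[str] = set()
    for i, c in enumerate(clusters):
        labs = [m[3] for m in c.members if m[3] is not None]
        if reverse_flags is not None and reverse_flags[i]:
            labs = labs[::-1]
        labels.update(labs)
        for a, b in zip(labs, labs[1:]):
            if a == b:
                continue
            votes[(a, b)] = votes.get((a, b), 0) + 1
    G = nx.DiGraph()
    G.add_nodes_from(sorted(labels))
    for (a, b), n_ab in sorted(votes.items()):
        n_ba = votes.get((b, a), 0)
        if n_ab > n_ba:
            G.add_edge(a, b)
    try:
        return list(nx.lexicographical_topological_sort(G)), False
    except nx.NetworkXUnfeasible:
        return sorted(labels), True


def _auto_column_order(clusters: Sequence[TandemCluster]) -> list[str]:
    """Column order maximizing agreement with within-cluster adjacencies.

    Genomically inverted loci vote against the ancestral order, so the
    majority order and the per-row reversal flags are solved jointly by a
    short fixed-point iteration: order -> reversal flags -> re-vote.
    """
    order, cyclic = _majority_order(clusters)
    for _ in range(4):
        col_index = {og: i for i, og in enumerate(order)}
        flags = [
            _row_agreement(c, col_index, True) > _row_agreement(c, col_index, False)
            for c in clusters
        ]
        new_order, cyclic = _majority_order(clusters, flags)
        if new_order == order:
            break
        order = new_order
    if cyclic:
        warnings.warn(
            "cyclic majority adjacencies; falling back to lexicographic column order"
        )
    return order


def _row_agreement(cluster: TandemCluster, col_index: dict[str, int], reverse: bool) -> int:
    labs = [m[3] for m in cluster.members if m[3] in col_index]
    if reverse:
        labs = labs[::-1]
    pos = [col_index[lab] for lab in labs]
    return sum(1 for a, b in zip(pos, pos[1:]) if a <= b)


def build_matrix(
    clusters: Sequence[TandemCluster],
    og_assignment: Optional[dict[str, str]] = None,
    column_order: Optional[Sequence[str]] | str = "auto",
) -> CollinearityMatrix:
    """Lay clusters out against a shared orthogroup column order.

    ``og_assignment`` overrides/supplies member OG labels.  With
    ``column_order="auto"`` the order maximizing agreement with observed
    within-cluster adjacencies is chosen; rows are reversed as a unit when
    reversal strictly increases their agreement with that order.
    """
    clusters = list(clusters)
    if og_assignment:
        clusters = [
            TandemCluster(
                c.species_code,
                c.chromosome,
                [(g, r, s, og_assignment.get(g, og)) for g, r, s, og in c.members],
            )
            for c in clusters
        ]
    if isinstance(column_order, str) and column_order == "auto":
        order = _auto_column_order(clusters)
    else:
        order = list(column_order)
    col_index = {og: i for i, og in enumerate(order)}
    cells = []
    reversed_rows = []
    for c in clusters:
        fwd = _row_agreement(c, col_index, reverse=False)
        rev = _row_agreement(c, col_index, reverse=True)
        reversed_rows.append(rev > fwd)
        cell: dict[str, list[str]] = {}
        for gid, _rank, _strand, og in c.members:
            key = og if og in col_index else PARTIAL
            cell.setdefault(key, []).append(gid)
        cells.append(cell)
    return CollinearityMatrix(
        column_order=order, clusters=clusters, cells=cells, reversed_rows=reversed_rows
    )


def consensus(matrix: CollinearityMatrix) -> dict[str, tuple[float, str]]:
    """Per-column (presence fraction, majority orientation).

    Orientation votes are the strands of the column's genes after
    normalizing reversed rows (strand flipped); '+' renders '>' and '−'
    renders '<'; ties are 'mixed', no stranded votes 'unknown'.
    """
    if not matrix.clusters:
        raise FamilyDataError("empty collinearity matrix")
    n_rows = len(matrix.clusters)
    out: dict[str, tuple[float, str]] = {}
    for og in matrix.column_order:
        present = 0
        plus = minus = 0
        for i, c in enumerate(matrix.clusters):
            genes = matrix.cells[i].get(og, [])
            if not genes:
                continue
            present += 1
            flip = matrix.reversed_rows[i]
            for gid, _rank, strand, lab in c.members:
                if lab != og or strand == "unknown":
                    continue
                eff = strand if not flip else ("+" if strand == "-" else "-")
                if eff == "+":
                    plus += 1
                else:
                    minus += 1
        if plus == minus == 0:
            orient = "unknown"
        elif plus == minus:
            orient = "mixed"
        else:
            orient = ">" if plus > minus else "<"
        out[og] = (present / n_rows, orient)
    return out
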