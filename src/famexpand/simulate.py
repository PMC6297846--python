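"""Synthetic data: codon alignments under selection regimes and gene
families with tandem/WGD duplication histories.

Two generators cover every pipeline stage without external data:

* :func:`simulate_codon_alignment` evolves codon sequences along a tree
  under any of the substitution models (single omega, site mixture, branch
  partition, branch-site), returning the true per-site class labels for
  sensitivity/specificity scoring.

* :func:`simulate_gene_family` runs a birth–death process of duplications
  and losses along a species tree, with tandem duplications inserting
  copies at adjacent gene-order ranks, segmental duplications landing on
  random chromosomes, and whole-genome duplications copying every locus
  followed by fractionation (loss of copies).  Every extant gene carries
  its true orthogroup (ancestral-gene identity at the configured split) and
  an event log records every event — the ground truth for recovery tests.

Chromosomes carry a backbone of inert "other genes" so rank gaps are
meaningful for the tandem-cluster rule.  All randomness flows from the
config seed through one integer-state generator; fixed seed means
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .family_data import GeneRecord, RootedGeneTree, TreeNode
from .codon.alignment import CodonAlignment
from .codon.genetic_code import N_CODONS
from .codon.likelihood import TreeIndex
from .codon.models import (
    BACKGROUND,
    CodonSubstModel,
    RateMatrixCache,
)

__all__ = ["SimulationConfig", "SimulatedFamily", "simulate_codon_alignment", "simulate_gene_family"]


# ---------------------------------------------------------------------------
# codon alignment simulation
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    tree: RootedGeneTree,
    model,
    n_codons: int,
    seed: int,
    kappa: Optional[float] = None,
    pi: Optional[np.ndarray] = None,
    labels: Optional[Sequence[str]] = None,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codons along a tree; returns (alignment, true class labels).

    ``model`` is a CodonSubstModel (single omega; carries kappa/pi) or any
    mixture model exposing ``classes()`` — those need ``kappa`` and ``pi``
    (``pi`` defaults to uniform).  Branch partitions come from '#' marks on
    the tree or the explicit post-order ``labels``.  Site classes are drawn
    once per site from the class proportions.  Transition matrices use the
    same scaling convention as the likelihood engine, so refitting
    simulated data recovers the generating parameters.
    """
    rng = np.random.default_rng(seed)
    if isinstance(model, CodonSubstModel):
        from .codon.models import BranchPartitionModel

        kappa = model.kappa
        pi = model.pi
        props, maps = BranchPartitionModel({BACKGROUND: model.omega}).classes()
    else:
        if kappa is None:
            raise ValueError("mixture models need kappa")
        if pi is None:
            pi = np.full(N_CODONS, 1.0 / N_CODONS)
        props, maps = model.classes()
    pi = np.asarray(pi, dtype=float)

    # dummy alignment so TreeIndex can pair leaves with rows
    leaf_labels = tree.leaf_labels()
    dummy = CodonAlignment(leaf_labels, np.zeros((len(leaf_labels), 0), dtype=np.int16))
    ti = TreeIndex(tree, dummy)
    labels = list(labels) if labels is not None else list(ti.labels)
    labels = [lab if lab in maps[0] else BACKGROUND for lab in labels]
    cache = RateMatrixCache(pi)
    used = set(labels)
    scale_map = {
        lab: float(sum(p * cache.rate(kappa, m[lab]) for p, m in zip(props, maps)))
        for lab in used
    }

    site_class = rng.choice(len(props), size=n_codons, p=np.asarray(props) / np.sum(props))
    states = np.empty((ti.n_nodes, n_codons), dtype=np.int16)
    states[ti.root_index] = rng.choice(N_CODONS, size=n_codons, p=pi)

    # preorder = reversed postorder
    for i in range(ti.n_nodes - 2, -1, -1):
        parent = _parent_index(ti, i)
        lab = labels[i]
        for k, omega_map in enumerate(maps):
            sites = np.flatnonzero(site_class == k)
            if sites.size == 0:
                continue
            P = cache.transition_matrix(kappa, omega_map[lab], ti.lengths[i], scale_map[lab])
            rows = P[states[parent, sites]]
            rows = rows / rows.sum(axis=1, keepdims=True)
            cdf = np.cumsum(rows, axis=1)
            u = rng.random(sites.size)
            states[i, sites] = (u[:, None] > cdf).sum(axis=1)

    codons = np.zeros((len(leaf_labels), n_codons), dtype=np.int16)
    row_of = {t: r for r, t in enumerate(leaf_labels)}
    for i in range(ti.n_nodes):
        if ti.is_leaf[i]:
            codons[row_of[ti.nodes[i].label]] = states[i]
    return CodonAlignment(leaf_labels, codons), site_class


def _parent_index(ti: TreeIndex, child: int) -> int:
    node = ti.nodes[child]
    return ti.index[id(node.parent)]


# ---------------------------------------------------------------------------
# gene family simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Conditions for a gene-family simulation.

    Rates are per gene lineage per unit branch length.  ``wgd_events`` maps
    a species-tree node label to the retention probability of the WGD on
    the branch leading to that node.  ``og_split`` names the species-tree
    node at which true orthogroup identities are frozen (None = root, i.e.
    the sample's last common ancestor).
    """

    seed: int = 0
    species_tree: Optional[RootedGeneTree] = None
    duplication_rate: float = 0.1
    loss_rate: float = 0.05
    tandem_probability: float = 0.7
    wgd_events: list[tuple[str, float]] = field(default_factory=list)
    og_split: Optional[str] = None
    n_ancestral_genes: int = 1
    n_chromosomes: int = 3
    genes_per_chromosome: int = 1000
    max_tandem_offset: int = 5  # new tandem copy lands within this many ranks
    inversion_probability: float = 0.25
    codon_model: Optional[object] = None  # optional sequence regime
    n_codons: int = 0
    kappa: float = 2.0

    def __post_init__(self) -> None:
        for name in ("duplication_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tandem_probability", "inversion_probability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for label, ret in self.wgd_events:
            if not (0.0 <= ret <= 1.0):
                raise ValueError(f"WGD retention for {label!r} must lie in [0, 1]")


@dataclass
class SimulatedFamily:
    """Ground-truthed output of one gene-family simulation."""

    records: list[GeneRecord]
    gene_tree: Optional[RootedGeneTree]
    og_labels: dict[str, str]  # gene_id -> true orthogroup
    event_log: list[dict]
    alignment: Optional[CodonAlignment] = None
    site_classes: Optional[np.ndarray] = None


class _Lineage:
    __slots__ = ("uid", "node", "birth", "strand", "og", "chrom")

    def __init__(self, uid, node, birth, strand, og, chrom):
        self.uid = uid
        self.node = node  # open gene-tree attachment point (parent)
        self.birth = birth
        self.strand = strand
        self.og = og
        self.chrom = chrom


def simulate_gene_family(config: SimulationConfig) -> SimulatedFamily:
    """Run the duplication/loss/WGD process along the species tree."""
    if config.species_tree is None:
        raise ValueError("config.species_tree is required")
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []
    uid_counter = [0]

    def new_uid() -> int:
        uid_counter[0] += 1
        return uid_counter[0]

    wgd_map: dict[str, list[float]] = {}
    for label, ret in config.wgd_events:
        wgd_map.setdefault(label, []).append(ret)

    gene_root = TreeNode(label="gene_root", length=0.0)

    # genome: dict chrom -> list of (uid or None); lineage objects track their
    # chromosome, positions are looked up in the lists
    def fresh_genome() -> dict[str, list]:
        return {
            f"chr{i + 1}": [None] * config.genes_per_chromosome
            for i in range(config.n_chromosomes)
        }

    records: list[GeneRecord] = []
    og_labels: dict[str, str] = {}
    leaf_nodes_by_gene: dict[str, TreeNode] = {}

    def place_initial(genome, lineages):
        for i, lin in enumerate(lineages):
            chrom = f"chr{(i % config.n_chromosomes) + 1}"
            pos = len(genome[chrom]) // 2 + (i // config.n_chromosomes) * 10
            genome[chrom].insert(pos, lin.uid)
            lin.chrom = chrom

    def find_pos(genome, lin) -> int:
        return genome[lin.chrom].index(lin.uid)

    def duplicate(genome, lineages, lin, t, branch_label, kind) -> _Lineage:
        node = TreeNode(length=t - lin.birth)
        lin.node.add_child(node)
        keep = _Lineage(lin.uid, node, t, lin.strand, lin.og, lin.chrom)
        new = _Lineage(new_uid(), node, t, lin.strand, lin.og, lin.chrom)
        if kind == "dup_tandem":
            pos = find_pos(genome, lin)
            offset = int(rng.integers(1, config.max_tandem_offset + 1))
            if rng.random() < config.inversion_probability:
                new.strand = "+" if lin.strand == "-" else "-"
            genome[lin.chrom].insert(pos + offset, new.uid)
        else:  # segmental
            chroms = sorted(genome)
            new.chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(len(genome[new.chrom]) + 1))
            genome[new.chrom].insert(pos, new.uid)
            new.strand = "+" if rng.random() < 0.5 else "-"
        lineages[lineages.index(lin)] = keep
        lineages.append(new)
        log.append(
            {"branch": branch_label, "type": kind, "parent_gene": lin.uid,
             "child_gene": new.uid, "time": t}
        )
        return new

    def apply_wgd(genome, lineages, retention, t, branch_label):
        old_chroms = sorted(genome)
        for chrom in old_chroms:
            copy_name = chrom + "w"
            while copy_name in genome:
                copy_name += "w"
            new_list = []
            for entry in genome[chrom]:
                if entry is None:
                    new_list.append(None)
                    continue
                lin = next(l for l in lineages if l.uid == entry)
                if rng.random() < retention:
                    node = TreeNode(length=t - lin.birth)
                    lin.node.add_child(node)
                    keep = _Lineage(lin.uid, node, t, lin.strand, lin.og, lin.chrom)
                    new = _Lineage(new_uid(), node, t, lin.strand, lin.og, copy_name)
                    lineages[lineages.index(lin)] = keep
                    lineages.append(new)
                    new_list.append(new.uid)
                    log.append(
                        {"branch": branch_label, "type": "wgd", "parent_gene": lin.uid,
                         "child_gene": new.uid, "time": t}
                    )
                else:
                    new_list.append(None)
            genome[copy_name] = new_list

    def process_branch(species_node: TreeNode, genome, lineages, t_start: float):
        """Evolve along the branch leading to species_node, then recurse."""
        label = species_node.label or ""
        T = species_node.length
        t = t_start
        t_end = t_start + T
        if species_node.parent is not None and T > 0:
            wgd_times = [
                (t_start + T * (k + 1) / (len(wgd_map.get(label, [])) + 1), ret)
                for k, ret in enumerate(wgd_map.get(label, []))
            ]
            next_wgd = 0
            while True:
                n = len(lineages)
                total = n * (config.duplication_rate + config.loss_rate)
                t_next = t + (rng.exponential(1.0 / total) if total > 0 else np.inf)
                if next_wgd < len(wgd_times) and wgd_times[next_wgd][0] <= min(t_next, t_end):
                    wt, ret = wgd_times[next_wgd]
                    apply_wgd(genome, lineages, ret, wt, label)
                    next_wgd += 1
                    t = wt
                    continue
                if t_next >= t_end or not lineages:
                    break
                t = t_next
                lin = lineages[int(rng.integers(len(lineages)))]
                p_dup = config.duplication_rate / (config.duplication_rate + config.loss_rate)
                if rng.random() < p_dup:
                    kind = (
                        "dup_tandem"
                        if rng.random() < config.tandem_probability
                        else "dup_segmental"
                    )
                    duplicate(genome, lineages, lin, t, label, kind)
                else:
                    genome[lin.chrom].remove(lin.uid)
                    lineages.remove(lin)
                    log.append(
                        {"branch": label, "type": "loss", "parent_gene": lin.uid,
                         "child_gene": None, "time": t}
                    )

        # freeze orthogroup identities at the configured split node
        split_here = (
            (config.og_split is None and species_node.parent is None)
            or (config.og_split is not None and label == config.og_split)
        )
        if split_here:
            ordered = sorted(lineages, key=lambda l: l.uid)
            for i, lin in enumerate(ordered):
                lin.og = f"OG{i + 1}"

        if species_node.is_leaf:
            code = species_node.label[-5:]
            for lin in lineages:
                leaf = TreeNode(
                    label=f"g{lin.uid:04d}_{code}", length=t_end - lin.birth
                )
                lin.node.add_child(leaf)
                leaf_nodes_by_gene[leaf.label] = leaf
                if lin.og is not None:
                    og_labels[leaf.label] = lin.og
            for chrom in sorted(genome):
                rank = 0
                for entry in genome[chrom]:
                    if entry is None:
                        rank += 1
                        continue
                    lin = next(l for l in lineages if l.uid == entry)
                    records.append(
                        GeneRecord(
                            gene_id=f"g{lin.uid:04d}_{code}",
                            species_code=code,
                            chromosome=chrom,
                            order_rank=rank,
                            strand=lin.strand,
                        )
                    )
                    rank += 1
            return

        for child in species_node.children:
            child_genome = {c: list(v) for c, v in genome.items()}
            child_lineages = []
            for lin in lineages:
                node = TreeNode(length=t_end - lin.birth)
                lin.node.add_child(node)
                child_lineages.append(
                    _Lineage(lin.uid, node, t_end, lin.strand, lin.og, lin.chrom)
                )
            # NB: re-using uid across sibling species is fine — gene ids are
            # suffixed with the species code
            process_branch(child, child_genome, child_lineages, t_end)

    # initial lineages at the root
    genome0 = fresh_genome()
    lineages0 = []
    for _ in range(config.n_ancestral_genes):
        uid = new_uid()
        node = TreeNode(length=0.0)
        gene_root.add_child(node)
        lineages0.append(_Lineage(uid, node, 0.0, "+", None, None))
    place_initial(genome0, lineages0)
    process_branch(config.species_tree.root, genome0, lineages0, 0.0)

    gene_tree = _prune_gene_tree(gene_root, set(leaf_nodes_by_gene))
    family = SimulatedFamily(
        records=records, gene_tree=gene_tree, og_labels=og_labels, event_log=log
    )

    if config.codon_model is not None and gene_tree is not None and config.n_codons > 0:
        aln, classes = simulate_codon_alignment(
            gene_tree,
            config.codon_model,
            config.n_codons,
            seed=config.seed + 1,
            kappa=config.kappa,
        )
        family.alignment = aln
        family.site_classes = classes
        from .codon.genetic_code import CODONS

        seq_of = {t: "".join(CODONS[s] for s in row) for t, row in zip(aln.taxa, aln.codons)}
        for rec in records:
            rec.cds_seq = seq_of.get(rec.gene_id)
    return family


def _prune_gene_tree(root: TreeNode, extant: set) -> Optional[RootedGeneTree]:
    """Drop extinct lineages and suppress single-child nodes."""

    def prune(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            if node.label in extant:
                return TreeNode(label=node.label, length=node.length)
            return None
        kept = [p for p in (prune(c) for c in node.children) if p is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child.length += node.length
            return child
        new = TreeNode(label=None, length=node.length)
        for c in kept:
            new.add_child(c)
        return new

    pruned = prune(root)
    if pruned is None:
        return None
    pruned.length = 0.0
    return RootedGeneTree(pruned)
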