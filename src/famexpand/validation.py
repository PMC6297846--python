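"""End-to-end validation studies on ground-truthed synthetic data.

The fitted quantities of the original GT61 analysis depend on its full
103-sequence codon alignment, which is not redistributable at desk scale;
the statistical machinery is therefore validated by simulation studies with
known truth: parameter recovery, type-I error of each selection test under
its own null, branch-site power with site recovery, and orthogroup/tandem
recovery on simulated gene families.  The LRT stage itself is checked
directly against the published log-likelihood pairs.

Study conditions (tree shapes, sizes, rates) are fixed here so the test
suite and the acceptance script exercise identical regimes.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional

import numpy as np

from .codon import (
    BranchSiteModel,
    BranchSpec,
    CodonSubstModel,
    SiteClassModel,
    branch_model_test,
    branch_site_test,
    fit,
    lrt,
    site_model_test,
)
from .codon.alignment import CodonAlignment
from .codon.likelihood import TreeIndex
from .codon.models import BACKGROUND
from .codon.selection import partition_labels
from .family_data import read_newick
from .gt61 import (
    BRANCH_MODEL_LNL,
    BRANCH_MODEL_M,
    BRANCH_MODEL_NULL_LNL,
    BRANCH_SITE_LNL,
    SITE_MODEL_LNL,
    musac_gene_records,
    table_clusters,
)
from .orthogroups import delineate
from .simulate import SimulationConfig, simulate_codon_alignment, simulate_gene_family
from .tandem import build_matrix, consensus, count_loci, detect_clusters

UNIFORM_PI = np.full(61, 1.0 / 61.0)

# six taxa, one long internal branch available as foreground
SIX_TAXON_TREE = (
    "(((a_MUSAC:0.3,b_ORYSA:0.3):0.2,(c_PHODA:0.25,d_ELAGV:0.25):0.2):0.15,"
    "(e_ARATH:0.35,f_VITVI:0.35):0.25);"
)
LONG_FG_TREE = (
    "(((a_MUSAC:0.3,b_ORYSA:0.3):0.1,(c_PHODA:0.25,d_ELAGV:0.25):0.7):0.2,"
    "(e_ARATH:0.35,f_VITVI:0.35):0.3);"
)
FIVE_TAXON_TREE = (
    "(((a_MUSAC:0.3,b_ORYSA:0.3):0.2,(c_PHODA:0.25,d_ELAGV:0.25):0.2):0.15,e_ARATH:0.4);"
)
FG_CLADE = {"c_PHODA", "d_ELAGV"}
G_CLADE = {"e_ARATH", "f_VITVI"}

SPECIES_TREE = (
    "(((MUSAC:0.3,(PHODA:0.2,ELAGV:0.2)arecales:0.1)commelinids:0.2,"
    "(ARATH:0.4,VITVI:0.4)dicots_c:0.1)root:0.0);"
)


# ---------------------------------------------------------------------------
# published-table checks (deterministic)
# ---------------------------------------------------------------------------

def lrt_reproduction() -> dict[str, dict[str, float]]:
    """Run the LRT stage on the published lnL pairs of the GT61 analysis.

    Returns, per test, the computed chi2(1) p-value alongside the published
    one.
    """
    out: dict[str, dict[str, float]] = {}
    for species, (_n, _k0, lnl0, _k1, lnl1, printed) in SITE_MODEL_LNL.items():
        res = lrt(lnl0, lnl1, df=1)
        out[f"site_{species}"] = {"p": res.p, "published": printed}
    for branch, (lnl1, printed) in BRANCH_MODEL_LNL.items():
        res = lrt(BRANCH_MODEL_NULL_LNL, lnl1, df=1, m=BRANCH_MODEL_M)
        out[f"branch_{branch}"] = {
            "p": res.p, "published": printed, "p_corrected": res.p_corrected
        }
    for branch, (lnl0, lnl1, printed) in BRANCH_SITE_LNL.items():
        res = lrt(lnl0, lnl1, df=1)
        out[f"branch_site_{branch}"] = {"p": res.p, "published": printed}
    return out


def musac_locus_counts(max_gap: int = 5) -> dict[str, int]:
    """Tandem locus counts for M. acuminata from the published gene list."""
    records, ogs = musac_gene_records()
    clusters = detect_clusters(records, max_gap=max_gap, og_assignment=ogs)
    return {
        "loci": count_loci(clusters, "MUSAC"),
        "chr02_loci": sum(1 for c in clusters if c.chromosome == "Chr02"),
    }


def consensus_pattern() -> list[str]:
    """Consensus orientation per orthogroup column over all published loci."""
    clusters, ogs = table_clusters()
    matrix = build_matrix(clusters, og_assignment=ogs)
    cons = consensus(matrix)
    return [cons[og][1] for og in matrix.column_order]


# ---------------------------------------------------------------------------
# simulation studies (stochastic; seeded)
# ---------------------------------------------------------------------------

def parameter_recovery_study(
    n_reps: int = 20,
    n_codons: int = 500,
    omega: float = 0.2,
    kappa: float = 2.0,
    seed: int = 0,
) -> dict[str, float]:
    """Refit single-omega data; report estimates and in-tolerance fractions.

    Tolerance: omega within +-25% of truth (the [0.15, 0.25] band at 0.2),
    kappa within +-25%.
    """
    tree = read_newick(SIX_TAXON_TREE)
    model = CodonSubstModel(kappa, omega, UNIFORM_PI)
    omegas, kappas = [], []
    for rep in range(n_reps):
        aln, _ = simulate_codon_alignment(tree, model, n_codons, seed=seed * 10_000 + rep)
        res = fit(aln, tree, BranchSpec((BACKGROUND,)), n_restarts=1,
                  seed=seed + rep, freq_model="uniform")
        omegas.append(res.parameters["omega_background"])
        kappas.append(res.parameters["kappa"])
    omegas, kappas = np.array(omegas), np.array(kappas)
    return {
        "omega_median": float(np.median(omegas)),
        "kappa_median": float(np.median(kappas)),
        "omega_in_tolerance": float(np.mean(np.abs(omegas - omega) <= 0.25 * omega)),
        "kappa_in_tolerance": float(np.mean(np.abs(kappas - kappa) <= 0.25 * kappa)),
        "n_reps": n_reps,
    }


def type_i_error_study(
    which: str, n_reps: int = 50, seed: int = 0, alpha: float = 0.05
) -> dict[str, float]:
    """Fraction of null-simulated replicates rejected by each test.

    The boundary tests (site, branch-site: the extra omega is constrained
    >= 1) are conservative against plain chi2(1), so rates at or below the
    nominal level are expected.
    """
    n_sig = n_sig_corrected = 0
    if which == "site":
        tree = read_newick(FIVE_TAXON_TREE)
        truth = SiteClassModel("M8a", p0=0.9, p_beta=0.5, q_beta=1.5, K=4)
        for rep in range(n_reps):
            aln, _ = simulate_codon_alignment(
                tree, truth, 150, seed=seed * 10_000 + rep, kappa=2.0, pi=UNIFORM_PI
            )
            _, _, res = site_model_test(
                aln, tree, K=4, n_restarts=1, seed=rep, branch_lengths="fixed",
                freq_model="uniform",
            )
            n_sig += res.p < alpha
    elif which == "branch":
        tree = read_newick(SIX_TAXON_TREE)
        truth = CodonSubstModel(2.0, 0.2, UNIFORM_PI)
        for rep in range(n_reps):
            aln, _ = simulate_codon_alignment(tree, truth, 200, seed=seed * 10_000 + rep)
            _, _, res = branch_model_test(
                aln, tree, FG_CLADE, [G_CLADE], n_restarts=1, seed=rep,
                branch_lengths="fixed", freq_model="uniform", m=6,
            )
            n_sig += res.p < alpha
            n_sig_corrected += res.p_corrected < alpha
    elif which == "branch-site":
        tree = read_newick(SIX_TAXON_TREE)
        dummy = CodonAlignment(tree.leaf_labels(), np.zeros((6, 0), dtype=np.int16))
        labels = partition_labels(TreeIndex(tree, dummy), foreground=FG_CLADE)
        truth = BranchSiteModel(p0=0.765, p1=0.135, omega0=0.15, omega2=1.0, null=True)
        for rep in range(n_reps):
            aln, _ = simulate_codon_alignment(
                tree, truth, 150, seed=seed * 10_000 + rep, kappa=2.0, pi=UNIFORM_PI,
                labels=labels,
            )
            _, _, res, _ = branch_site_test(
                aln, tree, FG_CLADE, n_restarts=1, seed=rep, branch_lengths="fixed",
                freq_model="uniform", alpha=-1.0,  # never run BEB here
            )
            n_sig += res.p < alpha
    else:
        raise ValueError(f"unknown test {which!r}")
    out = {"rate": n_sig / n_reps, "n_significant": n_sig, "n_reps": n_reps}
    if which == "branch":
        out["rate_corrected"] = n_sig_corrected / n_reps
    return out


def branch_site_power_study(
    n_reps: int = 20,
    n_codons: int = 300,
    omega2: float = 8.0,
    seed: int = 0,
) -> dict[str, float]:
    """Power and BEB site recovery under positive selection on one branch.

    Truth: 10% of sites in the positive classes (p0 = 0.765, p1 = 0.135)
    with the stated omega2 on a long post-duplication foreground branch.
    """
    tree = read_newick(LONG_FG_TREE)
    dummy = CodonAlignment(tree.leaf_labels(), np.zeros((6, 0), dtype=np.int16))
    labels = partition_labels(TreeIndex(tree, dummy), foreground=FG_CLADE)
    truth = BranchSiteModel(p0=0.765, p1=0.135, omega0=0.1, omega2=omega2)
    n_sig = n_sig_with_true_site = 0
    for rep in range(n_reps):
        aln, classes = simulate_codon_alignment(
            tree, truth, n_codons, seed=seed * 10_000 + rep, kappa=2.0, pi=UNIFORM_PI,
            labels=labels,
        )
        _, _, res, beb_res = branch_site_test(
            aln, tree, FG_CLADE, n_restarts=2, seed=rep, branch_lengths="fixed",
            freq_model="uniform", beb_grid_size=6,
        )
        if res.p < 0.05:
            n_sig += 1
            if beb_res is not None and any(classes[s] >= 2 for s in beb_res.flagged):
                n_sig_with_true_site += 1
    return {
        "power": n_sig / n_reps,
        "detection_with_true_site": n_sig_with_true_site / n_reps,
        "n_reps": n_reps,
    }


def og_recovery_study(n_reps: int = 5, seed: int = 0) -> dict[str, float]:
    """Orthogroup-label recovery on simulated families with exact trees.

    Each inferred orthogroup is mapped to its majority true ancestral-gene
    label; recovery is the fraction of genes whose label matches
    (unassigned genes count as misses).
    """
    total_correct = total_genes = 0
    from .gt61 import angiosperm_taxonomy

    taxonomy = angiosperm_taxonomy()
    for rep in range(n_reps):
        cfg = SimulationConfig(
            seed=seed * 1000 + rep,
            species_tree=read_newick(SPECIES_TREE),
            duplication_rate=0.3,
            loss_rate=0.0,
            tandem_probability=0.7,
            n_ancestral_genes=4,
            n_chromosomes=4,
        )
        fam = simulate_gene_family(cfg)
        if fam.gene_tree is None:
            continue
        report = delineate(fam.gene_tree, taxonomy, {"monocots", "dicots"})
        for og in report.orthogroups:
            truth = Counter(fam.og_labels[g] for g in og.members)
            total_correct += truth.most_common(1)[0][1]
        total_genes += len(fam.og_labels)
    return {"recovery": total_correct / total_genes, "n_genes": total_genes}


def tandem_recovery_study(n_reps: int = 5, seed: int = 0) -> dict[str, float]:
    """Exact recovery of tandem arrays when all duplications are tandem.

    With one ancestral locus per chromosome and tandem-only duplication,
    the true arrays are the per-(species, chromosome) gene sets; detection
    at max_gap = 5 must return them exactly.
    """
    n_exact = n_loci = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            seed=seed * 1000 + rep,
            species_tree=read_newick(SPECIES_TREE),
            duplication_rate=1.0,
            loss_rate=0.0,
            tandem_probability=1.0,
            n_ancestral_genes=2,
            n_chromosomes=2,
        )
        fam = simulate_gene_family(cfg)
        truth: dict[tuple[str, str], set[str]] = {}
        for r in fam.records:
            truth.setdefault((r.species_code, r.chromosome), set()).add(r.gene_id)
        clusters = detect_clusters(fam.records, max_gap=5, keep_singletons=True)
        detected = {
            (c.species_code, c.chromosome): set(c.gene_ids) for c in clusters
        }
        for key, members in truth.items():
            n_loci += 1
            n_exact += detected.get(key) == members
    return {"exact_fraction": n_exact / n_loci, "n_loci": n_loci}
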