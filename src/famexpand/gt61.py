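"""Bundled GT61 case-study inputs.

The glycosyltransferase family 61 (GT61), involved in grass cell-wall
xylan synthesis, is the package's worked example of a monocot gene-family
expansion: commelinid orthogroups OG-GT61-A1..A6 sit in collinear tandem
loci, and the ancestral branches leading to them were screened for
selection with site, branch and branch-site codon models.

This module carries the published summary inputs needed to exercise the
pipeline without genome downloads: the log-likelihoods of the fitted codon
models (the LRT stage runs on them directly), the gene coordinates of the
OG-GT61-A tandem loci in three monocot genomes, and the angiosperm species
taxonomy of the 13 sampled species.

Gene-order ranks of the *M. acuminata* genes are encoded in the gene ids
(annotation ids run in steps of ten along a chromosome: ``Ma01_g14150`` ->
rank 1415).  Strands of individual genes were not published with the locus
table; :func:`table_clusters` assigns SYNTHETIC strands consistent with the
ancestral locus orientation (forward loci) or its reverse complement
(loci whose gene-id order runs against the shared column order), so
consensus-orientation machinery can be exercised end to end.
"""

from __future__ import annotations

from .family_data import GeneRecord, SpeciesTaxonomy
from .tandem import TandemCluster

__all__ = [
    "SITE_MODEL_LNL",
    "BRANCH_MODEL_NULL_LNL",
    "BRANCH_MODEL_LNL",
    "BRANCH_SITE_LNL",
    "angiosperm_taxonomy",
    "musac_gene_records",
    "table_clusters",
    "ANCESTRAL_ORIENTATION",
]

# site models (M8a vs M8) fitted per species on OG-GT61-A paralogs:
# species -> (n_sequences, n_params_null, lnL_null, n_params_alt, lnL_alt, printed_p)
SITE_MODEL_LNL = {
    "ANACO": (23, 47, -13824.746, 48, -13822.802, 0.0486),
    "ELAGV": (16, 33, -8995.103, 34, -8994.781, 0.4220),
    "MUSAC": (37, 75, -21533.671, 76, -21533.671, 1.0),
    "PHODA": (10, 21, -7158.605, 22, -7158.294, 0.4300),
}

# branch models: two-ratio null (G group / rest) against a three-ratio
# alternative per tested ancestral branch; 206 vs 207 free parameters
BRANCH_MODEL_NULL_LNL = -56465.344
BRANCH_MODEL_LNL = {
    # branch -> (lnL_alt, printed_p_uncorrected)
    "A1": (-56462.935, 0.0282),
    "A2": (-56463.354, 0.0461),
    "A3": (-56464.683, 0.2503),
    "A4": (-56465.328, 0.8577),
    "A5": (-56463.471, 0.0530),
    "A6": (-56459.395, 5.62e-4),
}
BRANCH_MODEL_M = 6  # Bonferroni over the six branch partitions tested

# branch-site model A vs its omega2 = 1 null (207 vs 208 parameters);
# only the two branches with a finite printed LRT p-value
BRANCH_SITE_LNL = {
    "A5": (-55733.021, -55728.925, 0.421e-2),
    "A6": (-55721.491, -55717.905, 0.741e-2),
}

_TAXONOMY = {
    "AMBTC": "angiosperms;Amborellales",
    "ARATH": "angiosperms;dicots;rosids",
    "THECC": "angiosperms;dicots;rosids",
    "VITVI": "angiosperms;dicots;rosids",
    "COFCA": "angiosperms;dicots;asterids",
    "ASPOF": "angiosperms;monocots;Asparagales",
    "MUSAC": "angiosperms;monocots;commelinids;Zingiberales",
    "PHODA": "angiosperms;monocots;commelinids;Arecales",
    "ELAGV": "angiosperms;monocots;commelinids;Arecales",
    "ANACO": "angiosperms;monocots;commelinids;Poales",
    "ORYSA": "angiosperms;monocots;commelinids;Poales;Poaceae",
    "BRADI": "angiosperms;monocots;commelinids;Poales;Poaceae",
    "SETIT": "angiosperms;monocots;commelinids;Poales;Poaceae",
}


def angiosperm_taxonomy() -> SpeciesTaxonomy:
    """Taxonomy of the 13 sampled angiosperm species."""
    return SpeciesTaxonomy({c: p.split(";") for c, p in _TAXONOMY.items()})


# M. acuminata OG-GT61-A genes found in tandem loci, with orthogroup labels;
# gene-order rank is the annotation number divided by ten
_MUSAC_TABLE = [
    ("Chr01", [("Ma01_g14150", "A1"), ("Ma01_g14160", "A3"), ("Ma01_g14170", "A3"),
               ("Ma01_g14180", "A3"), ("Ma01_g14190", "A4"), ("Ma01_g14200", "A5")]),
    ("Chr02", [("Ma02_g16300", "A2"), ("Ma02_g16310", "A5"), ("Ma02_g16320", "A6")]),
    ("Chr02", [("Ma02_g24680", "A2"), ("Ma02_g24690", "A1")]),
    ("Chr04", [("Ma04_g30870", "A6"), ("Ma04_g30880", "A5"), ("Ma04_g30890", "A2")]),
    ("Chr06", [("Ma06_g11080", "A1"), ("Ma06_g11090", "A3")]),
    ("Chr07", [("Ma07_g11810", "A6"), ("Ma07_g11830", "A5"), ("Ma07_g11840", "A2")]),
    ("Chr09", [("Ma09_g00650", "A5"), ("Ma09_g00660", "A4"), ("Ma09_g00670", "A3"),
               ("Ma09_g00680", "A3")]),
    ("Chr10", [("Ma10_g20090", "A3"), ("Ma10_g20100", "A2"), ("Ma10_g20110", "A1")]),
    ("Chr11", [("Ma11_g12040", "A3"), ("Ma11_g12050", "A2"), ("Ma11_g12060", "A1")]),
]

# ancestral orientation of the commelinid tandem locus, per orthogroup column
ANCESTRAL_ORIENTATION = {"A1": "+", "A2": "-", "A3": "-", "A4": "-", "A5": "-", "A6": "+"}

COLUMN_ORDER = ["A1", "A2", "A3", "A4", "A5", "A6"]


def musac_rank(gene_id: str) -> int:
    """Gene-order rank encoded in a M. acuminata annotation id."""
    return int(gene_id.split("_g")[1]) // 10


def musac_gene_records() -> tuple[list[GeneRecord], dict[str, str]]:
    """The M. acuminata OG-GT61-A genes as GeneRecords plus OG labels.

    Strands are the synthetic locus-orientation assignment described in the
    module docstring.
    """
    records, ogs = [], {}
    for chrom, genes in _MUSAC_TABLE:
        reversed_row = _is_reversed([og for _g, og in genes])
        for gid, og in genes:
            strand = ANCESTRAL_ORIENTATION[og]
            if reversed_row:
                strand = "+" if strand == "-" else "-"
            records.append(
                GeneRecord(gid, "MUSAC", chrom, musac_rank(gid), strand)
            )
            ogs[gid] = og
    return records, ogs


def _is_reversed(ogs_in_rank_order: list[str]) -> bool:
    idx = [COLUMN_ORDER.index(og) for og in ogs_in_rank_order]
    fwd = sum(1 for a, b in zip(idx, idx[1:]) if a <= b)
    rev = sum(1 for a, b in zip(idx[::-1], idx[::-1][1:]) if a <= b)
    return rev > fwd


# tandem loci of the two Arecales genomes (all stored in ancestral
# orientation; PHODA carries one member without a resolved orthogroup)
_ARECALES_TABLE = [
    ("PHODA", "NW_008246516.1",
     [("LOC103696170", "A1"), ("LOC103696188", "A2"), ("LOC103696198", "A2"),
      # the A3 member of this locus is unresolved ("Partial"); placeholder id
      ("LOC103696205", None), ("LOC103696231", "A4"), ("LOC103696210", "A4"),
      ("LOC103697726", "A5"), ("LOC103696248", "A6")]),
    ("PHODA", "NW_008246831.1",
     [("LOC103719015", "A1"), ("LOC103719019", "A2")]),
    ("ELAGV", "NC_025995.1",
     [("LOC105041134", "A1"), ("LOC105041135", "A2"), ("LOC105041136", "A2"),
      ("LOC105041137", "A3"), ("LOC105041138", "A4"), ("LOC105041140", "A4"),
      ("LOC105041139", "A4"), ("LOC105041141", "A4"), ("LOC105041144", "A4"),
      ("LOC105041142", "A4"), ("LOC105041145", "A4"), ("LOC105041157", "A5"),
      ("LOC105041146", "A6")]),
]


def table_clusters() -> tuple[list[TandemCluster], dict[str, str]]:
    """All published tandem loci as clusters, plus the OG assignment map.

    Rows whose gene-id order runs against the shared column order are
    genomically inverted loci; their members get flipped synthetic strands
    so that consensus voting after row-reversal normalization is exercised.
    """
    clusters: list[TandemCluster] = []
    ogs: dict[str, str] = {}
    for species, chrom, genes in _ARECALES_TABLE:
        members = []
        for rank, (gid, og) in enumerate(genes):
            strand = ANCESTRAL_ORIENTATION[og] if og else "unknown"
            members.append((gid, rank, strand, og))
            if og:
                ogs[gid] = og
        clusters.append(TandemCluster(species, chrom, members))
    musac_records, musac_ogs = musac_gene_records()
    ogs.update(musac_ogs)
    from .tandem import detect_clusters

    clusters.extend(detect_clusters(musac_records, max_gap=5, og_assignment=musac_ogs))
    return clusters, ogs
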