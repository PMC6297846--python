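"""Core records and I/O for gene-family analyses.

Everything downstream (orthogroup delineation, tandem-cluster detection,
codon-model fitting) consumes the types defined here: :class:`GeneRecord`
for one family member and its genomic position, :class:`SpeciesTaxonomy`
for the lineage structure of the sampled species, and
:class:`RootedGeneTree` for rooted gene trees with branch lengths and
support values.

Conventions
-----------
* Species are identified by five-letter uppercase codes (e.g. ``MUSAC`` for
  *Musa acuminata*), carried as a ``_CODE`` suffix on sequence/leaf names.
* Gene order along a chromosome is an integer rank over all annotated genes
  of that chromosome (0-based), not a base-pair coordinate.  Tandem-cluster
  rules are rank rules.
* Newick support values are read from internal node labels; they are inputs
  (e.g. aLRT supports from the tree builder), never computed here.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "FamilyDataError",
    "GeneRecord",
    "SpeciesTaxonomy",
    "TreeNode",
    "RootedGeneTree",
    "parse_species_code",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_gene_positions",
    "write_gene_positions",
    "read_taxonomy",
]

_SPECIES_CODE_RE = re.compile(r"^[A-Z]{5}$")
_TRAILING_CODE_RE = re.compile(r"_([A-Z]{5})$")

_STOP_CODONS = {"TAA", "TAG", "TGA"}


class FamilyDataError(ValueError):
    """Raised for malformed inputs or violated record invariants."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    """One gene-family member with its genomic position.

    ``order_rank`` is the gene's position in the whole-annotation gene order
    of its chromosome (0-based).  ``strand`` is ``'+'``, ``'-'`` or
    ``'unknown'`` (scaffold-level assemblies often lack orientation).
    """

    gene_id: str
    species_code: str
    chromosome: str
    order_rank: int
    strand: str = "unknown"
    protein_seq: Optional[str] = None
    cds_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if not _SPECIES_CODE_RE.match(self.species_code):
            raise FamilyDataError(
                f"species code {self.species_code!r} for gene {self.gene_id!r} "
                "does not match [A-Z]{5}"
            )
        if self.order_rank < 0:
            raise FamilyDataError(
                f"gene {self.gene_id!r}: order_rank must be >= 0, got {self.order_rank}"
            )
        if self.strand not in {"+", "-", "unknown"}:
            raise FamilyDataError(
                f"gene {self.gene_id!r}: strand must be '+', '-' or 'unknown', "
                f"got {self.strand!r}"
            )
        if self.cds_seq is not None:
            ungapped = self.cds_seq.replace("-", "").upper()
            if len(ungapped) % 3 != 0:
                raise FamilyDataError(
                    f"gene {self.gene_id!r}: CDS length {len(ungapped)} not divisible by 3"
                )
            codons = [ungapped[i : i + 3] for i in range(0, len(ungapped), 3)]
            for k, codon in enumerate(codons[:-1]):
                if codon in _STOP_CODONS:
                    raise FamilyDataError(
                        f"gene {self.gene_id!r}: internal stop codon {codon} at codon {k}"
                    )


def validate_unique_ranks(records: Sequence[GeneRecord]) -> None:
    """Check the (species, chromosome, order_rank) uniqueness invariant."""
    seen: dict[tuple[str, str, int], str] = {}
    offenders = []
    for rec in records:
        key = (rec.species_code, rec.chromosome, rec.order_rank)
        if key in seen:
            offenders.append(f"{seen[key]} / {rec.gene_id} at {key}")
        else:
            seen[key] = rec.gene_id
    if offenders:
        raise FamilyDataError(
            "duplicate (species, chromosome, order_rank): " + "; ".join(offenders)
        )


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

class SpeciesTaxonomy:
    """Mapping from species codes to ordered lineage paths.

    A lineage path runs from the shared root label downward, e.g.
    ``angiosperms -> monocots -> commelinids -> Poales -> Poaceae``.
    Split levels for orthogroup delineation are sets of sibling lineage
    labels appearing on these paths (e.g. ``{"monocots", "dicots"}``).
    """

    def __init__(self, paths: dict[str, Sequence[str]]):
        if not paths:
            raise FamilyDataError("taxonomy is empty")
        roots = {tuple(p)[0] for p in paths.values() if len(p) > 0}
        if len(roots) != 1:
            raise FamilyDataError(f"lineage paths do not share a single root: {sorted(roots)}")
        for code in paths:
            if not _SPECIES_CODE_RE.match(code):
                raise FamilyDataError(f"invalid species code in taxonomy: {code!r}")
        self._paths = {code: tuple(p) for code, p in paths.items()}

    @property
    def species_codes(self) -> list[str]:
        return sorted(self._paths)

    def path(self, species_code: str) -> tuple[str, ...]:
        try:
            return self._paths[species_code]
        except KeyError:
            raise FamilyDataError(f"species code {species_code!r} not in taxonomy") from None

    def __contains__(self, species_code: str) -> bool:
        return species_code in self._paths

    def has_lineage(self, label: str) -> bool:
        return any(label in p for p in self._paths.values())

    def in_lineage(self, species_code: str, lineage: str) -> bool:
        return lineage in self.path(species_code)

    def split_lineage(self, species_code: str, split: Iterable[str]) -> Optional[str]:
        """Return the unique split lineage containing the species, or None.

        Raises if the species falls in more than one lineage of the split
        (the split labels are then not siblings).
        """
        hits = [lab for lab in split if self.in_lineage(species_code, lab)]
        if len(hits) > 1:
            raise FamilyDataError(
                f"species {species_code} lies in several split lineages {hits}; "
                "split labels must be mutually exclusive"
            )
        return hits[0] if hits else None

    def depth(self, label: str) -> int:
        """Depth (root = 0) of the first occurrence of a lineage label."""
        for p in self._paths.values():
            if label in p:
                return p.index(label)
        raise FamilyDataError(f"lineage label {label!r} not found in taxonomy")

    def is_strictly_deeper(self, deeper: Iterable[str], shallower: Iterable[str]) -> bool:
        """True when every lineage of ``deeper`` sits strictly below ``shallower``'s level."""
        dmin = min(self.depth(lab) for lab in deeper)
        smax = max(self.depth(lab) for lab in shallower)
        return dmin > smax


def read_taxonomy(path: str) -> SpeciesTaxonomy:
    """Read a two-column TSV: species_code, ';'-joined lineage path."""
    paths: dict[str, Sequence[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FamilyDataError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            code, lineage = parts
            if code == "species_code":  # optional header
                continue
            paths[code] = [x.strip() for x in lineage.split(";") if x.strip()]
    return SpeciesTaxonomy(paths)


# ---------------------------------------------------------------------------
# species codes on sequence names
# ---------------------------------------------------------------------------

def parse_species_code(
    leaf_label: str, leaf_to_species: Optional[dict[str, str]] = None
) -> str:
    """Extract the five-letter species code from a sequence/leaf name.

    Names carry the code as a trailing ``_CODE`` suffix (``Ma01_g14150_MUSAC``
    -> ``MUSAC``).  An explicit leaf->species map takes precedence for names
    without a suffix.
    """
    if leaf_to_species and leaf_label in leaf_to_species:
        code = leaf_to_species[leaf_label]
        if not _SPECIES_CODE_RE.match(code):
            raise FamilyDataError(f"mapped species code {code!r} is not a 5-letter code")
        return code
    m = _TRAILING_CODE_RE.search(leaf_label)
    if not m:
        raise FamilyDataError(
            f"cannot resolve species for {leaf_label!r}: no trailing _XXXXX code "
            "and no map entry"
        )
    return m.group(1)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs, order preserved.

    Any malformed input (no header, empty file, header with an empty body)
    raises :class:`FamilyDataError` naming the offending line.
    """
    records: list[tuple[str, str]] = []
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def _flush(lineno: int) -> None:
        nonlocal header
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FamilyDataError(
                f"{path}:{header_line}: record {header!r} has an empty sequence body"
            )
        records.append((header, seq))
        header = None
        chunks.clear()

    with open(path) as fh:
        any_line = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            any_line = True
            if line.startswith(">"):
                _flush(lineno)
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FamilyDataError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FamilyDataError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
        if not any_line:
            raise FamilyDataError(f"{path}:1: empty FASTA file")
        _flush(lineno + 1)
    return records


def write_fasta(path: str, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a rooted gene tree."""

    label: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None
    # branch partition mark parsed from '#k' suffixes (PAML-style), or set
    # programmatically to name foreground / outgroup branches
    branch_mark: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


class RootedGeneTree:
    """A rooted gene tree whose leaves carry species codes.

    Supports are attributes read from the input (internal Newick labels);
    polytomies are allowed.
    """

    def __init__(self, root: TreeNode, leaf_to_species: Optional[dict[str, str]] = None):
        self.root = root
        self.leaf_to_species = dict(leaf_to_species or {})
        labels = [lf.label for lf in self.leaves()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise FamilyDataError(f"duplicate leaf labels: {dupes}")
        for node in self.preorder():
            if node.length < 0:
                raise FamilyDataError(
                    f"negative branch length {node.length} above node {node.label!r}"
                )

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def species_of(self, leaf: TreeNode) -> str:
        return parse_species_code(leaf.label, self.leaf_to_species)

    def copy(self) -> "RootedGeneTree":
        def _clone(node: TreeNode) -> TreeNode:
            new = TreeNode(
                label=node.label,
                length=node.length,
                support=node.support,
                branch_mark=node.branch_mark,
            )
            for ch in node.children:
                new.add_child(_clone(ch))
            return new

        return RootedGeneTree(_clone(self.root), self.leaf_to_species)

    def subtree(self, node: TreeNode) -> "RootedGeneTree":
        """A copy of the clade rooted at ``node`` as a stand-alone tree."""
        sub = RootedGeneTree.__new__(RootedGeneTree)
        tmp = RootedGeneTree(node, self.leaf_to_species)  # validates
        clone = tmp.copy()
        clone.root.length = 0.0
        sub.root = clone.root
        sub.leaf_to_species = dict(self.leaf_to_species)
        return sub

    def validate_species(self, taxonomy: SpeciesTaxonomy) -> None:
        for lf in self.leaves():
            code = self.species_of(lf)
            if code not in taxonomy:
                raise FamilyDataError(
                    f"leaf {lf.label!r}: species {code} not in taxonomy"
                )


_BRANCH_MARK_RE = re.compile(r"\s*#\s*(\w+)\s*$")


def _label_and_mark(raw: Optional[str]) -> tuple[Optional[str], Optional[str]]:
    if raw is None:
        return None, None
    m = _BRANCH_MARK_RE.search(raw)
    if m:
        return (raw[: m.start()].strip() or None), m.group(1)
    return raw, None


def read_newick(path_or_string: str, leaf_to_species: Optional[dict[str, str]] = None) -> RootedGeneTree:
    """Parse a rooted Newick tree (file path or literal string).

    Internal node labels that parse as floats in [0, 1] are taken as branch
    supports; '#k' suffixes on any label are kept as branch partition marks.
    """
    text = path_or_string
    if not path_or_string.lstrip().startswith("(") and not path_or_string.lstrip().startswith(";"):
        with open(path_or_string) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FamilyDataError(f"Newick parse error: {exc}") from exc

    def _convert(dnode) -> TreeNode:
        raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
        label, mark = _label_and_mark(raw)
        support = None
        if dnode.child_nodes() and label is not None:
            try:
                val = float(label)
            except ValueError:
                val = None
            if val is not None and 0.0 <= val <= 1.0:
                support = val
                label = None
        node = TreeNode(
            label=label,
            length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
            support=support,
            branch_mark=mark,
        )
        for ch in dnode.child_nodes():
            node.add_child(_convert(ch))
        return node

    return RootedGeneTree(_convert(dtree.seed_node), leaf_to_species)


def _to_newick(node: TreeNode, with_lengths: bool = True) -> str:
    if node.is_leaf:
        s = node.label or ""
    else:
        inner = ",".join(_to_newick(c, with_lengths) for c in node.children)
        lab = ""
        if node.support is not None:
            lab = format(node.support, ".6g")
        elif node.label:
            lab = node.label
        s = f"({inner}){lab}"
    if node.branch_mark is not None:
        s += f" #{node.branch_mark}"
    if with_lengths and node.parent is not None:
        s += f":{node.length:.9g}"
    return s


def write_newick(tree: RootedGeneTree, path: Optional[str] = None) -> str:
    text = _to_newick(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


# ---------------------------------------------------------------------------
# gene positions (TSV or GFF3)
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = ["gene_id", "species_code", "chromosome", "order_rank", "strand"]


def read_gene_positions(
    path: str, species_code: Optional[str] = None, gff_feature: str = "gene"
) -> list[GeneRecord]:
    """Read gene positions from a 5-column TSV or a GFF3 file.

    TSV columns: gene_id, species_code, chromosome, order_rank, strand
    (header optional).  For GFF3, ``order_rank`` is computed by ranking
    features of type ``gff_feature`` per chromosome by start coordinate
    (ties: end coordinate, then ID), and ``species_code`` must be supplied.
    """
    with open(path) as fh:
        head = fh.read(4096)
    is_gff = head.startswith("##gff-version") or _looks_like_gff(head)
    records = _read_gff3(path, species_code, gff_feature) if is_gff else _read_tsv(path)
    validate_unique_ranks(records)
    return records


def _looks_like_gff(head: str) -> bool:
    for line in head.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        return len(parts) == 9 and parts[3].isdigit() and parts[4].isdigit()
    return False


def _read_tsv(path: str) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "gene_id":
                continue
            if len(parts) != 5:
                raise FamilyDataError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(parts)}"
                )
            gene_id, code, chrom, rank, strand = parts
            try:
                rank_i = int(rank)
            except ValueError:
                raise FamilyDataError(f"{path}:{lineno}: order_rank {rank!r} is not an integer")
            records.append(GeneRecord(gene_id, code, chrom, rank_i, strand))
    return records


def _read_gff3(path: str, species_code: Optional[str], feature: str) -> list[GeneRecord]:
    if species_code is None:
        raise FamilyDataError("species_code is required when reading GFF3 positions")
    rows: list[tuple[str, int, int, str, str]] = []  # chrom, start, end, id, strand
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FamilyDataError(f"{path}:{lineno}: GFF3 line has {len(parts)} columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != feature:
                continue
            gid = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gid = kv[3:]
                    break
            if gid is None:
                raise FamilyDataError(f"{path}:{lineno}: {feature} feature without ID attribute")
            rows.append((chrom, int(start), int(end), gid, strand if strand in "+-" else "unknown"))
    records = []
    by_chrom: dict[str, list] = {}
    for row in rows:
        by_chrom.setdefault(row[0], []).append(row)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda r: (r[1], r[2], r[3]))  # start, end, id — deterministic
        for rank, (c, _s, _e, gid, strand) in enumerate(group):
            records.append(GeneRecord(gid, species_code, c, rank, strand))
    return records


def write_gene_positions(path: str, records: Iterable[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_POSITION_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.species_code}\t{r.chromosome}\t{r.order_rank}\t{r.strand}\n")
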