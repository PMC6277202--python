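"""Alignment and tree I/O, supermatrix concatenation and matrix statistics.

Alignments are taxa x sites character matrices over the 20 amino-acid
one-letter codes plus a gap symbol ``-`` and missing symbols ``X``/``?``.
Reading normalises case and maps the ambiguity codes B/Z/J/U/O and the
stop/frameshift symbols ``*``/``.`` to ``X``.  Supermatrix partition
coordinates are 1-based inclusive (RAxML partition-file convention);
internal site indexing is 0-based half-open and converted only at the
I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

logger = logging.getLogger("compqc")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MISSING = "X"
MISSING_CHARS = frozenset("X?")
#: characters excluded from residue counts everywhere in the package
NON_RESIDUE = frozenset("-X?")
_AMBIGUOUS = frozenset("BZJUO*.")
_ALPHABET = frozenset(AMINO_ACIDS) | frozenset("-X?")


class AlignmentFormatError(ValueError):
    """Raised when an input alignment violates a format invariant."""


class TreeFormatError(ValueError):
    """Raised when a Newick tree cannot be parsed or is malformed."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A multiple sequence alignment with unique taxon labels.

    Parameters
    ----------
    taxa : list of str
        Ordered, unique taxon labels.
    sequences : list of str
        One uppercase sequence per taxon, all of equal length.
    name : str
        Gene / locus identifier.
    """

    taxa: list[str]
    sequences: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentFormatError(
                f"{self.name or 'alignment'}: {len(self.taxa)} taxa but "
                f"{len(self.sequences)} sequences"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentFormatError(
                f"{self.name or 'alignment'}: duplicate taxon labels {dupes}"
            )
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            for t, s in zip(self.taxa, self.sequences):
                if len(s) != len(self.sequences[0]):
                    raise AlignmentFormatError(
                        f"{self.name or 'alignment'}: record '{t}' has length "
                        f"{len(s)}, expected {len(self.sequences[0])}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def char_matrix(self) -> np.ndarray:
        """Return the alignment as an (n_taxa, n_sites) array of single chars."""
        if self.n_sites == 0:
            return np.empty((self.n_taxa, 0), dtype="U1")
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        """Restrict to the given taxa, preserving the requested order."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in idx]
        if missing:
            raise KeyError(f"taxa not in alignment {self.name!r}: {missing}")
        return Alignment(list(taxa), [self.sequences[idx[t]] for t in taxa], self.name)


def _normalise_residues(seq: str, record_id: str, warn: set[str]) -> str:
    out = seq.upper()
    bad = set(out) & _AMBIGUOUS
    if bad:
        warn.update(bad)
        out = out.translate(str.maketrans({c: MISSING for c in _AMBIGUOUS}))
    unknown = set(out) - _ALPHABET
    if unknown:
        raise AlignmentFormatError(
            f"record '{record_id}': unexpected characters {sorted(unknown)}"
        )
    return out


def read_alignment(path: str | Path, format: str = "fasta", name: str | None = None) -> Alignment:
    """Read an aligned FASTA or relaxed-PHYLIP file.

    Residues are uppercased; ambiguity codes B/Z/J/U/O and ``*``/``.`` are
    mapped to the missing symbol ``X`` (a warning is logged when this
    happens).  Unequal sequence lengths or duplicate labels raise
    :class:`AlignmentFormatError`.
    """
    path = Path(path)
    if format not in ("fasta", "phylip-relaxed"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    taxa: list[str] = []
    seqs: list[str] = []
    warned: set[str] = set()
    if format == "fasta":
        records = SeqIO.parse(str(path), "fasta")
    else:
        records = SeqIO.parse(str(path), "phylip-relaxed")
    for rec in records:
        taxa.append(rec.id)
        seqs.append(_normalise_residues(str(rec.seq), rec.id, warned))
    if not taxa:
        raise AlignmentFormatError(f"{path}: no sequence records found")
    if warned:
        logger.warning(
            "%s: ambiguity/stop characters %s mapped to missing ('X')",
            path.name, "".join(sorted(warned)),
        )
    aln = Alignment(taxa, seqs, name=name if name is not None else path.stem)
    return aln


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment as FASTA or relaxed (sequential) PHYLIP."""
    path = Path(path)
    with open(path, "w") as fh:
        if format == "fasta":
            for t, s in zip(aln.taxa, aln.sequences):
                fh.write(f">{t}\n")
                for i in range(0, len(s), 80):
                    fh.write(s[i:i + 80] + "\n")
        elif format == "phylip-relaxed":
            fh.write(f" {aln.n_taxa} {aln.n_sites}\n")
            width = max((len(t) for t in aln.taxa), default=0) + 2
            for t, s in zip(aln.taxa, aln.sequences):
                fh.write(t.ljust(width) + s + "\n")
        else:
            raise ValueError(f"unsupported alignment format: {format!r}")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a rooted tree; ``length`` is the branch to the parent."""

    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """Tip-labelled tree with non-negative branch lengths.

    Wraps a simple node structure suitable for pruning and simulation.
    Parsing and basic topology handling delegate to dendropy; only the
    numerics live here.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        tips = self.tip_labels()
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeFormatError(f"duplicate tip labels: {dupes}")
        for node in self.preorder():
            if node is not self.root and node.length < 0:
                raise TreeFormatError(
                    f"negative branch length {node.length} at {node.label or 'internal node'}"
                )

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def postorder(self) -> list[TreeNode]:
        return list(reversed(self._reverse_postorder()))

    def _reverse_postorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]  # type: ignore[misc]

    def __deepcopy_node(self, node: TreeNode) -> TreeNode:
        return TreeNode(node.label, node.length,
                        [self.__deepcopy_node(c) for c in node.children])

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.__deepcopy_node(self.root))

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels())

    @property
    def n_edges(self) -> int:
        return len(self.postorder()) - 1

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    # -- Newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=False,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeFormatError(f"could not parse Newick: {exc}") from exc
        missing = 0

        def convert(dnode) -> tuple[TreeNode, int]:
            nonlocal missing
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            length = dnode.edge.length
            if length is None:
                length = 0.0
                if dnode.parent_node is not None:
                    missing += 1
            node = TreeNode(label, float(length))
            for child in dnode.child_nodes():
                node.children.append(convert(child)[0])
            return node, missing

        root, _ = convert(dtree.seed_node)
        if missing:
            logger.warning("Newick tree: %d edge(s) without branch length, set to 0.0", missing)
        return cls(root)

    def to_newick(self, length_fmt: str = "%.10g") -> str:
        def render(node: TreeNode) -> str:
            if node.is_tip:
                base = _quote_label(node.label or "")
            else:
                base = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.label:
                    base += _quote_label(node.label)
            if node is self.root:
                return base
            return base + ":" + (length_fmt % node.length)
        return render(self.root) + ";"


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]:;,' \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def prune_to_taxa(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Restrict a tree to the given tips, suppressing unifurcations.

    Branch lengths of suppressed degree-2 nodes are summed, so patristic
    distances among retained tips are preserved.
    """
    keep = set(taxa)
    unknown = keep - set(tree.tip_labels())
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("pruning requires >= 2 retained taxa")

    def rebuild(node: TreeNode) -> TreeNode | None:
        if node.is_tip:
            if node.label in keep:
                return TreeNode(node.label, node.length)
            return None
        kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += node.length
            return kids[0]
        return TreeNode(node.label, node.length, kids)

    root = rebuild(tree.root)
    assert root is not None
    root.length = 0.0
    return PhyloTree(root)


def read_tree(path: str | Path) -> PhyloTree:
    """Read a single Newick tree; missing branch lengths default to 0.0."""
    text = Path(path).read_text().strip()
    if not text:
        raise TreeFormatError(f"{path}: empty tree file")
    if text.count("(") != text.count(")"):
        raise TreeFormatError(f"{path}: unbalanced parentheses")
    return PhyloTree.from_newick(text)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Supermatrix
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    """Concatenated alignment with a partition map and per-taxon occupancy.

    ``partitions`` holds ``(gene_name, start, end)`` in 1-based inclusive
    coordinates; ``occupancy`` maps each taxon to the number of genes in
    which it has at least one non-missing residue.
    """

    alignment: Alignment
    partitions: list[tuple[str, int, int]]
    occupancy: dict[str, int]

    @property
    def total_length(self) -> int:
        return self.alignment.n_sites


def concatenate(genes: Sequence[Alignment], missing_symbol: str = GAP) -> Supermatrix:
    """Concatenate gene alignments over the sorted union of their taxa.

    Taxa absent from a gene are filled with ``missing_symbol`` across that
    gene's partition.  Partition coordinates are 1-based inclusive, in
    input gene order.
    """
    if not genes:
        raise ValueError("concatenate requires at least one gene alignment")
    names = [g.name for g in genes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene names: {dupes}")
    taxa = sorted(set().union(*(set(g.taxa) for g in genes)))
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    occupancy = {t: 0 for t in taxa}
    pos = 0
    for gene in genes:
        idx = {t: i for i, t in enumerate(gene.taxa)}
        for t in taxa:
            if t in idx:
                seq = gene.sequences[idx[t]]
                if any(c not in NON_RESIDUE for c in seq):
                    occupancy[t] += 1
                chunks[t].append(seq)
            else:
                chunks[t].append(missing_symbol * gene.n_sites)
        parts.append((gene.name, pos + 1, pos + gene.n_sites))
        pos += gene.n_sites
    aln = Alignment(taxa, ["".join(chunks[t]) for t in taxa], name="supermatrix")
    return Supermatrix(aln, parts, occupancy)


@dataclass
class MatrixStats:
    """Summary statistics of a supermatrix."""

    total_sites: int
    n_taxa: int
    pct_gaps: float
    mean_partition_len: float
    sd_partition_len: float
    per_taxon_gene_counts: dict[str, int]
    per_clade_mean_counts: dict[str, float]


def matrix_stats(sm: Supermatrix, clade_map: Mapping[str, str] | None = None) -> MatrixStats:
    """Compute size, gap percentage and partition-length summaries.

    ``pct_gaps`` pools gap and missing symbols over all cells, matching
    the convention of reporting "% gaps or missing data".  With a
    ``clade_map`` (taxon -> clade label), per-clade means of the
    per-taxon gene counts are included.
    """
    aln = sm.alignment
    ncells = aln.n_taxa * aln.n_sites
    ngap = sum(sum(s.count(c) for c in NON_RESIDUE) for s in aln.sequences)
    lens = np.array([end - start + 1 for _, start, end in sm.partitions], dtype=float)
    clade_means: dict[str, float] = {}
    if clade_map is not None:
        unknown = sorted(set(clade_map) - set(aln.taxa))
        if unknown:
            raise KeyError(f"clade_map references unknown taxa: {unknown}")
        groups: dict[str, list[int]] = {}
        for taxon, clade in clade_map.items():
            groups.setdefault(clade, []).append(sm.occupancy[taxon])
        clade_means = {c: float(np.mean(v)) for c, v in sorted(groups.items())}
    return MatrixStats(
        total_sites=aln.n_sites,
        n_taxa=aln.n_taxa,
        pct_gaps=100.0 * ngap / ncells if ncells else 0.0,
        mean_partition_len=float(np.mean(lens)),
        sd_partition_len=float(np.std(lens, ddof=1)) if len(lens) > 1 else 0.0,
        per_taxon_gene_counts=dict(sm.occupancy),
        per_clade_mean_counts=clade_means,
    )


def write_partitions(sm: Supermatrix, path: str | Path, model: str = "LG+G") -> None:
    """Write a RAxML-style partition file: ``MODEL, gene = start-end``."""
    with open(path, "w") as fh:
        for name, start, end in sm.partitions:
            fh.write(f"{model}, {name} = {start}-{end}\n")


def write_matrix_stats(stats: MatrixStats, path: str | Path) -> None:
    """Write a two-column TSV report of matrix statistics."""
    with open(path, "w") as fh:
        fh.write("statistic\tvalue\n")
        fh.write(f"total_sites\t{stats.total_sites}\n")
        fh.write(f"n_taxa\t{stats.n_taxa}\n")
        fh.write(f"pct_gaps\t{stats.pct_gaps:.4f}\n")
        fh.write(f"mean_partition_len\t{stats.mean_partition_len:.4f}\n")
        fh.write(f"sd_partition_len\t{stats.sd_partition_len:.4f}\n")
        for taxon, count in sorted(stats.per_taxon_gene_counts.items()):
            fh.write(f"gene_count\t{taxon}={count}\n")
        for clade, mean in stats.per_clade_mean_counts.items():
            fh.write(f"clade_mean_gene_count\t{clade}={mean:.4f}\n")
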