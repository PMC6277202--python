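"""Synthetic gene sets with known compositional-bias structure.

Generates collections of gene alignments evolved on a shared species
tree under LG+Gamma, in which a configurable fraction of genes carry a
clade-restricted shift of their stationary composition (nonstationary
evolution) while the rest are compositionally homogeneous.  The shifted
composition concentrates mass on {A, G, P} — a caricature of the
GC-rich-proteome effect that drives real among-lineage composition
differences — and each gene loses taxa at random to emulate patchy
orthologue recovery.  Because the truth (which genes are biased, and
where) is recorded, the null test's operating characteristics (type-I
error, power, binning precision/recall) can be scored exactly.

All randomness flows from the single spec seed through named substreams
(tree, per-gene, missingness), so any gene is regenerable in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .comptest import CompTestResult
from .models import LG_PI, STATE_ORDER, lg_model
from .seqio import Alignment, PhyloTree, TreeNode, write_alignment, write_tree
from .simulate import BranchCompositionMap, CompositionOverride, simulate_alignment

logger = logging.getLogger("compqc")

#: shifted composition concentrating 75% of mass on A, G and P
PI_SHIFT = np.full(20, 0.25 / 17)
for _aa in "AGP":
    PI_SHIFT[STATE_ORDER.index(_aa)] = 0.25
del _aa


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic gene set."""

    n_taxa: int = 16
    n_genes: int = 200
    p_biased: float = 0.5
    site_range: tuple[int, int] = (200, 400)
    alpha_range: tuple[float, float] = (0.5, 1.5)
    bias_weight: float = 0.5
    biased_clade_size: int = 3
    bias_stem_extension: float = 0.75
    missing_taxon_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_biased <= 1:
            raise ValueError("p_biased must lie in [0, 1]")
        if not 0 <= self.bias_weight <= 1:
            raise ValueError("bias_weight must lie in [0, 1]")
        if self.site_range[0] > self.site_range[1] or self.site_range[0] < 1:
            raise ValueError("invalid site_range")
        if self.alpha_range[0] > self.alpha_range[1] or self.alpha_range[0] <= 0:
            raise ValueError("invalid alpha_range")
        if not self.biased_clade_size < self.n_taxa:
            raise ValueError("biased_clade_size must be smaller than n_taxa")
        if not 0 <= self.missing_taxon_rate < 1:
            raise ValueError("missing_taxon_rate must lie in [0, 1)")


@dataclass
class GeneTruth:
    biased: bool
    w: float
    affected_tips: frozenset[str]
    #: the true gene tree (species tree, with the affected clade's stem
    #: elongated for biased genes); None means the species tree as-is
    tree: PhyloTree | None = field(default=None, repr=False, compare=False)


@dataclass
class TruthTable:
    """Ground truth of a generated gene set, keyed by gene name."""

    genes: dict[str, GeneTruth] = field(default_factory=dict)

    @property
    def n_biased(self) -> int:
        return sum(t.biased for t in self.genes.values())


def generate_species_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Random Yule-process topology with exponential(mean 0.1) edge lengths.

    Tips are labelled ``t01``..; internal nodes carry labels ``n1``.. so
    composition overrides can address clades.  Deterministic given seed.
    """
    if n_taxa < 4:
        raise ValueError("a species tree needs at least 4 taxa")
    rng = np.random.default_rng([seed, 0x7ee])
    tips = [TreeNode("t01"), TreeNode("t02")]
    root = TreeNode(None, 0.0, tips[:])
    while len(tips) < n_taxa:
        k = int(rng.integers(len(tips)))
        old = tips[k]
        left = TreeNode(old.label)
        right = TreeNode(f"t{len(tips) + 1:02d}")
        old.label = None
        old.children = [left, right]
        tips[k] = left
        tips.append(right)
    tree = PhyloTree(root)
    counter = 0
    for node in tree.preorder():
        if node is not tree.root:
            node.length = float(rng.exponential(0.1))
        if not node.is_tip and node is not tree.root:
            counter += 1
            node.label = f"n{counter}"
    return tree


def _clades_of_size(tree: PhyloTree, size: int) -> list[tuple[str, frozenset[str]]]:
    out = []
    for node in tree.postorder():
        if node.is_tip or node is tree.root or node.label is None:
            continue
        tips = frozenset(n.label for n in PhyloTree(node).tips())
        if len(tips) == size:
            out.append((node.label, tips))
    return out


def generate_gene_set(spec: SyntheticSpec, tree: PhyloTree
                      ) -> tuple[list[Alignment], TruthTable]:
    """Generate per-gene alignments plus the ground-truth table.

    Per gene: the length and gamma shape are drawn from the spec ranges
    and a gene-specific composition is drawn from a Dirichlet centred on
    the LG frequencies (concentration 100*pi, typical total-variation
    distance from LG of about 0.03).  Biased genes evolve a clade of
    ``biased_clade_size`` tips under ``(1-w)*pi + w*pi_shift``.  Each
    taxon is dropped from each gene independently with
    ``missing_taxon_rate``.
    """
    tip_set = tree.tip_labels()
    if len(tip_set) != spec.n_taxa:
        raise ValueError("tree tip count does not match spec.n_taxa")
    rng = np.random.default_rng([spec.seed, 0xb1a5])
    n_biased = int(round(spec.p_biased * spec.n_genes))
    biased_idx = set(rng.choice(spec.n_genes, size=n_biased, replace=False).tolist())
    clades = _clades_of_size(tree, spec.biased_clade_size)
    if not clades and spec.biased_clade_size > 1 and n_biased:
        logger.warning(
            "no clade of exactly %d tips in the species tree; biased genes "
            "will use random tip sets", spec.biased_clade_size)

    genes: list[Alignment] = []
    truth = TruthTable()
    for g in range(spec.n_genes):
        grng = np.random.default_rng([spec.seed, 1, g])
        name = f"gene{g + 1:04d}"
        nsites = int(grng.integers(spec.site_range[0], spec.site_range[1] + 1))
        shape = float(grng.uniform(*spec.alpha_range))
        pi_gene = grng.dirichlet(100.0 * LG_PI)
        pi_gene = np.clip(pi_gene, 1e-6, None)
        pi_gene /= pi_gene.sum()
        model = lg_model(pi=pi_gene, alpha=shape)

        comp_map = None
        affected: frozenset[str] = frozenset()
        gene_tree = tree
        is_biased = g in biased_idx
        if is_biased:
            if clades:
                label, affected = clades[int(grng.integers(len(clades)))]
                override_nodes = [label]
            else:
                affected = frozenset(
                    grng.choice(tip_set, size=spec.biased_clade_size,
                                replace=False).tolist())
                override_nodes = sorted(affected)
            if spec.bias_weight > 0:
                pi_shift = ((1 - spec.bias_weight) * pi_gene
                            + spec.bias_weight * PI_SHIFT)
                pi_shift /= pi_shift.sum()
                # put the affected clade on an elongated stem so it
                # approaches its shifted composition (deviant lineages
                # are long-branched); the gene tree records the same
                # elongation, keeping the truth self-consistent
                gene_tree = tree.copy()
                for node in gene_tree.postorder():
                    if node.label in override_nodes:
                        node.length += spec.bias_stem_extension / len(override_nodes)
                comp_map = BranchCompositionMap(
                    pi_gene, {n: CompositionOverride(pi_shift, subtree=True)
                              for n in override_nodes})

        sim_seed = int(grng.integers(2 ** 31 - 1))
        aln = simulate_alignment(gene_tree, model, nsites, seed=sim_seed,
                                 comp_map=comp_map, name=name)

        mrng = np.random.default_rng([spec.seed, 2, g])
        keep = mrng.random(spec.n_taxa) >= spec.missing_taxon_rate
        kept_taxa = [t for t, k in zip(aln.taxa, keep) if k]
        if len(kept_taxa) >= 2:
            aln = aln.subset(kept_taxa)
        genes.append(aln)
        truth.genes[name] = GeneTruth(
            is_biased, spec.bias_weight if is_biased else 0.0, affected,
            tree=gene_tree if gene_tree is not tree else None)
    return genes, truth


def true_gene_tree(truth: TruthTable, species_tree: PhyloTree,
                   gene: str) -> PhyloTree:
    """The tree a gene's data actually evolved on (full taxon set)."""
    t = truth.genes[gene].tree
    return t if t is not None else species_tree


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class TestPerformance:
    """Operating characteristics of the test against known truth."""

    alpha: float
    n_homogeneous: int
    n_biased: int
    type_i_error: float
    type_i_ci: tuple[float, float]
    power: float
    power_ci: tuple[float, float]
    n_skipped: int


def _binom_ci(k: int, n: int) -> tuple[float, float]:
    from scipy.stats import binomtest
    if n == 0:
        return (float("nan"), float("nan"))
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return (float(ci.low), float(ci.high))


def evaluate_test_performance(results: list[CompTestResult], truth: TruthTable,
                              alpha: float) -> TestPerformance:
    """Type-I error and power of the test, with exact binomial 95% CIs."""
    if not results:
        raise ValueError("no test results to evaluate")
    names = {r.gene for r in results}
    if names != set(truth.genes):
        raise ValueError("results and truth table cover different gene sets")
    rej_h = tot_h = rej_b = tot_b = skipped = 0
    for r in results:
        if r.status == "skipped":
            skipped += 1
            continue
        reject = r.p_value < alpha
        if truth.genes[r.gene].biased:
            tot_b += 1
            rej_b += reject
        else:
            tot_h += 1
            rej_h += reject
    return TestPerformance(
        alpha=alpha,
        n_homogeneous=tot_h,
        n_biased=tot_b,
        type_i_error=rej_h / tot_h if tot_h else float("nan"),
        type_i_ci=_binom_ci(rej_h, tot_h),
        power=rej_b / tot_b if tot_b else float("nan"),
        power_ci=_binom_ci(rej_b, tot_b),
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# On-disk gene sets
# ---------------------------------------------------------------------------

def write_gene_set(outdir: str | Path, spec: SyntheticSpec, tree: PhyloTree,
                   genes: list[Alignment], truth: TruthTable) -> None:
    """Write per-gene FASTA and trees, the species tree, the truth table
    and a spec echo.

    Per-gene trees are the species tree pruned to the gene's surviving
    taxa, mirroring how per-gene ML trees accompany real orthologue
    sets; they pair with the alignments by basename, so the directory
    is directly consumable by the pipeline.
    """
    from .seqio import prune_to_taxa
    outdir = Path(outdir)
    (outdir / "genes").mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    write_tree(tree, outdir / "species_tree.nwk")
    for aln in genes:
        write_alignment(aln, outdir / "genes" / f"{aln.name}.fasta")
        write_tree(prune_to_taxa(true_gene_tree(truth, tree, aln.name), aln.taxa),
                   outdir / "trees" / f"{aln.name}.nwk")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene\tbiased\tw\taffected_tips\n")
        for name, t in truth.genes.items():
            fh.write(f"{name}\t{int(t.biased)}\t{t.w}\t"
                     f"{','.join(sorted(t.affected_tips))}\n")
    with open(outdir / "spec.yaml", "w") as fh:
        yaml.safe_dump({
            "n_taxa": spec.n_taxa, "n_genes": spec.n_genes,
            "p_biased": spec.p_biased, "site_range": list(spec.site_range),
            "alpha_range": list(spec.alpha_range), "bias_weight": spec.bias_weight,
            "biased_clade_size": spec.biased_clade_size,
            "missing_taxon_rate": spec.missing_taxon_rate, "seed": spec.seed,
        }, fh, sort_keys=False)


def generate_and_write(spec: SyntheticSpec, outdir: str | Path
                       ) -> tuple[PhyloTree, list[Alignment], TruthTable]:
    tree = generate_species_tree(spec.n_taxa, spec.seed)
    genes, truth = generate_gene_set(spec, tree)
    write_gene_set(outdir, spec, tree, genes, truth)
    return tree, genes, truth
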