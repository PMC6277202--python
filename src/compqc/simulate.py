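"""Forward simulation of alignments along trees.

Supports stationary simulation under a single composition vector (null
replicates for the compositional-homogeneity test) and nonstationary
simulation in which selected edges — optionally whole subtrees — evolve
under shifted composition vectors, which is the kind of lineage-
restricted bias the test is designed to detect.  The rate matrix is
rebuilt (and re-normalised to unit rate) from the composition in force
on each edge, keeping branch lengths interpretable as expected
substitutions per site everywhere on the tree.

A gap-mask projection utility copies the gap/missing pattern of an
observed alignment onto a simulated one so null replicates share the
data's missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import SubstitutionModel, TransitionKernel, build_rate_matrix, discretize_gamma, STATE_ORDER
from .seqio import Alignment, PhyloTree, NON_RESIDUE
from .likelihood import TreeArrays


@dataclass
class CompositionOverride:
    """Composition applied to one edge (and optionally its subtree)."""

    pi: np.ndarray
    subtree: bool = True


@dataclass
class BranchCompositionMap:
    """Root composition plus per-edge overrides keyed by child-node label."""

    default_pi: np.ndarray
    overrides: dict[str, CompositionOverride] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.default_pi = _check_pi(self.default_pi)
        for key, ov in self.overrides.items():
            ov.pi = _check_pi(ov.pi)


def _check_pi(pi) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("composition vectors must be strictly positive and sum to 1")
    return pi / pi.sum()


class SimulationKernel:
    """Precomputed per-edge transition CDFs for repeated simulation.

    Building the eigendecompositions and cumulative transition matrices
    once lets many replicates (e.g. the null distribution of a test) be
    drawn cheaply from the same fitted tree and model.
    """

    def __init__(self, tree: PhyloTree, model: SubstitutionModel,
                 comp_map: BranchCompositionMap | None = None):
        tr = TreeArrays(tree)
        if len(tr.tip_labels) < 2:
            raise ValueError("simulation requires a tree with >= 2 tips")
        if comp_map is not None:
            labels = {node.label for node in tree.postorder() if node.label}
            unknown = sorted(set(comp_map.overrides) - labels)
            if unknown:
                raise ValueError(
                    f"composition overrides name unknown nodes: {unknown}")
        self.tree = tr
        self.model = model
        self.ncat = model.ncat
        self.root_pi = comp_map.default_pi if comp_map is not None else model.pi
        gr = discretize_gamma(model.alpha, model.ncat)

        kernels: dict[bytes, TransitionKernel] = {}

        def kernel_for(pi: np.ndarray) -> TransitionKernel:
            key = pi.tobytes()
            if key not in kernels:
                q = build_rate_matrix(model.with_pi(pi))
                kernels[key] = TransitionKernel(q, pi)
            return kernels[key]

        # composition in force on each edge: overrides flow down subtrees
        default_pi = self.root_pi
        edge_pi = [default_pi] * tr.n_nodes
        inherited = [default_pi] * tr.n_nodes
        self.preorder = list(range(tr.n_nodes - 1, -1, -1))
        for v in self.preorder:
            p = tr.parent[v]
            base = default_pi if p < 0 else inherited[p]
            label = tr.nodes[v].label
            ov = (comp_map.overrides.get(label)
                  if (comp_map is not None and label) else None)
            if ov is not None:
                edge_pi[v] = ov.pi
                inherited[v] = ov.pi if ov.subtree else base
            else:
                edge_pi[v] = base
                inherited[v] = base

        self.edge_cdfs: list[np.ndarray | None] = [None] * tr.n_nodes
        for v in self.preorder:
            if v == tr.root:
                continue
            pstack = kernel_for(edge_pi[v]).probability_matrices(
                tr.lengths[v] * gr.rates)
            self.edge_cdfs[v] = np.cumsum(pstack, axis=2)

    def draw(self, nsites: int, seed: int) -> np.ndarray:
        """One replicate of tip states, (n_tips, nsites) int8."""
        if nsites < 1:
            raise ValueError("nsites must be >= 1")
        tr = self.tree
        rng = np.random.default_rng(seed)
        cat = rng.integers(0, self.ncat, size=nsites)
        states = np.empty((tr.n_nodes, nsites), dtype=np.int64)
        states[tr.root] = rng.choice(20, size=nsites, p=self.root_pi)
        for v in self.preorder:
            if v == tr.root:
                continue
            cdf_rows = self.edge_cdfs[v][cat, states[tr.parent[v]]]
            u = rng.random(nsites)
            states[v] = np.minimum((u[:, None] > cdf_rows).sum(axis=1), 19)
        return states[tr.tip_nodes].astype(np.int8)

    @property
    def tip_labels(self) -> list[str]:
        return list(self.tree.tip_labels)


def simulate_codes(tree: PhyloTree, model: SubstitutionModel, nsites: int,
                   seed: int, comp_map: BranchCompositionMap | None = None,
                   return_taxa: bool = False):
    """Simulate integer-encoded states at the tips; rows follow tip order.

    This is the numeric core behind :func:`simulate_alignment`; the test
    machinery uses it directly to avoid string round-trips.
    """
    kernel = SimulationKernel(tree, model, comp_map)
    tip_states = kernel.draw(nsites, seed)
    if return_taxa:
        return tip_states, kernel.tip_labels
    return tip_states


def simulate_alignment(tree: PhyloTree, model: SubstitutionModel, nsites: int,
                       seed: int, comp_map: BranchCompositionMap | None = None,
                       name: str = "simulated") -> Alignment:
    """Simulate an amino-acid alignment along a tree.

    Per site a gamma rate category is drawn, the root state is drawn from
    the (default) stationary composition, and states evolve down each
    edge under the transition matrix built from the composition in force
    on that edge.  Deterministic given ``seed``.
    """
    codes, taxa = simulate_codes(tree, model, nsites, seed, comp_map,
                                 return_taxa=True)
    lut = np.array(list(STATE_ORDER), dtype="U1")
    seqs = ["".join(lut[row]) for row in codes]
    return Alignment(taxa, seqs, name=name)


def apply_gap_mask(sim: Alignment, template: Alignment) -> Alignment:
    """Copy the gap/missing pattern of ``template`` onto ``sim``.

    Both alignments must cover the same taxa at the same length; cells
    that are gap or missing in the template are overwritten with the
    template's symbol, all other cells are untouched.
    """
    if set(sim.taxa) != set(template.taxa):
        raise ValueError("gap-mask template must cover the same taxa")
    if sim.n_sites != template.n_sites:
        raise ValueError(
            f"gap-mask template length {template.n_sites} != simulated length {sim.n_sites}")
    out = []
    for taxon in sim.taxa:
        s = list(sim.sequence(taxon))
        t = template.sequence(taxon)
        for i, ch in enumerate(t):
            if ch in NON_RESIDUE:
                s[i] = ch
        out.append("".join(s))
    return Alignment(list(sim.taxa), out, name=sim.name)
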