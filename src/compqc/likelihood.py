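"""Fixed-topology likelihood computation and model fitting.

Implements Felsenstein's pruning algorithm under a reversible amino-acid
model with discrete-gamma rate variation, with per-pattern rescaling to
prevent underflow, and a coordinate-ascent fit of branch lengths and the
gamma shape used to parameterise null simulations.

Branch-length optimisation exploits time reversibility: for any edge the
likelihood factorises into the partial likelihood of the subtree below
the edge (``D``) and of everything above it (``N``), so after one
post-order and one pre-order pass the likelihood is a cheap function of
that single branch length.  Each edge is optimised in turn with fresh
partials (Gauss-Seidel style), which makes every accepted update a true
ascent step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .models import (GammaRates, SubstitutionModel, TransitionKernel,
                     build_rate_matrix, discretize_gamma, STATE_INDEX)
from .seqio import Alignment, PhyloTree

logger = logging.getLogger("compqc")

BRANCH_MIN = 1e-8
BRANCH_MAX = 20.0
ALPHA_MIN = 0.02
ALPHA_MAX = 100.0


# ---------------------------------------------------------------------------
# Tree flattening and site-pattern compression
# ---------------------------------------------------------------------------

class TreeArrays:
    """Index-based view of a :class:`PhyloTree` for array computation.

    Nodes are numbered in postorder (root last); ``lengths[i]`` is the
    branch above node ``i``.
    """

    def __init__(self, tree: PhyloTree):
        nodes = tree.postorder()
        self.n_nodes = len(nodes)
        self.node_index = {id(n): i for i, n in enumerate(nodes)}
        self.nodes = nodes
        self.root = self.n_nodes - 1
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.lengths = np.zeros(self.n_nodes)
        self.tip_nodes: list[int] = []
        self.tip_labels: list[str] = []
        for i, node in enumerate(nodes):
            self.lengths[i] = node.length
            for child in node.children:
                j = self.node_index[id(child)]
                self.parent[j] = i
                self.children[i].append(j)
            if node.is_tip:
                self.tip_nodes.append(i)
                self.tip_labels.append(node.label)  # type: ignore[arg-type]

    def write_lengths(self) -> None:
        """Copy the (possibly optimised) lengths back onto the tree nodes."""
        for i, node in enumerate(self.nodes):
            if i != self.root:
                node.length = float(self.lengths[i])


def encode_alignment(aln: Alignment, taxa: list[str]) -> np.ndarray:
    """Integer-encode sequences for the given taxa; gap/missing -> -1."""
    table = np.full(128, -1, dtype=np.int8)
    for ch, idx in STATE_INDEX.items():
        table[ord(ch)] = idx
    rows = []
    lookup = {t: s for t, s in zip(aln.taxa, aln.sequences)}
    for t in taxa:
        if t not in lookup:
            raise ValueError(f"tree tip '{t}' has no sequence in alignment {aln.name!r}")
        rows.append(table[np.frombuffer(lookup[t].encode("ascii"), dtype=np.uint8)])
    return np.vstack(rows) if rows else np.empty((0, 0), dtype=np.int8)


def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse alignment columns to unique site patterns with counts."""
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _tip_partials(patterns: np.ndarray, n_states: int = 20) -> np.ndarray:
    """Per-tip partial likelihoods, (n_tips, npat, n_states); gaps -> ones."""
    n_tips, npat = patterns.shape
    partials = np.zeros((n_tips, npat, n_states))
    gap = patterns < 0
    partials[gap] = 1.0
    rows, cols = np.nonzero(~gap)
    partials[rows, cols, patterns[rows, cols]] = 1.0
    return partials


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------

class PruningEngine:
    """Shared state for repeated likelihood evaluations on one gene."""

    def __init__(self, tree: TreeArrays, aln: Alignment, model: SubstitutionModel):
        missing = set(aln.taxa) - set(tree.tip_labels)
        if missing:
            raise ValueError(
                f"alignment {aln.name!r} contains taxa absent from the tree: "
                f"{sorted(missing)}")
        self.tree = tree
        self.model = model
        codes = encode_alignment(aln, tree.tip_labels)
        self.patterns, self.weights = compress_patterns(codes)
        self.npat = self.patterns.shape[1]
        self.n_sites = codes.shape[1]
        self._tipL = _tip_partials(self.patterns)
        self._tip_row = {node: k for k, node in enumerate(tree.tip_nodes)}
        q = build_rate_matrix(model)
        self.kernel = TransitionKernel(q, model.pi)
        self.set_alpha(model.alpha)

    def set_alpha(self, alpha: float) -> None:
        self.alpha = float(alpha)
        gr = discretize_gamma(alpha, self.model.ncat)
        self.rates = gr.rates
        self.cat_weights = gr.weights

    # -- messages ----------------------------------------------------------

    def _message(self, partial: np.ndarray, t: float) -> np.ndarray:
        """Propagate a (ncat, npat, 20) partial through an edge of length t.

        Works for both directions: for reversible models the up-message
        uses the same ``sum_j P_ij x_j`` contraction as the down-message.
        """
        pstack = self.kernel.probability_matrices(t * self.rates)
        return np.matmul(partial, pstack.transpose(0, 2, 1))

    def _down_pass(self) -> tuple[list, np.ndarray]:
        """Postorder partials D[v] with per-pattern log-scale accumulators."""
        tr = self.tree
        ncat = self.model.ncat
        D: list[np.ndarray | None] = [None] * tr.n_nodes
        scale = np.zeros((tr.n_nodes, self.npat))
        for v in range(tr.n_nodes):
            if not tr.children[v]:
                D[v] = np.broadcast_to(self._tipL[self._tip_row[v]],
                                       (ncat, self.npat, 20)).copy()
                continue
            acc = np.ones((ncat, self.npat, 20))
            sc = np.zeros(self.npat)
            for c in tr.children[v]:
                acc *= self._message(D[c], tr.lengths[c])
                sc += scale[c]
            top = acc.max(axis=(0, 2))
            top[top == 0.0] = 1.0
            acc /= top[None, :, None]
            D[v] = acc
            scale[v] = sc + np.log(top)
        return D, scale

    def _up_pass(self, D: list, dscale: np.ndarray) -> tuple[list, np.ndarray]:
        """Preorder outside-subtree partials N[v] (reversible rerooting)."""
        tr = self.tree
        ncat = self.model.ncat
        N: list[np.ndarray | None] = [None] * tr.n_nodes
        scale = np.zeros((tr.n_nodes, self.npat))
        order = list(range(tr.n_nodes - 1, -1, -1))  # preorder (root first)
        for v in order:
            if v == tr.root:
                continue
            p = tr.parent[v]
            if p == tr.root:
                above = np.ones((ncat, self.npat, 20))
                sc = np.zeros(self.npat)
            else:
                above = self._message(N[p], tr.lengths[p])
                sc = scale[p].copy()
            for s in tr.children[p]:
                if s != v:
                    above = above * self._message(D[s], tr.lengths[s])
                    sc = sc + dscale[s]
            top = above.max(axis=(0, 2))
            top[top == 0.0] = 1.0
            above /= top[None, :, None]
            N[v] = above
            scale[v] = sc + np.log(top)
        return N, scale

    # -- likelihood --------------------------------------------------------

    def _root_loglik(self, D: list, dscale: np.ndarray,
                     per_site: bool = False) -> float | np.ndarray:
        site = np.einsum("c,cpi,i->p", self.cat_weights, D[self.tree.root],
                         self.model.pi)
        logs = np.log(np.clip(site, 1e-300, None)) + dscale[self.tree.root]
        if per_site:
            return logs
        return float(self.weights @ logs)

    def log_likelihood(self) -> float:
        if self.n_sites == 0:
            logger.warning("zero-length alignment: log-likelihood is 0.0")
            return 0.0
        D, dscale = self._down_pass()
        return self._root_loglik(D, dscale)

    def edge_loglik_fn(self, v: int, D: list, dscale: np.ndarray,
                       N: list, nscale: np.ndarray):
        """Return the log-likelihood as a cheap function of one branch length."""
        return self._edge_fn(D[v], N[v], dscale[v] + nscale[v])

    def _edge_fn(self, dv: np.ndarray, nv: np.ndarray, const: np.ndarray):
        weighted = nv * self.model.pi[None, None, :] * self.cat_weights[:, None, None]

        def fn(t: float) -> float:
            msg = self._message(dv, t)
            site = (weighted * msg).sum(axis=(0, 2))
            logs = np.log(np.clip(site, 1e-300, None)) + const
            return float(self.weights @ logs)

        return fn

    # -- in-place branch-length sweep (Euler tour) -------------------------

    def optimize_branches_sweep(self, xatol: float = 1e-4) -> None:
        """One Gauss-Seidel sweep of per-branch optimisation.

        Walks the tree depth-first, maintaining exact outside-subtree
        partials incrementally: entering an edge its ``N`` partial is
        assembled from the parent's up-message and current sibling
        messages, the branch is optimised, and on the way back up the
        below-subtree partials are refreshed — so every 1-D optimisation
        sees the likelihood under all current branch lengths, and each
        accepted update is a true ascent step.  Updates
        ``self.tree.lengths`` in place.
        """
        tr = self.tree
        ncat = self.model.ncat
        D: list[np.ndarray | None] = [None] * tr.n_nodes
        scD = np.zeros((tr.n_nodes, self.npat))
        full_D, full_scale = self._down_pass()
        for v in range(tr.n_nodes):
            D[v] = full_D[v]
            scD[v] = full_scale[v]

        def refresh_down(p: int) -> None:
            acc = np.ones((ncat, self.npat, 20))
            sc = np.zeros(self.npat)
            for c in tr.children[p]:
                acc *= self._message(D[c], tr.lengths[c])
                sc += scD[c]
            top = acc.max(axis=(0, 2))
            top[top == 0.0] = 1.0
            D[p] = acc / top[None, :, None]
            scD[p] = sc + np.log(top)

        def visit(p: int, above: np.ndarray, sc_above: np.ndarray) -> None:
            kids = tr.children[p]
            msgs = {c: self._message(D[c], tr.lengths[c]) for c in kids}
            for c in kids:
                nv = above
                sc = sc_above
                for s in kids:
                    if s != c:
                        nv = nv * msgs[s]
                        sc = sc + scD[s]
                top = nv.max(axis=(0, 2))
                top[top == 0.0] = 1.0
                nv = nv / top[None, :, None]
                sc = sc + np.log(top)
                fn = self._edge_fn(D[c], nv, sc + scD[c])
                res = minimize_scalar(lambda t: -fn(t),
                                      bounds=(BRANCH_MIN, BRANCH_MAX),
                                      method="bounded", options={"xatol": xatol})
                if -res.fun > fn(tr.lengths[c]):
                    tr.lengths[c] = float(res.x)
                if tr.children[c]:
                    visit(c, self._message(nv, tr.lengths[c]), sc)
                    refresh_down(c)
                msgs[c] = self._message(D[c], tr.lengths[c])
            refresh_down(p)

        visit(tr.root, np.ones((ncat, self.npat, 20)), np.zeros(self.npat))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def log_likelihood(tree: PhyloTree, aln: Alignment, model: SubstitutionModel) -> float:
    """Pruning log-likelihood of an alignment on a fixed tree.

    Gap/missing characters contribute all-ones partial likelihoods (the
    standard missing-data marginalisation); sites are assumed independent
    with gamma-distributed rates integrated over ``model.ncat`` discrete
    categories of equal weight.
    """
    tr = TreeArrays(tree)
    if len(tr.tip_labels) < 2:
        raise ValueError("likelihood requires a tree with >= 2 tips")
    return PruningEngine(tr, aln, model).log_likelihood()


@dataclass
class FittedGeneModel:
    """Result of fitting branch lengths and gamma shape on a fixed topology."""

    tree: PhyloTree
    model: SubstitutionModel
    loglik: float
    n_iterations: int
    converged: bool


def fit_branch_lengths_alpha(tree: PhyloTree, aln: Alignment,
                             model: SubstitutionModel,
                             optimize_branches: bool = True,
                             optimize_alpha: bool = True,
                             tol: float = 1e-4,
                             max_rounds: int = 30) -> FittedGeneModel:
    """Coordinate-ascent fit of branch lengths and gamma shape.

    Alternates a postorder sweep of bounded 1-D branch-length
    optimisations (each on ``[1e-8, 20]``) with a bounded optimisation of
    the gamma shape on ``[0.02, 100]``, until the log-likelihood improves
    by less than ``tol`` or ``max_rounds`` is reached.  The topology is
    never altered.  Deterministic: there is no randomness in the
    optimiser.
    """
    work = tree.copy()
    tr = TreeArrays(work)
    if len(tr.tip_labels) < 2:
        raise ValueError("fit requires a tree with >= 2 tips")
    engine = PruningEngine(tr, aln, model)
    if engine.n_sites == 0:
        logger.warning("zero-length alignment: nothing to fit")
        return FittedGeneModel(work, model, 0.0, 0, True)

    ll = engine.log_likelihood()
    if not np.isfinite(ll):
        per_site = engine._root_loglik(*engine._down_pass(), per_site=True)
        bad_pat = int(np.argmin(np.isfinite(per_site)))
        raise ValueError(
            f"non-finite starting likelihood (first offending site pattern "
            f"index {bad_pat})")

    np.clip(tr.lengths, BRANCH_MIN, BRANCH_MAX, out=tr.lengths)
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        prev = ll
        if optimize_branches:
            engine.optimize_branches_sweep()
        if optimize_alpha and model.ncat > 1:
            def neg_alpha(a: float) -> float:
                engine.set_alpha(a)
                return -engine.log_likelihood()
            # after the first round, search near the previous optimum and
            # widen again only if the optimum presses against the bracket
            if rounds == 1:
                lo, hi = ALPHA_MIN, ALPHA_MAX
            else:
                lo = max(ALPHA_MIN, engine.alpha / 1.6)
                hi = min(ALPHA_MAX, engine.alpha * 1.6)
            res = minimize_scalar(neg_alpha, bounds=(lo, hi),
                                  method="bounded", options={"xatol": 1e-2})
            best_alpha = float(res.x)
            if rounds > 1 and (best_alpha < lo * 1.02 or best_alpha > hi / 1.02):
                res = minimize_scalar(neg_alpha, bounds=(ALPHA_MIN, ALPHA_MAX),
                                      method="bounded", options={"xatol": 1e-2})
                best_alpha = float(res.x)
            engine.set_alpha(best_alpha)
        ll = engine.log_likelihood()
        if ll - prev < tol:
            converged = True
            break

    tr.write_lengths()
    fitted_model = model.with_alpha(engine.alpha)
    return FittedGeneModel(work, fitted_model, ll, rounds, converged)
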