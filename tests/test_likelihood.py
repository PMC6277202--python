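"""Pruning likelihood against independent oracles; branch/shape fitting."""

import math

import dendropy
import numpy as np
import pytest

from conftest import random_pi
from compqc.likelihood import fit_branch_lengths_alpha, log_likelihood
from compqc.models import (STATE_INDEX, build_rate_matrix, discretize_gamma,
                           empirical_frequencies, lg_model, poisson_model,
                           transition_matrix)
from compqc.seqio import Alignment, PhyloTree
from compqc.simulate import simulate_alignment


def enumeration_loglik(newick: str, aln: Alignment, model) -> float:
    """Independent oracle: sum over all internal-state assignments.

    Uses an einsum contraction over explicit per-node state axes — no
    pruning recursion shared with the implementation under test.
    """
    q = build_rate_matrix(model)
    gr = discretize_gamma(model.alpha, model.ncat)
    tree = PhyloTree.from_newick(newick)
    nodes = tree.postorder()
    axes = {id(n): chr(ord("a") + i) for i, n in enumerate(nodes)}
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for rate, weight in zip(gr.rates, gr.weights):
            ps = {id(n): transition_matrix(q, model.pi, n.length * rate)
                  for n in nodes if n is not tree.root}
            operands, subscripts = [], []
            for n in nodes:
                if n is tree.root:
                    continue
                parent = next(p for p in nodes if n in p.children)
                if n.is_tip:
                    # clamp the observed state: only the parent axis remains
                    obs = STATE_INDEX[aln.sequence(n.label)[site]]
                    subscripts.append(axes[id(parent)])
                    operands.append(ps[id(n)][:, obs])
                else:
                    subscripts.append(axes[id(parent)] + axes[id(n)])
                    operands.append(ps[id(n)])
            subscripts.append(axes[id(tree.root)])
            operands.append(model.pi)
            expr = ",".join(subscripts) + "->"
            site_lik += weight * float(np.einsum(expr, *operands, optimize=True))
        total += math.log(site_lik)
    return total


class TestPruningOracles:
    def test_two_taxon_closed_form(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.3);")
        model = poisson_model(ncat=1)
        aln = Alignment(["A", "B"], ["A", "A"])
        t = 0.4
        p_aa = 1 / 20 + (19 / 20) * math.exp(-20 * t / 19)
        assert log_likelihood(tree, aln, model) == pytest.approx(
            math.log(0.05 * p_aa), abs=1e-9)

    @pytest.mark.parametrize("newick,ntips", [
        ("((A:{a},B:{b}):{e},(C:{c},D:{d}):{f});", 4),
        ("(((A:{a},B:{b}):{e},C:{c}):{f},(D:{d},E:{g}):{h});", 5),
    ])
    def test_matches_exhaustive_enumeration(self, newick, ntips, rng):
        letters = "ABCDE"[:ntips]
        for rep in range(3):
            lens = {k: rng.uniform(0.02, 0.8)
                    for k in "abcdefgh"}
            nwk = newick.format(**{k: f"{v:.4f}" for k, v in lens.items()})
            seqs = ["".join(rng.choice(list("ARNDCQEGHILKMFPSTVWY"), 4))
                    for _ in letters]
            aln = Alignment(list(letters), seqs)
            model = lg_model(pi=random_pi(rng), alpha=rng.uniform(0.3, 2.0), ncat=2)
            tree = PhyloTree.from_newick(nwk)
            assert log_likelihood(tree, aln, model) == pytest.approx(
                enumeration_loglik(nwk, aln, model), abs=1e-8)

    def test_all_gap_column_contributes_nothing(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.1,(C:0.3,D:0.1):0.2);")
        model = lg_model(alpha=0.7)
        base = Alignment(list("ABCD"), ["ACD", "ACD", "ACC", "ADD"])
        padded = Alignment(list("ABCD"), ["ACD-", "ACD-", "ACCX", "ADD?"])
        assert log_likelihood(tree, padded, model) == pytest.approx(
            log_likelihood(tree, base, model), abs=1e-10)

    def test_reroot_invariance(self, rng):
        """Pulley principle: reversible likelihood ignores root placement."""
        nwk = "(((A:0.11,B:0.23):0.1,C:0.3):0.05,(D:0.4,E:0.15):0.12);"
        model = lg_model(pi=random_pi(rng), alpha=0.9)
        seqs = ["".join(rng.choice(list("ARNDCQEGHILKMFPSTVWY"), 30))
                for _ in range(5)]
        aln = Alignment(list("ABCDE"), seqs)
        ref = log_likelihood(PhyloTree.from_newick(nwk), aln, model)
        dtree = dendropy.Tree.get(data=nwk, schema="newick")
        edges = [e for e in dtree.preorder_edge_iter()
                 if e.length and e.head_node.parent_node]
        for k in range(min(5, len(edges))):
            t2 = dtree.clone(depth=1)
            e = [x for x in t2.preorder_edge_iter()
                 if x.length and x.head_node.parent_node][k]
            t2.reroot_at_edge(e, length1=e.length / 2, length2=e.length / 2)
            rerooted = PhyloTree.from_newick(t2.as_string(schema="newick"))
            assert log_likelihood(rerooted, aln, model) == pytest.approx(
                ref, rel=1e-10)

    def test_taxon_mismatch_errors(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.3);")
        model = poisson_model()
        with pytest.raises(ValueError, match="tip 'B'"):
            log_likelihood(tree, Alignment(["A"], ["AC"]), model)
        with pytest.raises(ValueError, match="absent from the tree"):
            log_likelihood(tree, Alignment(["A", "B", "C"], ["A", "A", "A"]),
                           model)


class TestFitting:
    def test_loglik_never_decreases(self, rng):
        tree = PhyloTree.from_newick(
            "((A:0.3,B:0.05):0.1,(C:0.6,D:0.02):0.2);")
        model = lg_model(alpha=0.8)
        aln = simulate_alignment(tree, model, 400, seed=5)
        start = PhyloTree.from_newick(
            "((A:0.9,B:0.9):0.9,(C:0.9,D:0.9):0.9);")
        ll0 = log_likelihood(start, aln,
                             lg_model(pi=empirical_frequencies(aln)))
        fm = fit_branch_lengths_alpha(start, aln,
                                      lg_model(pi=empirical_frequencies(aln)))
        assert fm.loglik >= ll0
        assert fm.converged
        assert log_likelihood(fm.tree, aln, fm.model) == pytest.approx(
            fm.loglik, abs=1e-6)

    def test_identical_sequences_collapse_branches(self):
        tree = PhyloTree.from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        aln = Alignment(list("ABCD"), ["ACDEF" * 12] * 4)
        fm = fit_branch_lengths_alpha(tree, aln,
                                      lg_model(pi=empirical_frequencies(aln)))
        lengths = [n.length for n in fm.tree.postorder()
                   if n is not fm.tree.root]
        assert max(lengths) < 1e-3

    def test_fit_is_deterministic(self, rng):
        tree = PhyloTree.from_newick("((A:0.3,B:0.1):0.1,(C:0.2,D:0.4):0.2);")
        aln = simulate_alignment(tree, lg_model(alpha=1.2), 200, seed=9)
        model = lg_model(pi=empirical_frequencies(aln))
        fm1 = fit_branch_lengths_alpha(tree, aln, model)
        fm2 = fit_branch_lengths_alpha(tree, aln, model)
        assert fm1.loglik == fm2.loglik
        assert fm1.model.alpha == fm2.model.alpha
        assert fm1.tree.to_newick() == fm2.tree.to_newick()

    def test_refit_off_keeps_lengths(self):
        tree = PhyloTree.from_newick("((A:0.3,B:0.1):0.1,(C:0.2,D:0.4):0.2);")
        aln = simulate_alignment(tree, lg_model(alpha=1.2), 150, seed=9)
        model = lg_model(pi=empirical_frequencies(aln))
        fm = fit_branch_lengths_alpha(tree, aln, model, optimize_branches=False)
        assert fm.tree.to_newick() == tree.to_newick()
        assert 0.02 <= fm.model.alpha <= 100
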