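"""The per-gene null-simulation homogeneity test and gene binning."""

import numpy as np
import pytest

from compqc.comptest import (CompTestResult, bin_genes, composition_null_test,
                             gene_seed, write_results_tsv)
from compqc.models import lg_model
from compqc.seqio import Alignment, PhyloTree
from compqc.simulate import simulate_alignment


@pytest.fixture(scope="module")
def homogeneous_gene():
    tree = PhyloTree.from_newick(
        "(((A:0.15,B:0.2):0.1,(C:0.25,D:0.1):0.05):0.05,(E:0.3,F:0.1):0.1);")
    aln = simulate_alignment(tree, lg_model(alpha=0.8), 250, seed=77,
                             name="homog")
    return tree, aln


class TestCompositionNullTest:
    def test_deterministic_given_seed(self, homogeneous_gene):
        tree, aln = homogeneous_gene
        r1 = composition_null_test(aln, tree, n_replicates=29, seed=5)
        r2 = composition_null_test(aln, tree, n_replicates=29, seed=5)
        assert (r1.p_value, r1.observed, r1.n_ge) == (r2.p_value, r2.observed, r2.n_ge)

    def test_add_one_p_value_rule(self, homogeneous_gene):
        tree, aln = homogeneous_gene
        r = composition_null_test(aln, tree, n_replicates=29, seed=5)
        assert r.p_value == pytest.approx((1 + r.n_ge) / 30)
        assert 0 < r.p_value <= 1
        assert r.n_replicates == 29

    def test_too_few_taxa_skipped(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
        aln = Alignment(list("ABC"), ["ACDEF" * 20] * 3)
        r = composition_null_test(aln, tree)
        assert r.status == "skipped" and "taxa" in r.reason

    def test_short_alignment_skipped(self, homogeneous_gene):
        tree, aln = homogeneous_gene
        short = Alignment(aln.taxa, [s[:30] for s in aln.sequences], "short")
        r = composition_null_test(short, tree)
        assert r.status == "skipped" and "sites" in r.reason

    def test_taxon_mismatch_errors(self, homogeneous_gene):
        tree, aln = homogeneous_gene
        sub = aln.subset(["A", "B", "C", "D"])
        with pytest.raises(ValueError, match="differ"):
            composition_null_test(sub, tree)

    def test_biased_gene_rejected_strongly(self):
        """A hard composition shift on one clade should give a tiny p."""
        from compqc.simulate import BranchCompositionMap, CompositionOverride
        from compqc.models import STATE_ORDER
        tree = PhyloTree.from_newick(
            "((A:0.3,B:0.3)n1:0.3,(C:0.3,D:0.3)n2:0.1,(E:0.3,F:0.3)n3:0.1);")
        m = lg_model(alpha=1.0)
        shift = np.full(20, 0.4 / 17)
        for aa in "AGP":
            shift[STATE_ORDER.index(aa)] = 0.2
        cmap = BranchCompositionMap(m.pi, {"n1": CompositionOverride(shift)})
        aln = simulate_alignment(tree, m, 300, seed=21, comp_map=cmap,
                                 name="biased")
        r = composition_null_test(aln, tree, n_replicates=99, seed=4)
        assert r.status == "fail"
        assert r.p_value == pytest.approx(1 / 100)
        assert r.z > 3

    def test_mask_gaps_respects_template(self, homogeneous_gene):
        tree, aln = homogeneous_gene
        gapped = Alignment(aln.taxa,
                           [("-" * 30 + s[30:]) if i == 0 else s
                            for i, s in enumerate(aln.sequences)], "gappy")
        r = composition_null_test(gapped, tree, n_replicates=19, seed=5)
        assert r.status in ("pass", "fail")
        assert r.n_taxa == 6


class TestGeneSeed:
    def test_stable_and_independent(self):
        assert gene_seed(7, "gene1") == gene_seed(7, "gene1")
        assert gene_seed(7, "gene1") != gene_seed(7, "gene2")
        assert 0 <= gene_seed(2 ** 29, "x") < 2 ** 30


class TestBinGenes:
    @staticmethod
    def _result(name, p, status=None):
        r = CompTestResult(gene=name, p_value=p)
        r.status = status or ("fail" if p < 0.1 else "pass")
        return r

    def test_threshold_rule(self):
        res = [self._result("a", 0.05), self._result("b", 0.50)]
        passing, failing, skipped = bin_genes(res, 0.10)
        assert failing == ["a"] and passing == ["b"] and skipped == []

    def test_boundary_p_value_passes(self):
        res = [self._result("a", 0.10)]
        passing, failing, _ = bin_genes(res, 0.10)
        assert passing == ["a"] and failing == []

    def test_empty_input(self):
        assert bin_genes([], 0.1) == ([], [], [])

    def test_skipped_kept_separate_order_preserved(self):
        res = [self._result("a", 0.5), self._result("b", 0.01),
               CompTestResult(gene="c", status="skipped"),
               self._result("d", 0.02)]
        passing, failing, skipped = bin_genes(res, 0.10)
        assert passing == ["a"] and failing == ["b", "d"] and skipped == ["c"]

    def test_duplicate_gene_names_rejected(self):
        res = [self._result("a", 0.5), self._result("a", 0.01)]
        with pytest.raises(ValueError, match="duplicate"):
            bin_genes(res, 0.10)

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            bin_genes([], 0.0)


class TestZScoreNormality:
    def test_per_taxon_z_scores_standard_normal_under_null(self):
        """Per-taxon composition z-scores on homogeneous genes ~ N(0,1).

        Simulates homogeneous genes, standardises each taxon's summed
        absolute composition distance against predictive replicates from
        the fitted model, and checks the pooled z-scores are centred
        with roughly standard-normal spread.
        """
        from compqc.compstats import distances_from_counts
        from compqc.comptest import _null_counts, _observed_counts
        from compqc.likelihood import TreeArrays, encode_alignment, fit_branch_lengths_alpha
        from compqc.models import empirical_frequencies, lg_model
        from compqc.seqio import prune_to_taxa
        from compqc.synthetic_data import (SyntheticSpec, generate_gene_set,
                                           generate_species_tree)
        spec = SyntheticSpec(n_taxa=8, n_genes=200, p_biased=0.0,
                             site_range=(120, 200), missing_taxon_rate=0.0,
                             seed=606)
        tree = generate_species_tree(8, 606)
        genes, _ = generate_gene_set(spec, tree)
        all_z = []
        for aln in genes:
            gt = prune_to_taxa(tree, aln.taxa)
            fitted = fit_branch_lengths_alpha(
                gt, aln, lg_model(pi=empirical_frequencies(aln)))
            codes = encode_alignment(aln, TreeArrays(gt).tip_labels)
            obs_d = distances_from_counts(_observed_counts(codes))
            null = _null_counts(fitted, codes, 60, seed=gene_seed(9, aln.name),
                                mask_gaps=True)
            null_d = np.array([distances_from_counts(c) for c in null])
            sd = null_d.std(axis=0, ddof=1)
            z = (obs_d - null_d.mean(axis=0)) / sd
            all_z.extend(z[np.isfinite(z)].tolist())
        all_z = np.array(all_z)
        assert abs(all_z.mean()) < 0.15
        assert np.mean(np.abs(all_z) < 2) > 0.90


def test_results_tsv_roundtrip(tmp_path, homogeneous_gene):
    import pandas as pd
    tree, aln = homogeneous_gene
    r = composition_null_test(aln, tree, n_replicates=19, seed=1)
    skipped = CompTestResult(gene="tiny", status="skipped", reason="too few taxa")
    write_results_tsv([r, skipped], tmp_path / "res.tsv")
    df = pd.read_csv(tmp_path / "res.tsv", sep="\t")
    assert list(df["gene"]) == ["homog", "tiny"]
    assert df.loc[0, "p_value"] == pytest.approx(r.p_value)
    assert df.loc[0, "n_ge"] == r.n_ge
    assert df.loc[1, "status"] == "skipped"
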