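"""Per-gene null-simulation test of among-lineage compositional homogeneity.

For each gene the test (i) estimates a homogeneous substitution model on
the gene's fixed tree — empirical stationary composition, optionally
refitted branch lengths and gamma shape; (ii) simulates replicate
alignments under that single-composition model, by default projecting
the observed gap/missing pattern onto each replicate; (iii) compares the
observed across-taxon composition chi-square with its simulated null
distribution.  The tail-area p-value uses the add-one rule
``p = (1 + #{null >= observed}) / (1 + n_replicates)``, which can never
be zero, and genes are binned as failing when ``p < alpha`` strictly.

No multiple-testing correction drives the binning (the screen operates
at a raw alpha by design); a Benjamini-Hochberg FDR column is included
in the TSV output for information only.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import false_discovery_control

from . import compstats
from .likelihood import FittedGeneModel, TreeArrays, encode_alignment, fit_branch_lengths_alpha
from .models import empirical_frequencies, model_by_name
from .seqio import Alignment, PhyloTree
from .simulate import SimulationKernel

logger = logging.getLogger("compqc")

DEFAULT_ALPHA = 0.10
DEFAULT_REPLICATES = 1000
MIN_TAXA = 4
MIN_SITES = 50
_SEED_SPACE = 2 ** 30


def gene_seed(base_seed: int, gene_name: str) -> int:
    """Stable per-gene seed: adding/removing genes never shifts others."""
    return int((base_seed + zlib.crc32(gene_name.encode())) % _SEED_SPACE)


@dataclass
class CompTestResult:
    """Outcome of the compositional-homogeneity test for one gene."""

    gene: str
    n_taxa: int = 0
    n_sites: int = 0
    observed: float = float("nan")
    null_mean: float = float("nan")
    null_sd: float = float("nan")
    n_replicates: int = 0
    n_ge: int = 0
    p_value: float = float("nan")
    z: float = float("nan")
    status: str = "skipped"
    reason: str = ""
    alpha: float = DEFAULT_ALPHA
    fitted: FittedGeneModel | None = field(default=None, repr=False, compare=False)


def _null_counts(fitted: FittedGeneModel, obs_codes: np.ndarray,
                 n_replicates: int, seed: int, mask_gaps: bool,
                 n_states: int = 20) -> np.ndarray:
    """Residue count matrices of null replicates, (n_replicates, n_taxa, 20).

    Replicate ``r`` uses seed ``seed + r`` so any replicate is
    regenerable in isolation.  With ``mask_gaps`` the observed
    gap/missing cells are excluded from each replicate's counts, exactly
    as projecting the observed mask and recounting would do.
    """
    n_taxa, n_sites = obs_codes.shape
    gap = obs_codes < 0
    kernel = SimulationKernel(fitted.tree, fitted.model)
    out = np.empty((n_replicates, n_taxa, n_states), dtype=np.int64)
    for r in range(n_replicates):
        codes = kernel.draw(n_sites, seed=int((seed + r) % (2 ** 31 - 1)))
        if mask_gaps:
            codes = np.where(gap, -1, codes)
        for i in range(n_taxa):
            row = codes[i]
            out[r, i] = np.bincount(row[row >= 0], minlength=n_states)
    return out


def _observed_counts(obs_codes: np.ndarray, n_states: int = 20) -> np.ndarray:
    counts = np.zeros((obs_codes.shape[0], n_states), dtype=np.int64)
    for i, row in enumerate(obs_codes):
        counts[i] = np.bincount(row[row >= 0], minlength=n_states)
    return counts


def composition_null_test(aln: Alignment, tree: PhyloTree, model_name: str = "LG",
                          n_replicates: int = DEFAULT_REPLICATES, seed: int = 0,
                          refit: bool = True, alpha: float = DEFAULT_ALPHA,
                          mask_gaps: bool = True, min_taxa: int = MIN_TAXA,
                          min_sites: int = MIN_SITES) -> CompTestResult:
    """Run the null-simulation compositional-homogeneity test on one gene.

    The tree must carry exactly the alignment's taxa (prune beforehand
    with :func:`compqc.seqio.prune_to_taxa` if needed).  Genes with fewer
    than ``min_taxa`` taxa carrying residues or fewer than ``min_sites``
    sites are skipped rather than tested.  Deterministic given ``seed``.
    """
    result = CompTestResult(gene=aln.name, alpha=alpha)
    tips = set(tree.tip_labels())
    if tips != set(aln.taxa):
        raise ValueError(
            f"gene {aln.name!r}: tree tips and alignment taxa differ "
            f"(only in tree: {sorted(tips - set(aln.taxa))[:5]}, "
            f"only in alignment: {sorted(set(aln.taxa) - tips)[:5]})")

    tr = TreeArrays(tree)
    obs_codes = encode_alignment(aln, tr.tip_labels)
    counted = (obs_codes >= 0).sum(axis=1)
    result.n_taxa = int((counted > 0).sum())
    result.n_sites = aln.n_sites
    if result.n_taxa < min_taxa:
        result.reason = "too few taxa"
        return result
    if aln.n_sites < min_sites:
        result.reason = "too few sites"
        return result

    pi = empirical_frequencies(aln)
    model = model_by_name(model_name, pi=pi)
    try:
        fitted = fit_branch_lengths_alpha(tree, aln, model,
                                          optimize_branches=refit)
    except ValueError as exc:
        result.reason = f"model fit failed: {exc}"
        return result
    if not np.isfinite(fitted.loglik):
        result.reason = "non-finite fitted likelihood"
        return result
    result.fitted = fitted

    obs_counts = _observed_counts(obs_codes)
    observed = compstats.chi_square_from_counts(obs_counts)
    null_counts = _null_counts(fitted, obs_codes, n_replicates, seed, mask_gaps)
    null_stats = np.array([compstats.chi_square_from_counts(c) for c in null_counts])

    result.observed = observed
    result.null_mean = float(null_stats.mean())
    result.null_sd = float(null_stats.std(ddof=1))
    result.n_replicates = n_replicates
    result.n_ge = int((null_stats >= observed).sum())
    result.p_value = (1 + result.n_ge) / (1 + n_replicates)
    result.z = compstats.z_scores(observed, null_stats.tolist())
    result.status = "fail" if result.p_value < alpha else "pass"
    return result


def bin_genes(results: list[CompTestResult], alpha: float
              ) -> tuple[list[str], list[str], list[str]]:
    """Split genes into test-passing / test-failing / skipped lists.

    Failing means ``p < alpha`` strictly: a boundary p-value equal to
    alpha passes (conservative toward keeping genes).  Input order is
    preserved in each list.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    names = [r.gene for r in results]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene names in results: {dupes}")
    passing, failing, skipped = [], [], []
    for r in results:
        if r.status == "skipped":
            skipped.append(r.gene)
        elif r.p_value < alpha:
            failing.append(r.gene)
        else:
            passing.append(r.gene)
    return passing, failing, skipped


def write_results_tsv(results: list[CompTestResult], path) -> None:
    """TSV report of per-gene test results (with an informational BH-FDR
    column that never drives binning)."""
    tested = [r for r in results if r.status != "skipped"]
    fdr = {}
    if tested:
        adj = false_discovery_control([r.p_value for r in tested], method="bh")
        fdr = {r.gene: q for r, q in zip(tested, adj)}
    cols = ("gene\tn_taxa\tn_sites\tobserved\tnull_mean\tnull_sd\tn_ge\t"
            "n_replicates\tp_value\tz\tfdr_bh\tstatus\treason\n")
    with open(path, "w") as fh:
        fh.write(cols)
        for r in results:
            fh.write(
                f"{r.gene}\t{r.n_taxa}\t{r.n_sites}\t{r.observed:.6g}\t"
                f"{r.null_mean:.6g}\t{r.null_sd:.6g}\t{r.n_ge}\t{r.n_replicates}\t"
                f"{r.p_value:.6g}\t{r.z:.6g}\t"
                f"{fdr.get(r.gene, float('nan')):.6g}\t{r.status}\t{r.reason}\n")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in open(path) if ln.strip()]


def write_gene_list(genes: list[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
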