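"""End-to-end compositional-QC pipeline.

Pairs per-gene alignments with their trees, runs the null-simulation
homogeneity test on every testable gene, bins genes into test-passing
and test-failing sets at a significance threshold, concatenates each bin
into a supermatrix (with partition file and matrix statistics), computes
a per-taxon composition z-score table for each supermatrix from plug-in
predictive replicates, and optionally writes Dayhoff-6 recoded copies.

Per-gene results are cached as JSON under ``output_dir/cache`` together
with the fitted model (tree with optimised lengths, gamma shape,
composition), so re-running with the same configuration reuses cached
results and re-running with only a different alpha merely re-bins.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import compstats
from .comptest import (CompTestResult, bin_genes, composition_null_test,
                       gene_seed, write_gene_list, write_results_tsv)
from .likelihood import FittedGeneModel, encode_alignment
from .models import model_by_name
from .recode import DAYHOFF6, recode_alignment
from .seqio import (Alignment, PhyloTree, Supermatrix, concatenate,
                    matrix_stats, prune_to_taxa, read_alignment, read_tree,
                    write_alignment, write_matrix_stats, write_partitions)
from .simulate import SimulationKernel

logger = logging.getLogger("compqc")

ALN_SUFFIXES = (".fasta", ".fa", ".faa", ".fas")
TREE_SUFFIXES = (".nwk", ".newick", ".tre", ".treefile")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    alignments_dir: str
    trees_dir: str
    output_dir: str
    model_name: str = "LG"
    n_replicates: int = 1000
    alpha: float = 0.10
    refit: bool = True
    mask_gaps: bool = True
    recode_output: bool = False
    seed: int = 0
    min_taxa: int = 4
    min_sites: int = 50
    n_pp_replicates: int = 100
    gene_list: str | None = None
    pairing_manifest: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly between 0 and 1")

    def cache_fingerprint(self) -> str:
        """Hash of the settings that determine per-gene test results.

        alpha is deliberately excluded: p-values are alpha-independent,
        so a re-run with a different alpha only re-bins.
        """
        key = json.dumps([self.model_name, self.n_replicates, self.refit,
                          self.mask_gaps, self.seed, self.min_taxa,
                          self.min_sites, __version__])
        return hashlib.sha256(key.encode()).hexdigest()[:16]


def pair_genes(config: RunConfig) -> list[tuple[str, Path, Path]]:
    """Pair alignments and trees by shared basename (or explicit manifest)."""
    if config.pairing_manifest:
        rows = [ln.split("\t") for ln in
                Path(config.pairing_manifest).read_text().strip().splitlines()]
        return [(r[0].strip(), Path(r[1].strip()), Path(r[2].strip())) for r in rows]
    adir, tdir = Path(config.alignments_dir), Path(config.trees_dir)
    trees = {}
    for p in sorted(tdir.iterdir()):
        if p.suffix.lower() in TREE_SUFFIXES:
            trees[p.stem] = p
    wanted = None
    if config.gene_list:
        wanted = {ln.strip() for ln in open(config.gene_list) if ln.strip()}
    pairs = []
    for p in sorted(adir.iterdir()):
        if p.suffix.lower() not in ALN_SUFFIXES:
            continue
        if wanted is not None and p.stem not in wanted:
            continue
        if p.stem in trees:
            pairs.append((p.stem, p, trees[p.stem]))
        else:
            logger.warning("gene %s: no matching tree file, skipped", p.stem)
    return pairs


# ---------------------------------------------------------------------------
# Per-gene result cache
# ---------------------------------------------------------------------------

def _result_to_json(r: CompTestResult, fingerprint: str) -> dict:
    doc = {"fingerprint": fingerprint}
    for k in ("gene", "n_taxa", "n_sites", "observed", "null_mean", "null_sd",
              "n_replicates", "n_ge", "p_value", "z", "status", "reason", "alpha"):
        doc[k] = getattr(r, k)
    if r.fitted is not None:
        doc["fitted"] = {
            "newick": r.fitted.tree.to_newick(),
            "alpha": r.fitted.model.alpha,
            "pi": list(map(float, r.fitted.model.pi)),
            "loglik": r.fitted.loglik,
        }
    return doc


def _result_from_json(doc: dict, model_name: str) -> CompTestResult:
    r = CompTestResult(gene=doc["gene"])
    for k in ("n_taxa", "n_sites", "observed", "null_mean", "null_sd",
              "n_replicates", "n_ge", "p_value", "z", "status", "reason", "alpha"):
        setattr(r, k, doc[k])
    if "fitted" in doc:
        f = doc["fitted"]
        model = model_by_name(model_name, pi=np.array(f["pi"]), alpha=f["alpha"])
        r.fitted = FittedGeneModel(PhyloTree.from_newick(f["newick"]), model,
                                   f["loglik"], 0, True)
    return r


# ---------------------------------------------------------------------------
# Per-supermatrix predictive z-score table
# ---------------------------------------------------------------------------

def _taxon_counts(codes: np.ndarray) -> np.ndarray:
    counts = np.zeros((codes.shape[0], 20), dtype=np.int64)
    for i, row in enumerate(codes):
        counts[i] = np.bincount(row[row >= 0], minlength=20)
    return counts


def _column_diversity(codes: np.ndarray) -> tuple[int, int]:
    """(sum of distinct residues over qualifying columns, n qualifying)."""
    pres = np.zeros((20, codes.shape[1]), dtype=bool)
    mask = codes >= 0
    rows, cols = np.nonzero(mask)
    pres[codes[rows, cols], cols] = True
    distinct = pres.sum(axis=0)
    qual = distinct > 0
    return int(distinct[qual].sum()), int(qual.sum())


def predictive_zscore_table(results: list[CompTestResult],
                            alignments: dict[str, Alignment],
                            sm: Supermatrix, n_replicates: int, seed: int,
                            out_path: str | Path) -> dict[str, float]:
    """Fig.-3C-style per-taxon composition z-scores for one supermatrix.

    Null replicates are plug-in parametric predictive simulations: each
    gene is re-simulated under its fitted homogeneous model (with the
    observed gap mask), the replicate supermatrix counts are pooled, and
    the observed per-taxon summed-absolute-distance statistics are
    standardised against the replicate distribution.  Matrix-level
    summaries (chi-square, distance mean/max, per-site diversity) are
    standardised the same way.  Returns the summary z-scores.
    """
    taxa = sm.alignment.taxa
    tindex = {t: i for i, t in enumerate(taxa)}
    gene_results = [r for r in results if r.fitted is not None]
    n_taxa = len(taxa)

    obs_counts = np.zeros((n_taxa, 20), dtype=np.int64)
    obs_div_num = 0
    obs_div_den = 0
    gene_ctx = []
    for r in gene_results:
        aln = alignments[r.gene]
        tr_tips = r.fitted.tree.tip_labels()
        codes = encode_alignment(aln, tr_tips)
        rows = np.array([tindex[t] for t in tr_tips])
        cnt = _taxon_counts(codes)
        np.add.at(obs_counts, rows, cnt)
        dn, dd = _column_diversity(codes)
        obs_div_num += dn
        obs_div_den += dd
        gene_ctx.append((r, codes < 0, rows,
                         SimulationKernel(r.fitted.tree, r.fitted.model)))

    present = obs_counts.sum(axis=1) > 0
    obs_dist = compstats.distances_from_counts(obs_counts[present])
    obs_chi = compstats.chi_square_from_counts(obs_counts)
    obs_div = obs_div_num / obs_div_den if obs_div_den else float("nan")

    null_dist = np.empty((n_replicates, present.sum()))
    null_chi = np.empty(n_replicates)
    null_dmean = np.empty(n_replicates)
    null_dmax = np.empty(n_replicates)
    null_div = np.empty(n_replicates)
    for rep in range(n_replicates):
        counts = np.zeros((n_taxa, 20), dtype=np.int64)
        div_num = div_den = 0
        for r, gapmask, rows, kernel in gene_ctx:
            rep_seed = int((gene_seed(seed + 104729, r.gene) + rep) % (2 ** 31 - 1))
            codes = kernel.draw(gapmask.shape[1], seed=rep_seed)
            codes = np.where(gapmask, -1, codes)
            np.add.at(counts, rows, _taxon_counts(codes))
            dn, dd = _column_diversity(codes)
            div_num += dn
            div_den += dd
        d = compstats.distances_from_counts(counts[present])
        null_dist[rep] = d
        null_chi[rep] = compstats.chi_square_from_counts(counts)
        null_dmean[rep] = np.nanmean(d)
        null_dmax[rep] = np.nanmax(d)
        null_div[rep] = div_num / div_den if div_den else float("nan")

    mean, sd = null_dist.mean(axis=0), null_dist.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_taxa = (obs_dist - mean) / sd
    summary = {
        "chi_square_z": compstats.z_scores(obs_chi, null_chi.tolist()),
        "distance_mean_z": compstats.z_scores(float(np.nanmean(obs_dist)),
                                              null_dmean.tolist()),
        "distance_max_z": compstats.z_scores(float(np.nanmax(obs_dist)),
                                             null_dmax.tolist()),
        "diversity_z": compstats.z_scores(obs_div, null_div.tolist()),
    }
    with open(out_path, "w") as fh:
        fh.write("# per-taxon composition z-scores against plug-in parametric "
                 "predictive replicates\n")
        fh.write(f"# (single fitted model per gene, {n_replicates} replicates; "
                 "not a posterior predictive sample)\n")
        fh.write("taxon\tobserved_distance\tnull_mean\tnull_sd\tz\n")
        for t, o, m, s, z in zip(np.array(taxa)[present], obs_dist, mean, sd, z_taxa):
            fh.write(f"{t}\t{o:.6g}\t{m:.6g}\t{s:.6g}\t{z:.6g}\n")
        for key, val in summary.items():
            fh.write(f"#summary\t{key}\t{val:.6g}\n")
    return summary


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunSummary:
    n_genes: int
    n_passing: int
    n_failing: int
    n_skipped: int
    results: list[CompTestResult] = field(repr=False, default_factory=list)
    passing: list[str] = field(default_factory=list)
    failing: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    output_dir: str = ""


def run_qc_pipeline(config: RunConfig) -> RunSummary:
    """Run test -> bin -> concatenate -> report for a directory of genes."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run(config: RunConfig, outdir: Path) -> RunSummary:
    pairs = pair_genes(config)
    if not pairs:
        raise ValueError("no pairable genes found")
    cache_dir = outdir / "cache"
    cache_dir.mkdir(exist_ok=True)
    fingerprint = config.cache_fingerprint()

    results: list[CompTestResult] = []
    alignments: dict[str, Alignment] = {}
    for i, (gene, aln_path, tree_path) in enumerate(pairs, 1):
        aln = read_alignment(aln_path)
        aln.name = gene
        alignments[gene] = aln
        cache_file = cache_dir / f"{gene}.json"
        if cache_file.exists():
            doc = json.loads(cache_file.read_text())
            if doc.get("fingerprint") == fingerprint:
                results.append(_result_from_json(doc, config.model_name))
                continue
        try:
            tree = read_tree(tree_path)
            extra = set(tree.tip_labels()) - set(aln.taxa)
            if extra:
                tree = prune_to_taxa(tree, set(tree.tip_labels()) & set(aln.taxa))
            res = composition_null_test(
                aln, tree, model_name=config.model_name,
                n_replicates=config.n_replicates,
                seed=gene_seed(config.seed, gene), refit=config.refit,
                alpha=config.alpha, mask_gaps=config.mask_gaps,
                min_taxa=config.min_taxa, min_sites=config.min_sites)
        except Exception as exc:
            logger.error("gene %s failed: %s", gene, exc)
            res = CompTestResult(gene=gene, status="skipped",
                                 reason=f"error: {exc}", alpha=config.alpha)
        results.append(res)
        tmp = cache_file.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(_result_to_json(res, fingerprint)))
        tmp.replace(cache_file)
        logger.info("gene %s [%d/%d]: %s (p=%.4g)", gene, i, len(pairs),
                    res.status, res.p_value)

    for r in results:
        r.alpha = config.alpha
        if r.status != "skipped":
            r.status = "fail" if r.p_value < config.alpha else "pass"
    write_results_tsv(results, outdir / "results.tsv")
    passing, failing, skipped = bin_genes(results, config.alpha)
    write_gene_list(passing, outdir / "passing_genes.txt")
    write_gene_list(failing, outdir / "failing_genes.txt")
    write_gene_list(skipped, outdir / "skipped_genes.txt")

    by_gene = {r.gene: r for r in results}
    for label, members in (("passing", passing), ("failing", failing)):
        if not members:
            continue
        sm = concatenate([alignments[g] for g in members])
        write_alignment(sm.alignment, outdir / f"supermatrix_{label}.fasta")
        write_alignment(sm.alignment, outdir / f"supermatrix_{label}.phy",
                        format="phylip-relaxed")
        write_partitions(sm, outdir / f"supermatrix_{label}.partitions",
                         model=config.model_name + "+G")
        write_matrix_stats(matrix_stats(sm), outdir / f"matrixstats_{label}.tsv")
        if config.recode_output:
            rec = recode_alignment(sm.alignment, DAYHOFF6)
            write_alignment(rec, outdir / f"supermatrix_{label}.dayhoff6.fasta")
        if config.n_pp_replicates >= 2:
            predictive_zscore_table(
                [by_gene[g] for g in members], alignments, sm,
                n_replicates=config.n_pp_replicates, seed=config.seed,
                out_path=outdir / f"zscores_{label}.tsv")

    summary = RunSummary(
        n_genes=len(results), n_passing=len(passing), n_failing=len(failing),
        n_skipped=len(skipped), results=results, passing=passing,
        failing=failing, skipped=skipped, output_dir=str(outdir))
    manifest = {
        "package": "compqc", "version": __version__,
        "python": sys.version.split()[0],
        "config": {k: v for k, v in asdict(config).items()},
        "fingerprint": fingerprint,
        "n_genes": summary.n_genes, "n_passing": summary.n_passing,
        "n_failing": summary.n_failing, "n_skipped": summary.n_skipped,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return summary
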