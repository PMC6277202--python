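"""Composition and diversity statistics for alignments.

All statistics are alphabet-generic: they count whatever non-gap,
non-missing symbols appear, so they apply unchanged to 20-state
amino-acid data and to reduced-alphabet (e.g. Dayhoff-6 recoded)
matrices.  Frequencies here use raw counts without pseudocounts — these
statistics describe the data; model-fitting frequencies (models module)
deliberately differ by adding pseudocounts.

Statistics:

* the across-taxon contingency chi-square, the discrepancy measure used
  for the null-simulation homogeneity test;
* the per-taxon summed absolute distance between taxon-specific and
  global empirical frequencies (with mean/max summaries), the statistic
  plotted in composition z-score figures;
* mean per-site residue diversity (distinct residues per column);
* z-score standardisation of any of these against predictive replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import Alignment, NON_RESIDUE

logger = logging.getLogger("compqc")


def _counts_frame(aln: Alignment) -> pd.DataFrame:
    """Per-taxon counts of every counted (non-gap/missing) symbol."""
    symbols = sorted(set("".join(aln.sequences)) - set(NON_RESIDUE))
    data = np.zeros((aln.n_taxa, len(symbols)), dtype=float)
    index = {s: j for j, s in enumerate(symbols)}
    for i, seq in enumerate(aln.sequences):
        for ch, n in pd.Series(list(seq)).value_counts().items():
            j = index.get(ch)
            if j is not None:
                data[i, j] = n
    return pd.DataFrame(data, index=aln.taxa, columns=symbols)


def residue_frequencies(aln: Alignment, per_taxon: bool = False):
    """Empirical residue frequencies, gaps and missing symbols excluded.

    Returns a Series (global, pooled over taxa) or a DataFrame with one
    row per taxon.  Taxa with no counted residues raise an error.
    """
    counts = _counts_frame(aln)
    if counts.size == 0 or counts.values.sum() == 0:
        raise ValueError(f"alignment {aln.name!r} contains no counted residues")
    if per_taxon:
        totals = counts.sum(axis=1)
        empty = list(totals.index[totals == 0])
        if empty:
            raise ValueError(f"taxa with no counted residues: {empty}")
        return counts.div(totals, axis=0)
    pooled = counts.sum(axis=0)
    return pooled / pooled.sum()


def chi_square_from_counts(counts: np.ndarray) -> float:
    """Contingency chi-square over a taxa x residue-class count matrix.

    Rows with zero total (taxa entirely missing) are dropped; classes
    with zero global count are skipped.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts.sum(axis=1) > 0]
    if counts.shape[0] < 2:
        raise ValueError("chi-square requires >= 2 taxa with counted residues")
    col = counts.sum(axis=0)
    keep = col > 0
    counts = counts[:, keep]
    freqs = col[keep] / col[keep].sum()
    expected = counts.sum(axis=1, keepdims=True) * freqs[None, :]
    return float(((counts - expected) ** 2 / expected).sum())


def chi_square_stat(aln: Alignment) -> float:
    """Across-taxon compositional chi-square of an alignment."""
    return chi_square_from_counts(_counts_frame(aln).values)


def distances_from_counts(counts: np.ndarray) -> np.ndarray:
    """Per-taxon summed absolute distance to the pooled composition.

    Rows with zero totals yield NaN (taxon absent)."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    pooled = counts.sum(axis=0)
    global_freq = pooled / pooled.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / totals[:, None]
    return np.abs(freqs - global_freq[None, :]).sum(axis=1)


def comp_distance_stat(aln: Alignment) -> tuple[dict[str, float], float, float]:
    """Summed absolute distance between taxon and global frequencies.

    Returns ``(per_taxon, mean, max)``; taxa with no counted residues are
    excluded from all three.
    """
    counts = _counts_frame(aln)
    totals = counts.sum(axis=1)
    present = counts[totals > 0]
    if present.shape[0] < 2:
        raise ValueError("distance statistic requires >= 2 taxa with counted residues")
    d = distances_from_counts(present.values)
    per_taxon = dict(zip(present.index, d.tolist()))
    return per_taxon, float(np.mean(d)), float(np.max(d))


def diversity_stat(aln: Alignment) -> float:
    """Mean number of distinct residues per column, all-gap sites excluded."""
    mat = aln.char_matrix()
    if mat.size == 0:
        raise ValueError("diversity undefined for an empty alignment")
    non_res = np.isin(mat, list(NON_RESIDUE))
    distinct = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        distinct[j] = len(set(mat[~non_res[:, j], j]))
    qualifying = distinct > 0
    if not qualifying.any():
        raise ValueError("no sites with counted residues")
    return float(distinct[qualifying].mean())


def z_scores(observed, null_values: Sequence):
    """Standardise observed statistics against predictive replicates.

    ``z = (observed - mean(null)) / sd(null)`` with the sample standard
    deviation; applied element-wise when ``observed`` is a mapping of
    per-taxon statistics (``null_values`` then being a sequence of
    matching mappings).  A degenerate null (sd = 0) yields signed
    infinity with a warning, or 0 when the observed value equals the
    null mean.
    """
    if isinstance(observed, Mapping):
        keys = list(observed)
        null_arr = np.array([[rep[k] for k in keys] for rep in null_values], dtype=float)
        zs = _z(np.array([observed[k] for k in keys], dtype=float), null_arr)
        return dict(zip(keys, zs.tolist()))
    null_arr = np.asarray(list(null_values), dtype=float).reshape(len(null_values), 1)
    return float(_z(np.array([float(observed)]), null_arr)[0])


def _z(obs: np.ndarray, null_arr: np.ndarray) -> np.ndarray:
    if null_arr.shape[0] < 2:
        raise ValueError("z-scores require >= 2 replicates")
    mean = null_arr.mean(axis=0)
    sd = null_arr.std(axis=0, ddof=1)
    out = np.zeros_like(obs, dtype=float)
    degen = sd == 0
    if degen.any():
        diff = obs[degen] != mean[degen]
        if diff.any():
            logger.warning("degenerate null distribution (sd = 0): z set to signed infinity")
        out[degen] = np.where(obs[degen] > mean[degen], np.inf,
                              np.where(obs[degen] < mean[degen], -np.inf, 0.0))
    ok = ~degen
    out[ok] = (obs[ok] - mean[ok]) / sd[ok]
    return out


@dataclass
class CompStatReport:
    """All composition/diversity summaries of one alignment."""

    global_freqs: pd.Series
    per_taxon_freqs: pd.DataFrame
    chi_square: float
    per_taxon_distance: dict[str, float]
    distance_mean: float
    distance_max: float
    diversity: float


def compstat_report(aln: Alignment) -> CompStatReport:
    per_taxon, dmean, dmax = comp_distance_stat(aln)
    return CompStatReport(
        global_freqs=residue_frequencies(aln),
        per_taxon_freqs=residue_frequencies(aln, per_taxon=True),
        chi_square=chi_square_stat(aln),
        per_taxon_distance=per_taxon,
        distance_mean=dmean,
        distance_max=dmax,
        diversity=diversity_stat(aln),
    )
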