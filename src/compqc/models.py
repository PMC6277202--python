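"""Amino-acid substitution-model numerics.

A model couples a symmetric exchangeability matrix ``S`` (LG, Poisson, or
user-supplied GTR) with a stationary composition vector ``pi``, a gamma
shape ``alpha`` and a number of discrete rate categories.  The rate
matrix is ``Q_ij = s_ij * pi_j`` (i != j), scaled so the expected
substitution rate at stationarity is one, i.e. ``-sum_i pi_i Q_ii = 1``.
Transition probabilities ``P(t) = exp(Qt)`` are obtained from the
symmetric eigendecomposition of ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``,
which is numerically stable and exact for reversible models.

Composition vectors estimated from data for model fitting use pooled
empirical counts with gaps/missing excluded plus a pseudocount of 0.5
per residue, so simulated replicates never carry a zero frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special

from ._lg_data import AA_ORDER, LG_FREQUENCIES, LG_LOWER_TRIANGLE
from .seqio import Alignment, NON_RESIDUE

N_STATES = 20
#: model state order (canonical PAML ordering, matches the LG constants)
STATE_ORDER = AA_ORDER
STATE_INDEX = {a: i for i, a in enumerate(STATE_ORDER)}


def _lg_matrix() -> np.ndarray:
    # column-major lower triangle: all s_ij for i > j, column by column
    s = np.zeros((N_STATES, N_STATES))
    k = 0
    for j in range(N_STATES - 1):
        for i in range(j + 1, N_STATES):
            s[i, j] = s[j, i] = LG_LOWER_TRIANGLE[k]
            k += 1
    return s


LG_EXCHANGEABILITIES = _lg_matrix()
LG_PI = np.array(LG_FREQUENCIES)
LG_PI = LG_PI / LG_PI.sum()


@dataclass
class SubstitutionModel:
    """Reversible amino-acid substitution model with discrete-gamma rates."""

    exchangeabilities: np.ndarray
    pi: np.ndarray
    alpha: float = 1.0
    ncat: int = 4
    name: str = "GTR"

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        s = self.exchangeabilities
        if s.shape != (N_STATES, N_STATES):
            raise ValueError(f"exchangeability matrix must be {N_STATES}x{N_STATES}")
        if not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if (s < 0).any():
            raise ValueError("exchangeabilities must be non-negative")
        if self.pi.shape != (N_STATES,):
            raise ValueError(f"pi must have {N_STATES} entries")
        if (self.pi <= 0).any():
            raise ValueError("stationary frequencies must be strictly positive")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("stationary frequencies must sum to 1")
        self.pi = self.pi / self.pi.sum()
        if not self.alpha > 0:
            raise ValueError("gamma shape alpha must be positive")
        if self.ncat < 1:
            raise ValueError("ncat must be a positive integer")

    def with_pi(self, pi: np.ndarray) -> "SubstitutionModel":
        return SubstitutionModel(self.exchangeabilities, pi, self.alpha, self.ncat, self.name)

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        return SubstitutionModel(self.exchangeabilities, self.pi, alpha, self.ncat, self.name)


def lg_model(pi: np.ndarray | None = None, alpha: float = 1.0, ncat: int = 4) -> SubstitutionModel:
    """LG exchangeabilities, optionally with a custom composition (+F)."""
    return SubstitutionModel(LG_EXCHANGEABILITIES, LG_PI if pi is None else pi,
                             alpha, ncat, name="LG")


def poisson_model(pi: np.ndarray | None = None, alpha: float = 1.0, ncat: int = 4) -> SubstitutionModel:
    """Equal exchangeabilities (Poisson / F81-style model)."""
    s = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
    pi = np.full(N_STATES, 1.0 / N_STATES) if pi is None else pi
    return SubstitutionModel(s, pi, alpha, ncat, name="POISSON")


def model_by_name(name: str, pi: np.ndarray | None = None, alpha: float = 1.0,
                  ncat: int = 4, exchange_tsv: str | Path | None = None) -> SubstitutionModel:
    """Build a preset model by name ("LG", "POISSON") or "GTR" from a TSV."""
    key = name.upper()
    if key == "LG":
        return lg_model(pi, alpha, ncat)
    if key == "POISSON":
        return poisson_model(pi, alpha, ncat)
    if key == "GTR":
        if exchange_tsv is None:
            raise ValueError("GTR requires a user-supplied exchangeability TSV")
        s = read_exchangeabilities_tsv(exchange_tsv)
        return SubstitutionModel(s, LG_PI if pi is None else pi, alpha, ncat, name="GTR")
    raise ValueError(f"unknown model name: {name!r}")


def read_exchangeabilities_tsv(path: str | Path) -> np.ndarray:
    """Read a symmetric exchangeability matrix from a TSV with header row/col
    of one-letter codes."""
    lines = [ln.split("\t") for ln in Path(path).read_text().strip().splitlines()]
    header = [c.strip().upper() for c in lines[0][1:]]
    if sorted(header) != sorted(STATE_ORDER):
        raise ValueError("exchangeability TSV must cover the 20 amino acids")
    s = np.zeros((N_STATES, N_STATES))
    for row in lines[1:]:
        i = STATE_INDEX[row[0].strip().upper()]
        for code, val in zip(header, row[1:]):
            s[i, STATE_INDEX[code]] = float(val)
    return s


def read_frequencies_tsv(path: str | Path) -> np.ndarray:
    """Read a composition vector from a two-column TSV (one-letter code, freq)."""
    pi = np.zeros(N_STATES)
    for ln in Path(path).read_text().strip().splitlines():
        code, val = ln.split("\t")[:2]
        code = code.strip().upper()
        if code in STATE_INDEX:
            pi[STATE_INDEX[code]] = float(val)
    return pi / pi.sum()


def write_frequencies_tsv(pi: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, f in zip(STATE_ORDER, pi):
            fh.write(f"{a}\t{f:.10g}\n")


def empirical_frequencies(aln: Alignment, pseudocount: float = 0.5) -> np.ndarray:
    """Pooled empirical amino-acid frequencies for model fitting.

    Gaps and missing symbols are excluded; a pseudocount (default 0.5 per
    residue) keeps every frequency strictly positive.
    """
    counts = np.full(N_STATES, pseudocount, dtype=float)
    for seq in aln.sequences:
        for ch in seq:
            idx = STATE_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1.0
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Rate matrix, discrete gamma, transition probabilities
# ---------------------------------------------------------------------------

def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Unit-rate-normalised reversible rate matrix Q from a model.

    ``Q_ij = s_ij pi_j`` off-diagonal, rows summing to zero, scaled so the
    stationary substitution rate ``-sum_i pi_i Q_ii`` equals one.
    """
    q = model.exchangeabilities * model.pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(model.pi * np.diag(q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero substitution rate)")
    return q / scale


@dataclass
class GammaRates:
    """Discrete-gamma rate categories with equal weights and unit mean."""

    rates: np.ndarray
    weights: np.ndarray


def discretize_gamma(alpha: float, ncat: int) -> GammaRates:
    """Mean-of-category discretisation of Gamma(alpha, alpha).

    Category boundaries sit at the j/ncat quantiles; each category rate is
    the conditional mean of the distribution within its interval, which
    preserves a unit expected rate exactly.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return GammaRates(np.array([1.0]), np.array([1.0]))
    probs = np.arange(1, ncat) / ncat
    # quantiles of Gamma(shape=alpha, rate=alpha)
    bounds = special.gammaincinv(alpha, probs) / alpha
    # conditional means via the regularized incomplete gamma of shape alpha+1:
    # E[X; X in (a,b)] = (P(alpha+1, b*alpha) - P(alpha+1, a*alpha)) for unit mean
    upper = special.gammainc(alpha + 1, bounds * alpha)
    cum = np.concatenate(([0.0], upper, [1.0]))
    rates = np.diff(cum) * ncat
    weights = np.full(ncat, 1.0 / ncat)
    return GammaRates(rates, weights)


class TransitionKernel:
    """Cached spectral decomposition of Q for fast ``P(t)`` evaluation.

    Uses the similarity transform ``B = diag(sqrt(pi)) Q diag(1/sqrt(pi))``
    which is symmetric for reversible Q, so ``P(t) = D^-1 U exp(L t) U' D``
    with an orthogonal U.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        self.pi = np.asarray(pi, dtype=float)
        sqrt_pi = np.sqrt(self.pi)
        b = sqrt_pi[:, None] * q / sqrt_pi[None, :]
        b = 0.5 * (b + b.T)  # enforce exact symmetry
        eigval, eigvec = np.linalg.eigh(b)
        self._eigval = eigval
        # left/right factors so that P(t) = right @ diag(exp(l t)) @ left
        self._right = eigvec / sqrt_pi[:, None]
        self._left = eigvec.T * sqrt_pi[None, :]

    def probability_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self._right * np.exp(self._eigval * t)) @ self._left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def probability_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stacked ``P(t)`` for a vector of times; shape (len(ts), 20, 20)."""
        ts = np.asarray(ts, dtype=float)
        if (ts < 0).any():
            raise ValueError("branch lengths must be non-negative")
        p = (self._right[None, :, :] * np.exp(np.outer(ts, self._eigval))[:, None, :]) @ self._left
        np.maximum(p, 0.0, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


def transition_matrix(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """Transition probability matrix ``P(t) = exp(Qt)`` for reversible Q."""
    return TransitionKernel(q, pi).probability_matrix(t)
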