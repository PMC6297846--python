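"""Codon substitution models: rate matrices, frequency models, site classes.

The instantaneous rate from codon *i* to *j* is zero unless the codons
differ at exactly one nucleotide, and otherwise proportional to the target
codon frequency pi_j, multiplied by kappa for transitions and by omega
(dN/dS) for non-synonymous changes.  Matrices are scaled so the expected
substitution rate is one, so branch lengths are in expected substitutions
per codon.

Three model families sit on top of the single-omega matrix:

* site models M8a/M8 — omega varies over sites as a discretized beta on
  (0, 1) plus one extra class with omega_s = 1 (M8a, nearly neutral) or
  omega_s >= 1 estimated (M8, positive selection);
* branch models — one omega per branch partition (outgroup "G" branches,
  background, and optionally one tested foreground branch);
* branch-site model A — four site classes (0, 1, 2a, 2b) whose omega
  differs between the foreground branch and the rest of the tree; the null
  variant fixes the foreground omega at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import betainc, betaln

from .genetic_code import (
    CODON_POS_NUC,
    N_CODONS,
    PAIR_I,
    PAIR_IS_SYNONYMOUS,
    PAIR_IS_TRANSITION,
    PAIR_J,
)

__all__ = [
    "CodonSubstModel",
    "SiteClassModel",
    "BranchPartitionModel",
    "BranchSiteModel",
    "build_rate_matrix",
    "codon_frequencies",
    "discretize_beta",
    "BACKGROUND",
    "FOREGROUND",
    "G_ROOT",
]

# canonical branch partition labels
BACKGROUND = "background"
FOREGROUND = "foreground"
G_ROOT = "G_root"


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def codon_frequencies(codon_matrix: np.ndarray, model: str = "F3x4") -> np.ndarray:
    """Equilibrium codon frequencies from observed data.

    ``codon_matrix`` holds codon indices (−1 = missing), shape (taxa, sites).
    ``model`` is one of ``uniform``, ``F1x4``, ``F3x4``, ``F61``.
    """
    obs = codon_matrix[codon_matrix >= 0]
    if model == "uniform":
        return np.full(N_CODONS, 1.0 / N_CODONS)
    if model == "F61":
        counts = np.bincount(obs, minlength=N_CODONS).astype(float) + 0.5
        return counts / counts.sum()
    # nucleotide-composition models
    nuc_of_obs = CODON_POS_NUC[obs]  # (n_obs, 3)
    if model == "F1x4":
        counts = np.bincount(nuc_of_obs.ravel(), minlength=4).astype(float) + 0.5
        f = counts / counts.sum()
        pi = f[CODON_POS_NUC[:, 0]] * f[CODON_POS_NUC[:, 1]] * f[CODON_POS_NUC[:, 2]]
    elif model == "F3x4":
        pi = np.ones(N_CODONS)
        for k in range(3):
            counts = np.bincount(nuc_of_obs[:, k], minlength=4).astype(float) + 0.5
            fk = counts / counts.sum()
            pi = pi * fk[CODON_POS_NUC[:, k]]
    else:
        raise ValueError(f"unknown frequency model {model!r}")
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# rate matrix
# ---------------------------------------------------------------------------

@dataclass
class CodonSubstModel:
    """Single-omega codon model (kappa, omega, equilibrium frequencies)."""

    kappa: float
    omega: float
    pi: np.ndarray
    freq_model: str = "F3x4"

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (N_CODONS,):
            raise ValueError(f"pi must have {N_CODONS} entries")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError(f"pi sums to {self.pi.sum()!r}, not 1 within 1e-8")


def _unscaled_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    rates = np.where(PAIR_IS_TRANSITION, kappa, 1.0) * np.where(
        PAIR_IS_SYNONYMOUS, 1.0, omega
    )
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[PAIR_I, PAIR_J] = rates * pi[PAIR_J]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def mean_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitution rate sum_i pi_i * (−Q_ii)."""
    return float(-(pi * np.diag(Q)).sum())


def build_rate_matrix(model: CodonSubstModel, scale: bool = True) -> np.ndarray:
    """61x61 generator matrix, scaled to unit expected rate by default."""
    Q = _unscaled_rate_matrix(model.kappa, model.omega, model.pi)
    if scale:
        r = mean_rate(Q, model.pi)
        if r > 0:
            Q = Q / r
    return Q


class RateMatrixCache:
    """Eigendecompositions of codon rate matrices, keyed by (kappa, omega).

    The GY-style matrix is reversible, so B = D^{1/2} Q D^{-1/2} with
    D = diag(pi) is symmetric; transition matrices come from its
    eigendecomposition: P(t) = D^{-1/2} U exp(L t) U' D^{1/2}.
    """

    def __init__(self, pi: np.ndarray):
        self.pi = np.asarray(pi, dtype=float)
        self._sqrt = np.sqrt(self.pi)
        self._cache: dict[tuple[float, float], tuple] = {}

    def decomposition(self, kappa: float, omega: float):
        key = (round(float(kappa), 12), round(float(omega), 12))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        Q = _unscaled_rate_matrix(kappa, omega, self.pi)
        B = Q * (self._sqrt[:, None] / self._sqrt[None, :])
        lam, U = np.linalg.eigh((B + B.T) / 2.0)
        left = U.T * self._sqrt[None, :]       # U' D^{1/2}
        right = U / self._sqrt[:, None]        # D^{-1/2} U
        rate = mean_rate(Q, self.pi)
        out = (lam, right, left, rate)
        if len(self._cache) > 256:
            self._cache.clear()
        self._cache[key] = out
        return out

    def transition_matrix(self, kappa: float, omega: float, t: float, rate_scale: float) -> np.ndarray:
        """P(t) for the matrix scaled by 1/rate_scale (unit-rate when
        rate_scale equals the matrix's own mean rate)."""
        lam, right, left, _rate = self.decomposition(kappa, omega)
        scaled_t = t / rate_scale if rate_scale > 0 else 0.0
        P = (right * np.exp(lam * scaled_t)[None, :]) @ left
        np.maximum(P, 0.0, out=P)
        return P

    def rate(self, kappa: float, omega: float) -> float:
        return self.decomposition(kappa, omega)[3]


# ---------------------------------------------------------------------------
# beta discretization (M8/M8a)
# ---------------------------------------------------------------------------

def discretize_beta(p: float, q: float, K: int) -> np.ndarray:
    """K equal-probability categories of Beta(p, q), each at its bin mean."""
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be > 0")
    edges = np.linspace(0.0, 1.0, K + 1)
    from scipy.stats import beta as beta_dist

    x_edges = beta_dist.ppf(edges, p, q)
    # mean of Beta(p,q) on [a,b]: E = B(p+1,q)/B(p,q) * (I_b(p+1,q)-I_a(p+1,q)) / (1/K)
    coeff = np.exp(betaln(p + 1, q) - betaln(p, q))
    upper = betainc(p + 1, q, x_edges[1:])
    lower = betainc(p + 1, q, x_edges[:-1])
    means = coeff * (upper - lower) * K
    return np.clip(means, 1e-9, 1.0 - 1e-9)


# ---------------------------------------------------------------------------
# mixture model descriptions
# ---------------------------------------------------------------------------

@dataclass
class SiteClassModel:
    """M8a/M8 site-class mixture.

    A proportion p0 of sites draws omega from a K-category discretized
    Beta(p, q); the remaining 1 − p0 sit in a final class with omega_s
    (fixed at 1 under M8a, a free parameter >= 1 under M8).
    """

    model_id: str  # "M8a" | "M8"
    p0: float
    p_beta: float
    q_beta: float
    omega_s: float = 1.0
    K: int = 10

    def __post_init__(self) -> None:
        if self.model_id not in {"M8a", "M8"}:
            raise ValueError("model_id must be 'M8a' or 'M8'")
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must lie in [0, 1]")
        if self.model_id == "M8a" and self.omega_s != 1.0:
            raise ValueError("M8a fixes omega_s = 1")
        if self.omega_s < 1.0:
            raise ValueError("omega_s must be >= 1")

    def classes(self) -> tuple[np.ndarray, list[dict[str, float]]]:
        """(proportions, per-class {branch label: omega}) — single partition."""
        omegas = discretize_beta(self.p_beta, self.q_beta, self.K)
        props = np.full(self.K, self.p0 / self.K)
        props = np.append(props, 1.0 - self.p0)
        maps = [{BACKGROUND: float(w)} for w in omegas]
        maps.append({BACKGROUND: float(self.omega_s)})
        return props, maps


@dataclass
class BranchPartitionModel:
    """One omega per branch partition; a single site class."""

    omegas: dict[str, float]  # label -> omega, e.g. {G_ROOT: .., BACKGROUND: ..}

    def __post_init__(self) -> None:
        if not self.omegas:
            raise ValueError("at least one branch partition required")
        for lab, w in self.omegas.items():
            if w < 0:
                raise ValueError(f"omega for partition {lab!r} must be >= 0")

    def classes(self) -> tuple[np.ndarray, list[dict[str, float]]]:
        return np.array([1.0]), [dict(self.omegas)]


@dataclass
class BranchSiteModel:
    """Branch-site model A and its null (omega2 fixed at 1).

    Site classes: 0 (omega0 everywhere), 1 (neutral everywhere),
    2a (omega0 background, omega2 foreground), 2b (neutral background,
    omega2 foreground), with p2a/p2b = p0/p1.
    """

    p0: float
    p1: float
    omega0: float
    omega2: float = 1.0
    null: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p0 < 1) or not (0 <= self.p1 < 1) or self.p0 + self.p1 > 1:
            raise ValueError("need 0 < p0, 0 <= p1, p0 + p1 <= 1")
        if not (0 <= self.omega0 < 1):
            raise ValueError("omega0 must lie in [0, 1)")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")
        if self.null and self.omega2 != 1.0:
            raise ValueError("null variant fixes omega2 = 1")

    def class_proportions(self) -> np.ndarray:
        p2 = 1.0 - self.p0 - self.p1
        denom = self.p0 + self.p1
        p2a = p2 * self.p0 / denom
        p2b = p2 * self.p1 / denom
        return np.array([self.p0, self.p1, p2a, p2b])

    def classes(self) -> tuple[np.ndarray, list[dict[str, float]]]:
        w0, w2 = self.omega0, self.omega2
        maps = [
            {BACKGROUND: w0, FOREGROUND: w0},
            {BACKGROUND: 1.0, FOREGROUND: 1.0},
            {BACKGROUND: w0, FOREGROUND: w2},
            {BACKGROUND: 1.0, FOREGROUND: w2},
        ]
        return self.class_proportions(), maps
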