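"""Maximum-likelihood fitting of codon models.

Each model variant is described by a small spec object that maps a free
parameter vector to (kappa, class proportions, per-class branch->omega
maps).  Optimization is bounded quasi-Newton (L-BFGS-B) from several
jittered starts, because the likelihood surfaces of the mixture models are
multimodal.  Branch lengths can optionally be optimized jointly; the
nested-test drivers re-optimize them under the null and hold them fixed
for the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from ..family_data import RootedGeneTree
from .alignment import CodonAlignment
from .likelihood import TreeIndex, compress_patterns, mixture_log_likelihood
from .models import (
    BACKGROUND,
    FOREGROUND,
    G_ROOT,
    BranchPartitionModel,
    BranchSiteModel,
    RateMatrixCache,
    SiteClassModel,
    codon_frequencies,
)

__all__ = [
    "FitResult",
    "FitError",
    "M8aSpec",
    "M8Spec",
    "BranchSpec",
    "BranchSiteSpec",
    "fit",
]

_KAPPA_BOUNDS = (0.05, 99.0)
_OMEGA_BOUNDS = (1e-4, 99.0)
_PROP_BOUNDS = (1e-6, 1.0 - 1e-6)
_SHAPE_BOUNDS = (5e-3, 99.0)
_OMEGA_POS_BOUNDS = (1.0, 99.0)  # omega constrained >= 1 (M8 omega_s, branch-site omega2)
_BLEN_BOUNDS = (1e-7, 25.0)


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    lnL: float
    parameters: dict
    n_params: int
    converged: bool
    n_restarts_used: int
    model_id: str
    pi: np.ndarray = field(repr=False, default=None)
    branch_lengths: Optional[np.ndarray] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not np.isfinite(self.lnL):
            raise FitError(f"non-finite maximized lnL for {self.model_id}")


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------

class ModelSpec:
    """Maps a free-parameter vector to a concrete mixture description."""

    model_id: str = ""
    names: tuple[str, ...] = ()

    def bounds(self) -> list[tuple[float, float]]:
        raise NotImplementedError

    def x0(self) -> np.ndarray:
        raise NotImplementedError

    def build(self, x: np.ndarray):
        """-> (kappa, props, class_maps)"""
        raise NotImplementedError

    def params_dict(self, x: np.ndarray) -> dict:
        return dict(zip(self.names, (float(v) for v in x)))

    def x_from_params(self, params: dict) -> np.ndarray:
        return np.array([params[n] for n in self.names], dtype=float)


class M8aSpec(ModelSpec):
    """Nearly neutral site mixture: beta(p, q) plus a class at omega = 1."""

    model_id = "M8a"
    names = ("kappa", "p0", "p_beta", "q_beta")

    def __init__(self, K: int = 10):
        self.K = K

    def bounds(self):
        return [_KAPPA_BOUNDS, _PROP_BOUNDS, _SHAPE_BOUNDS, _SHAPE_BOUNDS]

    def x0(self):
        return np.array([2.0, 0.9, 0.5, 1.5])

    def build(self, x):
        kappa, p0, p, q = x
        model = SiteClassModel("M8a", p0=p0, p_beta=p, q_beta=q, K=self.K)
        props, maps = model.classes()
        return kappa, props, maps


class M8Spec(M8aSpec):
    """Positive-selection site mixture: beta(p, q) plus a class at omega_s >= 1."""

    model_id = "M8"
    names = ("kappa", "p0", "p_beta", "q_beta", "omega_s")

    def bounds(self):
        return super().bounds() + [_OMEGA_POS_BOUNDS]

    def x0(self):
        return np.array([2.0, 0.9, 0.5, 1.5, 2.0])

    def build(self, x):
        kappa, p0, p, q, ws = x
        model = SiteClassModel("M8", p0=p0, p_beta=p, q_beta=q, omega_s=ws, K=self.K)
        props, maps = model.classes()
        return kappa, props, maps


class BranchSpec(ModelSpec):
    """One omega per branch partition (single site class).

    ``partitions`` lists the labels receiving their own omega; branches of
    the tree carrying other labels are treated as background.
    """

    def __init__(self, partitions: Sequence[str] = (BACKGROUND,)):
        self.partitions = tuple(partitions)
        if BACKGROUND not in self.partitions:
            raise ValueError("partitions must include the background label")
        self.model_id = "branch(" + ",".join(self.partitions) + ")"
        self.names = ("kappa",) + tuple(f"omega_{lab}" for lab in self.partitions)

    def bounds(self):
        return [_KAPPA_BOUNDS] + [_OMEGA_BOUNDS] * len(self.partitions)

    def x0(self):
        return np.array([2.0] + [0.2] * len(self.partitions))

    def build(self, x):
        kappa = x[0]
        model = BranchPartitionModel(dict(zip(self.partitions, x[1:])))
        props, maps = model.classes()
        return kappa, props, maps


class BranchSiteSpec(ModelSpec):
    """Branch-site model A (``null=True`` fixes the foreground omega2 at 1).

    Proportions are optimized as (ptot, f) with p0 = ptot*f, p1 = ptot*(1-f)
    so the triangle constraint p0 + p1 <= 1 maps to box bounds.
    """

    def __init__(self, null: bool = False):
        self.null = null
        self.model_id = "branch-site-A0" if null else "branch-site-A"
        base = ("kappa", "ptot", "f", "omega0")
        self.names = base if null else base + ("omega2",)

    def bounds(self):
        b = [_KAPPA_BOUNDS, _PROP_BOUNDS, _PROP_BOUNDS, (1e-4, 1.0 - 1e-6)]
        if not self.null:
            b.append(_OMEGA_POS_BOUNDS)
        return b

    def x0(self):
        base = [2.0, 0.85, 0.8, 0.15]
        return np.array(base if self.null else base + [2.0])

    def build(self, x):
        kappa, ptot, f, w0 = x[:4]
        w2 = 1.0 if self.null else x[4]
        model = BranchSiteModel(
            p0=ptot * f, p1=ptot * (1.0 - f), omega0=w0, omega2=w2, null=self.null
        )
        props, maps = model.classes()
        return kappa, props, maps

    def params_dict(self, x):
        d = super().params_dict(x)
        d["p0"] = d["ptot"] * d["f"]
        d["p1"] = d["ptot"] * (1.0 - d["f"])
        d["p2"] = 1.0 - d["p0"] - d["p1"]
        if self.null:
            d["omega2"] = 1.0
        return d


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

def fit(
    aln: CodonAlignment,
    tree: RootedGeneTree,
    spec: ModelSpec,
    n_restarts: int = 3,
    seed: int = 0,
    optimize_branch_lengths: bool = False,
    freq_model: str = "F3x4",
    pi: Optional[np.ndarray] = None,
    labels: Optional[Sequence[str]] = None,
    warm_start: Optional[dict] = None,
    maxiter: int = 200,
) -> FitResult:
    """Maximize the log-likelihood of ``spec`` on (alignment, tree).

    ``labels`` overrides the per-node branch partition labels (post-order,
    as produced by :class:`TreeIndex`); ``warm_start`` seeds the first
    restart from a previous fit's parameter dict.
    """
    ti = TreeIndex(tree, aln)
    patterns, counts, _ = compress_patterns(aln)
    if pi is None:
        pi = codon_frequencies(aln.codons, freq_model)
    cache = RateMatrixCache(pi)
    labels = list(labels) if labels is not None else list(ti.labels)

    bounds = spec.bounds()
    n_model = len(bounds)
    lengths0 = ti.lengths.copy()
    free_branches = [i for i in range(ti.n_nodes) if i != ti.root_index]
    if optimize_branch_lengths:
        bounds = bounds + [_BLEN_BOUNDS] * len(free_branches)

    def neg_lnL(x: np.ndarray) -> float:
        if optimize_branch_lengths:
            ti.lengths[free_branches] = x[n_model:]
        kappa, props, maps = spec.build(x[:n_model])
        try:
            ll = mixture_log_likelihood(
                ti, patterns, counts, pi, kappa, props, maps, cache=cache, labels=labels
            )
        except FloatingPointError:
            return 1e12
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    failures = []
    for r in range(max(1, n_restarts)):
        x0 = spec.x0().copy()
        if r == 0 and warm_start is not None:
            try:
                x0 = spec.x_from_params(warm_start)
            except KeyError:
                pass
        elif r > 0:
            lo = np.array([b[0] for b in spec.bounds()])
            hi = np.array([b[1] for b in spec.bounds()])
            jitter = np.exp(rng.normal(0.0, 0.5, size=x0.size))
            x0 = np.clip(x0 * jitter, lo, hi)
        if optimize_branch_lengths:
            x0 = np.concatenate([x0, np.clip(lengths0[free_branches], *_BLEN_BOUNDS)])
        try:
            res = minimize(
                neg_lnL,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError("all restarts failed: " + "; ".join(failures))

    if optimize_branch_lengths:
        ti.lengths[free_branches] = best.x[n_model:]
        fitted_lengths = ti.lengths.copy()
    else:
        ti.lengths[:] = lengths0
        fitted_lengths = None

    params = spec.params_dict(best.x[:n_model])
    n_params = n_model + (len(free_branches) if optimize_branch_lengths else 0)
    return FitResult(
        lnL=-float(best.fun),
        parameters=params,
        n_params=n_params,
        converged=bool(best.success),
        n_restarts_used=max(1, n_restarts),
        model_id=spec.model_id,
        pi=pi,
        branch_lengths=fitted_lengths,
    )
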