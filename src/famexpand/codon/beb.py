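"""Bayes empirical Bayes identification of positively selected codons.

After a significant branch-site test, each codon's posterior probability of
belonging to the foreground-positive classes (2a/2b, omega2 > 1 on the
tested branch) is computed by integrating over a uniform prior grid on
(p0, p1, omega0, omega2) centred on the unit hypercube rather than plugging
in the MLE alone — the "empirical Bayes" part keeps kappa, frequencies and
branch lengths at their estimates while averaging over the mixture
parameters, which are the poorly determined ones.  Sites with posterior
above 0.95 are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from ..family_data import FamilyDataError, RootedGeneTree
from .alignment import CodonAlignment
from .fit import FitResult
from .likelihood import TreeIndex, _class_site_logliks, compress_patterns
from .models import BACKGROUND, FOREGROUND, RateMatrixCache

__all__ = ["BEBResult", "beb"]

FLAG_THRESHOLD = 0.95


@dataclass
class BEBResult:
    """Per-codon posterior probabilities of positive selection."""

    site_posteriors: np.ndarray  # (n_codons,) P(class 2a/2b | data)
    flagged: list[int]  # 0-based alignment columns with posterior > 0.95
    column_map: Optional[np.ndarray] = field(default=None, repr=False)

    def flagged_positions(self, one_based: bool = True) -> list[int]:
        """Flagged sites in original coordinates (via the cleaning map)."""
        off = 1 if one_based else 0
        if self.column_map is None:
            return [s + off for s in self.flagged]
        return [int(self.column_map[s]) + off for s in self.flagged]


def beb(
    aln: CodonAlignment,
    tree: RootedGeneTree,
    fit_alt: FitResult,
    labels: Optional[Sequence[str]] = None,
    grid_size: int = 10,
    omega2_max: float = 11.0,
    column_map: Optional[np.ndarray] = None,
) -> BEBResult:
    """BEB site posteriors under a fitted branch-site alternative model.

    ``fit_alt`` must come from the branch-site model A fit (it supplies
    kappa, frequencies and, when optimized, branch lengths).  ``labels``
    are the post-order branch partition labels used in that fit.
    """
    if "omega2" not in fit_alt.parameters:
        raise ValueError("beb requires a fitted branch-site alternative model")
    kappa = fit_alt.parameters["kappa"]
    pi = fit_alt.pi
    ti = TreeIndex(tree, aln)
    if fit_alt.branch_lengths is not None:
        ti.lengths[:] = fit_alt.branch_lengths
    labels = list(labels) if labels is not None else list(ti.labels)
    labels = [FOREGROUND if lab == FOREGROUND else BACKGROUND for lab in labels]
    patterns, counts, inverse = compress_patterns(aln)
    cache = RateMatrixCache(pi)
    n = grid_size

    mids = (np.arange(n) + 0.5) / n
    w0_grid = mids  # omega0 in (0, 1)
    w2_grid = 1.0 + mids * (omega2_max - 1.0)  # omega2 in (1, omega2_max)
    # proportion grid over the simplex via (p0, f) with p1 = (1-p0)·f —
    # unlike a raw (p0, p1) grid this reaches p2 near 0, which keeps the
    # prior from forcing positive-class mass onto null-like data
    props_grid = [
        (p0, (1.0 - p0) * f)
        for p0 in mids
        for f in mids
    ]
    if not props_grid:
        raise FamilyDataError("empty proportion grid")

    # mixture-average rate scaling is held at the MLE mixture so branch
    # lengths keep their fitted meaning across grid points
    mle_props, mle_maps = _mle_classes(fit_alt)
    scale_map = {
        lab: float(sum(p * cache.rate(kappa, m[lab]) for p, m in zip(mle_props, mle_maps)))
        for lab in (BACKGROUND, FOREGROUND)
    }

    def class_ll(omega_map):
        return _class_site_logliks(ti, patterns, pi, cache, kappa, omega_map, scale_map, labels)

    npat = patterns.shape[1]
    ll_class1 = class_ll({BACKGROUND: 1.0, FOREGROUND: 1.0})
    ll_class0 = np.empty((n, npat))
    ll_class2b = np.empty((n, npat))
    for a, w0 in enumerate(w0_grid):
        ll_class0[a] = class_ll({BACKGROUND: w0, FOREGROUND: w0})
    for b, w2 in enumerate(w2_grid):
        ll_class2b[b] = class_ll({BACKGROUND: 1.0, FOREGROUND: w2})
    ll_class2a = np.empty((n, n, npat))
    for a, w0 in enumerate(w0_grid):
        for b, w2 in enumerate(w2_grid):
            ll_class2a[a, b] = class_ll({BACKGROUND: w0, FOREGROUND: w2})

    grid_loglik = []  # total data log-likelihood per grid point
    grid_post2 = []  # per-pattern posterior of classes 2a+2b per grid point
    for p0, p1 in props_grid:
        p2 = 1.0 - p0 - p1
        p2a = p2 * p0 / (p0 + p1)
        p2b = p2 * p1 / (p0 + p1)
        logw = np.log([p0, p1, p2a, p2b])
        for a in range(n):
            for b in range(n):
                stacked = np.stack(
                    [ll_class0[a], ll_class1, ll_class2a[a, b], ll_class2b[b]]
                ) + logw[:, None]
                site_ll = logsumexp(stacked, axis=0)
                grid_loglik.append(float(site_ll @ counts))
                with np.errstate(invalid="ignore"):
                    post2 = np.exp(logsumexp(stacked[2:], axis=0) - site_ll)
                grid_post2.append(post2)

    grid_loglik = np.asarray(grid_loglik)
    if not np.isfinite(grid_loglik).any():
        raise FamilyDataError("all BEB grid cells have zero likelihood")
    logweights = grid_loglik - logsumexp(grid_loglik)  # uniform prior over cells
    weights = np.exp(logweights)
    pattern_post = weights @ np.vstack(grid_post2)
    site_post = np.clip(pattern_post[inverse], 0.0, 1.0)
    flagged = [int(s) for s in np.flatnonzero(site_post > FLAG_THRESHOLD)]
    return BEBResult(site_posteriors=site_post, flagged=flagged, column_map=column_map)


def _mle_classes(fit_alt: FitResult):
    from .models import BranchSiteModel

    p = fit_alt.parameters
    model = BranchSiteModel(
        p0=p["p0"], p1=max(p["p1"], 1e-9), omega0=p["omega0"],
        omega2=max(p["omega2"], 1.0), null=False,
    )
    return model.classes()
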