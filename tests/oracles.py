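"""Independent oracles for the likelihood engine.

The brute-force oracle sums the joint probability over ALL internal-node
state assignments with transition matrices from scipy's generic matrix
exponential — no pruning, no eigendecomposition shortcuts — so it is an
independent check of the pruning engine on tiny instances.
"""

import itertools

import numpy as np
from scipy.linalg import expm

from famexpand.codon.models import BACKGROUND, _unscaled_rate_matrix, mean_rate


def brute_force_loglik(tree, aln, kappa, pi, props, class_maps, labels_of=None):
    """Enumerate internal states; mixture over site classes.

    ``labels_of``: optional map node-object -> partition label (default all
    background).  Missing leaf states (-1) are marginalized by enumeration.
    Matches the engine's scaling: per partition, matrices share the
    partition's mixture-average rate.
    """
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    row = {t: i for i, t in enumerate(aln.taxa)}

    def label(node):
        return labels_of(node) if labels_of else BACKGROUND

    used = {label(n) for n in nodes if n.parent is not None}
    scale = {
        lab: sum(
            p * mean_rate(_unscaled_rate_matrix(kappa, m[lab], pi), pi)
            for p, m in zip(props, class_maps)
        )
        for lab in used
    }

    # per class, per node: P matrix for the branch above the node
    P_of = []
    for m in class_maps:
        P_of.append(
            {
                id(n): expm(
                    _unscaled_rate_matrix(kappa, m[label(n)], pi)
                    * (n.length / scale[label(n)])
                )
                for n in nodes
                if n.parent is not None
            }
        )

    total = 0.0
    for site in range(aln.n_codons):
        site_l = 0.0
        for k, m in enumerate(class_maps):
            P = P_of[k]
            lik = 0.0
            # enumerate states of internal nodes and of missing leaves
            free = list(internal) + [
                lf for lf in leaves if aln.codons[row[lf.label], site] < 0
            ]
            for states in itertools.product(range(61), repeat=len(free)):
                assign = {id(n): s for n, s in zip(free, states)}
                for lf in leaves:
                    s = aln.codons[row[lf.label], site]
                    if s >= 0:
                        assign[id(lf)] = int(s)
                p = pi[assign[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    p *= P[id(n)][assign[id(n.parent)], assign[id(n)]]
                lik += p
            site_l += props[k] * lik
        total += np.log(site_l)
    return total
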