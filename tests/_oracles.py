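"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's pruning/likelihood code paths:
likelihoods are computed by exhaustive enumeration of ancestral states,
translation goes through Biopython, and rank statistics are evaluated
from their textbook formulas.
"""

import numpy as np
from Bio.Seq import Seq


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_force_two_taxon(pi, P1, P2, states1, states2) -> float:
    """Sum over the single ancestral state of a two-leaf tree."""
    total = 0.0
    for a, b in zip(states1, states2):
        total += np.log(sum(pi[r] * P1[r, a] * P2[r, b] for r in range(len(pi))))
    return total


def brute_force_three_taxon_mixture(pi, class_probs, class_Ps, states) -> float:
    """Exhaustive enumeration over both internal nodes of ((A,B),C).

    ``class_Ps[k]`` is a tuple (P_AB_stem, P_A, P_B, P_C) of transition
    matrices for site class k; ``states`` is a (3, n_sites) int array.
    """
    n_states = len(pi)
    total = 0.0
    for site in range(states.shape[1]):
        a, b, c = states[:, site]
        site_lik = 0.0
        for k, prob in enumerate(class_probs):
            P_stem, P_A, P_B, P_C = class_Ps[k]
            lik = 0.0
            for root in range(n_states):
                for inner in range(n_states):
                    lik += (
                        pi[root]
                        * P_stem[root, inner]
                        * P_A[inner, a]
                        * P_B[inner, b]
                        * P_C[root, c]
                    )
            site_lik += prob * lik
        total += np.log(site_lik)
    return total


def brute_force_dn_ds(sense_codons, pi, kappa, omega, tree_length):
    """dn/ds decomposition by explicit enumeration of all codon pairs."""

    def rate(ci, cj, w):
        diffs = [(x, y) for x, y in zip(ci, cj) if x != y]
        if len(diffs) != 1:
            return 0.0, False
        transition = frozenset(diffs[0]) in ({frozenset("AG"), frozenset("CT")})
        nonsyn = translate(ci) != translate(cj)
        q = pi[sense_codons.index(cj)]
        if transition:
            q *= kappa
        if nonsyn:
            q *= w
        return q, nonsyn

    def flows(w):
        flow_n = flow_total = 0.0
        for i, ci in enumerate(sense_codons):
            for cj in sense_codons:
                if ci == cj:
                    continue
                q, nonsyn = rate(ci, cj, w)
                flow_total += pi[i] * q
                if nonsyn:
                    flow_n += pi[i] * q
        return flow_n / flow_total, 1.0 - flow_n / flow_total

    rho_n, rho_s = flows(omega)
    p_n, p_s = flows(1.0)
    return tree_length * rho_n / (3 * p_n), tree_length * rho_s / (3 * p_s)


def midrank(values):
    """Textbook mid-ranks."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_midrank(x, y) -> float:
    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def partial_corr_recursive(r_xy, r_xz, r_yz) -> float:
    """First-order partial correlation from the recursion formula."""
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
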