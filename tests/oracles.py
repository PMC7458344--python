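"""From-scratch brute-force oracles, independent of the implementation paths
they are used to check."""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import t as t_dist


def average_ranks(x):
    """Average ranks computed by explicit sorting and tie grouping."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson_by_hand(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def spearman_by_hand(x, y):
    """Rank correlation: Pearson of average ranks."""
    return pearson_by_hand(average_ranks(x), average_ranks(y))


def pooled_t_by_hand(a, b):
    """Two-sided pooled two-sample t-test from first principles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * t_dist.sf(abs(t), df=na + nb - 2)
    return float(t), float(p)


def km_by_hand(times, events):
    """Product-limit estimate as {event_time: survival just after it}."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    surv = 1.0
    out = {}
    for t in sorted(set(times[events])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        surv *= 1.0 - d / at_risk
        out[t] = surv
    return out


def logrank_by_hand(times, events, groups):
    """Observed-minus-expected log-rank with hypergeometric variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = sorted(set(groups), key=str)
    a = groups == labels[0]
    O = E = V = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        N = int(at_risk.sum())
        nA = int((at_risk & a).sum())
        d = int(((times == t) & events).sum())
        dA = int(((times == t) & events & a).sum())
        O += dA
        E += d * nA / N
        if N > 1:
            V += d * (nA / N) * (1 - nA / N) * (N - d) / (N - 1)
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(chi2_dist.sf(chi2, df=1))


def rank1_complete(matrix):
    """Complete a rank-1 matrix with one missing entry by outer-product
    reconstruction from any fully observed row and column."""
    M = np.asarray(matrix, dtype=float)
    (r, c) = np.argwhere(np.isnan(M))[0]
    r2 = next(i for i in range(M.shape[0]) if i != r)
    c2 = next(j for j in range(M.shape[1]) if j != c)
    return M[r, c2] * M[r2, c] / M[r2, c2]


def agglomerate_by_hand(D, linkage):
    """Naive agglomerative clustering over a square distance matrix.

    Returns the merge sequence as a list of (frozenset_a, frozenset_b,
    height) with lowest-index-pair tie-breaking.  ``linkage`` is
    ``complete`` or ``average`` over the base pairwise distances.
    """
    D = np.asarray(D, dtype=float)
    clusters = [frozenset([i]) for i in range(len(D))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            pairs = [D[a, b] for a in clusters[i] for b in clusters[j]]
            d = max(pairs) if linkage == "complete" else float(np.mean(pairs))
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
    return merges


def scipy_linkage_merges(Z, n):
    """Convert a scipy linkage matrix to the same merge-sequence form."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (a, b, h, _) in enumerate(Z):
        fa, fb = members[int(a)], members[int(b)]
        merges.append((fa, fb, float(h)))
        members[n + row_idx] = fa | fb
    return merges


def enumeration_p(rhos, observed_rho):
    """Add-one rank p of the observed value within an enumerated null."""
    exceed = sum(1 for r in rhos if not np.isnan(r) and r >= observed_rho)
    return (1 + exceed) / (len(rhos) + 1)
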