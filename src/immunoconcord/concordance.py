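"""Concordance between deconvolution composites and quantitative IHC.

The central question is whether the composite built from the *true*
marker-to-cell-type mapping correlates with the matched IHC density better
than composites built from random cell-type assignments of the same size.
Significance is assessed empirically: random constituent sets are drawn from
the method's full cell-type catalog (cardinality preserved), the composite
is rebuilt, and the Spearman correlation recomputed; the add-one empirical
p-value locates the observed correlation within that null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composites import CompositeMapping, build_composites
from .io import DeconvolutionResult, GeneSetCollection


@dataclass
class PermutationReport:
    """Result of the random-reassignment significance procedure."""

    marker: str
    observed_rho: float
    permuted_rhos: list[float]
    n_perm: int
    empirical_p: float
    seed: int
    n_pairs: int

    def __post_init__(self) -> None:
        assert len(self.permuted_rhos) == self.n_perm
        assert 0.0 < self.empirical_p <= 1.0


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value in either vector are dropped.  Returns
    ``(rho, n_complete_pairs)``.  Fewer than 3 complete pairs is an error;
    zero variance in either rank vector yields ``rho = nan`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    keep = ~(np.isnan(x) | np.isnan(y))
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    xv, yv = x[keep], y[keep]
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        warnings.warn("zero variance in a rank vector; Spearman rho undefined", RuntimeWarning, stacklevel=2)
        return float("nan"), n
    rho = stats.spearmanr(xv, yv).statistic
    return float(rho), n


def pearson_matrix(table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix over a variables x samples table.

    Uses pairwise deletion of missing values; variable pairs with fewer than
    ``min_pairs`` complete observations, and constant variables, come back as
    missing.  The diagonal is 1 wherever defined.
    """
    corr = table.T.corr(method="pearson", min_periods=min_pairs)
    for v in corr.index:
        if table.loc[v].notna().sum() >= 1:
            if table.loc[v].nunique(dropna=True) <= 1:
                corr.loc[v, :] = np.nan
                corr.loc[:, v] = np.nan
            else:
                corr.loc[v, v] = 1.0
    return corr


def default_n_perm(catalog_size: int) -> int:
    """Default number of random cell-type reassignments.

    Mirrors the study design: 20 draws for a 22-type catalog and 100 for a
    64-type catalog (larger catalogs admit more distinct assignments).
    """
    return 100 if catalog_size > 22 else 20


def permutation_significance(
    decon: DeconvolutionResult,
    ihc_values: pd.Series,
    mapping: CompositeMapping,
    marker: str,
    n_perm: Optional[int] = None,
    seed: int = 0,
    rule: str = "sum",
    draws: Optional[Sequence[Sequence[str]]] = None,
) -> PermutationReport:
    """Empirical significance of composite-vs-IHC Spearman correlation.

    Each permutation draws, uniformly without replacement from the method's
    full cell-type catalog, a random constituent set with the same
    cardinality as the true set, rebuilds the composite under the same rule,
    and recomputes the Spearman correlation with the IHC densities.  The
    one-sided add-one empirical p-value is
    ``(1 + #{permuted rho >= observed rho}) / (n_perm + 1)``; large observed
    rho (concordance) is the alternative.  Draws may coincide with the true
    set by chance, and the three markers are permuted independently.
    Permuted composites with undefined rho (e.g. all-zero constituent draws)
    count as not exceeding the observed value.

    ``draws`` replaces the random draws with an explicit sequence of
    constituent sets (e.g. an exhaustive enumeration); ``n_perm`` and
    ``seed`` are then ignored for drawing.
    """
    constituents = mapping.constituents(marker)
    catalog = list(mapping.catalog)
    k = len(constituents)
    if k > len(catalog):
        raise ValueError(f"catalog size {len(catalog)} smaller than constituent count {k}")
    if draws is not None:
        draw_sets = [tuple(d) for d in draws]
        if any(len(d) != k for d in draw_sets):
            raise ValueError("every explicit draw must have the true set's cardinality")
        n_perm = len(draw_sets)
    else:
        if n_perm is None:
            n_perm = default_n_perm(len(catalog))
        draw_sets = None
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    samples = decon.scores.columns
    ihc = ihc_values.reindex(samples).astype(float)

    observed = build_composites(decon, mapping, rule=rule).values.loc[marker]
    observed_rho, n_pairs = spearman(observed.to_numpy(), ihc.to_numpy())

    rng = np.random.default_rng(seed)
    permuted: list[float] = []
    exceed = 0
    for i in range(n_perm):
        draw = draw_sets[i] if draw_sets is not None else tuple(rng.choice(catalog, size=k, replace=False))
        perm_map = CompositeMapping(mapping.method, {marker: draw}, mapping.catalog)
        perm_comp = build_composites(decon, perm_map, rule=rule).values.loc[marker]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rho, _ = spearman(perm_comp.to_numpy(), ihc.to_numpy())
        permuted.append(rho)
        if not np.isnan(rho) and rho >= observed_rho:
            exceed += 1
    empirical_p = (1 + exceed) / (n_perm + 1)
    return PermutationReport(
        marker=marker,
        observed_rho=observed_rho,
        permuted_rhos=permuted,
        n_perm=n_perm,
        empirical_p=empirical_p,
        seed=seed,
        n_pairs=n_pairs,
    )


def percent_match(sets: GeneSetCollection, metric: str = "row_fraction") -> pd.DataFrame:
    """Pairwise gene-overlap matrix between named gene sets, in percent.

    ``row_fraction`` (default): entry (A, B) = 100 * |A ∩ B| / |A| — the
    share of A's genes that also occur in B, referenced to the row set and
    hence asymmetric, with a 100% diagonal.  ``jaccard``: symmetric
    100 * |A ∩ B| / |A ∪ B|.
    """
    if metric not in ("row_fraction", "jaccard"):
        raise ValueError(f"unknown metric {metric!r}")
    names = sets.names
    if len(names) < 2:
        raise ValueError("need at least 2 gene sets")
    out = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        for b in names:
            inter = len(sets[a] & sets[b])
            denom = len(sets[a]) if metric == "row_fraction" else len(sets[a] | sets[b])
            out.loc[a, b] = 100.0 * inter / denom
    return out
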