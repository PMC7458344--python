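"""T-cell-infiltration gene-signature discovery and enrichment classification.

Discovery: patients are classed HI when both CD3 and CD8 IHC densities are
above their cutoffs (75th percentile and median by default) and LOW when
both are below; everyone else is excluded.  A per-gene two-sample t-test on
log-scale expression between the HI and LOW classes, with a stringent
unadjusted threshold (p < 0.001), defines the signature.

Validation: in an independent cohort each sample is z-scored per gene
against a reference distribution and called signature-enriched when at
least one signature gene reaches the over-expression threshold (z >= 2 by
default); enriched vs not-enriched groups can then be compared by survival.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .cluster import ClusterSpec, hcluster
from .concordance import pearson_matrix
from .io import ExpressionMatrix, IHCRecord, ihc_frame
from .survival import StratificationRule, stratify

logger = logging.getLogger(__name__)

DEFAULT_CD3_RULE = StratificationRule("cd3", "percentile", q=75)
DEFAULT_CD8_RULE = StratificationRule("cd8", "median")


def assign_classes(
    ihc: Sequence[IHCRecord],
    cd3_rule: StratificationRule = DEFAULT_CD3_RULE,
    cd8_rule: StratificationRule = DEFAULT_CD8_RULE,
) -> pd.Series:
    """HI / LOW / excluded class per patient from the two T-cell stains.

    HI requires both CD3 and CD8 above their cutoffs, LOW both below;
    discordant patients and patients missing either density are excluded.
    """
    table = ihc_frame(ihc)
    cd3 = stratify(table["cd3"], cd3_rule)
    cd8 = stratify(table["cd8"], cd8_rule)
    labels = pd.Series("excluded", index=table.index, dtype=object)
    labels[(cd3 == "high") & (cd8 == "high")] = "HI"
    labels[(cd3 == "low") & (cd8 == "low")] = "LOW"
    n_missing = int((cd3.isna() | cd8.isna()).sum())
    if n_missing:
        logger.info("%d patients excluded for missing CD3/CD8 density", n_missing)
    labels.name = "class"
    return labels


@dataclass
class GeneSignature:
    """Per-gene HI-vs-LOW comparison results and the selection they imply."""

    table: pd.DataFrame  # columns: mean_hi, mean_low, mean_diff, t, p, direction, selected
    alpha: float
    variant: str
    n_hi: int
    n_low: int

    @property
    def selected_genes(self) -> list[str]:
        sel = self.table[self.table["selected"]]
        return list(sel.sort_values("p").index)


def ttest_per_gene(
    expr: ExpressionMatrix,
    labels: pd.Series,
    variant: str = "pooled",
    alpha: float = 0.001,
) -> GeneSignature:
    """Two-sided per-gene t-test of HI vs LOW classes on log-scale values.

    ``variant`` is ``pooled`` (equal-variance, the default) or ``welch``.
    P-values are unadjusted — the stringent alpha is the false-positive
    control.  A gene whose values have zero variance within both classes
    gets a missing p-value and is never selected.  Direction follows the
    sign of the HI minus LOW mean difference.
    """
    if expr.transform == "tpm":
        raise ValueError("ttest_per_gene expects log-scale expression; apply log_transform first")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    labels = labels.reindex(expr.samples)
    hi_samples = labels.index[labels == "HI"]
    low_samples = labels.index[labels == "LOW"]
    if len(hi_samples) < 2 or len(low_samples) < 2:
        raise ValueError(f"need >= 2 patients per class, have HI={len(hi_samples)} LOW={len(low_samples)}")
    hi = expr.values[hi_samples].to_numpy(dtype=float)
    low = expr.values[low_samples].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(hi, low, axis=1, equal_var=(variant == "pooled"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (hi.std(axis=1) == 0) & (low.std(axis=1) == 0)
    if degenerate.any():
        logger.info("%d genes with zero variance in both classes; p set missing", int(degenerate.sum()))
        t[degenerate] = np.nan
        p[degenerate] = np.nan
    mean_hi = hi.mean(axis=1)
    mean_low = low.mean(axis=1)
    diff = mean_hi - mean_low
    table = pd.DataFrame(
        {
            "mean_hi": mean_hi,
            "mean_low": mean_low,
            "mean_diff": diff,
            "t": t,
            "p": p,
            "direction": np.where(diff >= 0, "up_in_HI", "up_in_LOW"),
            "selected": (p < alpha) & ~np.isnan(p),
        },
        index=expr.genes,
    )
    return GeneSignature(table=table, alpha=alpha, variant=variant, n_hi=len(hi_samples), n_low=len(low_samples))


def select_signature(sig: GeneSignature, direction_filter: str = "both") -> list[str]:
    """Selected genes, filtered by direction, in ascending-p order."""
    if direction_filter not in ("up_in_HI", "up_in_LOW", "both"):
        raise ValueError(f"unknown direction filter {direction_filter!r}")
    tab = sig.table[sig.table["selected"]]
    if direction_filter != "both":
        tab = tab[tab["direction"] == direction_filter]
    genes = list(tab.sort_values("p").index)
    if not genes:
        warnings.warn("signature selection is empty", RuntimeWarning, stacklevel=2)
    return genes


def zscore_vs_reference(
    expr: ExpressionMatrix,
    reference_samples: Optional[Sequence[str]] = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-gene z-scores against a reference sample distribution.

    When copy-number calls are unavailable the reference defaults to all
    samples (an explicit approximation of a diploid-reference convention).
    ``ddof=1`` gives the sample-sd convention; genes whose reference sd is
    zero get missing z-scores.
    """
    vals = expr.values
    ref = vals if reference_samples is None else vals[list(reference_samples)]
    if ref.shape[1] < 3:
        raise ValueError(f"reference needs >= 3 samples, have {ref.shape[1]}")
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=ddof)
    z = vals.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z


@dataclass
class EnrichmentCall:
    sample: str
    enriched: bool
    triggering_genes: dict[str, float] = field(default_factory=dict)


def classify_enriched(
    z: pd.DataFrame,
    signature_genes: Sequence[str],
    threshold: float = 2.0,
) -> list[EnrichmentCall]:
    """Call a sample signature-enriched when any signature gene has z >= threshold.

    Triggering genes and their z-scores are recorded per call.  Raising any
    signature gene's z can only flip not-enriched -> enriched (monotone).
    """
    present = [g for g in signature_genes if g in z.index]
    if not present:
        raise ValueError("no signature gene present in the z-score matrix")
    sub = z.loc[present]
    calls = []
    for sample in sub.columns:
        col = sub[sample]
        trig = col[col >= threshold].dropna()
        calls.append(EnrichmentCall(sample=str(sample), enriched=bool(len(trig)), triggering_genes=trig.to_dict()))
    return calls


class SignatureEnrichmentClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style wrapper: fit the per-gene reference distribution, then
    predict signature enrichment for new samples.

    Operates on genes x samples DataFrames.  ``rule='zscore'`` (default)
    calls a sample enriched when any signature gene is >= ``threshold``
    reference standard deviations above the reference mean; ``rule='log_ratio'``
    instead requires the log-scale expression to exceed the reference mean
    by ``threshold`` (an alternative reading of a "2 log fold" criterion).
    """

    def __init__(self, signature_genes: Sequence[str] = (), threshold: float = 2.0, rule: str = "zscore", ddof: int = 1):
        self.signature_genes = signature_genes
        self.threshold = threshold
        self.rule = rule
        self.ddof = ddof

    def fit(self, X: pd.DataFrame, y=None):
        if self.rule not in ("zscore", "log_ratio"):
            raise ValueError(f"unknown rule {self.rule!r}")
        genes = [g for g in self.signature_genes if g in X.index]
        if not genes:
            raise ValueError("no signature gene present in the reference matrix")
        if X.shape[1] < 3:
            raise ValueError("reference needs >= 3 samples")
        ref = X.loc[genes]
        self.genes_ = genes
        self.ref_mean_ = ref.mean(axis=1)
        self.ref_sd_ = ref.std(axis=1, ddof=self.ddof)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        sub = X.reindex(self.genes_)
        if self.rule == "zscore":
            stat = sub.sub(self.ref_mean_, axis=0).div(self.ref_sd_.replace(0.0, np.nan), axis=0)
        else:
            stat = sub.sub(self.ref_mean_, axis=0)
        return (stat.max(axis=0) - self.threshold).to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.decision_function(X) >= 0.0


def signature_infiltrate_correlation(
    expr: ExpressionMatrix,
    signature_genes: Sequence[str],
    infiltrates: pd.DataFrame,
    spec: Optional[ClusterSpec] = None,
):
    """Joint Pearson correlation matrix of signature-gene expression and
    cell-infiltrate scores over shared samples, with clustering.

    The correlation matrix spans #signature genes + #infiltrate types rows;
    it is clustered (Manhattan distance, average linkage by default, the
    published heatmap convention) to gather co-regulated genes and cell
    types.  Returns ``(correlation matrix, linkage matrix, leaf order)``.
    """
    genes = [g for g in signature_genes if g in expr.genes]
    if not genes:
        raise ValueError("no signature gene present in the expression matrix")
    shared = [s for s in expr.samples if s in infiltrates.columns]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, have {len(shared)}")
    block = pd.concat([expr.values.loc[genes, shared], infiltrates[shared]], axis=0)
    corr = pearson_matrix(block)
    if spec is None:
        spec = ClusterSpec(distance="manhattan", linkage="average", row_scaling="none")
    clean = corr.dropna(axis=0, how="all").dropna(axis=1, how="all").fillna(0.0)
    Z, _ = hcluster(clean, spec)
    from scipy.cluster import hierarchy

    order = [clean.index[i] for i in hierarchy.leaves_list(Z)]
    return corr, Z, order
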