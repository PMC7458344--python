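"""Cutoff stratification, Kaplan-Meier estimation and log-rank comparisons.

High/low groups are defined by a cutoff statistic of the stratifying
variable (median by default; an arbitrary percentile otherwise), with
*strictly greater than the cutoff* defining "high" so ties are unambiguous.
Kaplan-Meier curves and the log-rank test are computed with lifelines
(product-limit estimator; hypergeometric-variance log-rank with tie
correction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io import IHCRecord

logger = logging.getLogger(__name__)


@dataclass
class StratificationRule:
    """Cutoff rule for dichotomizing a per-patient variable.

    ``kind`` is ``median`` or ``percentile`` with ``q`` in (0, 100);
    percentiles use linear interpolation between order statistics.  A value
    is labeled high iff it is strictly greater than the cutoff.
    """

    variable: str
    kind: str = "median"
    q: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("median", "percentile"):
            raise ValueError(f"unknown cutoff kind {self.kind!r}")
        if self.kind == "percentile":
            if self.q is None or not 0 < self.q < 100:
                raise ValueError("percentile rule needs q in (0, 100)")

    def cutoff(self, values: pd.Series) -> float:
        v = values.dropna().to_numpy(dtype=float)
        if self.kind == "median":
            return float(np.median(v))
        return float(np.percentile(v, self.q, method="linear"))

    @classmethod
    def parse(cls, variable: str, text: str) -> "StratificationRule":
        """Parse e.g. ``median`` or ``percentile75`` into a rule."""
        text = text.strip().lower()
        if text == "median":
            return cls(variable, "median")
        if text.startswith("percentile"):
            return cls(variable, "percentile", q=float(text[len("percentile"):]))
        raise ValueError(f"cannot parse cutoff spec {text!r}")


def stratify(values: pd.Series, rule: StratificationRule) -> pd.Series:
    """High/low labels for each patient under the rule's cutoff.

    Missing values yield missing labels.  If all values are identical the
    split is degenerate: everything is labeled low, with a warning.
    """
    v = values.astype(float)
    if v.notna().sum() < 2:
        raise ValueError("need >= 2 non-missing values to stratify")
    if v.dropna().nunique() == 1:
        warnings.warn(f"all {rule.variable} values identical; degenerate split (all low)", RuntimeWarning, stacklevel=2)
        out = pd.Series("low", index=v.index, dtype=object)
        out[v.isna()] = np.nan
        return out
    cut = rule.cutoff(v)
    out = pd.Series(np.where(v > cut, "high", "low"), index=v.index, dtype=object)
    out[v.isna()] = np.nan
    return out


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Product-limit survival estimate as a step table.

    Returns one row per distinct event/censoring time with the survival
    probability just after that time and the number at risk just before it.
    Censored times reduce the risk set without a downward step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("need >= 1 record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
        }
    )
    return out.reset_index(drop=True)


def logrank(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> tuple[float, float]:
    """Two-group log-rank test; returns ``(chi-square statistic, p-value)``.

    Uses the observed-minus-expected form with hypergeometric variance and
    tie correction (1 df).  Both groups must be non-empty and at least one
    event must be observed overall.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, have {list(labels)}")
    a, b = groups == labels[0], groups == labels[1]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("a group has zero members")
    if events.sum() == 0:
        raise ValueError("no events observed in either group")
    res = logrank_test(times[a], times[b], event_observed_A=events[a], event_observed_B=events[b])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class StratumComparison:
    primary_stratum: str
    n_high: int
    n_low: int
    chi2: Optional[float]
    p_value: Optional[float]
    skipped_reason: Optional[str] = None


def two_factor_survival(
    table: pd.DataFrame,
    primary_rule: StratificationRule,
    secondary_rule: StratificationRule,
) -> dict[str, StratumComparison]:
    """Secondary-variable survival effect within each primary stratum.

    ``table`` must carry columns for both stratifying variables plus
    ``time`` and ``event``.  Within each primary stratum (high, then low),
    secondary-high is compared to secondary-low by log-rank; strata with
    fewer than 2 patients, or with a constant secondary label, are skipped
    with a log entry.  Used e.g. to ask whether macrophage (CD68) infiltrate
    modulates the survival benefit of T-cell (CD3/CD8) infiltrate.
    """
    for col in (primary_rule.variable, secondary_rule.variable, "time", "event"):
        if col not in table.columns:
            raise KeyError(f"table lacks column {col!r}")
    primary = stratify(table[primary_rule.variable], primary_rule)
    secondary = stratify(table[secondary_rule.variable], secondary_rule)
    out: dict[str, StratumComparison] = {}
    for stratum in ("high", "low"):
        sel = (primary == stratum) & secondary.notna()
        sub = table[sel]
        sec = secondary[sel]
        n_high = int((sec == "high").sum())
        n_low = int((sec == "low").sum())
        key = f"{primary_rule.variable}_{stratum}"
        if len(sub) < 2:
            logger.info("stratum %s skipped: fewer than 2 patients", key)
            out[key] = StratumComparison(stratum, n_high, n_low, None, None, "fewer than 2 patients")
            continue
        if n_high == 0 or n_low == 0:
            logger.info("stratum %s skipped: secondary labels constant", key)
            out[key] = StratumComparison(stratum, n_high, n_low, None, None, "secondary labels constant")
            continue
        chi2, p = logrank(sub["time"], sub["event"].astype(bool), sec)
        out[key] = StratumComparison(stratum, n_high, n_low, chi2, p)
    return out


def survival_table(records: Sequence[IHCRecord]) -> pd.DataFrame:
    """IHC records as the tabular input two_factor_survival expects."""
    from .io import ihc_frame

    return ihc_frame(records)
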