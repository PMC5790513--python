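"""Association tests and the median-score comparator signature.

Chi-square tests compare signature status against categorical
clinico-molecular variables; the Welch t test compares continuous variables
between two groups. The median-score classifier reproduces the common
literature-signature recipe: score each tumor by the median expression of a
fixed gene panel and split the cohort at a quantile of the scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

SPLIT_QUANTILES = {"median": 0.5, "upper-quartile": 0.75, "lower-quartile": 0.25}


@dataclass
class ContingencyResult:
    """Pearson chi-square test on an r x c contingency table."""

    table: pd.DataFrame
    chi2: float
    df: int
    p: float
    proportions: pd.DataFrame  # row-normalized

    def summary(self) -> str:
        return (f"chi-square = {self.chi2:.3f}, df = {self.df}, "
                f"p = {self.p:.4g}")


def chi_square(table, yates: bool = False) -> ContingencyResult:
    """Pearson chi-square without continuity correction (``yates=True``
    enables the correction for 2x2 tables). Zero margins are rejected."""
    tab = pd.DataFrame(table)
    arr = tab.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=yates)
    if (expected <= 0).any():
        raise ValidationError("expected counts must all be positive")
    props = tab.div(tab.sum(axis=1), axis=0)
    return ContingencyResult(table=tab, chi2=float(chi2), df=int(df),
                             p=float(p), proportions=props)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch unequal-variance t test: returns ``(t, df, p)`` with
    Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        raise ValidationError("both groups constant and equal: t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class MedianScoreResult:
    """Panel-median signature scores with a quantile split."""

    scores: pd.Series
    labels: pd.Series
    threshold: float
    split_rule: str
    panel_used: list[str]
    panel_missing: list[str]

    def summary(self) -> str:
        n_high = int((self.labels == "high").sum())
        return (f"median-score signature ({len(self.panel_used)} genes, "
                f"{self.split_rule} split at {self.threshold:.3f}): "
                f"{n_high}/{len(self.labels)} high")


def median_score_classify(expr: pd.DataFrame, panel: list[str],
                          split_rule: str = "median") -> MedianScoreResult:
    """Score samples by the median expression of a gene panel and split at
    a cohort quantile.

    At least half of the panel must be present in ``expr``; missing genes
    are logged and dropped. Samples strictly above the threshold are labeled
    ``high``; ties at the threshold go to ``low``.
    """
    if split_rule not in SPLIT_QUANTILES:
        raise ValidationError(
            f"split_rule must be one of {sorted(SPLIT_QUANTILES)}"
        )
    panel = list(panel)
    present = [g for g in panel if g in expr.index]
    missing = [g for g in panel if g not in expr.index]
    if not present:
        raise ValidationError("no panel genes present in the cohort")
    if len(present) < len(panel) / 2:
        raise ValidationError(
            f"only {len(present)}/{len(panel)} panel genes present"
        )
    if missing:
        logger.warning("median-score panel: dropping %d absent genes: %s",
                       len(missing), missing)
    scores = expr.loc[present].median(axis=0)
    threshold = float(scores.quantile(SPLIT_QUANTILES[split_rule]))
    labels = pd.Series(np.where(scores > threshold, "high", "low"),
                       index=scores.index, name="label")
    return MedianScoreResult(scores=scores.rename("score"), labels=labels,
                             threshold=threshold, split_rule=split_rule,
                             panel_used=present, panel_missing=missing)
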