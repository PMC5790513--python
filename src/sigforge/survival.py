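"""Survival machinery: Kaplan-Meier, log-rank, Cox proportional hazards,
administrative censoring and combined two-signature stratification.

All analyses work on a *records* DataFrame with columns ``time_years``
(non-negative, in years) and ``event`` (1 = event observed, 0 = censored),
plus arbitrary covariate columns. The clinical endpoint this mirrors is
distant metastasis-free survival censored administratively at five years:
an event exactly at the horizon still counts as an event; censoring applies
strictly after it.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
Cox models use the statsmodels proportional-hazards backend, which supports
both Efron (default) and Breslow tie handling. Hazard ratios carry Wald
95% confidence intervals, ``exp(beta +/- 1.96 se)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .exceptions import EstimationError, ValidationError

#: absolute log-hazard beyond which a coefficient is treated as diverging
#: (monotone likelihood / empty stratum)
BETA_DIVERGED = 15.0


def censor_at(records: pd.DataFrame, horizon: float = 5.0) -> pd.DataFrame:
    """Administratively censor at ``horizon`` years.

    Times beyond the horizon are truncated to it and their events removed;
    an event exactly at the horizon is kept (censoring is strictly after).
    """
    if horizon <= 0:
        raise ValidationError("censoring horizon must be > 0")
    out = records.copy()
    late = out["time_years"] > horizon
    out.loc[late, "time_years"] = horizon
    out.loc[late, "event"] = 0
    return out


@dataclass
class KMEstimate:
    """Product-limit survival curve with its risk table."""

    survival: pd.DataFrame   # index time, column "S"
    risk_table: pd.DataFrame
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step-function lookup."""
        s = self.survival[self.survival.index <= t]
        return float(s["S"].iloc[-1]) if len(s) else 1.0


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Kaplan-Meier estimate; censorings at an event time are processed
    after the events at that time (standard product-limit convention)."""
    if len(records) == 0:
        raise ValidationError("Kaplan-Meier needs at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_years"], records["event"])
    surv = kmf.survival_function_.rename(columns={"KM_estimate": "S"})
    return KMEstimate(
        survival=surv,
        risk_table=kmf.event_table,
        n=len(records),
        n_events=int(records["event"].sum()),
    )


def logrank_test(records: pd.DataFrame,
                 group_labels: pd.Series | np.ndarray
                 ) -> tuple[float, int, float]:
    """K-sample log-rank test. Returns ``(chi2, df, p)`` with
    ``df = n_groups - 1``."""
    groups = pd.Series(np.asarray(group_labels), index=records.index)
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValidationError("log-rank requires >= 2 non-empty groups")
    res = multivariate_logrank_test(records["time_years"], groups,
                                    records["event"])
    return float(res.test_statistic), n_groups - 1, float(res.p_value)


@dataclass
class CoxResults:
    """Per-covariate hazard ratios with Wald CIs and p-values.

    ``frame`` columns: ``beta``, ``hr``, ``ci_low``, ``ci_high``, ``p``,
    ``estimable``. Non-estimable rows (empty strata / monotone likelihood)
    keep their label but carry NaN estimates.
    """

    frame: pd.DataFrame
    loglik: float
    n: int
    n_events: int
    n_excluded: int
    ties: str
    converged: bool
    reference_levels: dict[str, str] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Cox proportional hazards ({self.ties} ties)  "
            f"n={self.n}, events={self.n_events}, excluded={self.n_excluded}",
            f"{'covariate':<32}{'HR':>8}{'95% CI':>18}{'p':>12}",
        ]
        for name, row in self.frame.iterrows():
            if not row["estimable"]:
                lines.append(f"{name:<32}{'--':>8}{'(not estimable)':>18}{'--':>12}")
                continue
            ci = f"({row['ci_low']:.2f}-{row['ci_high']:.2f})"
            lines.append(
                f"{name:<32}{row['hr']:>8.2f}{ci:>18}{row['p']:>12.2g}"
            )
        return "\n".join(lines)


class CoxModel:
    """Cox proportional-hazards model over declared covariates.

    Parameters
    ----------
    records
        DataFrame with ``time_years``, ``event`` and covariate columns.
    covariates
        Column names to include. Non-numeric columns are expanded to
        indicators against a reference level.
    reference_levels
        Explicit reference level per categorical covariate; defaults to the
        most frequent level.
    ties
        ``"efron"`` (default) or ``"breslow"``.

    Rows with missing values in any used column are excluded (complete-case)
    and counted in ``n_excluded``.
    """

    def __init__(self, records: pd.DataFrame, covariates: list[str],
                 reference_levels: dict[str, str] | None = None,
                 ties: str = "efron") -> None:
        if ties not in ("efron", "breslow"):
            raise ValidationError("ties must be 'efron' or 'breslow'")
        missing_cols = [c for c in covariates if c not in records.columns]
        if missing_cols:
            raise ValidationError(f"covariates absent from records: {missing_cols}")
        self.records = records
        self.covariates = list(covariates)
        self.reference_levels = dict(reference_levels or {})
        self.ties = ties

    def _design(self) -> tuple[pd.DataFrame, pd.DataFrame, int]:
        used = ["time_years", "event"] + self.covariates
        data = self.records[used]
        complete = data.dropna()
        n_excluded = len(data) - len(complete)
        cols = {}
        for cov in self.covariates:
            col = complete[cov]
            if pd.api.types.is_numeric_dtype(col):
                cols[cov] = col.astype(float)
            else:
                levels = list(pd.unique(col))
                ref = self.reference_levels.get(cov)
                if ref is None:
                    ref = col.mode().iloc[0]
                elif ref not in levels:
                    raise ValidationError(
                        f"reference level {ref!r} absent from covariate {cov!r}"
                    )
                self.reference_levels[cov] = ref
                for lev in levels:
                    if lev == ref:
                        continue
                    cols[f"{cov}[{lev} vs {ref}]"] = (col == lev).astype(float)
        X = pd.DataFrame(cols, index=complete.index)
        return complete, X, n_excluded

    def fit(self) -> CoxResults:
        complete, X, n_excluded = self._design()
        if int(complete["event"].sum()) < 1:
            raise EstimationError("Cox model needs at least one event")
        # constant columns (empty strata) and binary indicators whose
        # positive group carries no events (monotone likelihood: the MLE
        # diverges) are non-estimable by design
        dropped: list[str] = []
        keep: list[str] = []
        events = complete["event"].to_numpy()
        for c in X.columns:
            col = X[c].to_numpy()
            if X[c].nunique() <= 1:
                dropped.append(c)
            elif set(np.unique(col)) <= {0.0, 1.0} and (
                    events[col == 1].sum() == 0 or events[col == 0].sum() == 0):
                dropped.append(c)
            else:
                keep.append(c)
        Xv = X[keep]
        if Xv.shape[1] == 0:
            raise EstimationError("no non-constant covariates to fit")
        rank = np.linalg.matrix_rank(np.column_stack(
            [np.ones(len(Xv)), Xv.to_numpy()]))
        if rank < Xv.shape[1] + 1:
            raise EstimationError("collinear covariates: design matrix rank-deficient")

        model = PHReg(complete["time_years"].to_numpy(),
                      Xv.to_numpy(),
                      status=complete["event"].to_numpy(),
                      ties=self.ties)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(maxiter=200)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(
                f"Cox partial-likelihood maximization failed: {exc}"
            ) from exc
        beta = np.asarray(fit.params, dtype=float)
        se = np.asarray(fit.bse, dtype=float)
        diverged = np.abs(beta) > BETA_DIVERGED

        z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        rows = {}
        for j, name in enumerate(keep):
            if diverged[j] or not np.isfinite(se[j]):
                rows[name] = dict(beta=np.nan, hr=np.nan, ci_low=np.nan,
                                  ci_high=np.nan, p=np.nan, estimable=False)
            else:
                rows[name] = dict(
                    beta=beta[j], hr=np.exp(beta[j]),
                    ci_low=np.exp(beta[j] - 1.96 * se[j]),
                    ci_high=np.exp(beta[j] + 1.96 * se[j]),
                    p=p[j], estimable=True,
                )
        for name in dropped:
            rows[name] = dict(beta=np.nan, hr=np.nan, ci_low=np.nan,
                              ci_high=np.nan, p=np.nan, estimable=False)
        frame = pd.DataFrame.from_dict(rows, orient="index")
        return CoxResults(
            frame=frame,
            loglik=float(model.loglike(beta)),
            n=len(complete),
            n_events=int(complete["event"].sum()),
            n_excluded=n_excluded,
            ties=self.ties,
            converged=bool(~diverged.any()),
            reference_levels=dict(self.reference_levels),
        )


def cox_fit(records: pd.DataFrame, covariates: list[str],
            reference_levels: dict[str, str] | None = None,
            ties: str = "efron") -> CoxResults:
    """Functional front end to :class:`CoxModel`."""
    return CoxModel(records, covariates, reference_levels, ties).fit()


@dataclass
class CombinedStratification:
    """Four-level stratification by two binary signatures.

    Stratum codes: first letter = hypoxia signature, second = second
    signature; ``LL`` (both low) is the reference.
    """

    strata: pd.Series
    cox: CoxResults
    logrank_chi2: float
    logrank_df: int
    logrank_p: float

    def summary(self) -> str:
        sizes = self.strata.value_counts().to_dict()
        return "\n".join([
            "Combined two-signature stratification (reference LL)",
            f"  stratum sizes: {sizes}",
            f"  log-rank: chi2={self.logrank_chi2:.2f} df={self.logrank_df} "
            f"p={self.logrank_p:.3g}",
            self.cox.summary(),
        ])


def plot_km(records: pd.DataFrame, group_labels: pd.Series, ax=None,
            title: str | None = None):
    """Kaplan-Meier curves per group with the log-rank p-value annotated.

    Returns the matplotlib axes. Groups are drawn in sorted label order.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    groups = pd.Series(np.asarray(group_labels), index=records.index)
    for level in sorted(groups.unique()):
        sub = records.loc[groups == level]
        kmf = KaplanMeierFitter(label=f"{level} (n={len(sub)})")
        kmf.fit(sub["time_years"], sub["event"])
        kmf.plot_survival_function(ax=ax)
    if groups.nunique() >= 2:
        chi2, _, p = logrank_test(records, groups)
        ax.text(0.02, 0.02, f"log-rank p = {p:.3g}", transform=ax.transAxes)
    ax.set_xlabel("years")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    return ax


def combine_signatures(records: pd.DataFrame, hypoxia_labels: pd.Series,
                       second_labels: pd.Series) -> CombinedStratification:
    """Cross the hypoxia and second signature labels into four strata and
    test them jointly (log-rank across the four groups; Cox with three
    indicators against the low/low reference).

    Empty strata are retained in the output with their coefficient flagged
    non-estimable.
    """
    idx = records.index
    if hypoxia_labels.loc[idx].isna().any() or second_labels.loc[idx].isna().any():
        raise ValidationError("both signature labels required for every sample")
    code = (hypoxia_labels.loc[idx].map({"low": "L", "high": "H"})
            + second_labels.loc[idx].map({"low": "L", "high": "H"}))
    if code.isna().any():
        raise ValidationError("signature labels must be 'low' or 'high'")
    strata = code.rename("stratum")

    aug = records.copy()
    aug["stratum"] = strata
    # indicator design against LL, keeping empty strata visible
    design = aug[["time_years", "event"]].copy()
    for s in ("LH", "HL", "HH"):
        design[f"stratum[{s} vs LL]"] = (strata == s).astype(float)
    cox = CoxModel(design,
                   [f"stratum[{s} vs LL]" for s in ("LH", "HL", "HH")]).fit()

    chi2, df, p = logrank_test(aug, strata)
    return CombinedStratification(
        strata=strata, cox=cox,
        logrank_chi2=chi2, logrank_df=df, logrank_p=p,
    )
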