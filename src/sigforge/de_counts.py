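"""Two-condition differential expression on gene-level counts.

The contract is the familiar count-based DE recipe: median-of-ratios size
factors, a per-gene negative-binomial dispersion, a log-link NB GLM with a
condition indicator fitted by IRLS at fixed dispersion, a Wald test on the
condition coefficient, Benjamini-Hochberg adjustment, and a fold-change gate.

Dispersion uses a within-condition method-of-moments estimate per gene,
guarded by the gene-vs-trend maximum rule (each gene's test dispersion is
the larger of its own estimate and a fitted mean-dispersion trend): with a
handful of replicates the raw gene-wise estimate alone is too noisy for a
calibrated test. The module promises the DE contract, not bit-compatibility
with any particular reference package.

The model/results pair follows the statsmodels idiom::

    res = NBDifferentialExpression(experiment).fit(q=0.05, fc_gate=1.0)
    res.frame            # per-gene table
    res.up_genes         # fdr < q and log2fc >= fc_gate
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import EstimationError, ValidationError
from .io import CountExperiment

ALPHA_FLOOR = 1e-8
MAX_IRLS_ITER = 50
IRLS_TOL = 1e-8


def size_factors(counts: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Median-of-ratios library-size factors, rescaled to geometric mean 1.

    For each gene positive in every sample, the ratio of each sample's count
    to the gene's geometric mean is formed; a sample's factor is the median
    of these ratios. Genes with a zero anywhere carry no size-factor
    information and are skipped.
    """
    is_frame = isinstance(counts, pd.DataFrame)
    arr = np.asarray(counts, dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise EstimationError(
            "no gene has positive counts in every sample; "
            "filter to expressed genes before estimating size factors"
        )
    pos = arr[all_pos]
    geomean = np.exp(np.mean(np.log(pos), axis=1))
    s = np.median(pos / geomean[:, None], axis=0)
    s = s / np.exp(np.mean(np.log(s)))
    if is_frame:
        return pd.Series(s, index=counts.columns, name="size_factor")
    return s


def estimate_dispersion(norm_counts: np.ndarray,
                        condition: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion by within-condition method of moments.

    Using the ``var = mu + alpha mu**2`` parameterization,
    ``alpha = (pooled within-condition variance - pooled mean) / mean**2``,
    floored at a small positive value. Requires replication in at least one
    condition.
    """
    norm_counts = np.asarray(norm_counts, dtype=float)
    condition = np.asarray(condition)
    levels = pd.unique(condition)
    dfs = []
    ss = np.zeros(norm_counts.shape[0])
    total_df = 0
    for lev in levels:
        cols = norm_counts[:, condition == lev]
        if cols.shape[1] >= 2:
            ss += cols.shape[1] * np.var(cols, axis=1)  # sum of squares about group mean
            total_df += cols.shape[1] - 1
    if total_df == 0:
        raise EstimationError(
            "dispersion needs >= 2 replicates in at least one condition"
        )
    pooled_var = ss / total_df
    pooled_mean = norm_counts.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(np.isfinite(alpha), alpha, ALPHA_FLOOR)
    return np.maximum(alpha, ALPHA_FLOOR)


def dispersion_trend(alpha_mom: np.ndarray, mean_norm: np.ndarray,
                     trim_sd: float = 3.0) -> np.ndarray:
    """Mean-dispersion trend ``alpha(mu) = a0 + a1 / mu`` fitted to the
    gene-wise method-of-moments estimates by lightly trimmed least squares.

    Gene-wise dispersion estimates from a handful of replicates are noisy
    enough that a test using them directly is badly anticonservative; the
    fitting path therefore uses the *maximum* of the gene-wise estimate and
    this fitted trend, the classical conservative sharing rule for
    count-based differential expression.
    """
    pos = (alpha_mom > 1e-6) & (mean_norm > 0)
    if pos.sum() < 10:
        # too few informative genes for a trend: fall back to the gene-wise
        # estimates alone
        return np.full_like(alpha_mom, ALPHA_FLOOR)
    X = np.column_stack([np.ones(int(pos.sum())), 1.0 / mean_norm[pos]])
    y = alpha_mom[pos]
    keep = np.ones(len(y), dtype=bool)
    coef = np.zeros(2)
    for _ in range(3):
        coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        resid = y - X @ coef
        keep = np.abs(resid) < trim_sd * np.std(resid[keep])
    fitted = coef[0] + coef[1] / np.maximum(mean_norm, 1e-8)
    return np.maximum(fitted, ALPHA_FLOOR)


def _irls_nb(y: np.ndarray, x: np.ndarray, offset: np.ndarray,
             alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                         np.ndarray]:
    """Vectorized per-gene IRLS for the NB GLM  log mu = offset + b0 + b1 x.

    Returns (b0, b1, se_b1, converged); all arrays are per gene. The
    dispersion enters only through the working weights mu / (1 + alpha mu).
    """
    g, n = y.shape
    # initialise intercept at the log mean of offset-corrected counts
    mean0 = np.maximum((y * np.exp(-offset)[None, :]).mean(axis=1), 1e-8)
    b0 = np.log(mean0)
    b1 = np.zeros(g)
    converged = np.zeros(g, dtype=bool)
    se_b1 = np.full(g, np.nan)
    active = np.ones(g, dtype=bool)
    sxx_last = np.full(g, np.nan)
    sw_last = np.full(g, np.nan)
    swx_last = np.full(g, np.nan)

    for _ in range(MAX_IRLS_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = offset[None, :] + b0[idx, None] + np.outer(b1[idx], x)
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[idx, None] * mu)
        z = (b0[idx, None] + np.outer(b1[idx], x)) + (y[idx] - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)
        swxx = (w * x[None, :] ** 2).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x[None, :] * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        b0_new = (swxx * swz - swx * swxz) / det
        b1_new = (sw * swxz - swx * swz) / det
        bad = ~np.isfinite(b0_new) | ~np.isfinite(b1_new)
        b0_new = np.where(bad, b0[idx], b0_new)
        b1_new = np.where(bad, b1[idx], b1_new)
        delta = np.maximum(np.abs(b0_new - b0[idx]), np.abs(b1_new - b1[idx]))
        b0[idx], b1[idx] = b0_new, b1_new
        sw_last[idx], swx_last[idx], sxx_last[idx] = sw, swx, swxx
        done = (delta < IRLS_TOL) & ~bad
        converged[idx[done]] = True
        active[idx[done]] = False

    det = sw_last * sxx_last - swx_last**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw_last / det
    se_b1 = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    return b0, b1, se_b1, converged


@dataclass
class DEResults:
    """Per-gene Wald-test table with BH adjustment and fold-change gates.

    ``frame`` columns: ``mean_norm_count``, ``dispersion``, ``log2fc``
    (hypoxia vs normoxia), ``p``, ``fdr``, ``flag`` in {up, down, ns}.
    """

    frame: pd.DataFrame
    q: float
    fc_gate: float
    size_factors: pd.Series
    n_unconverged: int

    @property
    def up_genes(self) -> pd.Index:
        return self.frame.index[self.frame["flag"] == "up"]

    @property
    def down_genes(self) -> pd.Index:
        return self.frame.index[self.frame["flag"] == "down"]

    def summary(self) -> str:
        n_tested = int(self.frame["p"].notna().sum())
        lines = [
            "Negative-binomial Wald differential expression",
            f"  genes tested:      {n_tested} of {len(self.frame)}",
            f"  up   (fdr<{self.q:g}, log2fc>=+{self.fc_gate:g}): {len(self.up_genes)}",
            f"  down (fdr<{self.q:g}, log2fc<=-{self.fc_gate:g}): {len(self.down_genes)}",
            f"  IRLS non-convergent genes: {self.n_unconverged}",
        ]
        return "\n".join(lines)


class NBDifferentialExpression:
    """NB Wald differential expression between the two conditions of a
    paired-condition count experiment.

    Parameters
    ----------
    experiment
        Count matrix plus sample sheet; the sheet's ``condition`` column must
        have exactly two levels. The contrast is the second level versus the
        first in ``reference`` order (default normoxia -> hypoxia).
    reference
        Condition treated as baseline of the log2 fold change.
    """

    def __init__(self, experiment: CountExperiment,
                 reference: str = "normoxia") -> None:
        self.experiment = experiment
        cond = experiment.condition
        levels = list(pd.unique(cond))
        if len(levels) != 2:
            raise ValidationError(
                f"exactly two conditions required, found {levels}"
            )
        if reference not in levels:
            raise ValidationError(f"reference condition {reference!r} absent")
        self.reference = reference
        self.treatment = next(l for l in levels if l != reference)
        self._x = (cond == self.treatment).to_numpy().astype(float)

    def fit(self, q: float = 0.05, fc_gate: float = 1.0) -> DEResults:
        """Run the full pipeline: size factors, dispersion, IRLS, Wald, BH.

        ``fc_gate`` is on the log2 scale (1.0 = two-fold). Genes with zero
        counts in every sample are excluded from testing and from the BH
        denominator. Genes whose IRLS fails to converge are flagged ``ns``
        with p = 1.
        """
        counts = self.experiment.counts
        y = counts.to_numpy(dtype=float)
        s = size_factors(counts)
        offset = np.log(s.to_numpy())
        norm = y / s.to_numpy()[None, :]
        alpha_mom = estimate_dispersion(norm,
                                        self.experiment.condition.to_numpy())
        trend = dispersion_trend(alpha_mom, norm.mean(axis=1))
        alpha = np.maximum(alpha_mom, trend)

        expressed = y.sum(axis=1) > 0
        g = y.shape[0]
        b1 = np.full(g, np.nan)
        se = np.full(g, np.nan)
        conv = np.zeros(g, dtype=bool)
        if expressed.any():
            _, b1_e, se_e, conv_e = _irls_nb(
                y[expressed], self._x, offset, alpha[expressed]
            )
            b1[expressed], se[expressed], conv[expressed] = b1_e, se_e, conv_e

        log2fc = b1 / np.log(2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = b1 / se
        p = np.full(g, np.nan)
        tested = expressed & np.isfinite(wald)
        p[tested] = 2.0 * stats.norm.sf(np.abs(wald[tested]))
        # non-convergent (or degenerate-SE) expressed genes: ns with p = 1
        failed = expressed & (~conv | ~np.isfinite(wald))
        p[failed] = 1.0
        log2fc[failed & ~np.isfinite(log2fc)] = 0.0

        fdr = np.full(g, np.nan)
        in_bh = expressed
        if in_bh.any():
            fdr[in_bh] = multipletests(p[in_bh], method="fdr_bh")[1]

        flag = np.full(g, "ns", dtype=object)
        with np.errstate(invalid="ignore"):
            flag[(fdr < q) & (log2fc >= fc_gate) & ~failed] = "up"
            flag[(fdr < q) & (log2fc <= -fc_gate) & ~failed] = "down"

        frame = pd.DataFrame(
            {
                "mean_norm_count": norm.mean(axis=1),
                "dispersion": alpha,
                "log2fc": log2fc,
                "p": p,
                "fdr": fdr,
                "flag": flag,
            },
            index=counts.index,
        )
        return DEResults(
            frame=frame, q=q, fc_gate=fc_gate, size_factors=s,
            n_unconverged=int((expressed & ~conv).sum()),
        )


def nb_wald_test(counts: pd.DataFrame, sample_sheet: pd.DataFrame,
                 q: float = 0.05, fc_gate: float = 1.0,
                 reference: str = "normoxia") -> DEResults:
    """Functional front end to :class:`NBDifferentialExpression`."""
    exp = CountExperiment(counts=counts, sample_sheet=sample_sheet)
    return NBDifferentialExpression(exp, reference=reference).fit(q=q, fc_gate=fc_gate)
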