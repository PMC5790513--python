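"""Nearest-shrunken-centroid signature derivation and classification.

The classifier standardizes each gene's class-centroid deviation,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),
    m_k = sqrt(1/n_k - 1/n),

soft-thresholds it by the shrinkage amount Delta,

    d'_ik = sign(d_ik) * max(|d_ik| - Delta, 0),

and classifies a new sample by the shrunken-centroid discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k,
    xbar'_ik = xbar_i + m_k * (s_i + s0) * d'_ik,

choosing the class with the smallest score. Genes with some nonzero
``d'_ik`` form the signature, so gene selection and classification happen
jointly; the shrinkage amount is chosen by stratified 10-fold cross
validation, taking the largest Delta attaining the minimum error count
(the sparsest signature among the optima).

Usage follows the model/results idiom::

    model = ShrunkenCentroid(expr_seed, labels)        # genes x samples
    res = model.fit(delta=None, seed=0)                # CV-chosen Delta
    print(res.summary())
    pred = res.classify(expr_new)                      # new cohort
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import ValidationError

CLASSES = ("high", "low")


def soft_threshold(d, delta: float):
    """sign(d) * max(|d| - delta, 0) for scalar or array ``d``."""
    if delta < 0:
        raise ValidationError("shrinkage amount must be >= 0")
    d = np.asarray(d, dtype=float)
    out = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    return out if out.ndim else float(out)


@dataclass
class CrossValidationReport:
    """Stratified K-fold threshold selection trace."""

    folds: pd.Series
    threshold_grid: np.ndarray
    errors: np.ndarray
    n_samples: int
    chosen_delta: float
    chosen_errors: int

    @property
    def accuracy(self) -> np.ndarray:
        return 1.0 - self.errors / self.n_samples

    @property
    def chosen_accuracy(self) -> float:
        """Cross-validation accuracy at the chosen threshold, in percent
        rounded to one decimal."""
        return round(100.0 * (1.0 - self.chosen_errors / self.n_samples), 1)

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({
            "delta": self.threshold_grid,
            "cv_errors": self.errors,
            "cv_accuracy": self.accuracy,
        })


@dataclass
class ShrunkenCentroidResults:
    """Fitted shrunken-centroid model: centroids, shrinkage statistics,
    selected signature genes and (optionally) the CV report."""

    gene_ids: pd.Index
    overall_centroid: np.ndarray          # per gene
    class_centroids: pd.DataFrame         # genes x classes
    pooled_sd: np.ndarray                 # per gene s_i
    s0: float
    m_k: pd.Series                        # per class
    prior: pd.Series                      # per class pi_k
    delta: float
    d_ik: pd.DataFrame                    # genes x classes, unshrunk
    d_shrunk: pd.DataFrame                # genes x classes, after thresholding
    cv_report: CrossValidationReport | None = None
    n_ties: int = 0

    @property
    def selected_genes(self) -> pd.Index:
        mask = (self.d_shrunk != 0).any(axis=1)
        return self.gene_ids[mask.to_numpy()]

    @property
    def shrunken_centroids(self) -> pd.DataFrame:
        """xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik."""
        out = {}
        for k in self.d_shrunk.columns:
            out[k] = (self.overall_centroid
                      + self.m_k[k] * (self.pooled_sd + self.s0)
                      * self.d_shrunk[k].to_numpy())
        return pd.DataFrame(out, index=self.gene_ids)

    def classify(self, expr_new: pd.DataFrame) -> pd.DataFrame:
        """Nearest-shrunken-centroid classification of new samples.

        ``expr_new`` is genes x samples and must contain every model gene;
        it should be preprocessed the same way as the training data (log2 +
        per-cohort gene-median centering). Ties in the discriminant go to
        ``high`` — hypoxia is flagged conservatively — and are recorded.
        """
        missing = self.gene_ids.difference(expr_new.index)
        if len(missing) > 0:
            raise ValidationError(f"new cohort missing model genes: {list(missing)}")
        X = expr_new.loc[self.gene_ids].to_numpy(dtype=float)  # genes x samples
        cent = self.shrunken_centroids
        denom = (self.pooled_sd + self.s0) ** 2
        scores = {}
        for k in cent.columns:
            diff = X - cent[k].to_numpy()[:, None]
            scores[k] = (diff**2 / denom[:, None]).sum(axis=0) \
                - 2.0 * np.log(self.prior[k])
        score_df = pd.DataFrame(scores, index=expr_new.columns)
        ties = score_df["high"].to_numpy() == score_df["low"].to_numpy()
        label = np.where(score_df["high"].to_numpy()
                         <= score_df["low"].to_numpy(), "high", "low")
        out = pd.DataFrame(
            {
                "label": label,
                "delta_high": score_df["high"],
                "delta_low": score_df["low"],
                "tie": ties,
            },
            index=expr_new.columns,
        )
        out.index.name = "sample_id"
        return out

    def summary(self) -> str:
        lines = [
            "Nearest shrunken centroid signature",
            f"  candidate genes: {len(self.gene_ids)}",
            f"  shrinkage Delta: {self.delta:.4f}",
            f"  signature genes: {len(self.selected_genes)}",
            f"  class priors: high={self.prior['high']:.3f} "
            f"low={self.prior['low']:.3f}   fudge s0={self.s0:.4f}",
        ]
        if self.cv_report is not None:
            lines.append(
                f"  10-fold CV accuracy at chosen Delta: "
                f"{self.cv_report.chosen_accuracy:.1f}"
            )
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str | None:
        payload = {
            "gene_ids": list(self.gene_ids),
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": {k: self.class_centroids[k].tolist()
                                for k in self.class_centroids.columns},
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "m_k": self.m_k.to_dict(),
            "prior": self.prior.to_dict(),
            "delta": self.delta,
            "d_ik": {k: self.d_ik[k].tolist() for k in self.d_ik.columns},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
            return None
        return text

    @classmethod
    def from_json(cls, source) -> "ShrunkenCentroidResults":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        genes = pd.Index(payload["gene_ids"])
        d_ik = pd.DataFrame(payload["d_ik"], index=genes)
        res = cls(
            gene_ids=genes,
            overall_centroid=np.asarray(payload["overall_centroid"]),
            class_centroids=pd.DataFrame(payload["class_centroids"], index=genes),
            pooled_sd=np.asarray(payload["pooled_sd"]),
            s0=payload["s0"],
            m_k=pd.Series(payload["m_k"]),
            prior=pd.Series(payload["prior"]),
            delta=payload["delta"],
            d_ik=d_ik,
            d_shrunk=pd.DataFrame(
                {k: soft_threshold(d_ik[k].to_numpy(), payload["delta"])
                 for k in d_ik.columns}, index=genes),
        )
        return res


class ShrunkenCentroid:
    """Nearest-shrunken-centroid model over candidate (seed) genes.

    Parameters
    ----------
    expr
        genes x samples log2 expression, median-centered per gene; rows are
        the candidate genes (typically the seed genes).
    labels
        Per-sample class label, exactly the levels ``high`` and ``low``,
        each with at least two samples.
    """

    def __init__(self, expr: pd.DataFrame, labels: pd.Series) -> None:
        labels = labels.loc[expr.columns]
        levels = set(pd.unique(labels))
        if levels != set(CLASSES):
            raise ValidationError(
                f"class labels must be exactly {set(CLASSES)}, found {levels}"
            )
        for k in CLASSES:
            if (labels == k).sum() < 2:
                raise ValidationError(f"class {k!r} has fewer than 2 samples")
        self.expr = expr
        self.labels = labels

    # -- core fit at a fixed threshold --------------------------------------

    def _fit_arrays(self, X: np.ndarray, y: np.ndarray,
                    delta: float) -> dict:
        n = X.shape[1]
        stats = {"n": n}
        overall = X.mean(axis=1)
        cents, mks, priors, ss = {}, {}, {}, np.zeros(X.shape[0])
        for k in CLASSES:
            cols = y == k
            nk = int(cols.sum())
            Xk = X[:, cols]
            ck = Xk.mean(axis=1)
            cents[k] = ck
            mks[k] = np.sqrt(1.0 / nk - 1.0 / n)
            priors[k] = nk / n
            ss += ((Xk - ck[:, None]) ** 2).sum(axis=1)
        s = np.sqrt(ss / (n - len(CLASSES)))
        s0 = float(np.median(s))
        # s0 guards the denominator except in the degenerate all-zero-variance
        # case, where the standardized deviation is +/-inf by convention
        with np.errstate(divide="ignore", invalid="ignore"):
            d = {k: (cents[k] - overall) / (mks[k] * (s + s0)) for k in CLASSES}
        d_shrunk = {k: soft_threshold(d[k], delta) for k in CLASSES}
        stats.update(overall=overall, cents=cents, mks=mks, priors=priors,
                     s=s, s0=s0, d=d, d_shrunk=d_shrunk)
        return stats

    def fit_centroids(self, delta: float = 0.0) -> ShrunkenCentroidResults:
        """Fit all centroid/shrinkage statistics at a fixed threshold."""
        X = self.expr.to_numpy(dtype=float)
        y = self.labels.to_numpy()
        st = self._fit_arrays(X, y, delta)
        genes = self.expr.index
        return ShrunkenCentroidResults(
            gene_ids=genes,
            overall_centroid=st["overall"],
            class_centroids=pd.DataFrame(st["cents"], index=genes),
            pooled_sd=st["s"],
            s0=st["s0"],
            m_k=pd.Series(st["mks"]),
            prior=pd.Series(st["priors"]),
            delta=float(delta),
            d_ik=pd.DataFrame(st["d"], index=genes),
            d_shrunk=pd.DataFrame(st["d_shrunk"], index=genes),
        )

    # -- cross-validated threshold selection ---------------------------------

    def cross_validate(self, threshold_grid_size: int = 30,
                       n_folds: int = 10,
                       seed: int | None = 0) -> CrossValidationReport:
        """Stratified K-fold selection of the shrinkage amount.

        The grid is ``threshold_grid_size`` equally spaced values on
        ``[0, max |d_ik|]`` from the full-data fit. The chosen Delta is the
        largest grid value attaining the minimum total held-out error count.
        Fold count is reduced to the smaller class size when necessary.
        """
        X = self.expr.to_numpy(dtype=float)
        y = self.labels.to_numpy()
        full = self.fit_centroids(0.0)
        dmax = float(np.abs(full.d_ik.to_numpy()).max())
        grid = np.linspace(0.0, dmax, threshold_grid_size)

        min_class = min((y == k).sum() for k in CLASSES)
        folds = min(n_folds, int(min_class))
        if folds < 2:
            raise ValidationError("not enough samples per class for CV")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_of = pd.Series(-1, index=self.expr.columns, dtype=int)
        errors = np.zeros(len(grid), dtype=int)
        for f, (tr, te) in enumerate(skf.split(X.T, y)):
            fold_of.iloc[te] = f
            st = self._fit_arrays(X[:, tr], y[tr], 0.0)
            denom2 = (st["s"] + st["s0"]) ** 2
            for gi, delta in enumerate(grid):
                scores = {}
                for k in CLASSES:
                    dsh = soft_threshold(st["d"][k], delta)
                    cent = st["overall"] + st["mks"][k] * np.sqrt(denom2) * dsh
                    diff = X[:, te] - cent[:, None]
                    scores[k] = (diff**2 / denom2[:, None]).sum(axis=0) \
                        - 2.0 * np.log(st["priors"][k])
                pred = np.where(scores["high"] <= scores["low"], "high", "low")
                errors[gi] += int((pred != y[te]).sum())

        best = errors.min()
        chosen = float(grid[np.flatnonzero(errors == best)[-1]])
        return CrossValidationReport(
            folds=fold_of,
            threshold_grid=grid,
            errors=errors,
            n_samples=len(y),
            chosen_delta=chosen,
            chosen_errors=int(best),
        )

    def fit(self, delta: float | None = None, threshold_grid_size: int = 30,
            n_folds: int = 10, seed: int | None = 0) -> ShrunkenCentroidResults:
        """Fit the model; when ``delta`` is None it is chosen by CV."""
        report = None
        if delta is None:
            report = self.cross_validate(threshold_grid_size, n_folds, seed)
            delta = report.chosen_delta
        res = self.fit_centroids(delta)
        res.cv_report = report
        return res


def fit_centroids(expr: pd.DataFrame, labels: pd.Series,
                  delta: float = 0.0) -> ShrunkenCentroidResults:
    """Functional front end: fit centroid statistics at a fixed threshold."""
    return ShrunkenCentroid(expr, labels).fit_centroids(delta)


def classify(model: ShrunkenCentroidResults,
             expr_new: pd.DataFrame) -> pd.DataFrame:
    """Functional front end to :meth:`ShrunkenCentroidResults.classify`."""
    return model.classify(expr_new)


def cross_validate(expr: pd.DataFrame, labels: pd.Series,
                   threshold_grid_size: int = 30, n_folds: int = 10,
                   seed: int | None = 0) -> CrossValidationReport:
    """Functional front end to :meth:`ShrunkenCentroid.cross_validate`."""
    return ShrunkenCentroid(expr, labels).cross_validate(
        threshold_grid_size, n_folds, seed)
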