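import numpy as np
import pandas as pd
import pytest

from sigforge import ShrunkenCentroid, ShrunkenCentroidResults, soft_threshold
from sigforge.exceptions import ValidationError
from helpers import two_group_frame


def brute_force_fit(expr: pd.DataFrame, labels: pd.Series):
    """Independent straight-line recomputation of every model field."""
    X = expr.to_numpy(float)
    y = labels.loc[expr.columns].to_numpy()
    n = X.shape[1]
    out = {"overall": X.mean(axis=1)}
    ss = np.zeros(X.shape[0])
    for k in ("high", "low"):
        cols = X[:, y == k]
        nk = cols.shape[1]
        out[f"cent_{k}"] = cols.mean(axis=1)
        out[f"m_{k}"] = np.sqrt(1.0 / nk - 1.0 / n)
        out[f"pi_{k}"] = nk / n
        ss += ((cols - out[f"cent_{k}"][:, None]) ** 2).sum(axis=1)
    out["s"] = np.sqrt(ss / (n - 2))
    out["s0"] = np.median(out["s"])
    for k in ("high", "low"):
        out[f"d_{k}"] = (out[f"cent_{k}"] - out["overall"]) / (
            out[f"m_{k}"] * (out["s"] + out["s0"]))
    return out


def brute_force_scores(res, x: np.ndarray):
    """Discriminant scores recomputed from first principles."""
    scores = {}
    for k in ("high", "low"):
        dsh = np.sign(res.d_ik[k].to_numpy()) * np.maximum(
            np.abs(res.d_ik[k].to_numpy()) - res.delta, 0.0)
        cent = (res.overall_centroid
                + res.m_k[k] * (res.pooled_sd + res.s0) * dsh)
        scores[k] = float((((x - cent) ** 2)
                           / (res.pooled_sd + res.s0) ** 2).sum()
                          - 2.0 * np.log(res.prior[k]))
    return scores


class TestSoftThreshold:
    @pytest.mark.parametrize("d,delta,expected", [
        (2.0, 0.5, 1.5),
        (-0.3, 0.5, 0.0),
        (-2.0, 0.5, -1.5),
        (0.0, 0.0, 0.0),
    ])
    def test_scalar_cases(self, d, delta, expected):
        assert soft_threshold(d, delta) == pytest.approx(expected)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValidationError):
            soft_threshold(1.0, -0.1)


class TestFitOracle:
    def test_every_field_matches_bruteforce(self, rng):
        expr, labels = two_group_frame(rng, n_genes=10, n1=8, n2=12, shift=1.0)
        res = ShrunkenCentroid(expr, labels).fit_centroids(0.0)
        bf = brute_force_fit(expr, labels)
        assert np.allclose(res.overall_centroid, bf["overall"], atol=1e-12)
        assert np.allclose(res.pooled_sd, bf["s"], atol=1e-12)
        assert res.s0 == pytest.approx(bf["s0"], abs=1e-12)
        for k in ("high", "low"):
            assert np.allclose(res.class_centroids[k], bf[f"cent_{k}"],
                               atol=1e-12)
            assert res.m_k[k] == pytest.approx(bf[f"m_{k}"], abs=1e-12)
            assert res.prior[k] == pytest.approx(bf[f"pi_{k}"], abs=1e-12)
            assert np.allclose(res.d_ik[k], bf[f"d_{k}"], atol=1e-12)

    def test_single_gene_sign_structure(self):
        cols = [f"s{i}" for i in range(8)]
        labels = pd.Series(["high"] * 4 + ["low"] * 4, index=cols)
        expr = pd.DataFrame([[4.0] * 4 + [2.0] * 4], index=["g"], columns=cols)
        res = ShrunkenCentroid(expr, labels).fit_centroids(0.0)
        assert res.class_centroids.loc["g", "high"] == 4.0
        assert res.class_centroids.loc["g", "low"] == 2.0
        assert res.overall_centroid[0] == 3.0
        d_hi = res.d_ik.loc["g", "high"]
        d_lo = res.d_ik.loc["g", "low"]
        assert d_hi > 0 > d_lo

    def test_permuted_labels_concentrate_near_zero(self):
        rng = np.random.default_rng(5)
        expr, labels = two_group_frame(rng, n_genes=200, n1=50, n2=50,
                                       shift=2.0)
        perm = pd.Series(rng.permutation(labels.to_numpy()),
                         index=labels.index)
        res = ShrunkenCentroid(expr, perm).fit_centroids(0.0)
        assert np.median(np.abs(res.d_ik.to_numpy())) < 0.5

    def test_class_with_one_sample_rejected(self, rng):
        expr, labels = two_group_frame(rng, n1=1, n2=9)
        with pytest.raises(ValidationError):
            ShrunkenCentroid(expr, labels)


class TestClassify:
    def test_sample_at_high_centroid_is_high(self, rng):
        expr, labels = two_group_frame(rng, n_genes=6, n1=10, n2=10, shift=1.5)
        res = ShrunkenCentroid(expr, labels).fit_centroids(0.4)
        cent = res.shrunken_centroids
        new = pd.DataFrame({"x": cent["high"]})
        out = res.classify(new)
        assert out.loc["x", "label"] == "high"

    def test_fully_shrunk_equal_priors_ties_to_high(self, rng):
        expr, labels = two_group_frame(rng, n_genes=5, n1=10, n2=10)
        model = ShrunkenCentroid(expr, labels)
        dmax = np.abs(model.fit_centroids(0.0).d_ik.to_numpy()).max()
        res = model.fit_centroids(dmax + 1.0)
        assert (res.d_shrunk.to_numpy() == 0).all()
        out = res.classify(expr)
        assert (out["label"] == "high").all()
        assert out["tie"].all()

    def test_scores_match_bruteforce(self, rng):
        expr, labels = two_group_frame(rng, n_genes=10, n1=8, n2=12, shift=1.0)
        res = ShrunkenCentroid(expr, labels).fit_centroids(0.7)
        new = pd.DataFrame(rng.normal(size=(10, 5)), index=expr.index)
        out = res.classify(new)
        for j, col in enumerate(new.columns):
            bf = brute_force_scores(res, new[col].to_numpy())
            assert out.loc[col, "delta_high"] == pytest.approx(bf["high"],
                                                               abs=1e-10)
            assert out.loc[col, "delta_low"] == pytest.approx(bf["low"],
                                                              abs=1e-10)

    def test_missing_model_genes_listed(self, rng):
        expr, labels = two_group_frame(rng, n_genes=4)
        res = ShrunkenCentroid(expr, labels).fit_centroids(0.0)
        with pytest.raises(ValidationError, match="g3"):
            res.classify(expr.drop(index="g3"))

    def test_delta_zero_equals_diagonal_nearest_centroid(self, rng):
        # at no shrinkage the rule is the diagonal-covariance discriminant
        expr, labels = two_group_frame(rng, n_genes=8, n1=12, n2=12, shift=1.0)
        res = ShrunkenCentroid(expr, labels).fit_centroids(0.0)
        new = pd.DataFrame(rng.normal(size=(8, 20)), index=expr.index)
        out = res.classify(new)
        for col in new.columns:
            x = new[col].to_numpy()
            deltas = {}
            for k in ("high", "low"):
                cent = res.class_centroids[k].to_numpy()
                deltas[k] = ((x - cent) ** 2 /
                             (res.pooled_sd + res.s0) ** 2).sum() \
                    - 2 * np.log(res.prior[k])
            expected = "high" if deltas["high"] <= deltas["low"] else "low"
            assert out.loc[col, "label"] == expected


class TestCrossValidation:
    def test_monotone_gene_selection_along_grid(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            expr, labels = two_group_frame(rng, n_genes=12, n1=10, n2=10,
                                           shift=rng.uniform(0, 2))
            model = ShrunkenCentroid(expr, labels)
            full = model.fit_centroids(0.0)
            dmax = np.abs(full.d_ik.to_numpy()).max()
            sizes = [len(model.fit_centroids(d).selected_genes)
                     for d in np.linspace(0, dmax, 30)]
            assert all(a >= b for a, b in zip(sizes, sizes[1:]))
            assert sizes[0] == 12  # delta = 0 selects every candidate

    def test_separated_classes_zero_cv_error_with_sparse_model(self):
        rng = np.random.default_rng(2)
        # 20 informative genes, 13 pure-noise candidates
        expr, labels = two_group_frame(rng, n_genes=33, n1=40, n2=60)
        hi = (labels == "high").to_numpy()
        expr.iloc[:20, hi] += 3.0
        model = ShrunkenCentroid(expr, labels)
        report = model.cross_validate(seed=0)
        assert report.chosen_errors == 0
        assert report.chosen_delta > 0
        res = model.fit_centroids(report.chosen_delta)
        selected = set(res.selected_genes)
        informative = {f"g{i}" for i in range(20)}
        assert len(selected) < 33
        assert len(selected & informative) >= 16
        assert len(selected - informative) <= 6

    def test_same_seed_identical_report(self, rng):
        expr, labels = two_group_frame(rng, n_genes=10, n1=20, n2=20,
                                       shift=1.0)
        model = ShrunkenCentroid(expr, labels)
        a = model.cross_validate(seed=4)
        b = model.cross_validate(seed=4)
        assert a.folds.equals(b.folds)
        assert np.array_equal(a.errors, b.errors)
        assert a.chosen_delta == b.chosen_delta

    def test_folds_stratified_partition(self, rng):
        expr, labels = two_group_frame(rng, n_genes=6, n1=30, n2=70,
                                       shift=1.0)
        report = ShrunkenCentroid(expr, labels).cross_validate(seed=0)
        assert sorted(report.folds.unique()) == list(range(10))
        for f in range(10):
            members = report.folds.index[report.folds == f]
            assert set(labels[members]) == {"high", "low"}

    def test_accuracy_reported_as_percentage(self, rng):
        expr, labels = two_group_frame(rng, n_genes=8, n1=25, n2=25,
                                       shift=2.5)
        report = ShrunkenCentroid(expr, labels).cross_validate(seed=1)
        assert 0 <= report.chosen_accuracy <= 100
        assert report.chosen_accuracy == round(report.chosen_accuracy, 1)


class TestSerialization:
    def test_json_roundtrip_preserves_classification(self, rng, tmp_path):
        expr, labels = two_group_frame(rng, n_genes=7, n1=15, n2=15, shift=1.0)
        res = ShrunkenCentroid(expr, labels).fit_centroids(0.5)
        path = tmp_path / "model.json"
        res.to_json(path)
        back = ShrunkenCentroidResults.from_json(path)
        new = pd.DataFrame(rng.normal(size=(7, 10)), index=expr.index)
        a, b = res.classify(new), back.classify(new)
        assert (a["label"] == b["label"]).all()
        assert np.allclose(a["delta_high"], b["delta_high"], atol=1e-12)
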