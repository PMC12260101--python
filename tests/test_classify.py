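"""Discriminants, subspace ensemble, CV hygiene, ROC and operating points."""
import numpy as np
import pandas as pd
import pytest

from aacs.classify import (
    ClassifyError,
    CVPlan,
    DiscriminantClassifier,
    LinearSVMClassifier,
    SubspaceEnsemble,
    SubspaceEnsembleConfig,
    collapse_replicates,
    crossvalidate,
    evaluate_binary,
    roc_metrics,
    select_operating_point,
    site_grouping_task,
    train_discriminant,
)


def blobs(rng, n=40, d=5, sep=6.0):
    X = np.vstack([rng.normal(0, 1, (n // 2, d)), rng.normal(sep, 1, (n // 2, d))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


def test_discriminant_separable_blobs(rng):
    X, y = blobs(rng)
    for kind in ("linear", "quadratic"):
        model = train_discriminant(X, y, kind)
        assert (model.predict(X) == y).all()


def test_discriminant_label_swap_symmetry(rng):
    X, y = blobs(rng, sep=2.0)
    a = train_discriminant(X, y).predict(X)
    b = train_discriminant(X, 1 - y).predict(X)
    assert (a == 1 - b).all()


def test_discriminant_duplicated_column_with_ridge(rng):
    X, y = blobs(rng, d=3, sep=3.0)
    Xdup = np.column_stack([X, X[:, 0]])
    plain = train_discriminant(X, y).predict(X)
    ridged = train_discriminant(Xdup, y, regularization=0.05).predict(Xdup)
    assert (plain == ridged).mean() > 0.95


def test_discriminant_validation(rng):
    with pytest.raises(ClassifyError, match="2 classes"):
        train_discriminant(rng.normal(size=(6, 2)), np.zeros(6))
    with pytest.raises(ClassifyError, match="kind"):
        DiscriminantClassifier("cubic")


def test_ensemble_degenerate_equals_base(rng):
    """B=1, m=d subspace ensemble reproduces the plain discriminant."""
    for i in range(50):
        X, y = blobs(rng, n=30, d=4, sep=float(rng.uniform(0.5, 4)))
        Xt = rng.normal(1.0, 2.0, size=(25, 4))
        cfg = SubspaceEnsembleConfig(n_learners=1, subspace_size=4, n_dims=4,
                                     seed=i)
        ens = SubspaceEnsemble(cfg).fit(X, y)
        base = train_discriminant(X, y)
        assert (ens.predict(Xt) == base.predict(Xt)).all()
        assert np.allclose(ens.score(Xt), base.score(Xt))


def test_ensemble_determinism(rng):
    X, y = blobs(rng)
    cfg = SubspaceEnsembleConfig(seed=11)
    a = SubspaceEnsemble(cfg).fit(X, y)
    b = SubspaceEnsemble(cfg).fit(X, y)
    assert [s.tolist() for s in a.subspaces_] == [s.tolist() for s in b.subspaces_]
    Xt = rng.normal(size=(20, 5))
    assert np.array_equal(a.score(Xt), b.score(Xt))


def test_ensemble_config_validation():
    with pytest.raises(ClassifyError):
        SubspaceEnsembleConfig(subspace_size=6, n_dims=5)


def test_ensemble_separable_out_of_fold(rng):
    """Separation along 3 of 5 dims: out-of-fold AUROC >= 0.99."""
    n = 80
    X = rng.normal(size=(n, 5))
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X[y == 1, :3] += 4.0
    feats = pd.DataFrame(X, columns=list("abcde"))
    feats.insert(0, "sample_id", [f"s{i}" for i in range(n)])
    labels = pd.DataFrame({"sample_id": feats["sample_id"], "label": y})
    res = crossvalidate(
        feats, labels, list("abcde"),
        lambda: SubspaceEnsemble(SubspaceEnsembleConfig(seed=0)),
        CVPlan(k=5, seed=0),
    )
    scores, truth = res.positive_scores(1)
    assert roc_metrics(scores, truth).auroc >= 0.99


def _replicated_features(rng, n=30, reps=3):
    X = rng.normal(size=(n, 2))
    rows = []
    for i in range(n):
        for r in range(reps):
            rows.append({"sample_id": f"s{i}",
                         "a": X[i, 0] + rng.normal(0, 0.01),
                         "b": X[i, 1] + rng.normal(0, 0.01)})
    labels = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                           "label": (np.arange(n) % 2)})
    return pd.DataFrame(rows), labels


def test_crossvalidate_partition_and_replicates(rng):
    feats, labels = _replicated_features(rng)
    res = crossvalidate(feats, labels, ["a", "b"],
                        lambda: DiscriminantClassifier(), CVPlan(k=5, seed=1))
    # every patient appears in exactly one validation fold
    assert sorted(res.scores["sample_id"]) == sorted(labels["sample_id"])
    va = res.fold_assignments.query("role == 'validation'")
    assert va["sample_id"].is_unique
    # train and validation ids never intersect within any fold
    for fold, grp in res.fold_assignments.groupby("fold"):
        tr = set(grp.loc[grp["role"] == "train", "sample_id"])
        vl = set(grp.loc[grp["role"] == "validation", "sample_id"])
        assert not tr & vl


def test_crossvalidate_loo(rng):
    feats, labels = _replicated_features(rng, n=12)
    res = crossvalidate(feats, labels, ["a", "b"],
                        lambda: DiscriminantClassifier(), CVPlan(k="loo"))
    assert len(res.fold_accuracies) == 12
    assert (res.scores.groupby("fold").size() == 1).all()


def test_crossvalidate_rejects_tiny_classes(rng):
    feats, labels = _replicated_features(rng, n=8)
    labels.loc[labels.index[:7], "label"] = 0
    labels.loc[labels.index[7:], "label"] = 1
    with pytest.raises(ClassifyError, match="fewer members"):
        crossvalidate(feats, labels, ["a", "b"],
                      lambda: DiscriminantClassifier(), CVPlan(k=3, seed=0))


class _Memorizer:
    """Adversarial probe: perfect on training points, chance elsewhere."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self._bank = {tuple(row): lab for row, lab in zip(X, y)}
        self._rng = np.random.default_rng(0)
        return self

    def score(self, X):
        out = np.zeros((len(X), len(self.classes_)))
        for i, row in enumerate(X):
            if tuple(row) in self._bank:
                out[i, list(self.classes_).index(self._bank[tuple(row)])] = 1.0
            else:
                out[i] = self._rng.dirichlet(np.ones(len(self.classes_)))
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.score(X), axis=1)]


def test_crossvalidate_exposes_memorizer(rng):
    """A train-set memorizer scores ~chance out of fold: no leakage path."""
    n = 60
    feats = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "a": rng.normal(size=n), "b": rng.normal(size=n),
    })
    labels = pd.DataFrame({"sample_id": feats["sample_id"],
                           "label": rng.integers(0, 2, n)})
    res = crossvalidate(feats, labels, ["a", "b"], _Memorizer,
                        CVPlan(k=5, seed=0, collapse_replicates=False))
    assert 0.25 <= res.mean_accuracy <= 0.75


def test_roc_basics():
    scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
    labels = np.array([1, 1, 1, 0, 0, 0])
    roc = roc_metrics(scores, labels)
    assert roc.auroc == 1.0
    with pytest.raises(ClassifyError, match="both classes"):
        roc_metrics(scores, np.ones(6))


def test_auroc_equals_pair_counting(rng):
    """AUROC == Mann-Whitney U / (n1 n2) with half-credit ties, 100 sets."""
    for _ in range(100):
        n = int(rng.integers(8, 40))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.normal(size=n), 1)  # rounding makes ties likely
        pos, neg = s[y == 1], s[y == 0]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_metrics(s, y).auroc == pytest.approx(
            u / (len(pos) * len(neg)), abs=1e-12
        )


def test_roc_null_near_half(rng):
    s = rng.normal(size=4000)
    y = rng.integers(0, 2, 4000)
    assert abs(roc_metrics(s, y).auroc - 0.5) < 0.03


def test_operating_point_disjoint_scores():
    s = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
    y = np.array([0, 0, 0, 1, 1, 1])
    op = select_operating_point(s, y, 1.0)
    assert op["sensitivity"] == 1.0 and op["specificity"] == 1.0
    assert 0.3 < op["threshold"] < 0.7


def test_operating_point_floor_zero():
    s = np.array([0.4, 0.5, 0.6, 0.7])
    y = np.array([0, 1, 0, 1])
    op = select_operating_point(s, y, 0.0)
    assert op["sensitivity"] == 1.0
    assert op["threshold"] < s.min()


def test_operating_point_dominates_exhaustive_scan(rng):
    for _ in range(50):
        n = int(rng.integers(10, 40))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.normal(size=n), 1)
        floor = float(rng.choice([0.0, 0.5, 0.8, 1.0]))
        op = select_operating_point(s, y, floor)
        assert op["specificity"] >= floor
        # exhaustive threshold scan: nothing feasible beats the sensitivity
        best = 0.0
        for t in np.concatenate([s, [s.max() + 1]]):
            pred = s >= t
            m = evaluate_binary(pred.astype(int), y)
            if m.specificity >= floor:
                best = max(best, m.sensitivity)
        assert op["sensitivity"] == pytest.approx(best)
        # the returned threshold reproduces the reported point
        m = evaluate_binary((s >= op["threshold"]).astype(int), y)
        assert m.sensitivity == pytest.approx(op["sensitivity"])
        assert m.specificity == pytest.approx(op["specificity"])


def test_evaluate_binary_cases():
    m = evaluate_binary([1, 0, 1, 0], [1, 0, 1, 0])
    assert (m.sensitivity, m.specificity, m.ppv, m.fdr) == (1, 1, 1, 0)
    m = evaluate_binary([0, 0, 0], [1, 0, 1])
    assert m.ppv is None and "no_positive_predictions" in m.flags
    # hand-counted 2x2: tp=2 fp=1 tn=3 fn=1
    m = evaluate_binary([1, 1, 1, 0, 0, 0, 0], [1, 1, 0, 1, 0, 0, 0])
    assert (m.tp, m.fp, m.tn, m.fn) == (2, 1, 3, 1)
    assert m.ppv == pytest.approx(2 / 3) and m.fdr == pytest.approx(1 / 3)
    assert m.n == 7


def test_linear_svm_weights_match_pipeline(rng):
    X, y = blobs(rng, n=60, d=4, sep=2.0)
    model = LinearSVMClassifier().fit(X, y)
    w, b = model.linear_weights()
    assert np.allclose(X @ w + b, model.decision_function(X), atol=1e-8)


def test_site_grouping_mapping_and_errors(rng):
    n = 48
    X = rng.normal(size=(n, 5))
    types = np.repeat(["breast", "prostate", "colorectal", "pancreatic"], 12)
    X[np.isin(types, ["colorectal", "pancreatic"])] += 3.0
    feats = pd.DataFrame(X, columns=list("abcde"))
    feats.insert(0, "sample_id", [f"s{i}" for i in range(n)])
    labels = pd.DataFrame({"sample_id": feats["sample_id"], "label": types})
    res = site_grouping_task(feats, labels, list("abcde"),
                             plan=CVPlan(k=4, seed=0))
    assert set(res["per_group_accuracy"]) == {"abdominal", "hormonal"}
    assert res["accuracy"] > 0.8  # groups are well separated by construction
    assert res["confusion"].to_numpy().sum() == n
    bad = labels.copy()
    bad.loc[0, "label"] = "lung"
    with pytest.raises(ClassifyError, match="lung"):
        site_grouping_task(feats, bad, list("abcde"))
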