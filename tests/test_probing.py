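import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from multiprot.probing import (MLPProbe, ProbeConfig, ProbeTask, accuracy,
                               aupr_per_class, fit_probe, fmax,
                               predict_probe, roc_auc, roc_auc_from_labels,
                               run_downstream_suite, spearman_rho)


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        assert spearman_rho([1, 2, 3], [3, 1, 0]) == pytest.approx(-1.0)

    def test_worked_example(self):
        # rank-difference formula: 1 - 6*sum(d^2)/(n(n^2-1)) = 0.8
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_ties_use_average_ranks(self):
        from scipy.stats import spearmanr
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 5.0]
        assert spearman_rho(x, y) == pytest.approx(spearmanr(x, y).statistic)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


def sweep_auc(pos, neg):
    """Threshold-sweep ROC construction (trapezoid over all thresholds)."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1], [-np.inf]])
    tpr, fpr = [], []
    for t in thresholds:
        pred = scores >= t
        tpr.append((pred & (labels == 1)).sum() / len(pos))
        fpr.append((pred & (labels == 0)).sum() / len(neg))
    return float(np.trapezoid(tpr, fpr))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_multisets_half(self):
        assert roc_auc([0.3, 0.7], [0.3, 0.7]) == 0.5

    def test_worked_example(self):
        assert roc_auc([0.9, 0.6], [0.7, 0.1]) == pytest.approx(0.75)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [0.1])

    def test_matches_threshold_sweep_and_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pos = rng.normal(0.5, 1, size=8)
            neg = rng.normal(0, 1, size=11)
            ours = roc_auc(pos, neg)
            assert ours == pytest.approx(sweep_auc(pos, neg), abs=1e-9)
            y = np.concatenate([np.ones(8), np.zeros(11)])
            s = np.concatenate([pos, neg])
            assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_with_ties_matches_sklearn(self):
        pos = [0.5, 0.5, 0.9]
        neg = [0.5, 0.1]
        y = [1, 1, 1, 0, 0]
        s = pos + neg
        assert roc_auc(pos, neg) == pytest.approx(roc_auc_score(y, s))


class TestFmax:
    def test_perfect_predictor(self):
        truth = [[0], [1]]
        scores = np.array([[1.0, 0.0], [0.0, 1.0]])
        value, _ = fmax(truth, scores)
        assert value == pytest.approx(1.0)

    def test_worked_example_six_sevenths(self):
        truth = [[0], [1]]  # p1 true {A}, p2 true {B}
        scores = np.array([[0.9, 0.2], [0.7, 0.6]])
        value, thr = fmax(truth, scores)
        assert value == pytest.approx(6 / 7)
        # any threshold in [0.2, 0.6) yields the optimal prediction set
        # (the illustrative tau = 0.5 lies in this class); the finite scan
        # returns its lowest member
        assert 0.2 <= thr < 0.6

    def test_finite_scan_equals_dense_grid(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n, L = 8, 5
            scores = rng.random((n, L))
            truth = [list(np.nonzero(rng.random(L) > 0.5)[0]) or [0]
                     for _ in range(n)]
            ours, _ = fmax(truth, scores)

            best = 0.0
            for thr in np.linspace(0, 1, 10 ** 4):
                pred = scores > thr
                t = np.zeros((n, L), dtype=bool)
                for i, labs in enumerate(truth):
                    t[i, labs] = True
                tp = (pred & t).sum(axis=1)
                fp = (pred & ~t).sum(axis=1)
                fn = (~pred & t).sum(axis=1)
                prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
                rec = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
                P, R = prec.mean(), rec.mean()
                if P + R > 0:
                    best = max(best, 2 * P * R / (P + R))
            assert ours >= best - 1e-9
            assert ours <= best + 1e-3  # grid may just miss the optimum

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random((6, 4))
        truth = [[int(rng.integers(4))] for _ in range(6)]
        base, _ = fmax(truth, scores)
        transformed, _ = fmax(truth, scores ** 3)  # strictly monotone on [0,1]
        assert base == pytest.approx(transformed, abs=1e-12)

    def test_scores_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fmax([[0]], np.array([[1.5]]))

    def test_binary_vector_truth_accepted(self):
        truth = [np.array([1, 0]), np.array([0, 1])]
        scores = np.array([[0.9, 0.1], [0.2, 0.8]])
        value, _ = fmax(truth, scores)
        assert value == pytest.approx(1.0)


class TestAupr:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        scores = np.zeros((4, 2))
        scores[:, 1] = [0.1, 0.2, 0.8, 0.9]
        scores[:, 0] = 1 - scores[:, 1]
        assert aupr_per_class(y, scores, 1) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        y = np.array([1, 0, 0, 0, 1])
        scores = np.full((5, 2), 0.5)
        assert aupr_per_class(y, scores, 1) == pytest.approx(0.4)

    def test_six_instances_vs_exhaustive_enumeration(self):
        y = np.array([1, 0, 1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        scores = np.stack([1 - s, s], axis=1)
        ours = aupr_per_class(y, scores, 1)
        # step-wise AP by direct enumeration over distinct thresholds
        expected = 0.0
        prev_rec = 0.0
        for t in sorted(set(s), reverse=True):
            pred = s >= t
            tp = (pred & (y == 1)).sum()
            prec = tp / pred.sum()
            rec = tp / 3
            expected += (rec - prev_rec) * prec
            prev_rec = rec
        assert ours == pytest.approx(expected, abs=1e-12)
        assert ours == pytest.approx(average_precision_score(y, s), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            aupr_per_class(np.zeros(3, dtype=int), np.ones((3, 2)) / 2, 1)


class TestIqrLikeMetrics:
    def test_accuracy(self):
        assert accuracy([1, 0, 1], [1, 1, 1]) == pytest.approx(2 / 3)

    def test_auc_from_labels(self):
        assert roc_auc_from_labels([1, 1, 0, 0],
                                   [0.9, 0.6, 0.7, 0.1]) == pytest.approx(0.75)


def make_embeddings(n=80, d=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    w = rng.normal(size=d)
    margin = X @ w
    labels = (margin > 0).astype(int)
    emb = {f"p{i}": X[i] for i in range(n)}
    return emb, labels


class TestProbe:
    def test_separable_training_accuracy_one(self):
        emb, labels = make_embeddings(seed=3)
        ids = list(emb)
        task = ProbeTask("sep", "binary",
                         {i: int(l) for i, l in zip(ids, labels)})
        probe = fit_probe(emb, task, ProbeConfig(hidden=16, epochs=120),
                          seed=0, ids=ids)
        preds = (predict_probe(probe, emb, ids) > 0.5).astype(int)
        assert accuracy(labels, preds) == 1.0

    def test_same_seed_identical_predictions(self):
        emb, labels = make_embeddings(seed=4)
        ids = list(emb)
        task = ProbeTask("t", "binary",
                         {i: int(l) for i, l in zip(ids, labels)})
        p1 = fit_probe(emb, task, ProbeConfig(epochs=10), seed=7, ids=ids)
        p2 = fit_probe(emb, task, ProbeConfig(epochs=10), seed=7, ids=ids)
        assert np.array_equal(predict_probe(p1, emb, ids),
                              predict_probe(p2, emb, ids))

    def test_signal_beats_permuted_labels(self):
        emb, labels = make_embeddings(n=120, seed=5)
        ids = list(emb)
        train_ids, test_ids = ids[:90], ids[90:]
        rng = np.random.default_rng(0)
        permuted = rng.permutation(labels)

        def run(y, seed):
            task = ProbeTask("t", "binary",
                             {i: int(v) for i, v in zip(ids, y)})
            probe = fit_probe(emb, task, ProbeConfig(epochs=60), seed=seed,
                              ids=train_ids)
            preds = (predict_probe(probe, emb, test_ids) > 0.5).astype(int)
            truth = [int(task.labels[i]) for i in test_ids]
            return accuracy(truth, preds)

        signal = np.array([run(labels, s) for s in range(4)])
        null = np.array([run(permuted, s) for s in range(4)])
        spread = max(signal.std(ddof=1), 0.01)
        assert signal.mean() - null.mean() > 3 * spread

    def test_capacity_cap_enforced(self):
        with pytest.raises(ValueError, match="capacity"):
            MLPProbe(2000, 1000, "binary",
                     ProbeConfig(hidden=2000, max_parameters=1_500_000))

    def test_label_mismatch_rejected(self):
        emb, _ = make_embeddings(n=4)
        task = ProbeTask("t", "binary", {"p0": 1})
        with pytest.raises(KeyError):
            fit_probe(emb, task, ids=["p0", "p999"])


class TestSuite:
    def _tasks_and_embeddings(self):
        rng = np.random.default_rng(6)
        n, d = 60, 6
        X = rng.normal(size=(n, d))
        ids = [f"p{i}" for i in range(n)]
        emb = {i: x for i, x in zip(ids, X)}
        tasks = [
            ProbeTask("reg", "regression",
                      {i: float(x @ np.ones(d)) for i, x in zip(ids, X)}),
            ProbeTask("bin", "binary",
                      {i: int(x[0] > 0) for i, x in zip(ids, X)}),
        ]
        return emb, tasks, ids

    def test_single_run_zero_std(self):
        emb, tasks, ids = self._tasks_and_embeddings()
        table = run_downstream_suite({"m": emb}, tasks, ids[:40], ids[40:],
                                     n_runs=1, config=ProbeConfig(epochs=5))
        for row in table.aggregate():
            assert row["std"] == 0.0 and row["n_runs"] == 1

    def test_identical_embeddings_identical_metrics(self):
        emb, tasks, ids = self._tasks_and_embeddings()
        table = run_downstream_suite({"m1": emb, "m2": emb}, tasks,
                                     ids[:40], ids[40:], n_runs=2,
                                     config=ProbeConfig(epochs=5))
        agg = {(r["model"], r["task"], r["metric"]): r["mean"]
               for r in table.aggregate()}
        for (model, task, metric), v in agg.items():
            assert v == agg[("m1", task, metric)]

    def test_multimodel_multitask_shape(self):
        emb, tasks, ids = self._tasks_and_embeddings()
        table = run_downstream_suite({"m1": emb, "m2": emb}, tasks,
                                     ids[:40], ids[40:], n_runs=2,
                                     config=ProbeConfig(epochs=3))
        models = {c.model for c in table.cells}
        assert models == {"m1", "m2"}
        assert len(table.values("m1", "bin", "accuracy")) == 2
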