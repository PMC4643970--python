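"""Top-scoring-pairs classifier: pair scoring, prediction, evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pantcl.tsp import evaluate, fit_tsp, predict


def _data(rows: dict[str, list[float]], n1: int):
    n = len(next(iter(rows.values())))
    m = pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T
    labels = pd.Series(["c1"] * n1 + ["c2"] * (n - n1), index=m.columns)
    return m, labels


def brute_force_tsp(matrix: pd.DataFrame, labels: pd.Series, candidates):
    """Independent exhaustive pair scorer (plain loops, no vectorization)."""
    genes = sorted(g for g in candidates if g in matrix.index)
    classes = sorted(labels.unique())
    best = None
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            gi, gj = genes[a], genes[b]
            p = {}
            for c in classes:
                cols = labels.index[labels == c]
                p[c] = np.mean([matrix.loc[gi, s] < matrix.loc[gj, s] for s in cols])
            delta = abs(p[classes[0]] - p[classes[1]])
            # secondary score: between-class gap of mean within-sample rank difference
            gaps = {}
            for c in classes:
                cols = labels.index[labels == c]
                diffs = []
                for s in cols:
                    ranks = matrix.loc[genes, s].rank()
                    diffs.append(ranks[gi] - ranks[gj])
                gaps[c] = np.mean(diffs)
            gamma = abs(gaps[classes[0]] - gaps[classes[1]])
            key = (delta, gamma)
            if best is None or key > best[0]:
                best = (key, gi, gj)
    return best[1], best[2], best[0][0]


class TestFit:
    def test_perfect_separation_scores_delta_one(self):
        m, lab = _data({"A": [1, 1, 1, 1, 9, 9, 9, 9], "B": [5, 5, 5, 5, 5, 5, 5, 5]}, 4)
        model = fit_tsp(m, lab, ["A", "B"])
        assert model.delta == 1.0
        assert {model.gene_i, model.gene_j} == {"A", "B"}

    def test_partial_frequencies(self):
        # class1: A < B in 3/4; class2: A < B in 1/4 -> delta = 0.5
        m, lab = _data({"A": [1, 1, 1, 9, 9, 9, 9, 1], "B": [5, 5, 5, 5, 5, 5, 5, 5]}, 4)
        model = fit_tsp(m, lab, ["A", "B"])
        assert model.p_hat["c1"] == 0.75
        assert model.p_hat["c2"] == 0.25
        assert model.delta == 0.5

    def test_uninformative_pair_scores_zero(self):
        m, lab = _data({"A": [1, 9, 1, 9], "B": [5, 5, 5, 5]}, 2)
        model = fit_tsp(m, lab, ["A", "B"])
        assert model.delta == 0.0

    def test_too_few_candidates_rejected(self):
        m, lab = _data({"A": [1, 2, 3, 4]}, 2)
        with pytest.raises(ValueError):
            fit_tsp(m, lab, ["A", "missing"])

    def test_within_sample_tie_counts_as_not_less(self):
        m, lab = _data({"A": [5, 5, 9, 9], "B": [5, 5, 5, 5]}, 2)
        model = fit_tsp(m, lab, ["A", "B"])
        assert model.p_hat["c1"] == 0.0  # ties are not(i < j)


class TestAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n_samples = rng.integers(4, 11), rng.integers(6, 21)
        n1 = int(n_samples // 2)
        m = pd.DataFrame(
            rng.uniform(1, 100, (n_genes, n_samples)),
            index=[f"g{i:02d}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )
        labels = pd.Series(["c1"] * n1 + ["c2"] * (n_samples - n1), index=m.columns)
        model = fit_tsp(m, labels, m.index.tolist())
        gi, gj, delta = brute_force_tsp(m, labels, m.index.tolist())
        assert {model.gene_i, model.gene_j} == {gi, gj}
        assert model.delta == pytest.approx(delta, abs=1e-12)


class TestInvariances:
    def test_monotone_within_sample_transform_preserves_model(self, rng):
        m = pd.DataFrame(
            rng.uniform(1, 100, (6, 12)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(12)],
        )
        labels = pd.Series(["c1"] * 6 + ["c2"] * 6, index=m.columns)
        powers = rng.uniform(0.3, 3.0, 12)
        transformed = m ** powers  # per-sample monotone transform
        a = fit_tsp(m, labels, m.index.tolist())
        b = fit_tsp(transformed, labels, m.index.tolist())
        assert (a.gene_i, a.gene_j, a.delta) == (b.gene_i, b.gene_j, b.delta)

    def test_label_swap_keeps_delta_and_flips_decision(self):
        m, lab = _data({"A": [1, 1, 1, 9, 9, 9], "B": [5, 5, 5, 5, 5, 5]}, 3)
        swapped = lab.map({"c1": "c2", "c2": "c1"})
        a = fit_tsp(m, lab, ["A", "B"])
        b = fit_tsp(m, swapped, ["A", "B"])
        assert a.delta == b.delta
        sample = m["s0"]
        assert predict(a, sample) == "c1"
        assert predict(b, sample) == "c2"


class TestPredict:
    def test_direction_follows_larger_phat(self):
        m, lab = _data({"CAV1": [1, 1, 9, 9], "BCL10": [5, 5, 5, 5]}, 2)
        model = fit_tsp(m, lab, ["CAV1", "BCL10"])
        malignant_like = pd.Series({"CAV1": 100.0, "BCL10": 5.0})
        healthy_like = pd.Series({"CAV1": 1.0, "BCL10": 5.0})
        assert predict(model, malignant_like) == "c2"
        assert predict(model, healthy_like) == "c1"

    def test_tie_has_deterministic_class(self):
        m, lab = _data({"A": [1, 1, 9, 9], "B": [5, 5, 5, 5]}, 2)
        model = fit_tsp(m, lab, ["A", "B"])
        tie = pd.Series({"A": 5.0, "B": 5.0})
        assert predict(model, tie) == predict(model, pd.Series({"A": 9.0, "B": 5.0}))

    def test_missing_gene_rejected(self):
        m, lab = _data({"A": [1, 1, 9, 9], "B": [5, 5, 5, 5]}, 2)
        model = fit_tsp(m, lab, ["A", "B"])
        with pytest.raises(ValueError):
            predict(model, pd.Series({"A": 1.0}))


class TestEvaluate:
    def test_planted_pair_perfect_under_loocv(self, rng):
        n = 10
        a = np.concatenate([rng.uniform(1, 4, n), rng.uniform(6, 9, n)])
        m = pd.DataFrame(
            {"A": a, "B": np.full(2 * n, 5.0), "noise": rng.uniform(1, 9, 2 * n)},
            index=[f"s{i}" for i in range(2 * n)],
        ).T
        labels = pd.Series(["healthy"] * n + ["malignant"] * n, index=m.columns)
        ev = evaluate(m, labels, ["A", "B", "noise"], scheme="LOOCV")
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0
        assert ev.tp + ev.fn + ev.tn + ev.fp == 2 * n

    def test_null_labels_near_prevalence_accuracy(self, rng):
        accs = []
        for s in range(15):
            r = np.random.default_rng(s)
            m = pd.DataFrame(
                r.uniform(1, 100, (5, 14)),
                index=[f"g{i}" for i in range(5)],
                columns=[f"s{i}" for i in range(14)],
            )
            labels = pd.Series(
                r.permutation(["a"] * 8 + ["b"] * 6), index=m.columns
            )
            ev = evaluate(m, labels, m.index.tolist(), scheme="LOOCV", positive_class="b")
            accs.append((ev.tp + ev.tn) / 14)
        # chance level for the larger class is 8/14 ~ 0.57
        assert abs(np.mean(accs) - 8 / 14) < 0.2

    def test_resubstitution_not_worse_than_loocv_on_average(self, rng):
        diffs = []
        for s in range(10):
            r = np.random.default_rng(100 + s)
            m = pd.DataFrame(
                r.uniform(1, 100, (4, 12)),
                index=[f"g{i}" for i in range(4)],
                columns=[f"s{i}" for i in range(12)],
            )
            labels = pd.Series(["a"] * 6 + ["b"] * 6, index=m.columns)
            loo = evaluate(m, labels, m.index.tolist(), scheme="LOOCV", positive_class="b")
            res = evaluate(m, labels, m.index.tolist(), scheme="resubstitution",
                           positive_class="b")
            diffs.append((res.tp + res.tn) - (loo.tp + loo.tn))
        assert np.mean(diffs) >= 0

    def test_fold_losing_a_class_is_error(self):
        m, lab = _data({"A": [1, 2, 3, 9], "B": [5, 5, 5, 5]}, 3)
        lab.iloc[3] = "only_one"
        lab.iloc[:3] = "many"
        with pytest.raises(ValueError):
            evaluate(m, lab, ["A", "B"], scheme="LOOCV")
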