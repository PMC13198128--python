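"""Metric definitions, head contracts, recipes and split validation."""

import itertools
import math

import numpy as np
import pytest

from trialign import nn
from trialign.downstream import (
    ConfusionSummary,
    TaskSpec,
    UndefinedMetricError,
    acr_forward,
    aggregate_metrics,
    auc_score,
    compute_metrics,
    confusion_from,
    fitness_forward,
    init_acr_head,
    init_fitness_head,
    init_mic_head,
    init_peptide_head,
    init_thermo_head,
    init_variant_head,
    mic_forward,
    paired_t_report,
    peptide_forward,
    thermo_forward,
    train_head,
    validate_split_spec,
    variant_forward,
)


def table_arrays(tp, fp, tn, fn):
    y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
    y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
    return np.array(y_true), np.array(y_pred)


class TestClassificationMetrics:
    def test_all_small_confusion_tables_match_brute_force(self):
        # every 2x2 table with cells <= 5 (1296 tables), against sklearn
        # where defined and the definitional formulas elsewhere
        from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef, precision_score, recall_score

        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            if tp + fp + tn + fn == 0:
                continue
            c = ConfusionSummary(TP=tp, FP=fp, TN=tn, FN=fn)
            y_true, y_pred = table_arrays(tp, fp, tn, fn)
            assert c.ACC == pytest.approx(accuracy_score(y_true, y_pred), abs=1e-12)
            if tp + fp > 0:
                assert c.precision == pytest.approx(
                    precision_score(y_true, y_pred, zero_division=0), abs=1e-12
                )
            if tp + fn > 0:
                assert c.SN == pytest.approx(recall_score(y_true, y_pred, zero_division=0), abs=1e-12)
            assert c.F1 == pytest.approx(f1_score(y_true, y_pred, zero_division=0), abs=1e-12)
            den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            if den > 0:
                assert c.MCC == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
            else:
                assert c.MCC == 0.0
            assert c.BACC == pytest.approx(0.5 * (c.SN + c.SP), abs=1e-15)

    def test_confusion_from_counts(self):
        y_true, y_pred = table_arrays(3, 2, 4, 1)
        c = confusion_from(y_true, y_pred)
        assert (c.TP, c.FP, c.TN, c.FN) == (3, 2, 4, 1)

    def test_umami_all_positive_closed_form(self):
        # 28 positives / 61 negatives, everything predicted positive
        y_true = np.array([1] * 28 + [0] * 61)
        y_pred = np.ones(89, dtype=int)
        m = compute_metrics(y_true, y_pred, metrics=("SN", "SP", "BACC"))
        assert m["SN"] == 1.0 and m["SP"] == 0.0 and m["BACC"] == 0.5

    def test_mcc_formula_example(self):
        c = ConfusionSummary(TP=90, FP=20, TN=80, FN=10)
        expected = 7000 / math.sqrt(110 * 100 * 100 * 90)
        assert c.MCC == pytest.approx(expected, abs=1e-12)
        assert c.MCC == pytest.approx(0.7035, abs=1e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionSummary(TP=-1, FP=0, TN=0, FN=0)


class TestAUC:
    def test_perfect_reversed_tied(self):
        y = np.array([0, 0, 1, 1])
        assert auc_score(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auc_score(y, [0.9, 0.8, 0.2, 0.1]) == 0.0
        assert auc_score(y, [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.7, 0.9], size=n)
            assert auc_score(y, scores) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_single_class_truth_errors(self):
        with pytest.raises(UndefinedMetricError):
            auc_score(np.ones(5), np.arange(5))


class TestRegressionMetrics:
    def test_mse_spearman_pearson_r2(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        p = y + rng.normal(0, 0.1, size=50)
        m = compute_metrics(y, p, metrics=("MSE", "Spearman", "Pearson", "R2"))
        from scipy import stats as sps

        assert m["MSE"] == pytest.approx(float(np.mean((p - y) ** 2)), abs=1e-12)
        assert m["Spearman"] == pytest.approx(float(sps.spearmanr(y, p).statistic), abs=1e-12)
        assert m["Pearson"] == pytest.approx(float(sps.pearsonr(y, p).statistic), abs=1e-12)
        assert m["R2"] <= 1.0 and m["R2"] > 0.9


class TestHeadContracts:
    rng = np.random.default_rng(0)

    def test_variant_softmax_sums_to_one_and_order_matters(self):
        p = init_variant_head(np.random.default_rng(0), d=8)
        wt = self.rng.normal(size=(5, 8))
        mut = self.rng.normal(size=(5, 8))
        out = variant_forward(p, wt, mut)
        assert np.allclose(np.sum(out, axis=1), 1.0, atol=1e-9)
        swapped = variant_forward(p, mut, wt)
        assert not np.allclose(out, swapped)
        with pytest.raises(ValueError):
            variant_forward(p, wt, None)

    def test_thermo_logits_and_modality_check(self):
        p = init_thermo_head(np.random.default_rng(0), d=8)
        logits = thermo_forward(p, self.rng.normal(size=(3, 8)))
        assert logits.shape == (3, 5)
        with pytest.raises(ValueError, match="structure"):
            thermo_forward(p, np.zeros((1, 8)), modality="sequence")

    def test_acr_padding_rows_contribute_zero(self):
        p = init_acr_head(np.random.default_rng(0), d=8)
        x2 = self.rng.normal(size=(1, 2, 8))
        x3 = np.concatenate([x2, np.zeros((1, 1, 8))], axis=1)  # padded to set size 3
        m2 = np.ones((1, 2))
        m3 = np.concatenate([m2, np.zeros((1, 1))], axis=1)
        out2 = acr_forward(p, x2, m2)
        out3 = acr_forward(p, x3, m3)
        # same-padding conv with kernel 7 sees zeros beyond either end, so
        # masked padding must reproduce the unpadded computation
        assert np.allclose(out2, out3, atol=1e-9)

    def test_acr_empty_partner_set_errors(self):
        p = init_acr_head(np.random.default_rng(0), d=8)
        with pytest.raises(ValueError, match="partner"):
            acr_forward(p, np.zeros((1, 1, 8)), np.ones((1, 1)))

    def test_peptide_output_in_unit_interval(self):
        p = init_peptide_head(np.random.default_rng(0), d=16)
        out = peptide_forward(p, self.rng.normal(size=(4, 16)))
        assert out.shape == (4,) and np.all((out > 0) & (out < 1))

    def test_mic_scalar_output(self):
        p = init_mic_head(np.random.default_rng(0), d=8)
        out = mic_forward(p, self.rng.normal(size=(6, 8)))
        assert out.shape == (6,)

    def test_fitness_length_one_valid_and_eval_deterministic(self):
        p = init_fitness_head(np.random.default_rng(0), d=8)
        x = self.rng.normal(size=(2, 1, 8))
        m = np.ones((2, 1))
        a = fitness_forward(p, x, m)
        b = fitness_forward(p, x, m)
        assert a.shape == (2,) and np.array_equal(a, b)


class TestRecipesOnSeparableEmbeddings:
    """Head training sanity on analytically separable inputs (fast)."""

    def _class_embeddings(self, rng, n, d, y, scale=1.0):
        centers = rng.normal(size=(int(np.max(y)) + 1, d))
        return centers[y] + scale * 0.1 * rng.normal(size=(n, d))

    def test_mic_recovers_affine_target(self):
        rng = np.random.default_rng(0)
        y_class = rng.integers(0, 4, size=200)
        X = self._class_embeddings(rng, 200, 8, y_class)
        y = 0.5 * y_class + 1.0
        spec = TaskSpec(task="mic", modality="sequence", metrics=("MSE", "R2"), extra={"epochs": 150, "lr": 1e-2})
        params, aux = train_head("mic", {"X": X[:160], "y": y[:160]}, seed=0, spec=spec)
        pred = mic_forward(params, X[160:])
        m = compute_metrics(y[160:], np.asarray(pred), metrics=("R2",))
        assert m["R2"] > 0.9

    def test_constant_target_learned(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 6))
        y = np.full(60, 2.5)
        spec = TaskSpec(task="mic", modality="sequence", metrics=("MSE",), extra={"epochs": 150, "lr": 1e-2})
        params, _ = train_head("mic", {"X": X, "y": y}, seed=0, spec=spec)
        pred = np.asarray(mic_forward(params, X))
        assert float(np.mean((pred - 2.5) ** 2)) < 0.05

    def test_thermo_identical_architecture_different_weights_across_seeds(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 5, size=100)
        X = self._class_embeddings(rng, 100, 8, y)
        spec = TaskSpec(task="thermostability", modality="structure", metrics=("ACC",), epochs=30)
        p1, _ = train_head("thermostability", {"X": X, "y": y}, seed=0, spec=spec)
        p2, _ = train_head("thermostability", {"X": X, "y": y}, seed=1, spec=spec)
        assert p1["fc1"]["W"].shape == p2["fc1"]["W"].shape
        assert not np.allclose(p1["fc1"]["W"], p2["fc1"]["W"])


class TestReporting:
    def test_five_identical_seeds_zero_sd(self):
        per_seed = [{"ACC": 0.9, "F1": 0.8}] * 5
        mean, sd = aggregate_metrics(per_seed)
        assert mean == {"ACC": 0.9, "F1": 0.8}
        assert sd == {"ACC": 0.0, "F1": 0.0}

    def test_paired_t_against_itself_flags_undefined_variance(self):
        res = paired_t_report([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert res["undefined_variance"] and res["p"] == 1.0

    def test_t_statistic_matches_closed_form(self):
        a = [0.72, 0.70, 0.74, 0.71, 0.73]
        b = [0.65, 0.69, 0.70, 0.66, 0.68]
        d = np.array(a) - np.array(b)
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        res = paired_t_report(a, b)
        assert res["t"] == pytest.approx(t_expected, abs=1e-9)
        assert 0 < res["p"] < 1 and not res["undefined_variance"]

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_t_report([0.1], [0.1, 0.2])


class TestSplitSpecs:
    def test_dppiv_pass(self):
        res = validate_split_spec("dppiv", {"train_pos": 532, "train_neg": 532, "test_pos": 133, "test_neg": 133})
        assert res["passed"]

    def test_variant_pass(self):
        assert validate_split_spec("variant", {"train": 100, "test": 100})["passed"]

    def test_off_by_one_fails_with_named_cell(self):
        res = validate_split_spec("dppiv", {"train_pos": 533, "train_neg": 532, "test_pos": 133, "test_neg": 133})
        assert not res["passed"]
        assert res["mismatches"] == {"train_pos": (532, 533)}

    def test_unknown_task_errors(self):
        with pytest.raises(ValueError):
            validate_split_spec("nonexistent", {})

    def test_all_recorded_tables_validate_against_themselves(self):
        from trialign.downstream import load_split_specs

        table = load_split_specs()
        for task in table["task"].unique():
            rows = table[table["task"] == task]
            counts = dict(zip(rows["cell"], rows["count"]))
            assert validate_split_spec(task, counts)["passed"]
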