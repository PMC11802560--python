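import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sefcn.evaluate import (
    ConfusionCounts,
    FoldSpec,
    auc,
    confusion,
    detection_latency,
    lopo_splits,
    sen_spe_gmean_acc,
    split_fold_epochs,
    summarize,
    train_fold,
)
from sefcn.preprocess import EpochSet
from sefcn.montage import CANONICAL_32


def auc_all_pairs(labels, scores):
    """Brute-force oracle: all positive/negative pairs, ties count 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_enumeration(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_all_correct(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestRates:
    @pytest.mark.parametrize(
        "sen, spe, expected_gmean",
        [(0.968, 0.936, 0.952), (0.972, 0.917, 0.944)],
    )
    def test_gmean_reproduces_reported_rows(self, sen, spe, expected_gmean):
        assert np.sqrt(sen * spe) == pytest.approx(expected_gmean, abs=5e-4)

    def test_rates_from_counts(self):
        c = ConfusionCounts(tp=968, fn=32, tn=936, fp=64)
        sen, spe, gmean, acc = sen_spe_gmean_acc(c)
        assert sen == pytest.approx(0.968)
        assert spe == pytest.approx(0.936)
        assert gmean == pytest.approx(np.sqrt(0.968 * 0.936))
        assert acc == pytest.approx((968 + 936) / 2000)

    def test_perfect_classifier(self):
        sen, spe, gmean, acc = sen_spe_gmean_acc(ConfusionCounts(5, 0, 7, 0))
        assert sen == spe == gmean == acc == 1.0

    def test_zero_denominator_is_undefined_not_zero(self):
        sen, spe, gmean, _ = sen_spe_gmean_acc(ConfusionCounts(0, 2, 3, 0))
        assert np.isnan(sen) and np.isnan(gmean)
        assert spe == pytest.approx(0.6)

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(max_examples=100, derandomize=True)
    def test_am_gm_inequality(self, tp, fp, tn, fn):
        c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        if tp + fn == 0 or tn + fp == 0:
            return
        sen, spe, gmean, _ = sen_spe_gmean_acc(c)
        assert gmean <= (sen + spe) / 2 + 1e-12
        if sen == spe:
            assert gmean == pytest.approx((sen + spe) / 2)


class TestAUC:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        assert auc(labels, labels.astype(float)) == 1.0

    def test_constant_scores_give_half(self):
        assert auc([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3]) == 0.5

    def test_single_class_undefined(self):
        assert np.isnan(auc([1, 1], [0.2, 0.9]))

    def test_matches_all_pairs_oracle_exhaustively(self):
        """Every label pattern and tie-rich score pattern up to n=8,
        plus random instances up to n=12."""
        score_levels = [0.0, 0.5, 1.0]
        for n in (2, 3, 4):
            for labels in itertools.product([0, 1], repeat=n):
                if 0 < sum(labels) < n:
                    for scores in itertools.product(score_levels, repeat=n):
                        assert auc(np.array(labels), np.array(scores)) == pytest.approx(
                            auc_all_pairs(labels, scores)
                        )
        rng = np.random.default_rng(0)
        for n in range(5, 13):
            for _ in range(50):
                labels = rng.integers(0, 2, n)
                if labels.min() == labels.max():
                    continue
                scores = rng.choice([0.1, 0.4, 0.4, 0.8, 0.9], n)
                assert auc(labels, scores) == pytest.approx(
                    auc_all_pairs(labels, scores)
                )


class TestLatency:
    def test_detected_at_onset_epoch(self):
        lat = detection_latency([0, 1, 1, 0], [0, 1, 0, 0])
        assert lat == [0.0]

    def test_never_detected_is_undefined(self):
        lat = detection_latency([0, 1, 1, 0], [1, 0, 0, 1])
        assert len(lat) == 1 and np.isnan(lat[0])

    def test_delayed_detection_in_seconds(self):
        labels = [0, 1, 1, 1, 1, 1, 0]
        preds = [0, 0, 0, 0, 1, 1, 0]
        assert detection_latency(labels, preds) == [6.0]

    def test_multiple_events(self):
        labels = [1, 1, 0, 0, 1, 1]
        preds = [0, 1, 0, 0, 1, 0]
        assert detection_latency(labels, preds) == [2.0, 0.0]

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            detection_latency([0, 1], [1])


class TestSummarize:
    def make_rows(self, sens, spes):
        return pd.DataFrame(
            {
                "patient": [f"p{i}" for i in range(len(sens))],
                "sen": sens, "spe": spes,
                "gmean": np.sqrt(np.array(sens) * np.array(spes)),
                "acc": spes, "auc": spes, "latency_s": 2.0,
            }
        )

    def test_summary_gmean_is_gmean_of_means(self):
        # two patients whose mean sen/spe are 0.796 / 0.860
        rows = self.make_rows([0.792, 0.800], [0.850, 0.870])
        out = summarize(rows)
        mean_row = out[out["patient"] == "mean"].iloc[0]
        assert mean_row["sen"] == pytest.approx(0.796)
        assert mean_row["gmean"] == pytest.approx(np.sqrt(0.796 * 0.860))
        assert mean_row["gmean"] == pytest.approx(0.827, abs=5e-4)

    def test_identical_rows_have_zero_sem(self):
        rows = self.make_rows([0.9, 0.9, 0.9], [0.8, 0.8, 0.8])
        sem_row = summarize(rows)[lambda d: d["patient"] == "sem"].iloc[0]
        assert sem_row["sen"] == pytest.approx(0.0, abs=1e-12)
        assert sem_row["spe"] == pytest.approx(0.0, abs=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            summarize(self.make_rows([0.9], [0.8]))


class TestLOPOSplits:
    def test_one_fold_per_patient(self):
        ids = [f"chb{i:02d}" for i in range(1, 25)]
        folds = lopo_splits(ids, seed=0)
        assert len(folds) == 24
        assert sorted(f.test_patient for f in folds) == sorted(ids)

    def test_test_patient_excluded_from_training(self):
        folds = lopo_splits(["a", "b", "c"], seed=0)
        for f in folds:
            assert f.test_patient not in f.train_patients
            assert set(f.train_patients) | {f.test_patient} == {"a", "b", "c"}

    def test_deterministic_under_seed(self):
        a = lopo_splits(["a", "b", "c"], seed=5)
        b = lopo_splits(["a", "b", "c"], seed=5)
        assert a == b

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            lopo_splits(["only"])

    def test_fold_spec_rejects_leaky_fold(self):
        with pytest.raises(ValueError, match="test patient"):
            FoldSpec(test_patient="a", train_patients=("a", "b"))

    def test_epoch_partition_is_exact(self):
        rng = np.random.default_rng(0)
        eps = EpochSet(
            epochs=rng.standard_normal((30, 32, 16)),
            channel_names=list(CANONICAL_32),
            labels=rng.integers(0, 2, 30),
            patient_ids=np.repeat(["a", "b", "c"], 10),
            epoch_start_s=np.tile(np.arange(10) * 2.0, 3),
        )
        fold = lopo_splits(["a", "b", "c"], seed=1)[0]
        train, val, test = split_fold_epochs(fold, eps)
        assert set(test.patient_ids) == {fold.test_patient}
        assert fold.test_patient not in set(train.patient_ids) | set(val.patient_ids)
        assert train.n_epochs + val.n_epochs + test.n_epochs == 30
        assert val.n_epochs == round(0.2 * 20)


class TestTrainFold:
    def test_history_covers_every_epoch_and_selection_is_best(self, trained_fold):
        hist = trained_fold["history"]
        assert len(hist.train_acc) == len(hist.val_acc) == 8
        assert hist.val_acc[hist.best_epoch] >= hist.val_acc[-1]

    def test_same_seed_selects_same_checkpoint(self, tiny_model_config):
        from sefcn.preprocess import preprocess_record
        from sefcn.simulate import SeizureSpec, SimConfig, generate_cohort

        template = SimConfig(
            duration_s=48.0,
            seizures=(SeizureSpec(20.0, 44.0, (1, 2), 6.0, 3.0),),
        )
        records = generate_cohort(2, template, seed=3)
        eps = EpochSet.concatenate([preprocess_record(r) for r in records])
        fold = lopo_splits(sorted({str(p) for p in eps.patient_ids}), seed=3)[0]
        _, hist_a, _ = train_fold(fold, eps, tiny_model_config, n_epochs=3)
        _, hist_b, _ = train_fold(fold, eps, tiny_model_config, n_epochs=3)
        assert hist_a.best_epoch == hist_b.best_epoch
        assert hist_a.val_acc == hist_b.val_acc

    def test_single_class_training_rejected(self, tiny_model_config):
        eps = EpochSet(
            epochs=np.zeros((20, 32, 256)),
            channel_names=list(CANONICAL_32),
            labels=np.zeros(20, dtype=int),
            patient_ids=np.repeat(["a", "b"], 10),
            epoch_start_s=np.tile(np.arange(10) * 2.0, 2),
        )
        fold = lopo_splits(["a", "b"], seed=0)[0]
        with pytest.raises(ValueError, match="single class"):
            train_fold(fold, eps, tiny_model_config, n_epochs=1)
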