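import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from sefcn.interpret import (
    ChannelWeightReport,
    channel_weights,
    extract_feature_matrix,
    interpret_record,
    map_channels_to_regions,
    weight_matrix,
)
from sefcn.model import ModelConfig, build_model
from sefcn.montage import CANONICAL_32, electrode_region
from sefcn.preprocess import EpochSet


def weight_matrix_oracle(b):
    """Two-loop reference for the max-abs row normalization."""
    out = np.zeros_like(b, dtype=float)
    for i in range(b.shape[0]):
        row_max = max(abs(b[i, j]) for j in range(b.shape[1]))
        for j in range(b.shape[1]):
            out[i, j] = abs(b[i, j]) / row_max if row_max > 0 else 0.0
    return out


def make_epochs(n, n_rows=32, start=0.0, patient="p1"):
    rng = np.random.default_rng(0)
    return EpochSet(
        epochs=rng.standard_normal((n, n_rows, 256)),
        channel_names=list(CANONICAL_32[:n_rows]),
        patient_ids=np.array([patient] * n),
        epoch_start_s=start + np.arange(n) * 2.0,
    )


class TestWeightMatrix:
    def test_hand_example(self):
        W = weight_matrix(np.array([[1.0, -2.0, 0.5]]))
        np.testing.assert_allclose(W.C, [[0.5, 1.0, 0.25]])

    def test_constant_row_normalizes_to_ones(self):
        W = weight_matrix(np.full((1, 4), 3.3))
        np.testing.assert_array_equal(W.C, 1.0)

    def test_zero_row_maps_to_zero(self):
        W = weight_matrix(np.zeros((2, 5)))
        np.testing.assert_array_equal(W.C, 0.0)

    def test_matches_two_loop_oracle_exactly(self):
        b = np.random.default_rng(1).standard_normal((6, 9))
        np.testing.assert_array_equal(weight_matrix(b).C, weight_matrix_oracle(b))

    @given(
        b=hnp.arrays(
            dtype=np.float64,
            shape=st.tuples(st.integers(1, 6), st.integers(1, 12)),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_range_and_row_maximum_invariants(self, b):
        C = weight_matrix(b).C
        assert np.all((C >= 0) & (C <= 1))
        for i in range(b.shape[0]):
            if np.any(b[i] != 0):
                assert C[i].max() == 1.0

    def test_row_scale_invariance(self):
        b = np.random.default_rng(2).standard_normal((4, 8))
        for k in (-3.0, 0.25, 100.0):
            np.testing.assert_allclose(weight_matrix(k * b).C, weight_matrix(b).C)

    def test_idempotent_on_own_output(self):
        b = np.random.default_rng(3).standard_normal((4, 8))
        C = weight_matrix(b).C
        np.testing.assert_allclose(weight_matrix(C).C, C)


@pytest.fixture(scope="module")
def model():
    return build_model(ModelConfig(conv_filters=(4, 6, 8), se_reduction=2, seed=0))


class TestExtractFeatureMatrix:

    def test_ten_epochs_give_2560_columns(self, model):
        fm = extract_feature_matrix(model, make_epochs(10))
        assert fm.b.shape == (32, 2560)

    def test_single_epoch_gives_256_columns(self, model):
        fm = extract_feature_matrix(model, make_epochs(1))
        assert fm.b.shape == (32, 256)

    def test_row_order_is_canonical(self, model):
        fm = extract_feature_matrix(model, make_epochs(2))
        assert fm.row_labels == list(CANONICAL_32)

    def test_gap_rejected_with_position(self, model):
        eps = make_epochs(4)
        eps.epoch_start_s = np.array([0.0, 2.0, 6.0, 8.0])  # gap after epoch 1
        with pytest.raises(ValueError, match="epoch 2"):
            extract_feature_matrix(model, eps)

    def test_mixed_patients_rejected(self, model):
        eps = make_epochs(4)
        eps.patient_ids = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="single record"):
            extract_feature_matrix(model, eps)


class TestChannelWeights:
    def test_identical_rows_tie_broken_by_canonical_order(self):
        W = weight_matrix(np.ones((32, 10)))
        W.row_labels = list(CANONICAL_32)
        report = channel_weights(W)
        assert report.table["rank"].tolist() == list(range(1, 24))
        assert report.table["channel"].tolist() == list(CANONICAL_32[:23])

    def test_dominant_row_ranked_first_with_unit_score(self):
        b = np.zeros((32, 10))
        b[5] = 1.0
        W = weight_matrix(b)
        W.row_labels = list(CANONICAL_32)
        report = channel_weights(W)
        top = report.table.iloc[0]
        assert top["channel"] == CANONICAL_32[5]
        assert top["weight"] == 1.0

    def test_padding_rows_excluded_from_ranking(self):
        W = weight_matrix(np.ones((32, 4)))
        W.row_labels = list(CANONICAL_32)
        report = channel_weights(W)
        assert len(report.table) == 23
        assert not report.table["channel"].str.startswith("PAD").any()

    def test_aggregations(self):
        b = np.array([[0.0, 1.0], [0.5, 0.5]])
        W = weight_matrix(b)
        assert channel_weights(W, "mean").table["weight"].max() == 1.0
        with pytest.raises(ValueError, match="aggregation"):
            channel_weights(W, "median")


class TestRegionMapping:
    def make_report(self, channels_ranked):
        table = pd.DataFrame(
            {
                "channel": channels_ranked,
                "row": range(len(channels_ranked)),
                "weight": np.linspace(1, 0.1, len(channels_ranked)),
                "rank": range(1, len(channels_ranked) + 1),
            }
        )
        return ChannelWeightReport(table=table)

    def test_top_channel_flags_both_electrodes(self):
        out = map_channels_to_regions(self.make_report(["FZ-CZ", "T7-P7"]), top_k=1)
        assert out["flagged_electrodes"] == ["FZ", "CZ"]

    def test_ft_pair_parsed(self):
        out = map_channels_to_regions(self.make_report(["FT9-FT10"]), top_k=1)
        assert out["flagged_electrodes"] == ["FT9", "FT10"]
        assert "left frontotemporal" in out["flagged_regions"]
        assert "right frontotemporal" in out["flagged_regions"]

    def test_padding_label_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="PAD_3"):
            out = map_channels_to_regions(self.make_report(["PAD_3", "FZ-CZ"]))
        assert all(c["channel"] != "PAD_3" for c in out["channels"])

    def test_electrode_region_lookup(self):
        assert electrode_region("FZ") == "midline frontal"
        assert electrode_region("T8") == "right temporal"
        assert electrode_region("FT9") == "left frontotemporal"


class TestWindowSelection:
    def test_pre_onset_window_ends_at_onset(self, model):
        eps = make_epochs(30)  # covers [0, 60) s
        W_post, _, _ = interpret_record(model, eps, onset_s=40.0)
        W_pre, _, _ = interpret_record(model, eps, onset_s=40.0, pre_onset=True)
        assert W_post.C.shape == W_pre.C.shape == (32, 2560)
        # the two windows cover disjoint epochs, so weights differ
        assert not np.allclose(W_post.C, W_pre.C)

    def test_window_beyond_record_rejected(self, model):
        eps = make_epochs(5)
        with pytest.raises(ValueError, match="too short"):
            interpret_record(model, eps, onset_s=8.0)


class TestRecoveryOnTrainedModel:
    def test_injected_channels_dominate_weight_report(self, trained_fold):
        """The channels carrying the simulated discharge out-rank the rest."""
        model = trained_fold["model"]
        test = trained_fold["test"]
        W, report, regions = interpret_record(model, test, onset_s=40.0)
        top2 = set(report.table.head(2)["row"].tolist())
        assert top2 == {3, 7}
        flagged = set(regions["flagged_electrodes"])
        # rows 3 and 7 are P7-O1 and P3-O1
        assert {"P7", "O1", "P3"} <= flagged
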