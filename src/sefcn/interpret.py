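"""Channel-level interpretability from the final upsampled score map.

Because every convolution in the network acts along time only, each
electrode row of the final transposed-convolution map is driven by that
row's input signal (up to global batch statistics and the SE gates,
which are shared across rows).  Concatenating the seizure-class slice
of consecutive epochs' final maps therefore yields a channels x time
activation matrix whose rows can be compared.

The weight matrix is the max-abs row normalization of that matrix:
every entry is replaced by its absolute value divided by the row's
maximum absolute value, mapping each row into [0, 1] with the row
maximum at exactly 1.  Averaging each row over time scores the
channel's contribution; bipolar labels are then mapped onto 10-20
electrodes and cortical regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SEFCN
from .montage import electrode_region, is_padding, split_bipolar
from .preprocess import EpochSet
from .evaluate import standardized


@dataclass
class DeconvFeatureMatrix:
    """Seizure-class activations of the final deconvolution, channels x time."""

    b: np.ndarray  # (n_rows, t)
    row_labels: list[str]
    class_index: int
    fs: float
    start_s: float

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.b.ndim != 2 or self.b.shape[0] != len(self.row_labels):
            raise ValueError("feature matrix must be (n_rows, t) with row labels")


@dataclass
class WeightMatrix:
    """Row-normalized absolute activations; every entry in [0, 1]."""

    C: np.ndarray
    row_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.row_labels)


@dataclass
class ChannelWeightReport:
    """Per-channel aggregate weights and ranking (padding rows excluded)."""

    table: pd.DataFrame  # columns: channel, weight, rank
    aggregation: str = "mean"

    def top(self, k: int = 3) -> list[str]:
        return self.table.nsmallest(k, "rank")["channel"].tolist()


def extract_feature_matrix(
    model: SEFCN,
    consecutive_epochs: EpochSet,
    class_index: int = 1,
    rtol_s: float = 1e-6,
) -> DeconvFeatureMatrix:
    """Concatenate final-deconvolution maps of time-contiguous epochs.

    The epochs must come from a single record and be strictly contiguous
    (each starting where the previous one ended); 10 consecutive 2-s
    epochs at 128 Hz give a 32 x 2560 matrix.  ``class_index`` selects
    which of the two class score channels is read (1 = seizure).
    """
    eps = consecutive_epochs
    if eps.n_epochs == 0:
        raise ValueError("no epochs supplied")
    if eps.patient_ids is not None and len(set(np.asarray(eps.patient_ids))) > 1:
        raise ValueError("epochs must come from a single record")
    if eps.epoch_start_s is not None:
        starts = np.asarray(eps.epoch_start_s, dtype=float)
        expect = starts[0] + np.arange(eps.n_epochs) * eps.window_s
        gaps = np.flatnonzero(np.abs(starts - expect) > rtol_s)
        if len(gaps):
            g = gaps[0]
            raise ValueError(
                f"epochs are not contiguous: epoch {g} starts at {starts[g]} s, "
                f"expected {expect[g]} s"
            )
    if not 0 <= class_index < 2:
        raise ValueError("class_index must be 0 or 1")
    maps = model.final_deconv_maps(standardized(model, eps))  # (N, H, W, 2)
    b = np.concatenate([m[..., class_index] for m in maps], axis=1)  # (H, N*W)
    return DeconvFeatureMatrix(
        b=b,
        row_labels=list(eps.channel_names),
        class_index=class_index,
        fs=eps.fs,
        start_s=float(starts[0]) if eps.epoch_start_s is not None else 0.0,
    )


def weight_matrix(b: DeconvFeatureMatrix | np.ndarray,
                  row_labels: list[str] | None = None) -> WeightMatrix:
    """Max-abs row normalization: C[i, j] = |b[i, j]| / max_j |b[i, j]|.

    All-zero rows (padding channels) map to all-zero rows rather than
    dividing by zero.  The result is invariant to any per-row rescaling
    of the input, and idempotent on its own output.
    """
    if isinstance(b, DeconvFeatureMatrix):
        row_labels = b.row_labels
        mat = b.b
    else:
        mat = np.asarray(b, dtype=np.float64)
        if row_labels is None:
            row_labels = [f"row{i}" for i in range(mat.shape[0])]
    absb = np.abs(mat)
    rowmax = absb.max(axis=1, keepdims=True)
    safe = np.where(rowmax > 0, rowmax, 1.0)
    return WeightMatrix(C=absb / safe, row_labels=list(row_labels))


_AGGREGATIONS = {
    "mean": lambda rows: rows.mean(axis=1),
    "max": lambda rows: rows.max(axis=1),
    "p95": lambda rows: np.percentile(rows, 95, axis=1),
}


def channel_weights(
    W: WeightMatrix, aggregation: str = "mean"
) -> ChannelWeightReport:
    """Aggregate each channel's weight row over time and rank channels.

    Padding rows are excluded.  Ranks are descending by score; ties are
    broken by canonical row order (stable), so identical rows receive
    consecutive ranks in layout order.
    """
    if aggregation not in _AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    keep = [i for i, name in enumerate(W.row_labels) if not is_padding(name)]
    scores = _AGGREGATIONS[aggregation](W.C[keep])
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(keep), dtype=int)
    ranks[order] = np.arange(1, len(keep) + 1)
    table = pd.DataFrame(
        {
            "channel": [W.row_labels[i] for i in keep],
            "row": keep,
            "weight": scores,
            "rank": ranks,
        }
    ).sort_values("rank", ignore_index=True)
    return ChannelWeightReport(table=table, aggregation=aggregation)


def map_channels_to_regions(
    report: ChannelWeightReport, top_k: int = 3
) -> dict:
    """Map top-ranked bipolar channels onto 10-20 electrodes and regions.

    Each bipolar channel contributes both of its electrodes; a cortical
    region is flagged when any of its electrodes belongs to a top-k
    channel.  Unparseable labels are skipped with a warning.
    """
    flagged_electrodes: list[str] = []
    flagged_regions: list[str] = []
    per_channel = []
    for _, row in report.table.iterrows():
        pair = split_bipolar(row["channel"])
        if pair is None:
            continue
        regions = [electrode_region(e) for e in pair]
        per_channel.append(
            {
                "channel": row["channel"],
                "rank": int(row["rank"]),
                "weight": float(row["weight"]),
                "electrodes": list(pair),
                "regions": regions,
            }
        )
        if row["rank"] <= top_k:
            for e, r in zip(pair, regions):
                if e not in flagged_electrodes:
                    flagged_electrodes.append(e)
                if r not in flagged_regions:
                    flagged_regions.append(r)
    return {
        "top_k": top_k,
        "flagged_electrodes": flagged_electrodes,
        "flagged_regions": flagged_regions,
        "channels": per_channel,
    }


def interpret_record(
    model: SEFCN,
    epochs: EpochSet,
    onset_s: float,
    window_s: float = 20.0,
    class_index: int = 1,
    pre_onset: bool = False,
    aggregation: str = "mean",
) -> tuple[WeightMatrix, ChannelWeightReport, dict]:
    """Full interpretability pass around one seizure onset.

    Takes the ``window_s`` seconds of epochs starting at the seizure
    onset (or ending at it, with ``pre_onset=True``), builds the weight
    matrix, and returns (weight matrix, channel report, region map).
    """
    n_needed = int(round(window_s / epochs.window_s))
    starts = np.asarray(epochs.epoch_start_s, dtype=float)
    t0 = onset_s - window_s if pre_onset else onset_s
    first = int(np.argmin(np.abs(starts - t0)))
    idx = np.arange(first, first + n_needed)
    if idx[-1] >= epochs.n_epochs:
        raise ValueError(
            f"record too short for a {window_s} s window at {t0} s"
        )
    window = epochs.subset(idx)
    fm = extract_feature_matrix(model, window, class_index)
    W = weight_matrix(fm)
    report = channel_weights(W, aggregation)
    regions = map_channels_to_regions(report)
    return W, report, regions


def save_heatmap(W: WeightMatrix, path, title: str = "Channel weight matrix") -> None:
    """Write the channels x time weight image with row labels (PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(W.C, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_yticks(range(len(W.row_labels)))
    ax.set_yticklabels(W.row_labels, fontsize=5)
    ax.set_xlabel("time (samples at 128 Hz)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="normalized weight")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
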