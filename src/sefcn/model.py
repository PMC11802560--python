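"""The SE-FCN seizure classifier.

Topology (input 32 electrode rows x 256 time samples, one implicit
filter channel):

    CNN_1   conv (1,4)/(1,2), 32 filters  -> 32 x 128 x 32   + BN + ReLU
    CNN_2   conv (1,4)/(1,2), 64 filters  -> 32 x  64 x 64   + BN + ReLU
    CNN_3   conv (1,4)/(1,2), 128 filters -> 32 x  32 x 128  + ReLU
    SE      channel gate (reduction r=8)  -> 32 x  32 x 128
    CNN_4   conv (1,1), 2 filters (scores)-> 32 x  32 x 2
    CNN_Transposed_1 deconv (1,4)/(1,2)   -> 32 x  64 x 2
       + CNN_2_1 (1x1 scores of CNN_2 output)        [skip fusion: add]
    CNN_Transposed_2 deconv (1,4)/(1,2)   -> 32 x 128 x 2
       + CNN_1_1 (1x1 scores of CNN_1 output)        [skip fusion: add]
    CNN_Transposed_3 deconv (1,4)/(1,2)   -> 32 x 256 x 2    (final map)
    Flatten -> 16384 -> Dense -> 2 logits -> softmax

Skip fusion is element-wise addition of same-shaped 2-channel score
maps, the FCN-8s convention; it is the only wiring consistent with the
layer shapes above.  The final transposed convolution restores the
input width exactly (any width divisible by 8 is accepted), and its
2-channel output map is exposed per epoch for the interpretability
pipeline.  The attention stage is pluggable: ``attention="se"`` (default)
or ``"identity"`` for the ablated network.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import EpochSet


@dataclass(frozen=True)
class ModelConfig:
    n_rows: int = 32
    n_samples: int = 256
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    conv_kernel: int = 4
    conv_stride: int = 2
    se_reduction: int = 8
    score_channels: int = 2
    attention: str = "se"  # "se" | "identity"
    conv3_activation: bool = True
    dtype: str = "float32"  # compute precision; float64 for gradient audits
    seed: int = 0

    def validate(self) -> None:
        n_stages = len(self.conv_filters)
        if self.n_samples % (self.conv_stride**n_stages) != 0:
            raise ValueError(
                f"input time length {self.n_samples} must be divisible by "
                f"{self.conv_stride**n_stages} (three stride-2 stages)"
            )
        if self.attention not in ("se", "identity"):
            raise ValueError(f"unknown attention block {self.attention!r}")
        if self.score_channels != 2:
            raise ValueError("the classification head is binary: score_channels == 2")


class SEFCN:
    """Fully-convolutional seizure classifier with an SE channel gate."""

    def __init__(self, config: ModelConfig = ModelConfig()) -> None:
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        f1, f2, f3 = config.conv_filters
        k, s = config.conv_kernel, config.conv_stride
        sc = config.score_channels

        self.conv1 = nn.ConvTime(1, f1, k, s, 1, rng)
        self.bn1 = nn.BatchNorm(f1)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.ConvTime(f1, f2, k, s, 1, rng)
        self.bn2 = nn.BatchNorm(f2)
        self.relu2 = nn.ReLU()
        self.conv3 = nn.ConvTime(f2, f3, k, s, 1, rng)
        self.relu3 = nn.ReLU() if config.conv3_activation else nn.Identity()
        if config.attention == "se":
            self.attn: nn.Layer = nn.SEBlock(f3, config.se_reduction, rng)
        else:
            self.attn = nn.Identity()
        self.conv4 = nn.ConvTime(f3, sc, 1, 1, 0, rng)  # 1x1 score layer
        self.score2 = nn.ConvTime(f2, sc, 1, 1, 0, rng)  # CNN_2_1
        self.score1 = nn.ConvTime(f1, sc, 1, 1, 0, rng)  # CNN_1_1
        self.deconv1 = nn.ConvTransposeTime(sc, sc, k, s, 1, rng)
        self.deconv2 = nn.ConvTransposeTime(sc, sc, k, s, 1, rng)
        self.deconv3 = nn.ConvTransposeTime(sc, sc, k, s, 1, rng)
        self.head = nn.Dense(config.n_rows * config.n_samples * sc, sc, rng)

        self.layers: list[nn.Layer] = [
            self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2,
            self.conv3, self.relu3, self.attn, self.conv4, self.score2,
            self.score1, self.deconv1, self.deconv2, self.deconv3, self.head,
        ]
        dt = np.dtype(config.dtype)
        for layer in self.layers:
            for k_ in layer.params:
                layer.params[k_] = layer.params[k_].astype(dt)
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = layer.running_mean.astype(dt)
                layer.running_var = layer.running_var.astype(dt)

    # ---------------------------------------------------------------- forward
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.config.dtype)
        cfg = self.config
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != cfg.n_rows:
            raise ValueError(
                f"expected batch shaped (N, {cfg.n_rows}, {cfg.n_samples}); "
                f"got {x.shape}"
            )
        if x.shape[2] % (cfg.conv_stride ** len(cfg.conv_filters)) != 0:
            raise ValueError(
                f"time length {x.shape[2]} not divisible by "
                f"{cfg.conv_stride ** len(cfg.conv_filters)}"
            )
        return x

    def forward(
        self, batch: np.ndarray | EpochSet, train: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Run the network.

        Returns ``(probs, final_map)``: per-epoch class probabilities
        (N, 2) summing to 1, and the final transposed-convolution map
        (N, rows, time, 2) consumed by the interpretability module.
        """
        if isinstance(batch, EpochSet):
            batch = batch.epochs
        x = self._check_input(batch)[..., None]  # (N, H, W, 1)

        a1 = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        a2 = self.relu2.forward(self.bn2.forward(self.conv2.forward(a1, train), train), train)
        a3 = self.relu3.forward(self.conv3.forward(a2, train), train)
        a3 = self.attn.forward(a3, train)
        scores = self.conv4.forward(a3, train)
        d1 = self.deconv1.forward(scores, train) + self.score2.forward(a2, train)
        d2 = self.deconv2.forward(d1, train) + self.score1.forward(a1, train)
        d3 = self.deconv3.forward(d2, train)
        flat = d3.reshape(d3.shape[0], -1)
        logits = self.head.forward(flat, train)
        self._final_map_shape = d3.shape
        return nn.softmax(logits), d3

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate d loss / d logits through the whole network."""
        dflat = self.head.backward(dlogits)
        dd3 = dflat.reshape(self._final_map_shape)
        dd2 = self.deconv3.backward(dd3)
        da1_skip = self.score1.backward(dd2)
        dd1 = self.deconv2.backward(dd2)
        da2_skip = self.score2.backward(dd1)
        dscores = self.deconv1.backward(dd1)
        da3 = self.conv4.backward(dscores)
        da3 = self.attn.backward(da3)
        da2 = self.conv2.backward(
            self.bn2.backward(self.relu2.backward(
                self.conv3.backward(self.relu3.backward(da3)) + da2_skip))
        )
        self.conv1.backward(
            self.bn1.backward(self.relu1.backward(da2 + da1_skip))
        )

    def predict_proba(self, batch: np.ndarray | EpochSet, batch_size: int = 256) -> np.ndarray:
        if isinstance(batch, EpochSet):
            batch = batch.epochs
        out = []
        for i in range(0, len(batch), batch_size):
            probs, _ = self.forward(batch[i : i + batch_size], train=False)
            out.append(probs)
        return np.concatenate(out) if out else np.empty((0, 2))

    def predict(self, batch: np.ndarray | EpochSet) -> np.ndarray:
        return self.predict_proba(batch).argmax(axis=1)

    def final_deconv_maps(self, batch: np.ndarray | EpochSet, batch_size: int = 256) -> np.ndarray:
        """Per-epoch final upsampled score maps, shape (N, rows, time, 2)."""
        if isinstance(batch, EpochSet):
            batch = batch.epochs
        out = []
        for i in range(0, len(batch), batch_size):
            _, maps = self.forward(batch[i : i + batch_size], train=False)
            out.append(maps)
        cfg = self.config
        return (np.concatenate(out) if out
                else np.empty((0, cfg.n_rows, cfg.n_samples, 2)))

    # ------------------------------------------------------------- state
    def get_state(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                state[f"layer{i}_{k}"] = v.copy()
            if isinstance(layer, nn.BatchNorm):
                state[f"layer{i}_running_mean"] = layer.running_mean.copy()
                state[f"layer{i}_running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k][...] = state[f"layer{i}_{k}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = state[f"layer{i}_running_mean"]
                layer.running_var[...] = state[f"layer{i}_running_var"]

    def save(self, path: str | Path) -> None:
        """Checkpoint: weights (.npz) + architecture manifest (.json)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.get_state())
        manifest = {
            "config": asdict(self.config),
            "shapes": {k: list(v) for k, v in self.shape_manifest().items()},
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SEFCN":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        cfg_d = manifest["config"]
        cfg_d["conv_filters"] = tuple(cfg_d["conv_filters"])
        model = cls(ModelConfig(**cfg_d))
        with np.load(path.with_suffix(".npz")) as npz:
            model.set_state({k: npz[k] for k in npz.files})
        return model

    # ---------------------------------------------------------- introspection
    def shape_manifest(self, n_samples: int | None = None) -> dict[str, tuple[int, ...]]:
        """Expected output shape (rows, time, filters) of every stage."""
        cfg = self.config
        h = cfg.n_rows
        w = cfg.n_samples if n_samples is None else n_samples
        f1, f2, f3 = cfg.conv_filters
        sc = cfg.score_channels
        shapes = {
            "Input": (h, w),
            "CNN_1": (h, w // 2, f1),
            "Batch_Normalization_1": (h, w // 2, f1),
            "CNN_2": (h, w // 4, f2),
            "Batch_Normalization_2": (h, w // 4, f2),
            "CNN_3": (h, w // 8, f3),
            "SE_module": (h, w // 8, f3),
            "CNN_4": (h, w // 8, sc),
            "CNN_Transposed_1": (h, w // 4, sc),
            "CNN_Transposed_2": (h, w // 2, sc),
            "CNN_Transposed_3": (h, w, sc),
            "CNN_1_1": (h, w // 2, sc),
            "CNN_2_1": (h, w // 4, sc),
            "Flatten": (h * w * sc,),
            "MLP_head": (sc,),
        }
        return shapes

    def measured_shapes(self, n_samples: int | None = None) -> dict[str, tuple[int, ...]]:
        """Actually run one example through and record every stage's shape."""
        cfg = self.config
        w = cfg.n_samples if n_samples is None else n_samples
        x = np.zeros((1, cfg.n_rows, w))[..., None]
        out: dict[str, tuple[int, ...]] = {"Input": (cfg.n_rows, w)}
        c1 = self.conv1.forward(x)
        out["CNN_1"] = c1.shape[1:]
        b1 = self.bn1.forward(c1)
        out["Batch_Normalization_1"] = b1.shape[1:]
        a1 = self.relu1.forward(b1)
        c2 = self.conv2.forward(a1)
        out["CNN_2"] = c2.shape[1:]
        b2 = self.bn2.forward(c2)
        out["Batch_Normalization_2"] = b2.shape[1:]
        a2 = self.relu2.forward(b2)
        a3 = self.relu3.forward(self.conv3.forward(a2))
        out["CNN_3"] = a3.shape[1:]
        a3 = self.attn.forward(a3)
        out["SE_module"] = a3.shape[1:]
        scores = self.conv4.forward(a3)
        out["CNN_4"] = scores.shape[1:]
        s2 = self.score2.forward(a2)
        out["CNN_2_1"] = s2.shape[1:]
        s1 = self.score1.forward(a1)
        out["CNN_1_1"] = s1.shape[1:]
        d1 = self.deconv1.forward(scores) + s2
        out["CNN_Transposed_1"] = d1.shape[1:]
        d2 = self.deconv2.forward(d1) + s1
        out["CNN_Transposed_2"] = d2.shape[1:]
        d3 = self.deconv3.forward(d2)
        out["CNN_Transposed_3"] = d3.shape[1:]
        flat = d3.reshape(1, -1)
        out["Flatten"] = (flat.shape[1],)
        out["MLP_head"] = (self.head.forward(flat).shape[1],)
        return {k: tuple(int(i) for i in v) for k, v in out.items()}

    def clone_state(self) -> dict:
        return copy.deepcopy(self.get_state())


def build_model(config: ModelConfig = ModelConfig()) -> SEFCN:
    """Construct the classifier; rejects invalid input geometry."""
    return SEFCN(config)
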