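"""SFERA: segmentation-free regression of ventricular volumes.

The network consumes a short-axis stack of variable length, each slice a
2-channel (ED, ES) 150×150 frame:

* a residual CNN encoder (five blocks, channels doubling from 32, each block
  two 3×3 convolutions with batch normalization and ReLU, an identity or 1×1
  projection shortcut, then 2×2 max pooling) maps every slice to a flat
  feature vector reduced linearly to 128 elements;
* a bidirectional LSTM aggregates the base-to-apex feature sequence into a
  fixed-length stack embedding (concatenated final states of both
  directions);
* a linear head predicts normalized (EDV, ESV) during end-to-end training;
  after training a Bayesian ridge regressor can be fitted on frozen
  embeddings and used as the deployed head.

Training minimizes the root-mean-squared error over the normalized volume
pair with the Rectified Adam optimizer.  A width-reduced configuration (an
average-pooling stem, narrower channels and features) is available for
CPU-scale experiments.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.linear_model import BayesianRidge

from ._autodiff import Tensor, concat, no_grad
from ._nn import LSTM, BatchNorm2d, Conv2d, Linear, Module, RAdam
from .preprocessing import SliceSample, VolumeNormalizer
from .volumetrics import ejection_fraction

__all__ = [
    "EncoderConfig",
    "TrainConfig",
    "PredictionResult",
    "SferaModel",
    "build_model",
    "train",
    "fit_ridge_head",
    "pretrain_finetune",
    "reduced_config",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the per-slice encoder and the recurrent aggregator.

    Defaults give the full-size network: five residual blocks with channel
    counts 32, 64, 128, 256, 512, features reduced to 128, LSTM hidden size
    128 per direction.  ``stem_pool`` > 1 prepends an average-pooling stem
    that shrinks the spatial grid before the first block (used by the
    reduced CPU-scale configuration).
    """

    n_blocks: int = 5
    first_channels: int = 32
    feature_dim: int = 128
    input_channels: int = 2
    input_size: int = 150
    lstm_hidden: int = 128
    convs_per_block: int = 2
    stem_pool: int = 1

    @property
    def block_channels(self) -> tuple[int, ...]:
        return tuple(self.first_channels * 2**k for k in range(self.n_blocks))

    @property
    def spatial_chain(self) -> tuple[int, ...]:
        """Spatial side length after the stem and after each block's pool."""
        s = self.input_size // self.stem_pool
        chain = [s]
        for _ in range(self.n_blocks):
            s = s // 2
            chain.append(s)
        return tuple(chain)


@dataclass(frozen=True)
class TrainConfig:
    """End-to-end training recipe (Rectified Adam, RMSE loss)."""

    epochs: int = 20
    lr: float = 1e-3
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass(frozen=True)
class PredictionResult:
    """Normalized and physical volume predictions for one subject."""

    edv_norm: float
    esv_norm: float
    edv_ml: float
    esv_ml: float
    ef: float


def reduced_config() -> EncoderConfig:
    """Width-reduced encoder for CPU-scale training experiments."""
    return EncoderConfig(
        first_channels=6,
        feature_dim=48,
        lstm_hidden=48,
        stem_pool=4,
    )


class _ResidualBlock(Module):
    """Conv–BN–ReLU ×2 with shortcut, then 2×2 max pooling."""

    def __init__(self, in_ch: int, out_ch: int, n_convs: int, rng: np.random.Generator):
        self.convs = [
            Conv2d(in_ch if i == 0 else out_ch, out_ch, 3, rng) for i in range(n_convs)
        ]
        self.bns = [BatchNorm2d(out_ch) for _ in range(n_convs)]
        self.proj = None if in_ch == out_ch else Conv2d(in_ch, out_ch, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        out = x
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            out = bn(conv(out))
            if i < len(self.convs) - 1:
                out = out.relu()
        shortcut = x if self.proj is None else self.proj(x)
        return (out + shortcut).relu().maxpool2()


class _SliceEncoder(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        channels = cfg.block_channels
        ins = (cfg.input_channels,) + channels[:-1]
        self.blocks = [
            _ResidualBlock(i, o, cfg.convs_per_block, rng)
            for i, o in zip(ins, channels)
        ]
        side = cfg.spatial_chain[-1]
        if side < 1:
            raise ValueError(
                f"input {cfg.input_size} with stem_pool {cfg.stem_pool} collapses "
                f"to zero spatial extent after {cfg.n_blocks} pooling stages"
            )
        self.flat_dim = channels[-1] * side * side
        self.reduce = Linear(self.flat_dim, cfg.feature_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """(N, 2, H, W) batch of slices -> (N, feature_dim) features."""
        out = x.avgpool(self.cfg.stem_pool)
        for block in self.blocks:
            out = block(out)
        return self.reduce(out.reshape(out.shape[0], self.flat_dim))


class _StackAggregator(Module):
    """Bidirectional LSTM over the base-to-apex feature sequence."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.fwd = LSTM(cfg.feature_dim, cfg.lstm_hidden, rng)
        self.bwd = LSTM(cfg.feature_dim, cfg.lstm_hidden, rng)
        self.embedding_dim = 2 * cfg.lstm_hidden

    def __call__(self, features: Tensor) -> Tensor:
        """(T, feature_dim) sequence -> (2*hidden,) stack embedding."""
        if features.shape[0] < 1:
            raise ValueError("empty slice sequence")
        reversed_feats = features[::-1]
        return concat([self.fwd(features), self.bwd(reversed_feats)], axis=0)


class SferaModel(Module):
    """Encoder + biLSTM aggregator + volume head.

    ``head`` selects the inference path: the linear head trained end to end,
    or a Bayesian ridge pair fitted on frozen embeddings by
    :func:`fit_ridge_head`.
    """

    def __init__(self, cfg: EncoderConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.encoder = _SliceEncoder(cfg, rng)
        self.aggregator = _StackAggregator(cfg, rng)
        self.linear_head = Linear(self.aggregator.embedding_dim, 2, rng)
        self.ridge_heads: tuple[BayesianRidge, BayesianRidge] | None = None
        self.head: str = "linear"

    # -- forward paths -----------------------------------------------------

    def encode_slices(self, samples: list[SliceSample]) -> Tensor:
        """Encode one subject's slices into a (T, feature_dim) sequence."""
        batch = Tensor(np.stack([s.pixels for s in samples]))
        return self.encoder(batch)

    def embed(self, samples: list[SliceSample]) -> Tensor:
        return self.aggregator(self.encode_slices(samples))

    def forward_subjects(self, subjects: list[list[SliceSample]]) -> Tensor:
        """Predict normalized (EDV, ESV) for a batch of subjects.

        All slices of the batch share one encoder pass (one batch-norm
        batch); the aggregator runs per subject on its own sequence length.
        """
        counts = [len(s) for s in subjects]
        if min(counts) < 1:
            raise ValueError("every subject needs at least one slice")
        flat = [s for subj in subjects for s in subj]
        features = self.encoder(Tensor(np.stack([s.pixels for s in flat])))
        embeddings = []
        offset = 0
        for c in counts:
            embeddings.append(
                self.aggregator(features[offset : offset + c]).reshape(1, -1)
            )
            offset += c
        stacked = concat(embeddings, axis=0)
        return self.linear_head(stacked)

    # -- inference ---------------------------------------------------------

    def predict_normalized(self, samples: list[SliceSample]) -> tuple[float, float]:
        self.eval()
        with no_grad():
            embedding = self.embed(samples)
            if self.head == "ridge":
                if self.ridge_heads is None:
                    raise RuntimeError("ridge head not fitted; call fit_ridge_head")
                e = embedding.data.reshape(1, -1)
                return (
                    float(self.ridge_heads[0].predict(e)[0]),
                    float(self.ridge_heads[1].predict(e)[0]),
                )
            out = self.linear_head(embedding.reshape(1, -1)).data[0]
        return float(out[0]), float(out[1])

    def predict(
        self,
        samples: list[SliceSample],
        normalizer: VolumeNormalizer,
        slice_spacing_mm: float,
    ) -> PredictionResult:
        edv_n, esv_n = self.predict_normalized(samples)
        edv_ml, esv_ml = normalizer.denormalize(edv_n, esv_n, slice_spacing_mm)
        edv_ml = max(edv_ml, 1e-6)
        esv_ml = max(esv_ml, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ef = ejection_fraction(edv_ml, esv_ml)
        return PredictionResult(
            edv_norm=edv_n, esv_norm=esv_n, edv_ml=edv_ml, esv_ml=esv_ml, ef=ef
        )

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = self.state_arrays()
        np.savez_compressed(
            path,
            *arrays,
            _config=np.frombuffer(
                json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8
            ),
        )

    @classmethod
    def load(cls, path) -> "SferaModel":
        with np.load(path) as data:
            cfg = EncoderConfig(**json.loads(bytes(data["_config"]).decode()))
            arrays = [data[k] for k in data.files if k != "_config"]
        model = cls(cfg)
        model.load_state_arrays(arrays)
        return model


def build_model(cfg: EncoderConfig | None = None, seed: int = 0) -> SferaModel:
    return SferaModel(cfg or EncoderConfig(), seed=seed)


Dataset = list[tuple[list[SliceSample], tuple[float, float]]]


def _rmse_loss(pred: Tensor, targets: np.ndarray) -> Tensor:
    diff = pred - Tensor(targets)
    return (diff * diff).mean().sqrt()


def train(
    model: SferaModel,
    dataset: Dataset,
    cfg: TrainConfig,
    log: list[dict] | None = None,
) -> list[dict]:
    """End-to-end training with the linear head.

    ``dataset`` pairs each subject's preprocessed slices with its normalized
    (EDV, ESV) targets.  Returns the per-epoch training log
    (``{"epoch", "loss"}``); pass ``log`` to append across phases.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 subjects to train")
    rng = np.random.default_rng(cfg.seed)
    optimizer = RAdam(model.parameters(), lr=cfg.lr)
    log = log if log is not None else []
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start : start + cfg.batch_size]
            subjects = [dataset[i][0] for i in batch_idx]
            targets = np.array([dataset[i][1] for i in batch_idx])
            model.zero_grad()
            pred = model.forward_subjects(subjects)
            loss = _rmse_loss(pred, targets)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}"
                )
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        log.append({"epoch": epoch, "loss": float(np.mean(losses))})
    return log


def fit_ridge_head(model: SferaModel, dataset: Dataset) -> SferaModel:
    """Fit Bayesian ridge regressors (one per target) on frozen embeddings.

    The encoder and aggregator are untouched; the fitted pair replaces the
    linear head at inference (``model.head == "ridge"``).
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 subjects to fit the ridge head")
    model.eval()
    with no_grad():
        X = np.stack([model.embed(samples).data for samples, _ in dataset])
    y = np.array([t for _, t in dataset])
    heads = (BayesianRidge(), BayesianRidge())
    heads[0].fit(X, y[:, 0])
    heads[1].fit(X, y[:, 1])
    model.ridge_heads = heads
    model.head = "ridge"
    return model


def pretrain_finetune(
    model: SferaModel,
    pretrain_dataset: Dataset,
    finetune_dataset: Dataset,
    pretrain_cfg: TrainConfig,
    finetune_cfg: TrainConfig,
) -> tuple[SferaModel, list[dict]]:
    """Pretrain on one cohort, then finetune on another.

    The finetuning phase continues from the pretrained weights with a fresh
    optimizer state.  Returns the model and the concatenated training log
    (entries tagged with the phase).
    """
    log: list[dict] = []
    phase_log: list[dict] = []
    train(model, pretrain_dataset, pretrain_cfg, log=phase_log)
    log.extend({**e, "phase": "pretrain"} for e in phase_log)
    phase_log = []
    if finetune_cfg.epochs > 0:
        train(model, finetune_dataset, finetune_cfg, log=phase_log)
    log.extend({**e, "phase": "finetune"} for e in phase_log)
    return model, log
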