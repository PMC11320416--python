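"""Staged 3D bottleneck-residual segmentation encoder--decoder.

The encoder follows the 3D ResNet-50 layout: a stride-2 7x7x7 stem with
3x3x3/stride-2 max pooling, then four bottleneck stages.  Stage 1 keeps the
quarter-resolution grid; stage 2 halves it once more; stages 3 and 4 keep
that grid but dilate their 3x3x3 convolutions (rates 2 and 4), so on a
155x280x280 volume the stage grids are 39x70x70 then 20x35x35 for stages
2-4, with 256/512/1024/2048 channels at full width.  The decoder is
deliberately minimal — trilinear upsampling of the final stage back to the
stage-1 grid followed by a 1x1x1 projection to two channels and a voxelwise
softmax — so that representational capacity concentrates in the encoder,
whose weights are reused for feature extraction.

Segmentation training is class-label-blind: the training loop reads only the
image volume of the requested modality and the lesion mask, never the
case-level diagnosis.
"""

from __future__ import annotations


import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import DTYPE
from .volume_io import align_label_to_grid

MIN_INPUT_DIM = 8


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters of the encoder backbone."""

    in_channels: int = 1
    stem_channels: int = 64
    stage_channels: tuple[int, int, int, int] = (256, 512, 1024, 2048)
    stage_strides: tuple[int, int, int, int] = (1, 2, 1, 1)
    stage_dilations: tuple[int, int, int, int] = (1, 1, 2, 4)
    blocks_per_stage: tuple[int, int, int, int] = (3, 4, 6, 3)
    width_scale: float = 1.0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.stage_channels) or self.stem_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if list(self.stage_channels) != sorted(self.stage_channels) or len(
            set(self.stage_channels)
        ) != 4:
            raise ValueError("stage_channels must be strictly increasing")
        if any(b < 1 for b in self.blocks_per_stage):
            raise ValueError("blocks_per_stage must be >= 1")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")

    def scaled(self, channels: int) -> int:
        return max(1, round(channels * self.width_scale))

    @property
    def scaled_stage_channels(self) -> tuple[int, ...]:
        return tuple(self.scaled(c) for c in self.stage_channels)

    def stage_grids(self, input_shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        """Spatial grid of each stage output for a given input volume."""
        grid = tuple(-(-n // 2) for n in input_shape)  # stem, stride 2
        grid = tuple(-(-n // 2) for n in grid)  # max pool, stride 2
        grids = []
        for s in self.stage_strides:
            grid = tuple(-(-n // s) for n in grid)
            grids.append(grid)
        return grids


@dataclass
class StageFeatureSet:
    """Encoder stage outputs: (stage index, feature map (C, D, H, W), grid)."""

    stages: list[tuple[int, np.ndarray, tuple[int, int, int]]]

    def __post_init__(self) -> None:
        indices = [s[0] for s in self.stages]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError("stage indices must be contiguous from 1")

    def get(self, index: int) -> np.ndarray:
        return self.stages[index - 1][1]

    def grid(self, index: int) -> tuple[int, int, int]:
        return self.stages[index - 1][2]


@dataclass
class ProbabilityMap:
    """Voxelwise lesion probability on the stage-1 grid."""

    values: np.ndarray
    logits: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.min() < -1e-6 or v.max() > 1 + 1e-6:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TrainConfig:
    """Segmentation training schedule.

    ``epochs`` defaults to 200 full passes; ``pos_weight`` rescales the
    lesion class in the cross-entropy to counter voxel-level imbalance
    (lesions occupy a few percent of a volume).
    """

    epochs: int = 200
    loss: str = "cross_entropy"  # cross_entropy | dice | ce_plus_dice
    learning_rate: float = 1e-3
    batch_size: int = 4
    seed: int = 0
    early_stop: float | None = None
    pos_weight: float = 20.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss not in ("cross_entropy", "dice", "ce_plus_dice"):
            raise ValueError(f"unknown loss {self.loss!r}")


class _Bottleneck:
    """1x1 -> 3x3x3 (stride/dilation) -> 1x1 residual block with batch norm."""

    def __init__(self, cin: int, cmid: int, cout: int, stride: int, dilation: int,
                 rng: np.random.Generator) -> None:
        self.conv1 = nn.Conv3d(cin, cmid, 1, rng=rng)
        self.n1 = nn.BatchNorm3d(cmid)
        self.r1 = nn.ReLU()
        self.conv2 = nn.Conv3d(cmid, cmid, 3, stride=stride, dilation=dilation, rng=rng)
        self.n2 = nn.BatchNorm3d(cmid)
        self.r2 = nn.ReLU()
        self.conv3 = nn.Conv3d(cmid, cout, 1, rng=rng)
        self.n3 = nn.BatchNorm3d(cout)
        self.r3 = nn.ReLU()
        if stride != 1 or cin != cout:
            self.proj = nn.Conv3d(cin, cout, 1, stride=stride, rng=rng)
            self.nproj = nn.BatchNorm3d(cout)
        else:
            self.proj = None
            self.nproj = None

    def layers(self) -> dict[str, nn.Conv3d | nn.BatchNorm3d]:
        named = {
            "conv1": self.conv1, "n1": self.n1,
            "conv2": self.conv2, "n2": self.n2,
            "conv3": self.conv3, "n3": self.n3,
        }
        if self.proj is not None:
            named["proj"] = self.proj
            named["nproj"] = self.nproj
        return named

    def forward(self, x: np.ndarray, retain: bool = False) -> np.ndarray:
        out = self.r1.forward(self.n1.forward(self.conv1.forward(x, retain), retain), retain)
        out = self.r2.forward(self.n2.forward(self.conv2.forward(out, retain), retain), retain)
        out = self.n3.forward(self.conv3.forward(out, retain), retain)
        if self.proj is not None:
            short = self.nproj.forward(self.proj.forward(x, retain), retain)
        else:
            short = x
        return self.r3.forward(out + short, retain)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.r3.backward(dout)
        dshort = d
        dmain = self.conv3.backward(self.n3.backward(d))
        dmain = self.conv2.backward(self.n2.backward(self.r2.backward(dmain)))
        dmain = self.conv1.backward(self.n1.backward(self.r1.backward(dmain)))
        if self.proj is not None:
            dshort = self.proj.backward(self.nproj.backward(dshort))
        return dmain + dshort


class SegModel:
    """Encoder--decoder with named parameters; see module docstring."""

    def __init__(self, config: EncoderConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        stem_c = config.scaled(config.stem_channels)
        self.stem = nn.Conv3d(
            config.in_channels, stem_c, 7, stride=2, rng=rng, input_grad=False
        )
        self.stem_norm = nn.BatchNorm3d(stem_c)
        self.stem_relu = nn.ReLU()
        self.pool = nn.MaxPool3d(3, 2)
        self.stages: list[list[_Bottleneck]] = []
        cin = stem_c
        for idx in range(4):
            cout = config.scaled(config.stage_channels[idx])
            cmid = max(1, round(config.stage_channels[idx] * config.width_scale / 4))
            blocks = []
            for b in range(config.blocks_per_stage[idx]):
                stride = config.stage_strides[idx] if b == 0 else 1
                blocks.append(
                    _Bottleneck(cin, cmid, cout, stride, config.stage_dilations[idx], rng)
                )
                cin = cout
            self.stages.append(blocks)
        # zero-init projection: an untrained decoder emits logits 0 -> p = 0.5
        self.decoder_proj = nn.Conv3d(cin, 2, 1, init="zero")
        self._train_cache: dict | None = None

    # -- parameter bookkeeping ------------------------------------------------

    def _named_layers(self) -> dict[str, nn.Conv3d | nn.BatchNorm3d]:
        named: dict[str, nn.Conv3d | nn.BatchNorm3d] = {
            "stem.conv": self.stem,
            "stem.norm": self.stem_norm,
            "decoder.proj": self.decoder_proj,
        }
        for i, blocks in enumerate(self.stages, start=1):
            for b, block in enumerate(blocks, start=1):
                for lname, layer in block.layers().items():
                    named[f"stage{i}.block{b}.{lname}"] = layer
        return named

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{pname}": arr
            for name, layer in self._named_layers().items()
            for pname, arr in layer.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{pname}": arr
            for name, layer in self._named_layers().items()
            for pname, arr in layer.grads.items()
        }

    def zero_grad(self) -> None:
        for layer in self._named_layers().values():
            layer.zero_grad()

    # -- forward / backward ---------------------------------------------------

    @staticmethod
    def _check_input(shape: tuple[int, ...]) -> None:
        if len(shape) != 3 or any(n < MIN_INPUT_DIM for n in shape):
            raise ValueError(
                f"input volume must be 3D with every dimension >= {MIN_INPUT_DIM}, got {shape}"
            )

    def _encode_batch(self, x: np.ndarray, retain: bool = False) -> list[np.ndarray]:
        """x: (C, N, D, H, W) -> list of 4 stage outputs."""
        out = self.stem.forward(x, retain)
        out = self.stem_relu.forward(self.stem_norm.forward(out, retain), retain)
        out = self.pool.forward(out, retain)
        stage_outs = []
        for blocks in self.stages:
            for block in blocks:
                out = block.forward(out, retain)
            stage_outs.append(out)
        return stage_outs

    def _decode_batch(
        self, stage4: np.ndarray, stage1_grid: tuple[int, int, int], retain: bool = False
    ) -> np.ndarray:
        """Stage-4 features -> 2-channel logits on the stage-1 grid.

        The decoder is trilinear upsampling to the stage-1 grid composed with
        a 1x1x1 projection to 2 channels.  Both maps are linear and the
        projection acts voxelwise, so they commute; projecting first avoids
        materializing a full-resolution copy of the widest feature map.
        """
        resize = nn.TrilinearResize(stage1_grid)
        small = self.decoder_proj.forward(stage4, retain)
        logits = resize.forward(small, retain)
        if retain:
            self._decode_resize = resize
        return logits

    def _backward_batch(self, dlogits: np.ndarray) -> None:
        d = self._decode_resize.backward(dlogits)
        d = self.decoder_proj.backward(d)
        for blocks in reversed(self.stages):
            for block in reversed(blocks):
                d = block.backward(d)
        d = self.pool.backward(d)
        d = self.stem_norm.backward(self.stem_relu.backward(d))
        self.stem.backward(d)

    def forward_logits(self, x: np.ndarray, retain: bool = False) -> np.ndarray:
        """(C, N, D, H, W) -> 2-channel logits on the stage-1 grid."""
        stage_outs = self._encode_batch(x, retain)
        stage1_grid = stage_outs[0].shape[2:]
        return self._decode_batch(stage_outs[-1], stage1_grid, retain)

    # -- public single-volume API --------------------------------------------

    def encode(self, volume: np.ndarray) -> StageFeatureSet:
        self._check_input(volume.shape)
        x = np.asarray(volume, DTYPE)[None, None]
        stage_outs = self._encode_batch(x)
        stages = [
            (i, out[:, 0], tuple(out.shape[2:]))
            for i, out in enumerate(stage_outs, start=1)
        ]
        return StageFeatureSet(stages)

    def decode(self, stage_features: StageFeatureSet) -> ProbabilityMap:
        last = stage_features.stages[-1][1]
        if last.shape[0] != self.config.scaled_stage_channels[-1]:
            raise ValueError("stage features do not match this model's configuration")
        logits = self._decode_batch(last[:, None], stage_features.grid(1))
        probs = nn.softmax2(logits)
        return ProbabilityMap(values=probs[1, 0], logits=logits[:, 0])


# -- module-level operation surface -------------------------------------------


def build_model(config: EncoderConfig | None = None, seed: int = 0) -> SegModel:
    """Instantiate an encoder--decoder with deterministic initialization."""
    return SegModel(config or EncoderConfig(), seed=seed)


def encode(model: SegModel, volume: np.ndarray) -> StageFeatureSet:
    return model.encode(volume)


def decode(model: SegModel, stage_features: StageFeatureSet) -> ProbabilityMap:
    return model.decode(stage_features)


def predict_probability(model: SegModel, volume: np.ndarray) -> ProbabilityMap:
    return model.decode(model.encode(volume))


def _loss_and_grad(cfg: TrainConfig, logits: np.ndarray, target: np.ndarray):
    if cfg.loss == "cross_entropy":
        return nn.softmax_cross_entropy(logits, target, cfg.pos_weight)
    if cfg.loss == "dice":
        return nn.soft_dice_loss(logits, target)
    lce, gce = nn.softmax_cross_entropy(logits, target, cfg.pos_weight)
    ld, gd = nn.soft_dice_loss(logits, target)
    return lce + ld, gce + gd


def train_segmentation(
    model: SegModel,
    cases,
    modality: str,
    train_cfg: TrainConfig,
) -> tuple[SegModel, list[float]]:
    """Fit the encoder--decoder on lesion masks; class labels are never read.

    Returns the model (trained in place) and the per-epoch mean loss history.
    Labels are resampled to the stage-1 prediction grid before the loss.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("no training cases supplied")
    if all(c.label_mask.sum() == 0 for c in cases):
        raise ValueError("degenerate training set: every label mask is empty")
    for c in cases:
        if modality not in c.volumes:
            raise KeyError(f"modality {modality!r} missing from case {c.case_id}")

    shape = next(iter(cases[0].volumes.values())).shape
    model._check_input(shape)
    grid = model.config.stage_grids(shape)[0]
    vols = np.stack([np.asarray(c.volumes[modality], DTYPE) for c in cases])
    labels = np.stack([align_label_to_grid(c.label_mask, grid) for c in cases]).astype(DTYPE)

    rng = np.random.default_rng(train_cfg.seed)
    opt = nn.Adam(lr=train_cfg.learning_rate)
    history: list[float] = []
    n = len(cases)
    bs = max(1, train_cfg.batch_size)
    for _epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            x = vols[idx][None]  # (C=1, N, D, H, W)
            y = labels[idx]
            model.zero_grad()
            logits = model.forward_logits(x, retain=True)
            loss, dlogits = _loss_and_grad(train_cfg, logits, y)
            model._backward_batch(dlogits)
            opt.step(model.parameters(), model.gradients())
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if train_cfg.early_stop is not None and epoch_loss < train_cfg.early_stop:
            break
    return model, history


# -- checkpointing -------------------------------------------------------------


def _named_buffers(model: SegModel) -> dict[str, np.ndarray]:
    """Non-parameter state (batch-norm running statistics)."""
    buffers = {}
    for name, layer in model._named_layers().items():
        if isinstance(layer, nn.BatchNorm3d):
            buffers[f"{name}.running_mean"] = layer.running_mean
            buffers[f"{name}.running_var"] = layer.running_var
    return buffers


def save_checkpoint(model: SegModel, path) -> None:
    """Self-describing container: encoder config JSON + named arrays
    (parameters and batch-norm running statistics)."""
    meta = json.dumps(
        {k: v for k, v in model.config.__dict__.items()}, default=list
    )
    arrays = {
        name.replace(".", "/"): arr
        for name, arr in {**model.parameters(), **_named_buffers(model)}.items()
    }
    np.savez_compressed(path, __config__=np.frombuffer(meta.encode(), np.uint8), **arrays)


def load_checkpoint(path) -> SegModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        for key in ("stage_channels", "stage_strides", "stage_dilations", "blocks_per_stage"):
            meta[key] = tuple(meta[key])
        model = SegModel(EncoderConfig(**meta))
        for name, arr in {**model.parameters(), **_named_buffers(model)}.items():
            arr[...] = data[name.replace(".", "/")]
    return model
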