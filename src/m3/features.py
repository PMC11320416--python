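"""Mask-gated multi-scale deep-feature extraction.

The core operation: the decoder's lesion-probability map is resampled onto
each selected encoder stage's grid and multiplied elementwise into that
stage's feature maps (broadcast over channels), concentrating the pooled
features on the lesion and suppressing background structure.  Per stage,
channels are reduced by global average and global max pooling and the
blocks are concatenated across stages — with the default full-width encoder
and stages 2-4 this yields (512 + 1024 + 2048) x 2 = 7,168 dimensions.

Four variants mirror the ablation structure:

* ``plain``       last stage only, no gating;
* ``mask``        last stage only, gated;
* ``multiscale``  stages 2-4 concatenated, no gating;
* ``m3``          stages 2-4 concatenated, gated (the full method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .segnet import ProbabilityMap, SegModel

VARIANTS = ("plain", "mask", "multiscale", "m3")
POOLINGS = ("global_average", "global_max")


@dataclass(frozen=True)
class ExtractionConfig:
    variant: str = "m3"
    gated_stages: tuple[int, ...] = (2, 3, 4)
    pooling: tuple[str, ...] = ("global_average", "global_max")
    mask_resampling: str = "trilinear"  # trilinear | nearest

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not self.gated_stages or any(s not in (1, 2, 3, 4) for s in self.gated_stages):
            raise ValueError("gated_stages must be a non-empty subset of stages 1-4")
        if not self.pooling or any(p not in POOLINGS for p in self.pooling):
            raise ValueError(f"pooling must be a non-empty subset of {POOLINGS}")
        if self.mask_resampling not in ("trilinear", "nearest"):
            raise ValueError("mask_resampling must be 'trilinear' or 'nearest'")

    @property
    def uses_mask(self) -> bool:
        return self.variant in ("mask", "m3")

    @property
    def stages_used(self) -> tuple[int, ...]:
        if self.variant in ("plain", "mask"):
            return (self.gated_stages[-1],)
        return tuple(self.gated_stages)


@dataclass
class FeatureVector:
    """Pooled, gated, concatenated multi-scale features for one case/modality."""

    values: np.ndarray
    layout: list[tuple[int, str, int]]  # (stage, pooling, n_channels) blocks
    case_id: str = ""
    modality: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")
        if len(self.values) != sum(b[2] for b in self.layout):
            raise ValueError("layout does not match vector length")


def resample_mask(prob, target_grid, method: str = "trilinear") -> np.ndarray:
    """Bring a probability map onto a stage grid; values clamped to [0, 1].

    Half-pixel-aligned coordinates; ``trilinear`` interpolates, ``nearest``
    picks the closest source voxel.
    """
    values = prob.values if isinstance(prob, ProbabilityMap) else np.asarray(prob, float)
    target_grid = tuple(int(t) for t in target_grid)
    if values.shape == target_grid:
        return np.clip(values, 0.0, 1.0)
    coords = np.meshgrid(
        *[
            np.clip((np.arange(t) + 0.5) * s / t - 0.5, 0, s - 1)
            for t, s in zip(target_grid, values.shape)
        ],
        indexing="ij",
    )
    order = 1 if method == "trilinear" else 0
    out = map_coordinates(values.astype(np.float64), coords, order=order, mode="nearest")
    return np.clip(out, 0.0, 1.0)


def apply_mask(stage_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Elementwise gate: (C, D, H, W) feature map times (D, H, W) mask."""
    if stage_map.shape[1:] != mask.shape:
        raise ValueError(
            f"mask grid {mask.shape} does not match stage grid {stage_map.shape[1:]}"
        )
    return stage_map * mask[None].astype(stage_map.dtype)


def pool_and_concat(gated_stages, config: ExtractionConfig) -> FeatureVector:
    """Per-stage global pooling over spatial voxels, concatenated in
    (stage, pooling) block order."""
    gated_stages = list(gated_stages)
    if not gated_stages:
        raise ValueError("no stages to pool")
    expected = list(config.stages_used)
    if [s for s, _ in gated_stages] != expected:
        raise ValueError(f"stages {[s for s, _ in gated_stages]} do not match {expected}")
    blocks = []
    layout = []
    for stage_idx, fmap in gated_stages:
        flat = fmap.reshape(fmap.shape[0], -1)
        for pooling in config.pooling:
            if pooling == "global_average":
                blocks.append(flat.mean(axis=1))
            else:
                blocks.append(flat.max(axis=1))
            layout.append((stage_idx, pooling, fmap.shape[0]))
    return FeatureVector(values=np.concatenate(blocks), layout=layout)


def extract_variants(
    case,
    model: SegModel,
    modality: str,
    configs: dict[str, ExtractionConfig],
    prob_override: np.ndarray | None = None,
) -> dict[str, FeatureVector]:
    """Extract several variants from one shared encode/decode pass.

    ``prob_override`` replaces the decoder's probability map (on the stage-1
    grid) — used for oracle-mask analyses and gate-identity checks.
    """
    if modality not in case.volumes:
        raise KeyError(f"modality {modality!r} not present in case {case.case_id}")
    sfs = model.encode(case.volumes[modality])
    prob = None
    if any(c.uses_mask for c in configs.values()):
        if prob_override is not None:
            prob = np.asarray(prob_override, float)
        else:
            prob = model.decode(sfs).values
    out: dict[str, FeatureVector] = {}
    for name, config in configs.items():
        gated = []
        for stage_idx in config.stages_used:
            fmap = sfs.get(stage_idx)
            if config.uses_mask:
                mask = resample_mask(prob, sfs.grid(stage_idx), config.mask_resampling)
                fmap = apply_mask(fmap, mask)
            gated.append((stage_idx, fmap))
        vec = pool_and_concat(gated, config)
        vec.case_id = case.case_id
        vec.modality = modality
        out[name] = vec
    return out


def extract(
    case,
    model: SegModel,
    modality: str,
    config: ExtractionConfig,
    prob_override: np.ndarray | None = None,
) -> FeatureVector:
    """Full per-case extraction: encode, decode, gate, pool."""
    return extract_variants(case, model, modality, {"_": config}, prob_override)["_"]


def feature_length(config: ExtractionConfig, stage_channels) -> int:
    """|F| = sum over used stages of channels(stage) * |pooling|."""
    return sum(stage_channels[s - 1] for s in config.stages_used) * len(config.pooling)
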