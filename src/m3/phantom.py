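"""Synthetic multi-modal 3D lesion phantoms.

Each case is a set of co-registered modality volumes containing one compact
lesion (an axis-aligned ellipsoid with a Gaussian-smoothed rim), a handful of
class-uncorrelated background "distractor" blobs, and additive Gaussian
noise.  The class signal lives only inside the lesion: class 1 shifts the
per-modality lesion mean by ``class_effect[m]`` and rescales the within
lesion noise by ``texture_effect[m]``.  A class-independent base contrast
(``lesion_contrast``) keeps lesions visible in both classes, which is what
makes class-blind segmentation training possible — exactly the clinical
situation, where tumors of either diagnosis enhance against brain tissue.

All randomness flows from explicit integer seeds through independent
substreams (lesion geometry, distractors, noise), so a case is byte
reproducible and its background is identical across the two class labels at
a fixed ``case_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "CaseRecord",
    "generate_case",
    "generate_cohort",
    "get_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Generator parameters; intensities are in arbitrary units.

    ``class_effect`` and ``texture_effect`` have one entry per modality and
    control the between-class difference of lesion mean intensity and of
    within-lesion noise scale.  Distractor blobs are smaller and dimmer than
    the lesion and placed away from it, independent of the class label.
    """

    grid_shape: tuple[int, int, int] = (32, 48, 48)
    modalities: tuple[str, ...] = ("T1ce", "T2", "FLAIR")
    lesion_radius_range: tuple[float, float] = (4.0, 7.0)
    lesion_contrast: tuple[float, ...] = (2.0, 2.0, 2.0)
    class_effect: tuple[float, ...] = (1.0, 0.8, 0.6)
    texture_effect: tuple[float, ...] = (1.0, 1.0, 1.0)
    background_mean: float = 0.0
    distractor_amplitude: float = 1.0
    distractor_count: int = 3
    distractor_radius_range: tuple[float, float] = (2.0, 4.0)
    # per-blob internal texture: noise inside each blob is rescaled by a
    # factor drawn uniformly from this range (class-uncorrelated)
    distractor_texture_range: tuple[float, float] = (1.0, 1.0)
    # per-blob brightness jitter: each blob's amplitude is drawn uniformly
    # from ((1 - jitter) * distractor_amplitude, distractor_amplitude).
    # Without it distractor brightness is a constant a classifier can learn
    # to ignore; with it, ungated pooled intensities confound class signal
    # with background variation — the interference gating is meant to remove
    distractor_amplitude_jitter: float = 0.0
    noise_sigma: float = 0.1
    class_balance: tuple[int, int] = (40, 40)
    seed: int = 0

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3D with every entry >= 8")
        rmin, rmax = self.lesion_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("lesion_radius_range must satisfy 0 < min <= max")
        if any(2 * rmax + 2 > n for n in self.grid_shape):
            raise ValueError("lesion_radius_range does not fit inside grid_shape")
        for name in ("lesion_contrast", "class_effect", "texture_effect"):
            if len(getattr(self, name)) != self.n_modalities:
                raise ValueError(f"{name} must have one entry per modality")
        if any(t < 0 for t in self.texture_effect):
            raise ValueError("texture_effect entries must be >= 0")
        if self.noise_sigma < 0 or self.distractor_count < 0:
            raise ValueError("noise_sigma and distractor_count must be >= 0")
        tmin, tmax = self.distractor_texture_range
        if not (0 <= tmin <= tmax):
            raise ValueError("distractor_texture_range must satisfy 0 <= min <= max")


@dataclass
class CaseRecord:
    """One subject: co-registered modality volumes, lesion mask, class label."""

    case_id: str
    volumes: dict[str, np.ndarray]
    label_mask: np.ndarray
    class_label: int | None
    split_tag: str | None = None

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.volumes.values()} | {self.label_mask.shape}
        if len(shapes) != 1:
            raise ValueError("all volumes and label_mask must share one shape")
        n_set = int(self.label_mask.sum())
        if not (1 <= n_set < 0.5 * self.label_mask.size):
            raise ValueError("label_mask must mark >= 1 and < 50% of voxels")
        if self.class_label is not None and self.class_label not in (0, 1):
            raise ValueError("class_label must be 0 or 1")

    def without_class_label(self) -> "CaseRecord":
        """Copy with the diagnosis removed (for class-blind training)."""
        return CaseRecord(
            case_id=self.case_id,
            volumes=self.volumes,
            label_mask=self.label_mask,
            class_label=None,
            split_tag=self.split_tag,
        )


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def _soft_profile(mask: np.ndarray) -> np.ndarray:
    """Gaussian-smoothed rim (sigma = 1 voxel) that stays exactly 1 inside."""
    smooth = gaussian_filter(mask.astype(np.float32), sigma=1.0)
    return np.maximum(smooth, mask.astype(np.float32))


def generate_case(config: PhantomConfig, class_label: int, case_seed: int) -> CaseRecord:
    """One phantom case.  Identical ``case_seed`` gives identical geometry,
    distractors and noise fields regardless of ``class_label``, so the class
    signal is exactly the configured lesion effect."""
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    shape = config.grid_shape
    ss = np.random.SeedSequence([int(case_seed) % 2**31, 0x9E3779])
    rng_geom, rng_distr, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    rmin, rmax = config.lesion_radius_range
    radii = rng_geom.uniform(rmin, rmax, size=3)
    lo = np.ceil(radii).astype(int) + 1
    hi = np.array(shape) - lo - 1
    if np.any(hi < lo):
        raise ValueError("lesion cannot be placed inside the grid")
    center = np.array([rng_geom.integers(a, b + 1) for a, b in zip(lo, hi)])
    lesion = _ellipsoid_mask(shape, center, radii)
    profile = _soft_profile(lesion)

    # distractor blobs: class-uncorrelated background structure, kept clear of
    # the lesion (including its smoothed rim) by a 4-voxel guard band; each
    # blob also rescales the noise inside it (background texture variation)
    distr_field = np.zeros(shape, np.float32)
    texture_gain = np.ones(shape, np.float32)
    dmin, dmax = config.distractor_radius_range
    tmin, tmax = config.distractor_texture_range
    placed = 0
    attempts = 0
    while placed < config.distractor_count and attempts < 200 * max(1, config.distractor_count):
        attempts += 1
        r = rng_distr.uniform(dmin, dmax)
        c = rng_distr.uniform(r + 1, np.array(shape) - r - 1)
        tex = rng_distr.uniform(tmin, tmax)
        gain = rng_distr.uniform(1.0 - config.distractor_amplitude_jitter, 1.0)
        guard = _ellipsoid_mask(shape, c, np.full(3, r + 4.0))
        if np.any(guard & lesion):
            continue
        blob = _ellipsoid_mask(shape, c, np.full(3, r))
        distr_field += gain * _soft_profile(blob)
        texture_gain[blob] = np.maximum(texture_gain[blob], tex)
        placed += 1

    base_noise = {
        m: rng_noise.standard_normal(shape).astype(np.float32) for m in config.modalities
    }

    volumes = {}
    for m_idx, m in enumerate(config.modalities):
        amp = config.lesion_contrast[m_idx] + config.class_effect[m_idx] * class_label
        vol = np.full(shape, config.background_mean, np.float32)
        vol += amp * profile
        vol += config.distractor_amplitude * distr_field
        noise = config.noise_sigma * base_noise[m] * texture_gain
        if class_label == 1:
            noise[lesion] *= config.texture_effect[m_idx]
        vol += noise
        volumes[m] = vol.astype(np.float32)

    return CaseRecord(
        case_id=f"s{int(case_seed)}y{class_label}",
        volumes=volumes,
        label_mask=lesion.astype(np.uint8),
        class_label=class_label,
    )


def _case_seed(cohort_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(cohort_seed), int(index)]).generate_state(1)[0] % 2**31)


def generate_cohort(config: PhantomConfig) -> list[CaseRecord]:
    """Deterministic cohort: ``class_balance[0]`` class-0 cases then
    ``class_balance[1]`` class-1 cases, per-case seeds derived from
    ``config.seed`` and the case index."""
    n0, n1 = config.class_balance
    if n0 < 1 or n1 < 1:
        raise ValueError("class_balance counts must be >= 1")
    cases = []
    for index in range(n0 + n1):
        label = 0 if index < n0 else 1
        case = generate_case(config, label, _case_seed(config.seed, index))
        case.case_id = f"{index:04d}"
        cases.append(case)
    return cases


PRESETS: dict[str, PhantomConfig] = {
    # balanced tumor-like task: 3 structural modalities, clear class effect
    "tumor3": PhantomConfig(
        grid_shape=(32, 48, 48),
        modalities=("T1ce", "T2", "FLAIR"),
        lesion_radius_range=(4.0, 7.0),
        lesion_contrast=(2.0, 2.0, 2.0),
        class_effect=(1.0, 0.8, 0.6),
        texture_effect=(1.5, 1.3, 1.2),
        distractor_amplitude=1.0,
        distractor_count=3,
        noise_sigma=0.1,
        class_balance=(40, 40),
        seed=0,
    ),
    # imbalanced stroke-like task: 5 perfusion/diffusion modalities, 60 vs 11
    "stroke5": PhantomConfig(
        grid_shape=(32, 48, 48),
        modalities=("ADC", "CBF", "CBV", "MTT", "TTP"),
        lesion_radius_range=(4.0, 7.0),
        lesion_contrast=(2.0, 1.8, 1.8, 2.0, 2.2),
        class_effect=(0.6, 0.5, 0.4, 0.5, 0.7),
        texture_effect=(1.2, 1.1, 1.0, 1.1, 1.3),
        distractor_amplitude=1.0,
        distractor_count=3,
        noise_sigma=0.15,
        class_balance=(60, 11),
        seed=0,
    ),
    # single-modality, heavy class-uncorrelated background structure with a
    # weak class effect: the regime where probability-map gating should pay
    # off.  Distractors are brighter than any lesion (so ungated max pooling
    # locks onto them) but much smaller (so a mask network can reject them);
    # the class also shifts within-lesion texture, which higher-resolution
    # encoder stages resolve better than the last one.
    "distractor1": PhantomConfig(
        grid_shape=(32, 48, 48),
        modalities=("T1ce",),
        # lesions span several feature-grid cells (diameter ~16-22 voxels vs
        # an 8-voxel stage cell), as in real data, so mask-confidence noise
        # averages out of the gated pooled features
        lesion_radius_range=(8.0, 11.0),
        lesion_contrast=(2.0,),
        class_effect=(0.35,),
        texture_effect=(1.8,),
        distractor_amplitude=2.9,
        distractor_count=10,
        distractor_radius_range=(1.5, 2.5),
        distractor_texture_range=(1.0, 4.0),
        distractor_amplitude_jitter=0.4,
        noise_sigma=0.1,
        class_balance=(24, 24),
        seed=0,
    ),
}


def get_preset(name: str, **overrides) -> PhantomConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg
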