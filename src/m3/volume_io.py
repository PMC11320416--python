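"""Volume and manifest I/O plus in-scope intensity preprocessing.

Covers NIfTI-1 reading/writing via nibabel, the CSV case manifest, landmark
based histogram standardization (Nyul-style percentile mapping), and
nearest-neighbour resampling of binary labels onto a prediction grid.

Bias-field correction, registration and skull stripping are external-tool
steps expected to have happened upstream: volumes of one case must arrive
co-registered on a single grid, and "foreground" means nonzero voxels (the
post-skull-strip convention).  A brain mask, when available, should be
applied multiplicatively before landmark fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

DEFAULT_PERCENTILES = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)


@dataclass(frozen=True)
class IntensityLandmarks:
    """Cohort reference intensities at fixed foreground percentiles."""

    modality: str
    percentile_positions: tuple[float, ...]
    reference_values: tuple[float, ...]

    def __post_init__(self) -> None:
        pos = self.percentile_positions
        if len(pos) != len(self.reference_values):
            raise ValueError("percentile_positions and reference_values differ in length")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("percentile_positions must be strictly increasing")
        if any(p <= 0 or p >= 100 for p in pos):
            raise ValueError("percentiles must lie in (0, 100)")


# -- NIfTI / manifest ---------------------------------------------------------


def write_nifti(path, array: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_case(case, out_dir, affine: np.ndarray | None = None) -> dict[str, str]:
    """Write one case's modality volumes + label; return the manifest row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    row: dict[str, str] = {"case_id": case.case_id, "class_label": case.class_label}
    for modality, vol in case.volumes.items():
        p = out_dir / f"CASE_{case.case_id}_{modality}.nii.gz"
        write_nifti(p, vol.astype(np.float32), affine)
        row[modality] = str(p)
    lp = out_dir / f"CASE_{case.case_id}_label.nii.gz"
    write_nifti(lp, case.label_mask.astype(np.uint8), affine)
    row["label"] = str(lp)
    return row


def write_manifest(cases, out_dir, affine: np.ndarray | None = None) -> Path:
    rows = [write_case(c, out_dir, affine) for c in cases]
    path = Path(out_dir) / "manifest.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_case(manifest_row):
    """Build a CaseRecord from one manifest row (modalities in column order).

    Raises if any referenced file is missing or if the grids disagree across
    modalities/label — a shape mismatch signals unregistered input.
    """
    from .phantom import CaseRecord  # local import to avoid a cycle

    row = dict(manifest_row)
    case_id = str(row.pop("case_id"))
    class_label = int(row.pop("class_label"))
    label_path = row.pop("label")
    split_tag = row.pop("split_tag", None)
    volumes = {}
    shape = None
    for modality, path in row.items():
        if not Path(str(path)).exists():
            raise FileNotFoundError(f"missing volume file {path} for case {case_id}")
        arr, _ = read_nifti(path)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"case {case_id}: modality {modality} grid {arr.shape} != {shape}; "
                "volumes must be co-registered on one grid"
            )
        volumes[modality] = np.asarray(arr, np.float32)
    if not Path(str(label_path)).exists():
        raise FileNotFoundError(f"missing label file {label_path} for case {case_id}")
    label, _ = read_nifti(label_path)
    if label.shape != shape:
        raise ValueError(
            f"case {case_id}: label grid {label.shape} != volume grid {shape}"
        )
    return CaseRecord(
        case_id=case_id,
        volumes=volumes,
        label_mask=(np.asarray(label) > 0).astype(np.uint8),
        class_label=class_label,
        split_tag=split_tag,
    )


def read_manifest(path):
    df = pd.read_csv(path)
    return [read_case(row) for _, row in df.iterrows()]


# -- histogram standardization -------------------------------------------------


def _foreground(volume: np.ndarray) -> np.ndarray:
    fg = volume[volume != 0]
    if fg.size == 0:
        raise ValueError("volume has no nonzero (foreground) voxels")
    return fg


def fit_landmarks(volumes, percentiles=DEFAULT_PERCENTILES, modality: str = "") -> IntensityLandmarks:
    """Average each foreground percentile over the cohort -> reference values."""
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one volume to fit landmarks")
    pcts = np.asarray(percentiles, float)
    per_vol = np.stack([np.percentile(_foreground(v), pcts) for v in volumes])
    return IntensityLandmarks(
        modality=modality,
        percentile_positions=tuple(pcts.tolist()),
        reference_values=tuple(per_vol.mean(axis=0).tolist()),
    )


def standardize(volume: np.ndarray, landmarks: IntensityLandmarks) -> np.ndarray:
    """Piecewise-linear map of the volume's own foreground percentiles onto
    the landmark reference values; monotone, linearly extrapolated beyond the
    outermost landmarks."""
    fg = _foreground(volume)
    own = np.percentile(fg, np.asarray(landmarks.percentile_positions, float))
    ref = np.asarray(landmarks.reference_values, float)
    if own.max() - own.min() <= 0:
        raise ValueError("constant volume: histogram standardization undefined")
    # collapse ties in own percentiles to keep np.interp well defined
    keep = np.concatenate([[True], np.diff(own) > 0])
    own, ref = own[keep], ref[keep]
    if own.size < 2:
        raise ValueError("degenerate histogram: fewer than two distinct landmarks")
    out = np.interp(volume, own, ref)
    # linear extrapolation from the terminal segments
    lo_slope = (ref[1] - ref[0]) / (own[1] - own[0])
    hi_slope = (ref[-1] - ref[-2]) / (own[-1] - own[-2])
    below = volume < own[0]
    above = volume > own[-1]
    out[below] = ref[0] + (volume[below] - own[0]) * lo_slope
    out[above] = ref[-1] + (volume[above] - own[-1]) * hi_slope
    return out.astype(volume.dtype, copy=False)


# -- label alignment -----------------------------------------------------------


def align_label_to_grid(label_mask: np.ndarray, target_shape) -> np.ndarray:
    """Nearest-neighbour resampling of a binary label onto a coarser grid.

    The prediction grid of the segmentation network is 4x (or 8x) coarser
    than the input; the reference label is brought onto that grid for loss
    computation.  Upsampling is refused: each target dimension must not
    exceed the source dimension.
    """
    label_mask = np.asarray(label_mask)
    target_shape = tuple(int(t) for t in target_shape)
    if label_mask.ndim != 3 or len(target_shape) != 3:
        raise ValueError("label and target shape must be 3D")
    if any(t > s for t, s in zip(target_shape, label_mask.shape)):
        raise ValueError(
            f"target shape {target_shape} exceeds source {label_mask.shape}; "
            "labels are only aligned onto coarser grids"
        )
    if any(t < 1 for t in target_shape):
        raise ValueError("target dimensions must be >= 1")
    coords = np.meshgrid(
        *[
            np.minimum(
                np.maximum((np.arange(t) + 0.5) * s / t - 0.5, 0), s - 1
            )
            for t, s in zip(target_shape, label_mask.shape)
        ],
        indexing="ij",
    )
    out = map_coordinates(label_mask.astype(np.uint8), coords, order=0, mode="nearest")
    return (out > 0).astype(np.uint8)
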