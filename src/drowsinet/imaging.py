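"""Construction of the network input variants from frames and eye landmarks.

A frame plus per-eye landmark points yields, via landmark-extrema bounding
boxes, three input variants:

* ``face``: the whole frame resized to 28x28 (or 32x32 inside the fusion),
* ``eye``: each eye crop resized to 16x64 and stacked vertically into 32x64
  (left eye on top by convention),
* ``fusion``: the 32x32 face thumbnail concatenated left of the 32x64 eye
  pair, giving 32x96,

plus the gender-signal variant: the eye pair with a 5-row constant strip
appended below (0 for male, 255 for female), 37x64.

Conventions: coordinates are (row, col), boxes are 0-based half-open
``[start, end)``, resizing is bilinear. All composite builders are lossless —
each source block is recoverable bit-exactly from its slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

__all__ = [
    "LandmarkSet",
    "BoundingBox",
    "eye_box_from_landmarks",
    "crop_resize",
    "stack_eyes",
    "split_eyes",
    "build_fusion",
    "split_fusion",
    "build_gender_signal",
    "strip_gender_signal",
    "preprocess_frame",
    "INPUT_TYPES",
]

FACE_SIZE = (28, 28)
FACE_IN_FUSION_SIZE = (32, 32)
EYE_SIZE = (16, 64)
GENDER_STRIP_ROWS = 5
INPUT_TYPES = ("face", "eye", "fusion", "eye+gender")


@dataclass(frozen=True)
class LandmarkSet:
    """Per-eye landmark coordinates, (row, col) pixels, one array per eye."""

    left_eye: np.ndarray  # (n, 2) int/float
    right_eye: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "left_eye", np.atleast_2d(np.asarray(self.left_eye)))
        object.__setattr__(self, "right_eye", np.atleast_2d(np.asarray(self.right_eye)))
        for pts in (self.left_eye, self.right_eye):
            if pts.size == 0 or pts.shape[1] != 2:
                raise ValueError("each eye needs a non-empty (n, 2) point array")

    def to_frame(self) -> pd.DataFrame:
        rows = [("left", i, r, c) for i, (r, c) in enumerate(self.left_eye)]
        rows += [("right", i, r, c) for i, (r, c) in enumerate(self.right_eye)]
        return pd.DataFrame(rows, columns=["eye", "point_index", "row", "col"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkSet":
        df = pd.read_csv(path)
        return cls(
            left_eye=df.loc[df["eye"] == "left", ["row", "col"]].to_numpy(),
            right_eye=df.loc[df["eye"] == "right", ["row", "col"]].to_numpy(),
        )


@dataclass(frozen=True)
class BoundingBox:
    """0-based half-open box: rows [row_start, row_end), cols [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self):
        if self.row_start >= self.row_end or self.col_start >= self.col_end:
            raise ValueError(f"degenerate box {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)

    def slice(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_end), slice(self.col_start, self.col_end))


def eye_box_from_landmarks(
    points: np.ndarray,
    margin: float = 0.0,
    image_shape: tuple[int, int] | None = None,
) -> BoundingBox:
    """Anchor box spanned by the landmark extrema, optionally padded.

    The raw box covers ``[min, max]`` per axis (half-open: ``[min, max+1)``);
    ``margin`` expands each side by ``margin`` times that axis' extent,
    rounded, then clips to ``image_shape`` bounds when given.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2 or np.unique(pts, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct landmark points")
    rmin, cmin = pts.min(axis=0)
    rmax, cmax = pts.max(axis=0)
    r_ext, c_ext = rmax - rmin, cmax - cmin
    r0 = int(np.floor(rmin - margin * r_ext))
    r1 = int(np.ceil(rmax + margin * r_ext)) + 1
    c0 = int(np.floor(cmin - margin * c_ext))
    c1 = int(np.ceil(cmax + margin * c_ext)) + 1
    if image_shape is not None:
        h, w = image_shape[:2]
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, h), min(c1, w)
    return BoundingBox(r0, r1, c0, c1)


def crop_resize(image: np.ndarray, box: BoundingBox, out_size: tuple[int, int]) -> np.ndarray:
    """Crop ``box`` from ``image`` and bilinearly resize to ``out_size``.

    Output dtype matches the input (uint8 images stay uint8, rounded).
    A resize to the crop's own size returns the crop pixel-identically.
    """
    h, w = image.shape[:2]
    if not (0 <= box.row_start < box.row_end <= h and 0 <= box.col_start < box.col_end <= w):
        raise ValueError(f"box {box} not inside image of shape {(h, w)}")
    crop = image[box.slice()]
    if crop.shape[:2] == tuple(out_size):
        return crop.copy()
    out = _sk_resize(crop.astype(float), out_size, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(image.dtype)


def _require_shape(block: np.ndarray, shape: tuple[int, ...], name: str) -> None:
    if block.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {block.shape}")


def stack_eyes(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Stack the two 16x64x3 eye crops into the 32x64x3 eye-pair image.

    Left eye occupies rows 0-15, right eye rows 16-31.
    """
    _require_shape(left, (*EYE_SIZE, 3), "left eye block")
    _require_shape(right, (*EYE_SIZE, 3), "right eye block")
    return np.concatenate([left, right], axis=0)


def split_eyes(eyes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`stack_eyes`."""
    _require_shape(eyes, (32, 64, 3), "eye-pair image")
    return eyes[:16].copy(), eyes[16:].copy()


def build_fusion(face32: np.ndarray, eyes: np.ndarray) -> np.ndarray:
    """Concatenate the 32x32x3 face block left of the 32x64x3 eye pair -> 32x96x3."""
    _require_shape(face32, (*FACE_IN_FUSION_SIZE, 3), "face block")
    _require_shape(eyes, (32, 64, 3), "eye-pair image")
    return np.concatenate([face32, eyes], axis=1)


def split_fusion(fusion: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`build_fusion`: (face block, eye pair)."""
    _require_shape(fusion, (32, 96, 3), "fusion image")
    return fusion[:, :32].copy(), fusion[:, 32:].copy()


def build_gender_signal(eyes: np.ndarray, gender: str) -> np.ndarray:
    """Append a 5-row constant strip below the eye pair: 0 = male, 255 = female.

    Output shape is (37, 64, 3).
    """
    _require_shape(eyes, (32, 64, 3), "eye-pair image")
    if gender not in ("male", "female"):
        raise ValueError(f"gender must be 'male' or 'female', got {gender!r}")
    value = 0 if gender == "male" else 255
    strip = np.full((GENDER_STRIP_ROWS, eyes.shape[1], 3), value, dtype=eyes.dtype)
    return np.concatenate([eyes, strip], axis=0)


def strip_gender_signal(image: np.ndarray) -> np.ndarray:
    """Inverse of :func:`build_gender_signal`: the original eye pair."""
    _require_shape(image, (32 + GENDER_STRIP_ROWS, 64, 3), "gender-signal image")
    return image[:32].copy()


def preprocess_frame(
    image: np.ndarray,
    landmarks: LandmarkSet,
    input_type: str,
    gender: str | None = None,
    margin: float = 0.25,
    mask: np.ndarray | None = None,
):
    """Build one network input (uint8) from a frame and its landmarks.

    ``margin`` pads the landmark-extrema eye boxes by that fraction of their
    extent before cropping. When ``mask`` (a boolean frame-sized map, e.g. a
    sclera mask) is given, it is carried through the identical geometric
    transform and returned alongside as a boolean map in input coordinates.
    """
    if input_type not in INPUT_TYPES:
        raise ValueError(f"input_type must be one of {INPUT_TYPES}, got {input_type!r}")
    h, w = image.shape[:2]
    full_box = BoundingBox(0, h, 0, w)

    def transform(img, box, size):
        return crop_resize(img, box, size)

    def mask_block(box, size):
        if mask is None:
            return None
        m = crop_resize(mask.astype(np.float64) * 255.0, box, size)
        return m > 127.5

    if input_type == "face":
        out = transform(image, full_box, FACE_SIZE)
        return (out, mask_block(full_box, FACE_SIZE)) if mask is not None else out

    lbox = eye_box_from_landmarks(landmarks.left_eye, margin=margin, image_shape=(h, w))
    rbox = eye_box_from_landmarks(landmarks.right_eye, margin=margin, image_shape=(h, w))
    eyes = stack_eyes(transform(image, lbox, EYE_SIZE), transform(image, rbox, EYE_SIZE))
    if mask is not None:
        eye_mask = np.concatenate([mask_block(lbox, EYE_SIZE), mask_block(rbox, EYE_SIZE)], axis=0)

    if input_type == "eye":
        return (eyes, eye_mask) if mask is not None else eyes
    if input_type == "fusion":
        face32 = transform(image, full_box, FACE_IN_FUSION_SIZE)
        out = build_fusion(face32, eyes)
        if mask is not None:
            fmask = np.concatenate([mask_block(full_box, FACE_IN_FUSION_SIZE), eye_mask], axis=1)
            return out, fmask
        return out
    # eye+gender
    if gender is None:
        raise ValueError("input_type 'eye+gender' requires the gender")
    out = build_gender_signal(eyes, gender)
    if mask is not None:
        pad = np.zeros((GENDER_STRIP_ROWS, eyes.shape[1]), dtype=bool)
        return out, np.concatenate([eye_mask, pad], axis=0)
    return out
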