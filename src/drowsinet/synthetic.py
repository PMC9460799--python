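"""Parametric synthetic face/eye frames with known class and gender structure.

The generator renders schematic faces — a skin ellipse, a hair band, a mouth
and two eyes — where the *drowsiness* signal lives exclusively in the eye
region and the *gender* signal exclusively in the face context:

* **sclera redness**: drowsy subjects have a higher red-channel excess over
  the visible sclera (drowsiness is commonly accompanied by reddened eyes);
* **eyelid aperture**: drowsy subjects have more closed eyes (smaller
  fraction of the maximal opening);
* **hair band darkness**: correlated with gender only, never with class, so
  that gender is recoverable from the face but not from the eyes.

Rendering is schematic, not photorealistic: the point is that every
downstream stage (cropping, training, Grad-CAM localization, feature
analysis) can be tested against known ground truth — per-pixel region masks
and landmark extrema are returned with every frame.

Everything is deterministic: the same ``(profile, frame_index)`` always
renders the identical image, and the same master seed reproduces a dataset
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .imaging import LandmarkSet

__all__ = [
    "GeneratorConfig",
    "SubjectProfile",
    "SyntheticFrame",
    "generate_subject",
    "render_frame",
    "generate_dataset",
    "profile_table",
]

MANIFEST_COLUMNS = ["subject_id", "path", "label", "gender"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Population-level knobs of the generator.

    ``effect_size`` is the between-class difference of the subject-level
    redness and aperture means, expressed in units of the within-class
    standard deviation ``subject_sd``. Subject means are drawn from a normal
    clipped at ±1.4 within-class sd, so at the default effect size of 3 the
    two class ranges cannot overlap (every drowsy subject is strictly redder
    and strictly more closed-eyed than every alert one).
    """

    class_balance: float = 0.5
    gender_balance: float = 0.5
    effect_size: float = 3.0
    #: per-cue overrides of effect_size; None = use effect_size. Setting one
    #: of them to 0 isolates the other cue (e.g. a redness-only population).
    redness_effect_size: float | None = None
    aperture_effect_size: float | None = None
    subject_sd: float = 0.08
    alert_redness: float = 0.15
    alert_aperture: float = 0.82
    noise_sd: float = 0.03  # per-pixel Gaussian noise sd, on the [0, 1] scale
    frame_jitter: float = 0.01  # per-frame sd of redness/aperture around the subject mean
    image_size: tuple[int, int] = (128, 128)
    gender_confound: bool = True  # hair band darkness carries gender; off = neutral face
    #: clip bound (in within-class sd) of subject means around the class mean
    clip_sd: float = 1.4


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: int
    gender: str  # "male" | "female"
    drowsy_class: str  # "alert" | "drowsy"
    sclera_redness_mean: float  # red-channel excess over sclera, in [0, 1]
    eyelid_aperture_mean: float  # fraction of maximal eye opening, in [0, 1]
    face_tone: float  # skin intensity, in [0, 1]
    noise_sd: float
    seed: int  # per-subject render seed


@dataclass
class SyntheticFrame:
    image: np.ndarray  # (H, W, 3) uint8
    landmarks: LandmarkSet
    sclera_mask: np.ndarray  # (H, W) bool, visible sclera
    eye_region_mask: np.ndarray  # (H, W) bool, maximal (open-eye) eye regions
    label: str
    gender: str
    subject_id: int


def _bresenham_flag(index: int, fraction: float) -> bool:
    """Deterministic assignment hitting ``fraction`` of indices as evenly as
    possible: True when the running count must advance."""
    return int(np.floor((index + 1) * fraction)) > int(np.floor(index * fraction))


def generate_subject(
    subject_id: int,
    class_balance: float = 0.5,
    effect_size: float = 3.0,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> SubjectProfile:
    """Draw one subject's profile.

    Class assignment is a deterministic even spread (so dataset class
    proportions match ``class_balance`` within one subject); gender alternates
    within each class, keeping gender and class orthogonal by construction.
    Subject-level redness/aperture means are clipped normals around the class
    means, which differ by ``effect_size`` within-class standard deviations.
    """
    cfg = config or GeneratorConfig(class_balance=class_balance, effect_size=effect_size)
    if not 0 < cfg.class_balance < 1:
        raise ValueError(f"class_balance must be in (0, 1), got {cfg.class_balance}")
    if cfg.effect_size < 0:
        raise ValueError(f"effect_size must be >= 0, got {cfg.effect_size}")
    if cfg.noise_sd <= 0:
        raise ValueError(f"noise_sd must be positive, got {cfg.noise_sd}")

    drowsy = _bresenham_flag(subject_id, cfg.class_balance)
    # index of this subject within its class, computable without global state
    if drowsy:
        within = int(np.floor(subject_id * cfg.class_balance))
    else:
        within = subject_id - int(np.floor(subject_id * cfg.class_balance))
    female = _bresenham_flag(within, cfg.gender_balance)

    rng = np.random.default_rng([seed, subject_id])
    sd = cfg.subject_sd
    red_eff = cfg.effect_size if cfg.redness_effect_size is None else cfg.redness_effect_size
    ap_eff = cfg.effect_size if cfg.aperture_effect_size is None else cfg.aperture_effect_size
    red_mu = cfg.alert_redness + (red_eff * sd if drowsy else 0.0)
    ap_mu = cfg.alert_aperture - (ap_eff * sd if drowsy else 0.0)
    red = float(np.clip(rng.normal(red_mu, sd), red_mu - cfg.clip_sd * sd, red_mu + cfg.clip_sd * sd))
    ap = float(np.clip(rng.normal(ap_mu, sd), ap_mu - cfg.clip_sd * sd, ap_mu + cfg.clip_sd * sd))
    return SubjectProfile(
        subject_id=subject_id,
        gender="female" if female else "male",
        drowsy_class="drowsy" if drowsy else "alert",
        sclera_redness_mean=float(np.clip(red, 0.0, 1.0)),
        eyelid_aperture_mean=float(np.clip(ap, 0.0, 1.0)),
        face_tone=float(rng.uniform(0.45, 0.75)),
        noise_sd=cfg.noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _ellipse_mask(h, w, cr, cc, rr, rc):
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    return ((rows - cr) / rr) ** 2 + ((cols - cc) / rc) ** 2 <= 1.0


def render_frame(
    profile: SubjectProfile,
    frame_index: int,
    image_size: tuple[int, int] | None = None,
    gender_confound: bool = True,
    frame_jitter: float = 0.01,
) -> SyntheticFrame:
    """Render one frame of a subject.

    The two eye regions are ellipses whose vertical extent is scaled by the
    (jittered) eyelid aperture; the visible sclera is the open-eye ellipse
    minus the iris disc, tinted so that the mean red-minus-green intensity
    over the sclera equals ``redness * 255``. ``eye_region_mask`` is the
    maximal (fully open) eye ellipse, independent of aperture, and the
    landmarks are its four per-eye extrema.
    """
    if frame_index < 0:
        raise ValueError(f"frame_index must be >= 0, got {frame_index}")
    h, w = image_size or (128, 128)
    if h < 64 or w < 64:
        raise ValueError(f"image size must be at least 64x64, got {(h, w)}")
    rng = np.random.default_rng([profile.seed, frame_index])
    redness = float(np.clip(profile.sclera_redness_mean + rng.normal(0, frame_jitter), 0, 1))
    aperture = float(np.clip(profile.eyelid_aperture_mean + rng.normal(0, frame_jitter), 0, 1))
    if profile.eyelid_aperture_mean == 0.0:
        aperture = 0.0  # degenerate case stays degenerate

    img = np.zeros((h, w, 3), dtype=np.float64)
    img[:] = 110.0  # background

    # face ellipse (slightly warm skin tone)
    tone = profile.face_tone * 255.0
    face = _ellipse_mask(h, w, 0.52 * h, 0.5 * w, 0.42 * h, 0.34 * w)
    img[face] = [min(255.0, tone * 1.05), tone, tone * 0.9]

    # hair band across the top of the face; darkness encodes gender only
    if gender_confound:
        band_val = 200.0 if profile.gender == "female" else 40.0
    else:
        band_val = 120.0
    hair = face & (np.arange(h)[:, None] < 0.26 * h + np.zeros((h, w)))
    img[hair] = band_val

    # mouth: dark horizontal bar
    mouth = _ellipse_mask(h, w, 0.76 * h, 0.5 * w, 0.022 * h, 0.10 * w)
    img[mouth] = 70.0

    # eyes
    eye_centers = [(0.45 * h, 0.34 * w), (0.45 * h, 0.66 * w)]  # (row, col): left, right
    max_rr, rc = 0.055 * h, 0.085 * w
    eye_region = np.zeros((h, w), dtype=bool)
    sclera = np.zeros((h, w), dtype=bool)
    landmark_pairs = []
    g_val = 240.0 * (1.0 - redness)
    r_val = g_val + 255.0 * redness
    for cr, cc in eye_centers:
        full = _ellipse_mask(h, w, cr, cc, max_rr, rc)
        eye_region |= full
        if aperture > 0:
            open_eye = _ellipse_mask(h, w, cr, cc, max_rr * aperture, rc)
            iris = _ellipse_mask(h, w, cr, cc, 0.45 * max_rr, 0.45 * max_rr)
            img[open_eye] = [r_val, g_val, g_val]
            img[open_eye & iris] = 60.0
            sclera |= open_eye & ~iris
        rows, cols = np.nonzero(full)
        top = (rows.min(), cc)
        bottom = (rows.max(), cc)
        left = (cr, cols.min())
        right = (cr, cols.max())
        landmark_pairs.append(
            np.array([top, bottom, left, right], dtype=float).round().astype(int)
        )

    noise = rng.normal(0.0, profile.noise_sd * 255.0, size=img.shape)
    out = np.clip(img + noise, 0, 255).astype(np.uint8)
    return SyntheticFrame(
        image=out,
        landmarks=LandmarkSet(left_eye=landmark_pairs[0], right_eye=landmark_pairs[1]),
        sclera_mask=sclera,
        eye_region_mask=eye_region,
        label=profile.drowsy_class,
        gender=profile.gender,
        subject_id=profile.subject_id,
    )


def generate_dataset(
    n_subjects: int,
    frames_per_subject: int,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[SyntheticFrame], pd.DataFrame]:
    """Generate a full synthetic dataset and its manifest.

    Returns the frames (in manifest order) and a manifest DataFrame with
    columns ``subject_id, path, label, gender``. If ``out_dir`` is given, the
    frames are written as PNGs and the manifest as ``manifest.csv`` there;
    otherwise ``path`` holds the would-be relative filename.
    """
    if n_subjects < 4:
        raise ValueError(f"need at least 4 subjects for 4-fold splitting, got {n_subjects}")
    cfg = config or GeneratorConfig()
    frames: list[SyntheticFrame] = []
    rows = []
    for sid in range(n_subjects):
        profile = generate_subject(sid, seed=seed, config=cfg)
        for fi in range(frames_per_subject):
            frame = render_frame(
                profile,
                fi,
                image_size=cfg.image_size,
                gender_confound=cfg.gender_confound,
                frame_jitter=cfg.frame_jitter,
            )
            path = f"s{sid:03d}_f{fi:03d}.png"
            frames.append(frame)
            rows.append((sid, path, frame.label, frame.gender))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for frame, path in zip(frames, manifest["path"]):
            iio.imwrite(out_dir / path, frame.image)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return frames, manifest


def profile_table(n_subjects: int, config: GeneratorConfig | None = None, seed: int = 0
                  ) -> pd.DataFrame:
    """Subject-level ground-truth parameters, handy for calibration checks."""
    cfg = config or GeneratorConfig()
    return pd.DataFrame([dataclasses.asdict(generate_subject(s, seed=seed, config=cfg))
                         for s in range(n_subjects)])
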