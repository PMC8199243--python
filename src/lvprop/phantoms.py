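"""Synthetic short-axis cardiac phantoms, masks and motion sequences.

A short-axis slice through the left ventricle shows a bright, roughly
circular blood pool surrounded by a darker myocardial annulus, sitting on a
textured background with other tissue ("distractor") blobs of similar
intensity.  The generators here rasterize that geometry so that every
downstream stage (superpixels, dictionary, fusion, anchors, tracker,
metrics) can be exercised with exact ground truth and no external data.

Conventions shared across the package: pixel coordinates are 0-based
``(row, col)``; boxes are ``(x1, y1, x2, y2)`` half-open with ``x`` = column
and ``y`` = row.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomSpec",
    "MotionSpec",
    "make_phantom",
    "make_sequence",
    "make_training_set",
    "write_manifest",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of one left-ventricle phantom.

    The LV mask is the filled disk of radius
    ``blood_pool_radius + myocardium_thickness`` (blood pool plus
    myocardium), which is what the candidate-region machinery must recover.
    Intensities are grayscale in [0, 1].
    """

    image_size: tuple[int, int] = (256, 256)  # (H, W)
    lv_center: tuple[float, float] = (128.0, 128.0)  # (row, col)
    blood_pool_radius: float = 20.0
    myocardium_thickness: float = 8.0
    blood_intensity: float = 0.9
    myo_intensity: float = 0.35
    background_mean: float = 0.15
    background_gradient: float = 0.05  # amplitude of the smooth shading ramp
    noise_sd: float = 0.02
    n_distractors: int = 3
    seed: int = 0

    @property
    def outer_radius(self) -> float:
        return self.blood_pool_radius + self.myocardium_thickness

    def validate(self) -> None:
        h, w = self.image_size
        cy, cx = self.lv_center
        r = self.outer_radius
        if self.blood_pool_radius < 2:
            raise ValueError("blood_pool_radius must be >= 2")
        if self.myocardium_thickness < 1:
            raise ValueError("myocardium_thickness must be >= 1")
        if not (cy - r >= 0 and cy + r < h and cx - r >= 0 and cx + r < w):
            raise ValueError(
                f"LV annulus (center {self.lv_center}, outer radius {r:.1f}) "
                f"extends outside the {h}x{w} image"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class MotionSpec:
    """Smooth per-frame rigid drift and isotropic scale change.

    ``translation`` is the per-frame ``(dx, dy)`` shift in pixels (x = col,
    y = row) and ``scale`` the per-frame size factor; both compound over the
    sequence, emulating the slice-to-slice drift of one individual's
    acquisition.
    """

    n_frames: int = 10
    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.9 <= self.scale <= 1.1):
            raise ValueError("per-frame scale factor must lie in [0.9, 1.1]")


def _background(
    spec: PhantomSpec, rng: np.random.Generator,
    shift: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # smooth low-frequency shading: a diagonal ramp emulating intensity
    # inhomogeneity, without simulating a physical bias field
    img = spec.background_mean + spec.background_gradient * (
        (xx - shift[1]) / max(w - 1, 1) + (yy - shift[0]) / max(h - 1, 1) - 1.0
    )
    return img


def _paint_lv(img: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    h, w = spec.image_size
    cy, cx = spec.lv_center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d = np.hypot(yy - cy, xx - cx)
    lv_mask = d < spec.outer_radius
    img = img.copy()
    img[lv_mask] = spec.myo_intensity
    img[d < spec.blood_pool_radius] = spec.blood_intensity
    return img, lv_mask


def _blob_mask(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float,
    phi: float,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(phi) + dx * np.sin(phi)
    v = -dy * np.sin(phi) + dx * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 < 1.0


def _sample_distractors(
    spec: PhantomSpec,
    forbidden: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[float, float, float, float, float, float]]:
    """Ellipse distractors with intensities near blood/myocardium levels.

    Returns (cy, cx, a, b, phi, intensity) tuples.  Placement is
    rejection-sampled so no distractor pixel touches ``forbidden`` (the LV
    mask, or its largest footprint over a sequence).
    """
    h, w = spec.image_size
    params = []
    for _ in range(200 * max(spec.n_distractors, 1)):
        if len(params) >= spec.n_distractors:
            break
        a = rng.uniform(4, 14)
        b = rng.uniform(4, 14)
        cy = rng.uniform(a, h - 1 - a)
        cx = rng.uniform(b, w - 1 - b)
        phi = rng.uniform(0, np.pi)
        inten = rng.choice([spec.blood_intensity, spec.myo_intensity]) + rng.uniform(
            -0.08, 0.08
        )
        blob = _blob_mask((h, w), cy, cx, a, b, phi)
        if np.any(blob & forbidden):
            continue
        params.append((cy, cx, a, b, phi, float(np.clip(inten, 0.0, 1.0))))
    return params


def _draw_distractors(
    img: np.ndarray,
    params: list[tuple[float, float, float, float, float, float]],
    shift: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    img = img.copy()
    for cy, cx, a, b, phi, inten in params:
        blob = _blob_mask(img.shape, cy + shift[0], cx + shift[1], a, b, phi)
        img[blob] = inten
    return img


def mask_to_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight half-open bounding box (x1, y1, x2, y2) of a binary mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return (int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)


def make_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int, int]]:
    """Render one phantom.

    Returns ``(image, lv_mask, lv_box)`` where ``lv_mask`` is the filled
    outer disk (blood pool plus myocardium) and ``lv_box`` its tight
    bounding box.  Output is a pure function of ``spec`` (including its
    seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    img = _background(spec, rng)
    img, lv_mask = _paint_lv(img, spec)
    params = _sample_distractors(spec, lv_mask, rng)
    img = _draw_distractors(img, params)  # rejection keeps them off the LV
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return img, lv_mask, mask_to_box(lv_mask)


def make_sequence(
    spec: PhantomSpec, motion: MotionSpec
) -> list[tuple[np.ndarray, tuple[int, int, int, int]]]:
    """Render a slice sequence of one individual with compounding motion.

    The in-plane translation is global — background shading, noise texture
    and distractor tissue drift together with the LV, as the whole field of
    view does between neighboring slices — while the scale factor changes
    the LV size only.  Frame ``t`` has LV center ``center + t*(dy, dx)``
    and radii scaled by ``scale**t``; identity motion yields bit-identical
    frames.  Raises if any frame's annulus would leave the image.
    """
    spec.validate()
    motion.validate()
    dx, dy = motion.translation
    specs = []
    for t in range(motion.n_frames):
        s = motion.scale**t
        ft = replace(
            spec,
            lv_center=(spec.lv_center[0] + t * dy, spec.lv_center[1] + t * dx),
            blood_pool_radius=spec.blood_pool_radius * s,
            myocardium_thickness=spec.myocardium_thickness * s,
            noise_sd=0.0,
            n_distractors=0,
        )
        try:
            ft.validate()
        except ValueError as e:
            raise ValueError(f"trajectory leaves bounds at frame {t}: {e}") from e
        specs.append(ft)

    rng = np.random.default_rng(spec.seed)
    # distractors travel with the LV, so rejecting against the largest LV
    # footprint at the frame-0 position keeps them clear in every frame
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    r_max = max(ft.outer_radius for ft in specs)
    footprint = (
        np.hypot(yy - spec.lv_center[0], xx - spec.lv_center[1]) < r_max + 1
    )
    params = _sample_distractors(spec, footprint, rng)
    # one noise canvas large enough for every integer shift of the scene
    pad_y = int(np.ceil(abs(dy) * (motion.n_frames - 1))) + 1
    pad_x = int(np.ceil(abs(dx) * (motion.n_frames - 1))) + 1
    noise_canvas = (
        rng.normal(0.0, spec.noise_sd, (h + 2 * pad_y, w + 2 * pad_x))
        if spec.noise_sd > 0
        else None
    )

    frames = []
    for t, ft in enumerate(specs):
        shift = (t * dy, t * dx)
        img = _background(spec, rng, shift=shift)
        img = _draw_distractors(img, params, shift=shift)
        img, m = _paint_lv(img, ft)
        if noise_canvas is not None:
            oy = pad_y - int(round(shift[0]))
            ox = pad_x - int(round(shift[1]))
            img = img + noise_canvas[oy : oy + h, ox : ox + w]
        img = np.clip(img, 0.0, 1.0)
        frames.append((img, mask_to_box(m)))
    return frames


def make_training_set(
    n_images: int,
    size_range: tuple[float, float] = (33.0, 14134.0),
    seed: int = 0,
    image_size: tuple[int, int] = (256, 256),
    noise_sd: float = 0.02,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Phantom training pairs with LV areas log-uniform over ``size_range``.

    The default range spans the two orders of magnitude of LV area observed
    across short-axis slices (a few tens of pixels up to ~14k pixels).
    Returns ``n_images`` reproducible ``(image, lv_mask)`` pairs.
    """
    lo, hi = size_range
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not (0 < lo <= hi):
        raise ValueError("size_range must be a nonempty positive interval")
    h, w = image_size
    max_area = np.pi * (min(h, w) / 2 - 2) ** 2
    if lo > max_area:
        raise ValueError("size_range does not fit the requested image size")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_images):
        area = float(np.exp(rng.uniform(np.log(lo), np.log(min(hi, max_area)))))
        r_out = max(np.sqrt(area / np.pi), 3.0)
        thick = max(1.0, 0.3 * r_out)
        margin = r_out + 1
        spec = PhantomSpec(
            image_size=image_size,
            lv_center=(
                rng.uniform(margin, h - 1 - margin),
                rng.uniform(margin, w - 1 - margin),
            ),
            blood_pool_radius=r_out - thick,
            myocardium_thickness=thick,
            blood_intensity=float(np.clip(0.9 + rng.normal(0, 0.03), 0, 1)),
            myo_intensity=float(np.clip(0.35 + rng.normal(0, 0.03), 0, 1)),
            noise_sd=noise_sd,
            n_distractors=int(rng.integers(1, 5)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, mask, _ = make_phantom(spec)
        out.append((img, mask))
    return out


def write_manifest(
    directory: str | Path,
    pairs: list[tuple[np.ndarray, np.ndarray]],
    name: str = "manifest.csv",
) -> Path:
    """Write PNG images/masks plus a manifest CSV (paths and LV boxes)."""
    from skimage.io import imsave

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (img, mask) in enumerate(pairs):
        ip = directory / f"image_{k:04d}.png"
        mp = directory / f"mask_{k:04d}.png"
        imsave(ip, (np.clip(img, 0, 1) * 255).astype(np.uint8), check_contrast=False)
        imsave(mp, (mask.astype(np.uint8) * 255), check_contrast=False)
        x1, y1, x2, y2 = mask_to_box(mask)
        rows.append([str(ip), str(mp), x1, y1, x2, y2])
    path = directory / name
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "mask", "x1", "y1", "x2", "y2"])
        writer.writerows(rows)
    return path
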