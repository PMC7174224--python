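"""Synthetic bulk-saffron scene generator with exact ground truth.

Renders the three Iranian commercial grades as they appear in bulk
photographs on a black background:

* **Pushal** — filaments joined in triplets at a common base, with a yellow
  style portion at the joined end (style is lower-value "foreign matter").
* **Negin** — long, intact, separate red filaments, little to no style.
* **Sargol** — short broken red fragments, essentially style-free.

Filaments are rendered as curved capsules (disks stamped along a random
quadratic Bezier spine). Every image comes with an exact label mask, so the
foreground pixel count and the style ("foreign matter") pixel fraction are
known by construction — this is what makes the composition estimator and the
whole downstream pipeline testable without a reference dataset.

Determinism contract: identical parameters (including the seed) produce
bit-identical images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import imageio.v3 as iio

__all__ = [
    "CLASS_LABELS",
    "SceneParams",
    "GroundTruth",
    "default_scene_params",
    "generate_image",
    "generate_dataset",
]

CLASS_LABELS = ("Pushal", "Negin", "Sargol")

#: Dark stigma red and style yellow (hue ~0.12, inside the 0.045-0.279 window).
STIGMA_COLOR = (150, 28, 30)
STYLE_COLOR = (225, 185, 70)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one rendered scene.

    ``filament_length_px`` / ``filament_width_px`` are inclusive sampling
    ranges. ``style_fraction`` is the target fraction of foreground pixels
    rendered in the style (yellow) color; the renderer hits it to within a
    few percent by thresholding position along each filament's spine.
    """

    class_label: str
    n_filaments: int
    filament_length_px: tuple[float, float]
    filament_width_px: tuple[float, float]
    break_probability: float = 0.0
    triplet_join: bool = False
    style_fraction: float = 0.0
    stigma_color: tuple[int, int, int] = STIGMA_COLOR
    style_color: tuple[int, int, int] = STYLE_COLOR
    background_level: int = 8
    noise_sd: float = 2.0
    illumination_gradient: float = 0.2
    brightness_jitter: float = 0.15
    height: int = 512
    width: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.class_label!r}; expected one of {CLASS_LABELS}")
        if self.n_filaments <= 0:
            raise ValueError("n_filaments must be positive")
        lo_l, hi_l = self.filament_length_px
        lo_w, hi_w = self.filament_width_px
        if not (0 < lo_l <= hi_l) or not (0 < lo_w <= hi_w):
            raise ValueError("length/width ranges must be nonempty and positive")
        if hi_w >= lo_l:
            raise ValueError(
                f"degenerate geometry: filament width range {self.filament_width_px} "
                f"reaches the length range {self.filament_length_px}"
            )
        if not 0.0 <= self.break_probability <= 1.0:
            raise ValueError("break_probability must be in [0, 1]")
        if not 0.0 <= self.style_fraction <= 1.0:
            raise ValueError("style_fraction must be in [0, 1]")
        if not 0 <= self.background_level <= 20:
            raise ValueError("background_level must be in [0, 20] to stay below the foreground threshold")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.illumination_gradient <= 1.0:
            raise ValueError("illumination_gradient must be in [0, 1]")
        if self.height < 256 or self.width < 256:
            raise ValueError("canvas must be at least 256 x 256")


@dataclass
class GroundTruth:
    """Exact per-scene truth derived from the rendered label masks."""

    foreground_pixels: int
    style_pixels: int
    filaments: list[dict] = field(default_factory=list)
    label_mask: np.ndarray | None = None
    style_mask: np.ndarray | None = None

    @property
    def style_fraction(self) -> float:
        if self.foreground_pixels == 0:
            return 0.0
        return self.style_pixels / self.foreground_pixels


_CLASS_DEFAULTS = {
    # n_filaments, length range, width range, break prob, triplets, style fraction
    "Pushal": dict(n_filaments=15, filament_length_px=(110.0, 170.0),
                   filament_width_px=(5.0, 8.0), break_probability=0.05,
                   triplet_join=True, style_fraction=0.20),
    "Negin": dict(n_filaments=18, filament_length_px=(140.0, 200.0),
                  filament_width_px=(5.0, 8.0), break_probability=0.0,
                  triplet_join=False, style_fraction=0.03),
    "Sargol": dict(n_filaments=30, filament_length_px=(40.0, 80.0),
                   filament_width_px=(5.0, 8.0), break_probability=0.6,
                   triplet_join=False, style_fraction=0.0),
}


def default_scene_params(class_label: str, seed: int = 0, **overrides) -> SceneParams:
    """Class-typical scene parameters: Negin long and intact, Sargol short and
    broken, Pushal joined triplets carrying ~20% style at the joined end."""
    if class_label not in _CLASS_DEFAULTS:
        raise ValueError(f"unknown class {class_label!r}")
    kwargs = dict(_CLASS_DEFAULTS[class_label])
    kwargs.update(overrides)
    return SceneParams(class_label=class_label, seed=seed, **kwargs)


def _bezier_points(p0, p1, p2, n):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * t * (1 - t) * p1 + (t**2) * p2


def _stamp_filament(label, pos, owner, fid, p0, p2, curvature, width, rng):
    """Stamp disks along a quadratic Bezier spine from p0 to p2.

    ``pos`` records, per pixel, the normalized spine position t of the last
    stamp covering it; t=0 is the filament base (style end), t=1 the tip.
    """
    h, w = label.shape
    chord = p2 - p0
    length = float(np.hypot(*chord))
    mid = (p0 + p2) / 2.0
    normal = np.array([-chord[1], chord[0]]) / max(length, 1e-9)
    p1 = mid + normal * curvature * length
    n = max(int(2 * length), 8)
    pts = _bezier_points(p0, p1, p2, n)
    r = width / 2.0
    ri = int(np.ceil(r))
    dy, dx = np.mgrid[-ri : ri + 1, -ri : ri + 1]
    disk = (dy**2 + dx**2) <= r**2
    offs_y, offs_x = dy[disk], dx[disk]
    t_vals = np.linspace(0.0, 1.0, n)
    for (y, x), t in zip(pts, t_vals):
        yy = np.rint(y + offs_y).astype(int)
        xx = np.rint(x + offs_x).astype(int)
        keep = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        yy, xx = yy[keep], xx[keep]
        label[yy, xx] = True
        pos[yy, xx] = t
        owner[yy, xx] = fid


def generate_image(params: SceneParams) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; returns the uint8 RGB image and its ground truth."""
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    label = np.zeros((h, w), dtype=bool)
    pos = np.full((h, w), -1.0)
    owner = np.full((h, w), -1, dtype=np.int32)

    margin = 0.12
    lo_l, hi_l = params.filament_length_px
    lo_w, hi_w = params.filament_width_px
    filaments = []
    fid = 0
    remaining = params.n_filaments
    while remaining > 0:
        group = min(3, remaining) if params.triplet_join else 1
        base = np.array([
            rng.uniform(margin * h, (1 - margin) * h),
            rng.uniform(margin * w, (1 - margin) * w),
        ])
        theta0 = rng.uniform(0, 2 * np.pi)
        for g in range(group):
            length = rng.uniform(lo_l, hi_l)
            broken = rng.random() < params.break_probability
            if broken:
                length *= rng.uniform(0.3, 0.6)
            width = rng.uniform(lo_w, hi_w)
            # triplet members fan out from the shared base
            theta = theta0 + (g - 1) * rng.uniform(0.25, 0.5) if group > 1 else theta0
            tip = base + length * np.array([np.sin(theta), np.cos(theta)])
            curvature = rng.uniform(-0.18, 0.18)
            _stamp_filament(label, pos, owner, fid, base.copy(), tip, curvature, width, rng)
            filaments.append({
                "id": fid, "base": tuple(base), "tip": tuple(tip),
                "length_px": length, "width_px": width, "broken": broken,
            })
            fid += 1
        remaining -= group

    fg = np.flatnonzero(label)
    style_mask = np.zeros((h, w), dtype=bool)
    if params.style_fraction > 0 and fg.size > 0:
        # style occupies the low-t (base) end of each filament: threshold the
        # spine-position map at the global quantile hitting the target fraction
        tau = np.quantile(pos.ravel()[fg], params.style_fraction)
        style_mask = label & (pos <= tau)

    # per-filament multiplicative brightness jitter
    jitter = 1.0 + rng.uniform(-params.brightness_jitter, params.brightness_jitter,
                               size=max(fid, 1))
    image = np.full((h, w, 3), float(params.background_level))
    stigma = np.array(params.stigma_color, dtype=float)
    style = np.array(params.style_color, dtype=float)
    on = label
    col = np.where(style_mask[..., None], style, stigma)
    gain = jitter[np.clip(owner, 0, None)][..., None]
    image[on] = (col * gain)[on]

    if params.illumination_gradient > 0:
        phi = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        u = (np.cos(phi) * xx / max(w - 1, 1)) + (np.sin(phi) * yy / max(h - 1, 1))
        u = (u - u.min()) / max(u.max() - u.min(), 1e-9)
        image *= (1.0 - 0.3 * params.illumination_gradient * (1.0 - u))[..., None]

    if params.noise_sd > 0:
        image += rng.normal(0.0, params.noise_sd, size=image.shape)

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    gt = GroundTruth(
        foreground_pixels=int(label.sum()),
        style_pixels=int(style_mask.sum()),
        filaments=filaments,
        label_mask=label,
        style_mask=style_mask,
    )
    return image, gt


def generate_dataset(
    counts: dict[str, int],
    params_by_class: dict[str, SceneParams] | None = None,
    seed: int = 0,
    out_dir: str | None = None,
) -> tuple[list[tuple[np.ndarray, GroundTruth]], pd.DataFrame]:
    """Generate a labeled image set plus its manifest.

    Parameters
    ----------
    counts : mapping class label -> number of scenes (>= 0).
    params_by_class : optional per-class :class:`SceneParams` templates; the
        per-scene seed is overridden with one derived from ``seed``.
    seed : master seed; child seeds are spawned deterministically from it.
    out_dir : if given, PNGs are written there and the manifest gains paths.

    Returns
    -------
    scenes : list of (image, ground truth), in manifest order.
    manifest : DataFrame with columns sample_id, path, class, style_fraction, seed.
    """
    for cls, n in counts.items():
        if cls not in CLASS_LABELS:
            raise ValueError(f"unknown class {cls!r}")
        if n < 0:
            raise ValueError("counts must be nonnegative")
    total = sum(counts.values())
    child_seeds = np.random.SeedSequence(seed).generate_state(max(total, 1)) % (2**31)
    scenes: list[tuple[np.ndarray, GroundTruth]] = []
    rows = []
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    i = 0
    for cls in CLASS_LABELS:
        for _ in range(counts.get(cls, 0)):
            template = (params_by_class or {}).get(cls) or default_scene_params(cls)
            sp = replace(template, class_label=cls, seed=int(child_seeds[i]))
            image, gt = generate_image(sp)
            sample_id = f"{cls.lower()}_{i:04d}"
            path = ""
            if out_dir is not None:
                path = os.path.join(out_dir, f"{sample_id}.png")
                iio.imwrite(path, image)
            rows.append({
                "sample_id": sample_id, "path": path, "class": cls,
                "style_fraction": sp.style_fraction, "seed": sp.seed,
            })
            scenes.append((image, gt))
            i += 1
    manifest = pd.DataFrame(rows, columns=["sample_id", "path", "class", "style_fraction", "seed"])
    return scenes, manifest
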