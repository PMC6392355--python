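"""Seeded synthetic camera-trap deployments with exact ground truth.

The generator emulates the circumstances that make camera-trap filtering
hard: bursts of ~10 frames over a static textured background, 0-1 moving
human/animal sprites per sequence, blowing-vegetation block flicker,
smooth bright sunspot patches, day/night (grayscale IR) variants, and
sensor noise — all rendered deterministically from one seed, with
per-frame bounding boxes and sequence labels recorded by construction.

Sprites are textured ellipsoidal blobs: animals are wide brown blotchy
ellipses, humans are tall dark striped figures with a head.  They are
deliberately discriminable by shape and texture without pretrained
weights, so a desk-scale CNN separates the classes in minutes on a CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

DEFAULT_IMAGE_SIZE = (512, 384)       # (w, h)
DEFAULT_FRAMES = 10
BASE_TIME = datetime(2023, 6, 1, 8, 0, 0, tzinfo=timezone.utc)

# demo deployment: 2 animal, 1 human, 3 background (vegetation flicker
# twice, one sunspot); one animal sequence is a night/IR burst
DEFAULT_PLAN = (
    {"cls": "animal", "nuisance": "none", "night": False},
    {"cls": "animal", "nuisance": "none", "night": True},
    {"cls": "human", "nuisance": "none", "night": False},
    {"cls": "none", "nuisance": "vegetation", "night": False},
    {"cls": "none", "nuisance": "vegetation", "night": False},
    {"cls": "none", "nuisance": "sunspot", "night": False},
)

_EXIF_IFD = 0x8769
_DATETIME_ORIGINAL = 36867


@dataclass
class SceneConfig:
    """Parameters of one synthetic deployment."""

    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE
    frames_per_sequence: int = DEFAULT_FRAMES
    plan: tuple[dict, ...] = DEFAULT_PLAN
    noise_sigma: float = 2.0
    veg_flicker_rate: float = 0.02    # fraction of blocks perturbed per frame
    sunspot_frames: tuple[int, int] = (3, 8)   # half-open frame range
    seed: int = 0

    @property
    def n_sequences(self) -> int:
        return len(self.plan)


# ---------------------------------------------------------------------------
# renderers


def _background_texture(rng: np.random.Generator, w: int, h: int) -> np.ndarray:
    """Static vegetation-like texture: strong isotropic local contrast.

    Local gradients are kept well above sensor-noise scale so that block
    orientation histograms are texture-dominated, as in real foliage, and
    isotropic so that oriented object structure stands out.
    """
    base = np.array(
        [[95, 105, 80], [105, 95, 75], [90, 100, 90], [110, 105, 85]][rng.integers(4)],
        dtype=np.float64,
    )
    low = gaussian_filter(rng.standard_normal((h, w)), sigma=18) * 120
    mid = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0) * 50
    fine = gaussian_filter(rng.standard_normal((h, w)), sigma=0.8) * 35
    lum = low + mid + fine
    img = base[None, None, :] + lum[:, :, None]
    tint = gaussian_filter(rng.standard_normal((h, w)), sigma=12) * 40
    img[:, :, 1] += tint          # green modulation
    return np.clip(img, 0, 255)


def _ellipse_alpha(w: int, h: int, edge: float = 0.12) -> np.ndarray:
    y, x = np.mgrid[0:h, 0:w]
    ry = (y - (h - 1) / 2) / (h / 2)
    rx = (x - (w - 1) / 2) / (w / 2)
    r = np.sqrt(rx**2 + ry**2)
    return np.clip((1.0 - r) / edge, 0, 1)


def _ring_texture(
    rng: np.random.Generator, w: int, h: int, period: float, amp: float, n_patches: int
) -> np.ndarray:
    """Concentric elliptical banding plus oriented patches.

    The local orientation varies across the body, so the block histogram
    of a moving sprite changes frame to frame — unlike straight striping,
    whose orientation histogram is translation-invariant and would let
    the background model mistake a co-located sprite pair for background.
    """
    y, x = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r = np.sqrt(((x - cx) / (w / 2)) ** 2 + ((y - cy) / (h / 2)) ** 2)
    tex = amp * np.sin(2 * np.pi * r * max(w, h) / 2 / period + rng.uniform(0, 2 * np.pi))
    for _ in range(n_patches):
        px, py = rng.uniform(0.15, 0.85) * w, rng.uniform(0.15, 0.85) * h
        theta = rng.uniform(0, np.pi)
        pp = rng.uniform(8, 14)
        win = np.exp(-(((x - px) ** 2 + (y - py) ** 2) / (2 * (min(w, h) / 6) ** 2)))
        tex = tex + 45 * win * np.sin(2 * np.pi * (x * np.cos(theta) + y * np.sin(theta)) / pp)
    return tex


def animal_sprite(rng: np.random.Generator, w: int = 120, h: int = 72):
    """Wide brown ellipse with coarse fur-like banding;
    returns (rgb float HxWx3, alpha HxW)."""
    alpha = _ellipse_alpha(w, h)
    base = np.array([115, 82, 55], dtype=np.float64)
    tex = _ring_texture(rng, w, h, period=14, amp=40, n_patches=5)
    blotch = gaussian_filter(rng.standard_normal((h, w)), sigma=6) * 20
    rgb = np.clip(base[None, None, :] + (tex + blotch)[:, :, None], 0, 255)
    return rgb, alpha


def human_sprite(rng: np.random.Generator, w: int = 64, h: int = 128):
    """Tall dark torso with fine clothing-like banding and a head blob."""
    alpha = np.zeros((h, w))
    head_h = h // 4
    torso = _ellipse_alpha(w, h - head_h, edge=0.18)
    alpha[head_h:] = torso
    head_w = max(w // 2, 8)
    head = _ellipse_alpha(head_w, int(head_h * 1.3), edge=0.2)
    x0 = (w - head_w) // 2
    alpha[: head.shape[0] - head_h // 3, x0 : x0 + head_w] = np.maximum(
        alpha[: head.shape[0] - head_h // 3, x0 : x0 + head_w],
        head[head_h // 3 :],
    )
    base = np.array([58, 60, 92], dtype=np.float64)
    tex = _ring_texture(rng, w, h, period=8, amp=42, n_patches=4)
    shade = gaussian_filter(rng.standard_normal((h, w)), sigma=6) * 15
    rgb = np.clip(base[None, None, :] + (tex + shade)[:, :, None], 0, 255)
    # head gets a smooth skin-ish tone
    rgb[:head_h] = np.clip(
        np.array([170, 140, 115])[None, None, :]
        + (gaussian_filter(rng.standard_normal((head_h, w)), sigma=3) * 10)[:, :, None],
        0,
        255,
    )
    return rgb, alpha


def _compose(scene: np.ndarray, sprite_rgb: np.ndarray, alpha: np.ndarray, x: int, y: int):
    """Alpha-blend a sprite at (x, y); returns the tight bbox of alpha>0.5."""
    h, w = alpha.shape
    scene[y : y + h, x : x + w] = (
        scene[y : y + h, x : x + w] * (1 - alpha[:, :, None]) + sprite_rgb * alpha[:, :, None]
    )
    ys, xs = np.nonzero(alpha > 0.5)
    return (x + int(xs.min()), y + int(ys.min()), x + int(xs.max()) + 1, y + int(ys.max()) + 1)


def _vegetation_flicker(rng: np.random.Generator, scene: np.ndarray, rate: float) -> np.ndarray:
    """Transient wind-blown vegetation: clumps of blocks overwritten by
    smooth dappled stripes at a random orientation, different every frame.

    The oriented structure makes flicker clumps genuinely trigger the
    block-level foreground test, exercising the downstream false-positive
    defenses (SHL, patch classification, cross-frame verification).
    """
    out = scene.copy()
    h, w = scene.shape[:2]
    rows, cols = h // 16, w // 16
    n_clumps = max(1, int(rate * rows * cols / 4))
    yy, xx = np.mgrid[0:32, 0:32]
    for _ in range(n_clumps):
        r = int(rng.integers(rows - 1))
        c = int(rng.integers(cols - 1))
        y0, x0 = r * 16, c * 16
        theta = rng.uniform(0, np.pi)
        period = rng.uniform(8, 16)
        phase = rng.uniform(0, 2 * np.pi)
        wave = 50 * np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / period + phase)
        region = out[y0 : y0 + 32, x0 : x0 + 32]
        tint = np.array([0.9, 1.1, 0.85])
        region[:] = np.clip(region * tint[None, None, :] + wave[: region.shape[0], : region.shape[1], None], 0, 255)
    return out


def _sunspot(scene: np.ndarray, cx: float, cy: float, ax: float = 60, ay: float = 40) -> np.ndarray:
    """Smooth bright saturated ellipse, like sun through the canopy."""
    h, w = scene.shape[:2]
    y, x = np.mgrid[0:h, 0:w]
    r = np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2)
    glow = np.clip(1.6 * (1.0 - r), 0, 1) ** 0.7
    return np.clip(scene + glow[:, :, None] * 220, 0, 255)


# ---------------------------------------------------------------------------
# deployment generation


def _sprite_plan(cls: str, rng: np.random.Generator, w: int, h: int, n_frames: int):
    """Sprite renderer plus a linear motion path that stays in frame."""
    if cls == "animal":
        sw, sh = 120, 72
        rgb, alpha = animal_sprite(rng, sw, sh)
        step = 35
    else:
        sw, sh = 64, 128
        rgb, alpha = human_sprite(rng, sw, sh)
        step = 20
    span = step * (n_frames - 1)
    x0 = int(rng.integers(16, max(17, w - sw - span - 16)))
    y0 = int(rng.integers(16, h - sh - 16))
    direction = 1 if rng.random() < 0.5 else -1
    if direction < 0:
        x0 = x0 + span
    xs = [x0 + direction * step * f for f in range(n_frames)]
    ys = [y0 + int(3 * np.sin(f)) for f in range(n_frames)]
    return rgb, alpha, xs, ys


def _write_jpeg(path: Path, arr: np.ndarray, timestamp: datetime, night: bool):
    if night:
        gray = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
        img = Image.fromarray(np.clip(np.round(gray), 0, 255).astype(np.uint8), mode="L")
    else:
        img = Image.fromarray(np.clip(np.round(arr), 0, 255).astype(np.uint8))
    exif = Image.Exif()
    exif.get_ifd(_EXIF_IFD)[_DATETIME_ORIGINAL] = timestamp.strftime("%Y:%m:%d %H:%M:%S")
    img.save(path, quality=95, exif=exif)


def gen_deployment(out_dir: str | Path, config: SceneConfig | None = None) -> dict:
    """Render a deployment into ``out_dir``.

    Writes one JPEG per frame (EXIF DateTimeOriginal set, timestamp also
    encoded in the filename), ``ground_truth.csv`` with per-frame boxes,
    and ``manifest.json`` with sequence labels.  Returns the manifest.
    Byte-identical for a fixed config.
    """
    config = config or SceneConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    w, h = config.image_size
    seqs = []
    gt_rows = []
    children = np.random.SeedSequence(config.seed).spawn(config.n_sequences)
    t = BASE_TIME
    for si, spec in enumerate(config.plan):
        rng = np.random.default_rng(children[si])
        cls, nuisance, night = spec["cls"], spec["nuisance"], spec["night"]
        background = _background_texture(rng, w, h)
        sprite = None
        if cls in ("animal", "human"):
            sprite = _sprite_plan(cls, rng, w, h, config.frames_per_sequence)
        spot_cx = rng.uniform(0.25, 0.75) * w
        spot_cy = rng.uniform(0.25, 0.75) * h
        images, boxes = [], {}
        for f in range(config.frames_per_sequence):
            scene = background.copy()
            if nuisance == "vegetation":
                scene = _vegetation_flicker(rng, scene, config.veg_flicker_rate)
            if nuisance == "sunspot" and config.sunspot_frames[0] <= f < config.sunspot_frames[1]:
                scene = _sunspot(scene, spot_cx + 2 * f, spot_cy)
            bbox = None
            if sprite is not None:
                rgb, alpha, xs, ys = sprite
                bbox = _compose(scene, rgb, alpha, xs[f], ys[f])
            scene = scene + rng.standard_normal(scene.shape) * config.noise_sigma
            name = f"seq{si:02d}_{t.strftime('%Y%m%d_%H%M%S')}_f{f:02d}.jpg"
            _write_jpeg(out_dir / name, scene, t, night)
            images.append(name)
            if bbox is not None:
                boxes[name] = [list(bbox) + [cls]]
                gt_rows.append(
                    {"image": name, "x_min": bbox[0], "y_min": bbox[1],
                     "x_max": bbox[2], "y_max": bbox[3], "class": cls}
                )
            t = t + timedelta(seconds=int(rng.integers(1, 6)))
        label = cls if cls in ("animal", "human") else "background"
        seqs.append(
            {"sequence_id": f"seq{si:02d}", "label": label, "nuisance": nuisance,
             "night": night, "n_frames": config.frames_per_sequence,
             "images": images, "boxes": boxes}
        )
        t = t + timedelta(seconds=600)   # well past the 60 s grouping gap
    manifest = {
        "deployment_id": out_dir.name,
        "seed": config.seed,
        "image_size": list(config.image_size),
        "sequences": seqs,
    }
    pd.DataFrame(
        gt_rows, columns=["image", "x_min", "y_min", "x_max", "y_max", "class"]
    ).to_csv(out_dir / "ground_truth.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# patch dataset generation


def _render_patch(cls: str, rng: np.random.Generator) -> np.ndarray:
    """One labeled patch: sprite crop over texture, or pure background."""
    if cls == "animal":
        sw = int(rng.integers(90, 150))
        sh = int(sw * 0.6 * rng.uniform(0.85, 1.15))
        rgb, alpha = animal_sprite(rng, sw, sh)
    elif cls == "human":
        sh = int(rng.integers(100, 160))
        sw = int(sh * 0.5 * rng.uniform(0.85, 1.15))
        rgb, alpha = human_sprite(rng, sw, sh)
    else:
        sw = sh = 0
    mx = int(rng.integers(8, 40))
    my = int(rng.integers(8, 40))
    w, h = sw + 2 * mx, sh + 2 * my
    if cls == "background":
        w = h = int(rng.integers(64, 160))
    scene = _background_texture(rng, w, h)
    if cls == "background":
        kind = rng.integers(3)
        if kind == 1:
            scene = _sunspot(scene, w * rng.uniform(0.3, 0.7), h * rng.uniform(0.3, 0.7),
                             ax=w * 0.45, ay=h * 0.45)
        elif kind == 2:
            scene = _vegetation_flicker(rng, scene, rate=0.3)
    else:
        _compose(scene, rgb, alpha, mx, my)
    scene = scene + rng.standard_normal(scene.shape) * 2.0
    if rng.random() < 1 / 3:   # night/IR variant
        gray = scene[..., 0] * 0.299 + scene[..., 1] * 0.587 + scene[..., 2] * 0.114
        scene = np.repeat(gray[:, :, None], 3, axis=2)
    return np.clip(np.round(scene), 0, 255).astype(np.uint8)


def gen_patch_dataset(
    out_dir: str | Path,
    n_per_class: int = 600,
    n_test_per_class: int = 200,
    seed: int = 0,
) -> dict:
    """Write a class-per-subfolder 96x96 patch tree with disjoint
    ``train/`` and ``test/`` splits.  Returns a manifest dict."""
    from .patch_classifier import CLASSES, rescale_patch

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    counts = {}
    ss = np.random.SeedSequence(seed)
    train_ss, test_ss = ss.spawn(2)
    for split, n, split_ss in (("train", n_per_class, train_ss), ("test", n_test_per_class, test_ss)):
        class_seeds = split_ss.spawn(len(CLASSES))
        for cls, cseed in zip(CLASSES, class_seeds):
            rng = np.random.default_rng(cseed)
            cdir = out_dir / split / cls
            cdir.mkdir(parents=True, exist_ok=True)
            for i in range(n):
                patch = rescale_patch(_render_patch(cls, rng))
                Image.fromarray(patch).save(cdir / f"{cls}_{i:05d}.png")
            counts[f"{split}/{cls}"] = n
    manifest = {"seed": seed, "counts": counts, "patch_size": 96}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
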