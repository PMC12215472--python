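"""Augmentation and challenge-set synthesis for robustness evaluation.

Real bird photographs are frequently degraded in the field: sensor noise,
birds hidden behind foliage and branches, hard shadows.  This module builds
the machinery to emulate those conditions on any class-per-folder image
dataset:

* geometric/photometric augmentation (rotation, flips, shift, scale, shear)
  with a preset matching the statistical-validation protocol's parameter
  ranges: rotation 10–20 deg, horizontal-flip probability 0.1–0.5, vertical
  shift 0–0.1, per-axis scale 0.01–0.1;
* class balancing by augmenting each class folder up to a target count;
* noise challenge sets — TD1 corrupts 25–40% of pixels, TD2 40–50%
  (salt-and-pepper by default; an additive-Gaussian mode is provided);
* occlusion challenge sets (TD3) — parametric leaves, branches and shadows
  composited over the frame with a target coverage fraction;
* a procedural bird-like image generator so the whole pipeline is testable
  without any external dataset.

Every randomized operation is a pure function of (input, spec, seed): the
same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, ImageDraw

__all__ = [
    "AugmentSpec",
    "NoiseSpec",
    "OccluderSpec",
    "DatasetManifest",
    "ManifestEntry",
    "augment_image",
    "balance_class",
    "add_noise",
    "add_occluders",
    "make_occluded_subset",
    "generate_synthetic_images",
]

_IMAGE_EXTS = {".png", ".jpg", ".jpeg"}


def _as_range(value, name: str) -> tuple[float, float]:
    if np.isscalar(value):
        value = (float(value), float(value))
    lo, hi = float(value[0]), float(value[1])
    if hi < lo:
        raise ValueError(f"{name}: range ({lo}, {hi}) is decreasing")
    return lo, hi


def _load_rgb(image) -> np.ndarray:
    """Accept a PIL image, an array or a path; return uint8 RGB (H, W, 3)."""
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, Image.Image):
        arr = np.asarray(image.convert("RGB"))
    else:
        arr = np.asarray(image)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an RGB raster, got shape {arr.shape}")
    return np.ascontiguousarray(arr, dtype=np.uint8)


# ---------------------------------------------------------------------------
# geometric / photometric augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentSpec:
    """Parameter ranges for one augmentation draw.

    Each field is a (lo, hi) range (scalars are treated as degenerate ranges);
    the realised parameter for an image is drawn uniformly from the range.
    ``hflip_prob``/``vflip_prob`` are per-image flip probabilities (themselves
    drawn from a range, so a range (0.1, 0.5) means "flip with a probability
    drawn between 10% and 50%").
    """

    rotation_deg: tuple[float, float] = (0.0, 0.0)
    hflip_prob: tuple[float, float] = (0.0, 0.0)
    vflip_prob: tuple[float, float] = (0.0, 0.0)
    vshift_frac: tuple[float, float] = (0.0, 0.0)
    scale_frac: tuple[float, float] = (0.0, 0.0)
    shear_deg: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "hflip_prob", "vflip_prob",
                     "vshift_frac", "scale_frac", "shear_deg"):
            object.__setattr__(self, name, _as_range(getattr(self, name), name))
        for name in ("hflip_prob", "vflip_prob"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi > 1:
                raise ValueError(f"{name} must lie within [0, 1]")

    @classmethod
    def identity(cls) -> "AugmentSpec":
        return cls()

    @classmethod
    def validation(cls) -> "AugmentSpec":
        """The statistical-validation preset: rotation 10–20 deg, horizontal
        flip 0.1–0.5, vertical shift 0–0.1, per-axis scale 0.01–0.1."""
        return cls(rotation_deg=(10.0, 20.0), hflip_prob=(0.1, 0.5),
                   vshift_frac=(0.0, 0.1), scale_frac=(0.01, 0.1))

    def sample(self, rng: np.random.Generator) -> dict:
        """Draw one concrete parameter set (fixed draw order for determinism)."""
        rot = rng.uniform(*self.rotation_deg)
        rot_sign = -1.0 if rng.random() < 0.5 else 1.0
        hflip = rng.random() < rng.uniform(*self.hflip_prob)
        vflip = rng.random() < rng.uniform(*self.vflip_prob)
        vshift = rng.uniform(*self.vshift_frac)
        shift_sign = -1.0 if rng.random() < 0.5 else 1.0
        sx = rng.uniform(*self.scale_frac)
        sy = rng.uniform(*self.scale_frac)
        shear = rng.uniform(*self.shear_deg)
        shear_sign = -1.0 if rng.random() < 0.5 else 1.0
        return {"rotation": rot_sign * rot, "hflip": bool(hflip), "vflip": bool(vflip),
                "vshift": shift_sign * vshift, "scale_x": sx, "scale_y": sy,
                "shear": shear_sign * shear}


def augment_image(image, spec: AugmentSpec, seed: int) -> np.ndarray:
    """Apply one seeded augmentation draw; identity spec returns the input.

    Operations whose sampled parameter is exactly zero are skipped, so the
    all-zero spec is a strict no-op and outputs are bit-reproducible per seed.
    """
    arr = _load_rgb(image)
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError(f"image too small to augment: {arr.shape[:2]}")
    rng = np.random.default_rng(seed)
    params = spec.sample(rng)

    out = arr
    if params["hflip"]:
        out = out[:, ::-1]
    if params["vflip"]:
        out = out[::-1]

    h, w = out.shape[:2]
    img = Image.fromarray(np.ascontiguousarray(out))
    if params["scale_x"] != 0.0 or params["scale_y"] != 0.0:
        # enlarge per axis then center-crop back to the original frame
        nw = max(w + 1, int(round(w * (1 + params["scale_x"]))))
        nh = max(h + 1, int(round(h * (1 + params["scale_y"]))))
        img = img.resize((nw, nh), Image.BILINEAR)
        left, top = (nw - w) // 2, (nh - h) // 2
        img = img.crop((left, top, left + w, top + h))
    if params["shear"] != 0.0:
        m = np.tan(np.deg2rad(params["shear"]))
        img = img.transform((w, h), Image.AFFINE, (1.0, m, -m * h / 2, 0.0, 1.0, 0.0),
                            resample=Image.BILINEAR)
    if params["rotation"] != 0.0:
        img = img.rotate(params["rotation"], resample=Image.BILINEAR)
    if params["vshift"] != 0.0:
        dy = int(round(params["vshift"] * h))
        if dy:
            img = img.transform((w, h), Image.AFFINE, (1.0, 0.0, 0.0, 0.0, 1.0, -dy),
                                resample=Image.NEAREST)
    return np.asarray(img, dtype=np.uint8)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    path: str
    provenance: str  # original | augmented | occluded | noised


@dataclass
class DatasetManifest:
    """Class-per-folder listing with provenance tags per image."""

    root: str
    classes: dict[str, list[ManifestEntry]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.classes.items()}

    def verify(self) -> None:
        root = Path(self.root)
        for cls, entries in self.classes.items():
            for e in entries:
                if not (root / e.path).exists():
                    raise FileNotFoundError(f"manifest entry missing on disk: {e.path}")

    def to_dict(self) -> dict:
        return {"root": self.root,
                "counts": self.counts,
                "classes": {c: [{"path": e.path, "provenance": e.provenance}
                                for e in v] for c, v in self.classes.items()}}

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        classes = {c: [ManifestEntry(e["path"], e["provenance"]) for e in v]
                   for c, v in d["classes"].items()}
        return cls(root=d["root"], classes=classes)

    @classmethod
    def scan(cls, root: str | Path) -> "DatasetManifest":
        """Build a manifest from a class-per-folder tree (all tagged original)."""
        root = Path(root)
        classes: dict[str, list[ManifestEntry]] = {}
        for sub in sorted(p for p in root.iterdir() if p.is_dir()):
            entries = [ManifestEntry(str(f.relative_to(root)), "original")
                       for f in sorted(sub.iterdir())
                       if f.suffix.lower() in _IMAGE_EXTS]
            if entries:
                classes[sub.name] = entries
        return cls(root=str(root), classes=classes)


def balance_class(folder: str | Path, target_count: int, spec: AugmentSpec,
                  seed: int, out_dir: str | Path | None = None) -> list[ManifestEntry]:
    """Top a class folder up to ``target_count`` images by seeded augmentation.

    Originals are all retained; the remainder are augmented copies cycling
    over the originals with per-image sub-seeds.  Output files are written to
    ``out_dir`` (defaults to the folder itself) as PNG.
    """
    folder = Path(folder)
    out_dir = folder if out_dir is None else Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    originals = sorted(f for f in folder.iterdir() if f.suffix.lower() in _IMAGE_EXTS)
    if not originals:
        raise ValueError(f"class folder {folder} contains no images")
    if target_count < len(originals):
        raise ValueError(
            f"target {target_count} below current count {len(originals)}"
        )
    entries = [ManifestEntry(str(f), "original") for f in originals]
    rng = np.random.default_rng(seed)
    for i in range(target_count - len(originals)):
        src = originals[i % len(originals)]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out = augment_image(src, spec, sub_seed)
        dest = out_dir / f"aug_{i:05d}_{src.stem}.png"
        Image.fromarray(out).save(dest)
        entries.append(ManifestEntry(str(dest), "augmented"))
    return entries


# ---------------------------------------------------------------------------
# noise injection (TD1 / TD2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Pixel-corruption spec; the realised fraction is drawn from the range."""

    fraction_range: tuple[float, float] = (0.25, 0.40)
    kind: str = "salt_pepper"  # or "gaussian"

    def __post_init__(self) -> None:
        lo, hi = _as_range(self.fraction_range, "fraction_range")
        if lo < 0 or hi > 1:
            raise ValueError(f"fraction_range must lie within [0, 1], got ({lo}, {hi})")
        object.__setattr__(self, "fraction_range", (lo, hi))
        if self.kind not in ("salt_pepper", "gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")

    @classmethod
    def td1(cls) -> "NoiseSpec":
        return cls(fraction_range=(0.25, 0.40))

    @classmethod
    def td2(cls) -> "NoiseSpec":
        return cls(fraction_range=(0.40, 0.50))


def add_noise(image, spec: NoiseSpec, seed: int) -> np.ndarray:
    """Corrupt a seeded uniform draw f of the pixels.

    Salt-and-pepper mode flips exactly ``round(f * n_pixels)`` distinct pixels
    to black or white (50/50); a pixel already equal to the drawn extreme is
    set to the other one, so the changed-pixel count is exact.  Gaussian mode
    adds zero-mean noise with standard deviation ``f * 127.5`` to every pixel.
    """
    arr = _load_rgb(image).copy()
    rng = np.random.default_rng(seed)
    f = rng.uniform(*spec.fraction_range)
    h, w = arr.shape[:2]
    if spec.kind == "gaussian":
        noise = rng.normal(0.0, f * 127.5, size=arr.shape)
        return np.clip(arr.astype(float) + noise, 0, 255).astype(np.uint8)
    n_corrupt = int(round(f * h * w))
    if n_corrupt == 0:
        return arr
    flat_idx = rng.choice(h * w, size=n_corrupt, replace=False)
    colors = rng.integers(0, 2, size=n_corrupt) * 255  # 0 = pepper, 255 = salt
    rows, cols = np.unravel_index(flat_idx, (h, w))
    already = (arr[rows, cols] == colors[:, None]).all(axis=1)
    colors[already] = 255 - colors[already]
    arr[rows, cols] = colors[:, None]
    return arr


# ---------------------------------------------------------------------------
# occluder synthesis (TD3)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccluderSpec:
    """Parametric foreground occluders with a target coverage fraction.

    ``shapes`` selects from leaf (filled ellipse, green-brown palette),
    branch (thick brown polyline) and shadow (semi-transparent dark polygon).
    ``opacity`` is the shadow darkening strength; leaves and branches are
    opaque.  Shapes are added until the mask covers the target; each shape is
    capped at 20% of the target area, bounding the rendered coverage within
    +-20% relative of the target.
    """

    shapes: tuple[str, ...] = ("leaf", "branch", "shadow")
    coverage: float = 0.12
    count_range: tuple[int, int] = (1, 400)
    opacity: float = 0.5

    def __post_init__(self) -> None:
        shapes = tuple(self.shapes)
        if not shapes or not set(shapes) <= {"leaf", "branch", "shadow"}:
            raise ValueError(f"shapes must be a non-empty subset of leaf/branch/shadow")
        object.__setattr__(self, "shapes", shapes)
        if not (0.0 <= self.coverage < 1.0):
            raise ValueError(f"coverage must lie in [0, 1), got {self.coverage}")
        if not (0.0 < self.opacity <= 1.0):
            raise ValueError("opacity must lie in (0, 1]")


_LEAF_PALETTE = [(34, 102, 34), (60, 122, 48), (86, 130, 40), (110, 96, 40)]
_BRANCH_PALETTE = [(101, 67, 33), (80, 55, 30), (120, 85, 45)]


def _draw_one_occluder(draw_img: Image.Image, mask_img: Image.Image,
                       kind: str, max_area: float, opacity: float,
                       rng: np.random.Generator) -> None:
    w, h = draw_img.size
    draw = ImageDraw.Draw(draw_img, "RGBA")
    mdraw = ImageDraw.Draw(mask_img)
    cx, cy = rng.uniform(0, w), rng.uniform(0, h)
    if kind == "leaf":
        aspect = rng.uniform(0.35, 0.9)
        a = np.sqrt(max_area / (np.pi * aspect))  # semi-axes: pi*a*b = max_area
        b = a * aspect
        angle = rng.uniform(0, 180)
        color = _LEAF_PALETTE[int(rng.integers(len(_LEAF_PALETTE)))]
        # rotated ellipse approximated by a polygon
        t = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        xs = a * np.cos(t)
        ys = b * np.sin(t)
        rad = np.deg2rad(angle)
        px = cx + xs * np.cos(rad) - ys * np.sin(rad)
        py = cy + xs * np.sin(rad) + ys * np.cos(rad)
        poly = list(zip(px, py))
        draw.polygon(poly, fill=color + (255,))
        mdraw.polygon(poly, fill=255)
    elif kind == "branch":
        length = np.sqrt(max_area * rng.uniform(6, 12))
        width = max(1, int(round(max_area / max(length, 1.0))))
        angle = rng.uniform(0, np.pi)
        x0, y0 = cx - length / 2 * np.cos(angle), cy - length / 2 * np.sin(angle)
        x1, y1 = cx + length / 2 * np.cos(angle), cy + length / 2 * np.sin(angle)
        xm = (x0 + x1) / 2 + rng.uniform(-0.1, 0.1) * length
        ym = (y0 + y1) / 2 + rng.uniform(-0.1, 0.1) * length
        color = _BRANCH_PALETTE[int(rng.integers(len(_BRANCH_PALETTE)))]
        for seg in (((x0, y0), (xm, ym)), ((xm, ym), (x1, y1))):
            draw.line(seg, fill=color + (255,), width=width)
            mdraw.line(seg, fill=255, width=width)
    else:  # shadow
        n_vert = int(rng.integers(3, 7))
        radius = np.sqrt(max_area / np.pi) * 1.2
        t = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
        px = cx + radius * np.cos(t) * rng.uniform(0.6, 1.4, n_vert)
        py = cy + radius * np.sin(t) * rng.uniform(0.6, 1.4, n_vert)
        poly = list(zip(px, py))
        alpha = int(round(255 * opacity))
        draw.polygon(poly, fill=(10, 10, 15, alpha))
        mdraw.polygon(poly, fill=255)


def add_occluders(image, spec: OccluderSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Composite parametric occluders; returns (image, boolean mask).

    Opaque occluders (leaf, branch) are guaranteed to change every masked
    pixel; shadows darken multiplicatively, so a pure-black pixel under a
    shadow may be unchanged.
    """
    arr = _load_rgb(image)
    h, w = arr.shape[:2]
    if spec.coverage == 0.0:
        return arr.copy(), np.zeros((h, w), dtype=bool)
    rng = np.random.default_rng(seed)
    target_px = spec.coverage * h * w
    per_shape_cap = max(4.0, 0.2 * target_px)

    img = Image.fromarray(arr)
    mask_img = Image.new("L", (w, h), 0)
    lo, hi = spec.count_range
    count = 0
    while count < hi:
        mask_frac = np.asarray(mask_img, dtype=bool).mean()
        if mask_frac * h * w >= target_px and count >= lo:
            break
        kind = spec.shapes[int(rng.integers(len(spec.shapes)))]
        remaining = max(target_px - mask_frac * h * w, 4.0)
        _draw_one_occluder(img, mask_img, kind, min(per_shape_cap, remaining * 1.05),
                           spec.opacity, rng)
        count += 1

    out = np.asarray(img, dtype=np.uint8).copy()
    mask = np.asarray(mask_img, dtype=bool)
    # opaque occluders must differ from the underlying pixel everywhere on the
    # mask; nudge the rare coincidental matches by one grey level
    same = mask & (out == arr).all(axis=2)
    if same.any():
        r = out[..., 0]
        r[same] = np.where(r[same] < 255, r[same] + 1, r[same] - 1)
    return out, mask


def make_occluded_subset(manifest: DatasetManifest,
                         spec: OccluderSpec,
                         seed: int,
                         fraction_range: tuple[float, float] = (0.10, 0.15),
                         out_root: str | Path | None = None) -> DatasetManifest:
    """Replace a seeded 10–15% draw of each class's images by occluded variants."""
    lo, hi = _as_range(fraction_range, "fraction_range")
    root = Path(manifest.root)
    out_root = root if out_root is None else Path(out_root)
    rng = np.random.default_rng(seed)
    new_classes: dict[str, list[ManifestEntry]] = {}
    for cls, entries in manifest.classes.items():
        f = rng.uniform(lo, hi)
        n_occ = int(round(f * len(entries)))
        chosen = set(rng.choice(len(entries), size=n_occ, replace=False).tolist()) \
            if n_occ else set()
        new_entries = []
        for i, e in enumerate(entries):
            if i in chosen:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                occluded, _ = add_occluders(root / e.path, spec, sub_seed)
                rel = Path(e.path)
                dest_rel = rel.with_name(f"occ_{rel.stem}.png")
                dest = out_root / dest_rel
                dest.parent.mkdir(parents=True, exist_ok=True)
                Image.fromarray(occluded).save(dest)
                new_entries.append(ManifestEntry(str(dest_rel), "occluded"))
            else:
                new_entries.append(e)
        new_classes[cls] = new_entries
    return DatasetManifest(root=str(out_root), classes=new_classes)


# ---------------------------------------------------------------------------
# procedural fixture generator
# ---------------------------------------------------------------------------

def _distinct_palettes(k: int, rng: np.random.Generator,
                       min_dist: float = 60.0) -> list[tuple[int, int, int]]:
    palettes: list[tuple[int, int, int]] = []
    while len(palettes) < k:
        cand = tuple(int(v) for v in rng.integers(30, 226, size=3))
        if all(np.linalg.norm(np.subtract(cand, p)) >= min_dist for p in palettes):
            palettes.append(cand)
    return palettes


def generate_synthetic_images(n_classes: int, per_class: int, seed: int,
                              out_dir: str | Path,
                              size: tuple[int, int] = (96, 96)) -> DatasetManifest:
    """Procedural bird-like fixtures: body ellipse + beak triangle + textured
    background, one distinct colour palette per class.  Deterministic per seed.
    """
    if n_classes < 2 or per_class < 1:
        raise ValueError("need n_classes >= 2 and per_class >= 1")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    w, h = size
    palettes = _distinct_palettes(n_classes, rng)
    classes: dict[str, list[ManifestEntry]] = {}
    for c in range(n_classes):
        cls = f"class_{c:02d}"
        folder = out_dir / cls
        folder.mkdir(parents=True, exist_ok=True)
        body = palettes[c]
        entries = []
        for i in range(per_class):
            bg = rng.integers(90, 170, size=3)
            arr = np.clip(bg + rng.normal(0, 18, size=(h, w, 3)), 0, 255).astype(np.uint8)
            img = Image.fromarray(arr)
            draw = ImageDraw.Draw(img)
            cx = w / 2 + rng.uniform(-w / 8, w / 8)
            cy = h / 2 + rng.uniform(-h / 8, h / 8)
            rx = w * rng.uniform(0.18, 0.28)
            ry = h * rng.uniform(0.12, 0.2)
            draw.ellipse((cx - rx, cy - ry, cx + rx, cy + ry), fill=body)
            beak = (int(np.clip(body[0] * 1.3 + 40, 0, 255)),
                    int(np.clip(body[1] * 0.7, 0, 255)), 30)
            draw.polygon([(cx + rx, cy), (cx + rx + w * 0.09, cy - h * 0.03),
                          (cx + rx + w * 0.09, cy + h * 0.03)], fill=beak)
            draw.ellipse((cx + rx * 0.45 - 2, cy - ry * 0.4 - 2,
                          cx + rx * 0.45 + 2, cy - ry * 0.4 + 2), fill=(10, 10, 10))
            name = f"{cls}_{i:04d}.png"
            img.save(folder / name)
            entries.append(ManifestEntry(str(Path(cls) / name), "original"))
        classes[cls] = entries
    manifest = DatasetManifest(root=str(out_dir), classes=classes)
    manifest.save(out_dir / "manifest.json")
    return manifest
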