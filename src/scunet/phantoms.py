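"""Synthetic brain-tumour phantoms.

Each phantom is a grayscale "brain" — a bright elliptical head region with
smooth low-frequency texture on a dark field — containing 0-2 elliptical
lesions.  Every lesion carries one of three tumour classes (glioma,
meningioma, pituitary), rendered with a class-specific intensity so the
class is learnable from appearance, and rasterised into an integer label
mask (0 = background).  Masks can be round-tripped through the canonical
colour coding red / green / yellow for classes 1 / 2 / 3.

This is a deliberately simplified stand-in for T1-weighted MRI: there is no
bias field, no anatomy beyond the head ellipse, and class-intensity
separation is idealised.  It exercises the data contracts (shapes, label
ranges, class balance, boundaries) rather than MRI realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

__all__ = ["PhantomParams", "Lesion", "Phantom", "generate_phantom",
           "generate_dataset", "augment_pairs", "encode_mask_rgb",
           "decode_mask_rgb", "make_split", "write_dataset", "load_dataset",
           "CLASS_COLOURS"]

# canonical mask colours: glioma red, meningioma green, pituitary yellow
CLASS_COLOURS = {
    0: (0, 0, 0),
    1: (255, 0, 0),
    2: (0, 255, 0),
    3: (255, 255, 0),
}
CLASS_NAMES = {0: "background", 1: "glioma", 2: "meningioma", 3: "pituitary"}

# lesion brightness by class, chosen well-separated from the ~0.35 brain base
_CLASS_INTENSITY = {1: (0.62, 0.03), 2: (0.78, 0.03), 3: (0.93, 0.03)}


@dataclass(frozen=True)
class PhantomParams:
    size: tuple[int, int] = (512, 512)
    lesions_per_image: tuple[int, int] = (0, 2)       # inclusive range
    class_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    axis_range: tuple[float, float] = (10.0, 50.0)    # semi-axes, pixels
    intensity: dict = field(default_factory=lambda: dict(_CLASS_INTENSITY))
    background_texture_scale: float = 12.0            # gaussian blur sigma
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError("phantom size must be at least 32x32")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if any(p < 0 for p in self.class_probs):
            raise ValueError("class_probs must be nonnegative")
        lo, hi = self.axis_range
        if not (0 < lo <= hi) or 2 * hi >= min(h, w):
            raise ValueError("axis_range must be positive and fit in the image")
        if self.lesions_per_image[0] < 0 or \
                self.lesions_per_image[0] > self.lesions_per_image[1]:
            raise ValueError("invalid lesions_per_image range")


@dataclass(frozen=True)
class Lesion:
    cls: int
    center: tuple[float, float]     # (row, col)
    axes: tuple[float, float]       # semi-axes (a, b)
    angle: float                    # radians

    @property
    def area(self) -> float:
        return float(np.pi * self.axes[0] * self.axes[1])

    @property
    def perimeter(self) -> float:
        # Ramanujan's approximation
        a, b = self.axes
        h = ((a - b) / (a + b)) ** 2
        return float(np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h))))


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray               # H x W float in [0, 1]
    mask: np.ndarray                # H x W int in {0..3}
    params: PhantomParams
    lesions: tuple[Lesion, ...]


def _brain_canvas(params: PhantomParams, rng: np.random.Generator):
    h, w = params.size
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2, (w - 1) / 2
    ry, rx = 0.42 * h, 0.38 * w
    head = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    texture = gaussian_filter(rng.standard_normal((h, w)),
                              params.background_texture_scale)
    ptp = texture.max() - texture.min()
    if ptp > 0:
        texture = (texture - texture.min()) / ptp - 0.5
    image = np.full((h, w), 0.05)
    image[head] = 0.35 + 0.15 * texture[head]
    return image, head


def generate_phantom(params: PhantomParams,
                     seed: int | None = None) -> Phantom:
    """One seeded phantom; identical parameters and seed give identical output."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    h, w = params.size
    image, head = _brain_canvas(params, rng)
    mask = np.zeros((h, w), dtype=np.int64)

    lo, hi = params.lesions_per_image
    n_lesions = int(rng.integers(lo, hi + 1))
    lesions: list[Lesion] = []
    for _ in range(n_lesions):
        for attempt in range(50):
            a = rng.uniform(*params.axis_range)
            b = rng.uniform(*params.axis_range)
            m = max(a, b) + 2
            cy = rng.uniform(m, h - 1 - m)
            cx = rng.uniform(m, w - 1 - m)
            if head[int(cy), int(cx)]:
                break
        else:
            raise RuntimeError("could not place a lesion inside the head region")
        cls = int(rng.choice((1, 2, 3), p=params.class_probs))
        angle = float(rng.uniform(0, np.pi))
        lesion = Lesion(cls=cls, center=(cy, cx), axes=(a, b), angle=angle)
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=angle)
        mu, sd = params.intensity[cls]
        image[rr, cc] = np.clip(mu + sd * rng.standard_normal(rr.shape), 0, 1)
        mask[rr, cc] = cls                   # later lesions overwrite earlier
        lesions.append(lesion)

    image = np.clip(image + params.noise_sigma * rng.standard_normal((h, w)),
                    0.0, 1.0)
    return Phantom(image=image, mask=mask, params=params,
                   lesions=tuple(lesions))


def generate_dataset(n: int, params: PhantomParams) -> list[Phantom]:
    """n phantoms with per-image seeds derived from ``params.seed``."""
    root = np.random.SeedSequence(params.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n)]
    return [generate_phantom(params, seed=s) for s in seeds]


def augment_pairs(pairs, n_extra: int, seed: int = 0):
    """Enlarge a list of (image, mask) pairs with flips and 90-degree
    rotations (a simple stand-in for dataset enhancement; off unless called).

    Each extra sample is a random transform of a randomly chosen original;
    image and mask receive the identical transform.
    """
    if n_extra < 0:
        raise ValueError("n_extra must be >= 0")
    rng = np.random.default_rng(seed)
    ops = [
        lambda a: a[::-1],                      # vertical flip
        lambda a: a[:, ::-1],                   # horizontal flip
        lambda a: np.rot90(a, 1),
        lambda a: np.rot90(a, 2),
        lambda a: np.rot90(a, 3),
    ]
    out = list(pairs)
    for _ in range(n_extra):
        img, mask = pairs[int(rng.integers(len(pairs)))]
        op = ops[int(rng.integers(len(ops)))]
        out.append((np.ascontiguousarray(op(np.asarray(img))),
                    np.ascontiguousarray(op(np.asarray(mask)))))
    return out


# -- colour codec -----------------------------------------------------------

def encode_mask_rgb(mask) -> np.ndarray:
    """Label mask -> uint8 RGB image using the canonical class colours."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 3:
        raise ValueError("mask labels must lie in {0..3}")
    lut = np.array([CLASS_COLOURS[i] for i in range(4)], dtype=np.uint8)
    return lut[mask]


def decode_mask_rgb(rgb) -> np.ndarray:
    """Inverse of :func:`encode_mask_rgb`; rejects non-canonical colours."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("expected an H x W x 3 colour image")
    rgb = rgb[..., :3]
    mask = np.full(rgb.shape[:2], -1, dtype=np.int64)
    for cls, colour in CLASS_COLOURS.items():
        mask[np.all(rgb == colour, axis=-1)] = cls
    if (mask < 0).any():
        bad = np.argwhere(mask < 0)
        r, c = bad[0]
        raise ValueError(
            f"{len(bad)} pixels have non-canonical colours, e.g. "
            f"{tuple(int(v) for v in rgb[r, c])} at ({r}, {c})")
    return mask


# -- splits ------------------------------------------------------------------

def make_split(n: int, ratio: tuple[int, int] = (10, 1),
               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled disjoint train/test indices in `ratio` proportion.

    The test set gets ``(n // sum(ratio)) * ratio[1]`` items; the remainder
    goes to the training set.
    """
    total = ratio[0] + ratio[1]
    if n < total:
        raise ValueError(f"need at least {total} items for a "
                         f"{ratio[0]}:{ratio[1]} split, got {n}")
    n_test = (n // total) * ratio[1]
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


# -- disk I/O ----------------------------------------------------------------

def write_dataset(phantoms: list[Phantom], out_dir, *,
                  ratio: tuple[int, int] = (10, 1), seed: int = 0) -> dict:
    """Write images/, masks/, masks_rgb/ PNGs and a manifest.json."""
    import imageio.v3 as iio

    out = Path(out_dir)
    for sub in ("images", "masks", "masks_rgb"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    records = []
    for i, ph in enumerate(phantoms):
        stem = f"{i:05d}.png"
        iio.imwrite(out / "images" / stem,
                    (ph.image * 255).round().astype(np.uint8))
        iio.imwrite(out / "masks" / stem, ph.mask.astype(np.uint8))
        iio.imwrite(out / "masks_rgb" / stem, encode_mask_rgb(ph.mask))
        records.append({
            "file": stem,
            "lesions": [
                {"class": l.cls, "class_name": CLASS_NAMES[l.cls],
                 "center": list(l.center), "axes": list(l.axes),
                 "angle": l.angle} for l in ph.lesions],
        })
    train, test = make_split(len(phantoms), ratio, seed)
    manifest = {
        "n": len(phantoms),
        "params": _params_dict(phantoms[0].params) if phantoms else None,
        "split": {"ratio": list(ratio), "seed": seed,
                  "train": [int(i) for i in train],
                  "test": [int(i) for i in test]},
        "images": records,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _params_dict(p: PhantomParams) -> dict:
    d = asdict(p)
    d["intensity"] = {str(k): list(v) for k, v in p.intensity.items()}
    return d


def load_dataset(data_dir, subset: str | None = None):
    """Read (image, mask) pairs written by :func:`write_dataset`.

    subset: None for all images, or "train"/"test" per the manifest split.
    """
    import imageio.v3 as iio

    root = Path(data_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    idx = range(manifest["n"]) if subset is None else manifest["split"][subset]
    pairs = []
    for i in idx:
        stem = manifest["images"][i]["file"]
        img = iio.imread(root / "images" / stem).astype(np.float64) / 255.0
        mask = iio.imread(root / "masks" / stem).astype(np.int64)
        pairs.append((img, mask))
    return pairs
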