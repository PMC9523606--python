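"""Synthetic leaf-disease image banks with controllable class separability
and domain shift.

Each class is a point in a 3-parameter appearance space — leaf hue, lesion
spatial frequency, lesion density — placed at a distance from the bank's
shared center that scales with a single separability knob ``delta``. Images
are composited as a smooth elliptical "leaf" of the class hue on a uniform
background, with lesions cut from thresholded band-pass noise. A domain is
a (background colour, illumination gain, blur, noise) quadruple, so the
lab-vs-field gap can be emulated by re-rendering or post-hoc shifting a
bank.

With ``delta = 0`` every class shares the same appearance distribution, so
no classifier can beat chance; large ``delta`` spreads the classes apart.
All randomness is driven by counter-derived substreams of a single bank
seed: per-class parameter streams are seeded by (seed, class_id) and
per-sample jitter by (seed, class_id, sample_index), so banks are bitwise
reproducible and classes do not share streams.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "ClassSpec",
    "DomainSpec",
    "ImageSample",
    "ImageBank",
    "BankSpec",
    "generate_bank",
    "apply_domain_shift",
    "make_registry",
    "export_bank",
    "load_image_folder",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration (counts, duplicate names/ids)."""


# Shared appearance center of every bank: a healthy green leaf with sparse
# mid-frequency lesions. Classes are displaced from this point by delta.
_HUE_CENTER = 0.33
_FREQ_CENTER = 6.0
_DENSITY_CENTER = 0.30
_NEUTRAL_BG = (0.5, 0.5, 0.5)


@dataclass(frozen=True)
class ClassSpec:
    """Appearance parameters of one synthetic class."""

    class_id: int
    base_hue: float          # leaf hue in [0, 1)
    lesion_frequency: float  # spatial frequency of lesion texture, > 0
    lesion_density: float    # fraction of leaf area covered, in [0, 1]
    separability: float      # the delta that produced this spec, >= 0

    def __post_init__(self):
        if not (0.0 <= self.base_hue < 1.0):
            raise ConfigurationError("base_hue must lie in [0, 1)")
        if self.lesion_frequency <= 0:
            raise ConfigurationError("lesion_frequency must be positive")
        if not (0.0 <= self.lesion_density <= 1.0):
            raise ConfigurationError("lesion_density must lie in [0, 1]")
        if self.separability < 0:
            raise ConfigurationError("separability must be >= 0")


@dataclass(frozen=True)
class DomainSpec:
    """Imaging conditions: background, illumination, optics, sensor noise."""

    name: str = "identity"
    background_color: tuple[float, float, float] = _NEUTRAL_BG
    illumination_gain: float = 1.0
    blur_radius: float = 0.0
    noise_sd: float = 0.0
    image_size: int = 32

    def __post_init__(self):
        if self.illumination_gain <= 0:
            raise ConfigurationError("illumination_gain must be positive")
        if self.blur_radius < 0 or self.noise_sd < 0:
            raise ConfigurationError("blur_radius and noise_sd must be >= 0")
        if self.image_size < 4:
            raise ConfigurationError("image_size too small")

    @property
    def is_identity(self) -> bool:
        return (
            self.background_color == _NEUTRAL_BG
            and self.illumination_gain == 1.0
            and self.blur_radius == 0.0
            and self.noise_sd == 0.0
        )


@dataclass
class ImageSample:
    """One RGB image: pixels (3, H, W) in [0, 1], class label, domain tag."""

    pixels: np.ndarray
    label: int
    domain: str


@dataclass
class ImageBank:
    """A labelled image dataset stored densely: images (n, 3, H, W)."""

    images: np.ndarray
    labels: np.ndarray
    domain: str
    class_specs: dict[int, ClassSpec] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        for img, lab in zip(self.images, self.labels):
            yield ImageSample(img, int(lab), self.domain)

    @property
    def class_ids(self) -> list[int]:
        return sorted(set(int(c) for c in self.labels))

    def subset(self, class_ids) -> "ImageBank":
        wanted = set(int(c) for c in class_ids)
        missing = wanted - set(self.class_ids)
        if missing:
            raise KeyError(f"classes not in bank: {sorted(missing)}")
        mask = np.isin(self.labels, sorted(wanted))
        return ImageBank(
            self.images[mask],
            self.labels[mask],
            self.domain,
            {c: s for c, s in self.class_specs.items() if c in wanted},
        )

    def indices_by_class(self) -> dict[int, np.ndarray]:
        return {c: np.flatnonzero(self.labels == c) for c in self.class_ids}


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    """Scalar HSV -> RGB triple."""
    i = int(np.floor(h * 6.0)) % 6
    f = h * 6.0 - np.floor(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    table = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)]
    return np.asarray(table[i], dtype=np.float64)


def _class_spec(seed: int, class_id: int, delta: float) -> ClassSpec:
    """Deterministic class parameters: center + delta * class offset."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xC1A5, class_id])
    d_hue = rng.uniform(-0.22, 0.22)
    d_freq = rng.uniform(-2.5, 2.5)
    d_dens = rng.uniform(-0.18, 0.18)
    hue = (_HUE_CENTER + delta * d_hue) % 1.0
    freq = float(np.clip(_FREQ_CENTER + delta * d_freq, 1.0, 14.0))
    dens = float(np.clip(_DENSITY_CENTER + delta * d_dens, 0.02, 0.85))
    return ClassSpec(class_id, float(hue), freq, dens, float(delta))


def _render_sample(spec: ClassSpec, domain: DomainSpec,
                   seed: int, sample_index: int) -> np.ndarray:
    """Render one (3, S, S) image for a class under a domain."""
    s = domain.image_size
    rng = np.random.default_rng(
        [seed & 0x7FFFFFFF, 0x5A3B, spec.class_id, sample_index]
    )
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy = s / 2 + rng.uniform(-0.06, 0.06) * s
    cx = s / 2 + rng.uniform(-0.06, 0.06) * s
    ry = s * rng.uniform(0.30, 0.40)
    rx = s * rng.uniform(0.20, 0.30)
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    leaf = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0

    hue = (spec.base_hue + rng.normal(0.0, 0.015)) % 1.0
    sat = np.clip(0.70 + rng.normal(0.0, 0.04), 0.0, 1.0)
    val = np.clip(0.60 + rng.normal(0.0, 0.04), 0.05, 1.0)
    leaf_rgb = _hsv_to_rgb(float(hue), float(sat), float(val))

    # band-pass noise -> lesion spots at the class's spatial frequency
    noise = rng.normal(size=(s, s))
    sigma = max(s / (2.0 * spec.lesion_frequency), 0.6)
    band = gaussian_filter(noise, sigma) - gaussian_filter(noise, 2.0 * sigma)
    dens = float(np.clip(spec.lesion_density + rng.normal(0.0, 0.02), 0.0, 1.0))
    if dens > 0:
        thr = np.quantile(band, 1.0 - dens)
        lesion = (band >= thr) & leaf
    else:
        lesion = np.zeros_like(leaf)

    img = np.empty((s, s, 3), dtype=np.float64)
    img[:] = np.asarray(domain.background_color)
    img[leaf] = leaf_rgb
    img[lesion] = np.array([0.35, 0.22, 0.08])  # necrotic brown

    img *= domain.illumination_gain
    if domain.blur_radius > 0:
        img = gaussian_filter(img, (domain.blur_radius, domain.blur_radius, 0))
    if domain.noise_sd > 0:
        img += rng.normal(0.0, domain.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0).transpose(2, 0, 1).astype(np.float32)


def generate_bank(n_classes: int, per_class: int, delta: float,
                  domain: DomainSpec = DomainSpec(), seed: int = 0,
                  class_id_start: int = 0) -> ImageBank:
    """Generate a balanced labelled bank of synthetic leaf images.

    Parameters
    ----------
    n_classes, per_class : bank geometry (>= 2 classes, >= 1 image each).
    delta : class separability; 0 makes all classes identically distributed.
    domain : imaging conditions the bank is rendered under.
    seed : master seed; identical calls are bitwise reproducible.
    class_id_start : first class id (ids are consecutive from here).
    """
    if n_classes < 2:
        raise ConfigurationError("need at least 2 classes")
    if per_class < 1:
        raise ConfigurationError("need at least 1 image per class")
    if delta < 0:
        raise ConfigurationError("delta must be >= 0")
    s = domain.image_size
    images = np.empty((n_classes * per_class, 3, s, s), dtype=np.float32)
    labels = np.empty(n_classes * per_class, dtype=np.int64)
    specs: dict[int, ClassSpec] = {}
    k = 0
    for ci in range(n_classes):
        cid = class_id_start + ci
        spec = _class_spec(seed, cid, delta)
        specs[cid] = spec
        for si in range(per_class):
            images[k] = _render_sample(spec, domain, seed, si)
            labels[k] = cid
            k += 1
    return ImageBank(images, labels, domain.name, specs)


def apply_domain_shift(bank: ImageBank, target: DomainSpec,
                       seed: int = 0) -> ImageBank:
    """Re-image a bank under new conditions: background replacement, then
    illumination gain, then blur, then sensor noise; clipped to [0, 1].

    Background replacement swaps pixels that exactly match the generator's
    neutral background; it is a no-op on banks rendered under a non-neutral
    background. Labels are untouched.
    """
    if len(bank) == 0:
        raise ConfigurationError("bank is empty")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xD05E])
    imgs = bank.images.astype(np.float64).copy()
    if tuple(target.background_color) != _NEUTRAL_BG:
        bg = np.asarray(_NEUTRAL_BG).reshape(3, 1, 1)
        is_bg = np.all(np.abs(imgs - bg) < 1e-6, axis=1)  # (n, H, W)
        new_bg = np.asarray(target.background_color)
        for c in range(3):
            ch = imgs[:, c]
            ch[is_bg] = new_bg[c]
    if target.illumination_gain != 1.0:
        imgs *= target.illumination_gain
    if target.blur_radius > 0:
        imgs = gaussian_filter(
            imgs, (0, 0, target.blur_radius, target.blur_radius)
        )
    if target.noise_sd > 0:
        imgs += rng.normal(0.0, target.noise_sd, imgs.shape)
    imgs = np.clip(imgs, 0.0, 1.0).astype(np.float32)
    return ImageBank(imgs, bank.labels.copy(), target.name, dict(bank.class_specs))


@dataclass(frozen=True)
class BankSpec:
    """Recipe for one domain's bank inside a registry."""

    name: str
    n_classes: int
    per_class: int
    delta: float
    domain: DomainSpec = DomainSpec()
    seed: int = 0
    shift_from_identity: bool = False  # render neutral, then shift to `domain`

    def build(self, class_id_start: int) -> ImageBank:
        dom = replace(self.domain, name=self.name)
        if self.shift_from_identity and not dom.is_identity:
            base = generate_bank(
                self.n_classes, self.per_class, self.delta,
                replace(dom, background_color=_NEUTRAL_BG,
                        illumination_gain=1.0, blur_radius=0.0, noise_sd=0.0),
                self.seed, class_id_start,
            )
            return apply_domain_shift(base, dom, seed=self.seed)
        return generate_bank(self.n_classes, self.per_class, self.delta,
                             dom, self.seed, class_id_start)


def make_registry(bank_specs: list[BankSpec]) -> dict[str, ImageBank]:
    """Build named domains (e.g. G / S / T) with globally unique class ids."""
    if not bank_specs:
        raise ConfigurationError("need at least one bank spec")
    names = [b.name for b in bank_specs]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate domain name in registry")
    registry: dict[str, ImageBank] = {}
    seen: set[int] = set()
    next_id = 0
    for spec in bank_specs:
        bank = spec.build(class_id_start=next_id)
        ids = set(bank.class_ids)
        if ids & seen:
            raise ConfigurationError("class ids overlap across domains")
        seen |= ids
        next_id = max(seen) + 1
        registry[spec.name] = bank
    return registry


def export_bank(bank: ImageBank, root: str) -> None:
    """Write a bank as per-class directories of PNGs (class id = dir name)."""
    counters: dict[int, int] = {}
    for sample in bank:
        d = os.path.join(root, f"class_{sample.label:04d}")
        os.makedirs(d, exist_ok=True)
        i = counters.get(sample.label, 0)
        counters[sample.label] = i + 1
        arr = (sample.pixels.transpose(1, 2, 0) * 255.0).round().astype(np.uint8)
        Image.fromarray(arr).save(os.path.join(d, f"{i:05d}.png"))


def load_image_folder(root: str, domain: str | None = None,
                      image_size: int | None = None) -> ImageBank:
    """Read a per-class-directory image dataset (the PNG/JPEG layout that
    PlantVillage-style datasets ship in) into an ImageBank.

    Class ids are assigned by sorted directory name; a leading ``class_``
    prefix with an integer suffix is honoured verbatim.
    """
    dirs = sorted(
        d for d in os.listdir(root) if os.path.isdir(os.path.join(root, d))
    )
    if not dirs:
        raise ConfigurationError(f"no class directories under {root!r}")
    images, labels = [], []
    for k, d in enumerate(dirs):
        if d.startswith("class_") and d[6:].isdigit():
            cid = int(d[6:])
        else:
            cid = k
        for fn in sorted(os.listdir(os.path.join(root, d))):
            if not fn.lower().endswith((".png", ".jpg", ".jpeg")):
                continue
            im = Image.open(os.path.join(root, d, fn)).convert("RGB")
            if image_size is not None:
                im = im.resize((image_size, image_size), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.float32) / 255.0
            images.append(arr.transpose(2, 0, 1))
            labels.append(cid)
    return ImageBank(
        np.stack(images), np.asarray(labels, dtype=np.int64),
        domain or os.path.basename(os.path.normpath(root)),
    )
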