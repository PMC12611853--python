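"""Synthetic thorax phantoms with paired lung and nodule masks.

Each phantom is a piecewise-constant grayscale slice: a dark background
(air), a bright body ellipse (soft tissue), two vertically elongated dark
lung ellipses placed symmetrically inside the body, and 0-5 bright filled
elliptical nodules strictly inside the lung fields, plus additive Gaussian
noise.  Intensities are ordered background < lung < nodule <= body, emulating
air-dark lungs containing denser-than-parenchyma nodules.

Every sample is a deterministic function of its seed, which makes the whole
downstream pipeline (preprocessing, training, evaluation) testable without
any external data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .train_eval import split_dataset


class SizingError(ValueError):
    """The lung fields cannot fit a nodule of the requested size."""


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 128
    n_nodules_range: tuple[int, int] = (0, 5)
    nodule_radius_range: tuple[float, float] = (2.0, 8.0)
    lung_intensity: float = 0.25
    body_intensity: float = 0.70
    nodule_intensity: float = 0.65
    background_intensity: float = 0.05
    noise_sigma: float = 0.02
    juxtapleural: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        lo, hi = self.n_nodules_range
        if not (0 <= lo <= hi):
            raise ValueError("n_nodules_range must be a non-negative interval")
        rlo, rhi = self.nodule_radius_range
        if not (0 < rlo <= rhi):
            raise ValueError("nodule_radius_range must be positive")
        if not (self.background_intensity < self.lung_intensity
                < self.nodule_intensity <= self.body_intensity):
            raise ValueError(
                "intensities must satisfy background < lung < nodule <= body"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class PhantomSample:
    image: np.ndarray        # (H, W) float32
    lung_mask: np.ndarray    # (H, W) uint8 in {0, 1}
    nodule_mask: np.ndarray  # (H, W) uint8 in {0, 1}
    n_nodules: int


def _ellipse_mask(shape: tuple[int, int], center, semi_axes, theta: float = 0.0) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dr + st * dc
    v = -st * dr + ct * dc
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def _lung_geometry(s: int):
    """Centers and semi-axes (rows, cols) of the two lung ellipses."""
    return [
        ((0.50 * s, 0.32 * s), (0.27 * s, 0.13 * s)),
        ((0.50 * s, 0.68 * s), (0.27 * s, 0.13 * s)),
    ]


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Deterministic phantom generation from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    s = config.image_size
    shape = (s, s)

    body = _ellipse_mask(shape, (0.5 * s, 0.5 * s), (0.40 * s, 0.46 * s))
    lungs = _lung_geometry(s)
    lung_mask = np.zeros(shape, dtype=bool)
    for center, axes in lungs:
        lung_mask |= _ellipse_mask(shape, center, axes)

    r_max = config.nodule_radius_range[1]
    min_axis = min(min(a) for _, a in lungs)
    if not config.juxtapleural and min_axis - r_max - 1.0 <= 0:
        raise SizingError(
            f"nodule radius up to {r_max} px does not fit inside lung fields "
            f"with smallest semi-axis {min_axis:.1f} px"
        )

    n_lo, n_hi = config.n_nodules_range
    n_nodules = int(rng.integers(n_lo, n_hi + 1))
    nodule_mask = np.zeros(shape, dtype=bool)
    placed = 0
    attempts = 0
    while placed < n_nodules:
        attempts += 1
        if attempts > 200 * n_nodules:
            raise SizingError(
                f"could not place {n_nodules} disjoint nodules of radius up to "
                f"{r_max} px inside the lung fields"
            )
        center_l, axes_l = lungs[int(rng.integers(0, 2))]
        a = rng.uniform(*config.nodule_radius_range)
        b = rng.uniform(*config.nodule_radius_range)
        theta = rng.uniform(0, np.pi)
        r_eff = max(a, b)
        if config.juxtapleural:
            # allowed to touch the pleural boundary: sample inside the lung
            shrink = (axes_l[0], axes_l[1])
        else:
            shrink = (axes_l[0] - r_eff - 1.0, axes_l[1] - r_eff - 1.0)
            if min(shrink) <= 0:
                continue
        # rejection-sample a center in the shrunken ellipse
        dr = rng.uniform(-shrink[0], shrink[0])
        dc = rng.uniform(-shrink[1], shrink[1])
        if (dr / shrink[0]) ** 2 + (dc / shrink[1]) ** 2 > 1.0:
            continue
        cand = _ellipse_mask(shape, (center_l[0] + dr, center_l[1] + dc), (a, b), theta)
        if config.juxtapleural:
            cand &= lung_mask
            if not cand.any():
                continue
        # enforce 8-connectivity disjointness: a one-pixel gap to earlier nodules
        dil = (np.roll(nodule_mask, 1, 0) | np.roll(nodule_mask, -1, 0) | nodule_mask)
        dil = np.roll(dil, 1, 1) | np.roll(dil, -1, 1) | dil
        if (cand & dil).any():
            continue
        nodule_mask |= cand
        placed += 1

    image = np.full(shape, config.background_intensity, dtype=np.float32)
    image[body] = config.body_intensity
    image[lung_mask] = config.lung_intensity
    image[nodule_mask] = config.nodule_intensity
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, shape).astype(np.float32)

    return PhantomSample(
        image=image.astype(np.float32),
        lung_mask=lung_mask.astype(np.uint8),
        nodule_mask=(nodule_mask & lung_mask).astype(np.uint8),
        n_nodules=n_nodules,
    )


def scaled_config(image_size: int = 128, seed: int = 0, **overrides) -> PhantomConfig:
    """Phantom config with the nodule radius range scaled to the image size.

    The default radius range (2, 8) px is calibrated to 128-px slices; for
    smaller phantoms the upper radius shrinks proportionally so nodules still
    fit strictly inside the lung fields, and very small phantoms carry fewer
    nodules so disjoint placement remains feasible.
    """
    overrides.setdefault("nodule_radius_range",
                         (2.0, max(3.0, image_size / 16.0)))
    if image_size < 48:
        lo, hi = overrides.get("n_nodules_range", (0, 5))
        overrides["n_nodules_range"] = (min(lo, 2), min(hi, 2))
    return PhantomConfig(image_size=image_size, seed=seed, **overrides)


def generate_phantom_dataset(
    n: int, config: PhantomConfig | None = None,
    split_fractions=(0.8, 0.1, 0.1),
) -> dict[str, list[PhantomSample]]:
    """Generate n phantoms and partition them train/val/test.

    Per-sample seeds derive from ``config.seed``; the index partition uses a
    seeded shuffle, so the whole dataset is reproducible.
    """
    config = config or PhantomConfig()
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n) % (2**31)
    samples = [
        generate_phantom(replace(config, seed=int(cs))) for cs in child_seeds
    ]
    tr, va, te = split_dataset(n, split_fractions, seed=config.seed)
    return {
        "train": [samples[i] for i in tr],
        "val": [samples[i] for i in va],
        "test": [samples[i] for i in te],
    }


def save_samples(samples: list[PhantomSample], outdir: str | Path,
                 prefix: str = "phantom") -> Path:
    """Write image/mask PNG pairs and a TSV manifest; returns manifest path."""
    from .io import write_mask
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["index", "image", "lung_mask", "nodule_mask", "n_nodules"])
        for i, s in enumerate(samples):
            img8 = np.clip(s.image * 255.0, 0, 255).astype(np.uint8)
            img_path = outdir / f"{prefix}_{i:04d}.png"
            Image.fromarray(img8).save(img_path)
            lung_path = outdir / f"{prefix}_{i:04d}_lung.png"
            nod_path = outdir / f"{prefix}_{i:04d}_nodule.png"
            write_mask(s.lung_mask, lung_path)
            write_mask(s.nodule_mask, nod_path)
            writer.writerow([i, img_path.name, lung_path.name, nod_path.name,
                             s.n_nodules])
    return manifest
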