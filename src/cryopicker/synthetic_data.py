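"""Synthetic micrographs with exactly known ground truth.

Real training data for particle picking comes from manually curated
coordinate sets over archived micrographs; those are multi-gigabyte
downloads. This module emulates their geometry at desk scale so the whole
pipeline — denoising, label building, training, inference, filtering,
evaluation — runs against inputs whose truth is known to the pixel.

A simulated micrograph is a smooth low-frequency background gradient plus
roughly convex particles (soft-edged disks or ellipses at a signed contrast
offset), plus optional high-contrast irregular "distractor" blobs emulating
ice contamination and carbon-edge junk that a good picker must NOT pick
(distractors carry no annotation), plus additive Gaussian noise. Everything
is a pure function of ``(cfg.seed, index)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formats_io import (
    AnnotationSet,
    Micrograph,
    ParticleAnnotation,
    build_coco,
    write_mrc,
)

__all__ = ["SimConfig", "simulate_micrograph", "simulate_dataset", "particle_mask"]

_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class SimConfig:
    """Conditions of the simulated data.

    Defaults model a small, visibly noisy micrograph: dark particles
    (negative contrast, as protein appears in real bright-field cryo-EM
    data) of 14-20 px radius, 5-15 per image, on a gently sloping
    background with strong additive Gaussian noise, plus up to three
    darker distractor blobs. The radius is chosen so a particle spans
    roughly one cell of the detector's 1/32-resolution feature grid, the
    same ratio real micrographs (hundreds-of-pixel particles on
    4k-7k-pixel images) present to the backbone.
    """

    image_size: tuple[int, int] = (256, 256)  # (H0, W0)
    n_particles_range: tuple[int, int] = (5, 15)
    particle_radius_range: tuple[float, float] = (14.0, 20.0)
    particle_shape: str = "disk"  # or "ellipse"
    particle_contrast: float = -50.0
    noise_sd: float = 25.0
    n_distractors_range: tuple[int, int] = (0, 3)
    distractor_contrast: float = -90.0
    background_gradient_amplitude: float = 10.0
    background_level: float = 128.0
    seed: int = 0

    def __post_init__(self):
        h0, w0 = self.image_size
        if 2 * self.particle_radius_range[1] >= min(h0, w0):
            raise ValueError("largest particle does not fit in the image")
        if self.n_particles_range[1] > 600:
            raise ValueError("at most 600 particles per micrograph are supported")
        if self.particle_shape not in {"disk", "ellipse"}:
            raise ValueError(f"unknown particle shape {self.particle_shape!r}")


def _rng_for(cfg: SimConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, index])


def _soft_blob(
    h0: int, w0: int, cx: float, cy: float, rx: float, ry: float, theta: float
) -> np.ndarray:
    """Unit-amplitude ellipse with a ~2 px Gaussian-soft edge."""
    yy, xx = np.mgrid[0:h0, 0:w0]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    r = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    edge = 2.0 / max(rx, ry)  # ~2 px soft edge in normalized radius units
    from scipy.special import expit

    return expit(-(r - 1.0) / (edge / 2.0))


def _place_centers(
    rng: np.random.Generator, n: int, radii: np.ndarray, h0: int, w0: int
) -> np.ndarray:
    """Rejection-sample centers >= one radius inside the border with pairwise
    separation >= 1.2 x mean radius."""
    min_sep = 1.2 * float(radii.mean()) if n else 0.0
    centers: list[tuple[float, float]] = []
    attempts = 0
    for r in radii:
        while True:
            attempts += 1
            if attempts > _MAX_PLACEMENT_ATTEMPTS:
                raise RuntimeError(
                    f"could not place {n} particles after {_MAX_PLACEMENT_ATTEMPTS} attempts; "
                    "configuration too crowded"
                )
            cx = rng.uniform(r, w0 - 1 - r)
            cy = rng.uniform(r, h0 - 1 - r)
            if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep**2 for px, py in centers):
                centers.append((cx, cy))
                break
    return np.asarray(centers).reshape(n, 2)


def simulate_micrograph(
    cfg: SimConfig, index: int
) -> tuple[Micrograph, list[ParticleAnnotation]]:
    """Render one micrograph and its exact annotations.

    Returns the image (float64 intensities) and one annotation per
    particle with the true center and box = 2 x radius. Distractors are
    rendered but never annotated.
    """
    h0, w0 = cfg.image_size
    rng = _rng_for(cfg, index)
    mic_id = f"sim_{cfg.seed}_{index:05d}"

    n = int(rng.integers(cfg.n_particles_range[0], cfg.n_particles_range[1] + 1))
    radii = rng.uniform(*cfg.particle_radius_range, size=n)
    centers = _place_centers(rng, n, radii, h0, w0)

    # smooth low-frequency background: one oblique cosine ramp
    yy, xx = np.mgrid[0:h0, 0:w0]
    phase = rng.uniform(0, 2 * np.pi)
    kx, ky = rng.uniform(0.5, 1.5, size=2)
    img = cfg.background_level + cfg.background_gradient_amplitude * np.cos(
        2 * np.pi * (kx * xx / w0 + ky * yy / h0) + phase
    )

    annotations = []
    for i in range(n):
        cx, cy = centers[i]
        r = radii[i]
        if cfg.particle_shape == "ellipse":
            rx, ry = r, r * rng.uniform(0.6, 1.0)
            theta = rng.uniform(0, np.pi)
        else:
            rx = ry = r
            theta = 0.0
        img += cfg.particle_contrast * _soft_blob(h0, w0, cx, cy, rx, ry, theta)
        annotations.append(
            ParticleAnnotation(
                particle_id=index * 1000 + i,
                micrograph_id=mic_id,
                cx=float(cx),
                cy=float(cy),
                bw=2.0 * r,
                bh=2.0 * r,
            )
        )

    n_d = int(rng.integers(cfg.n_distractors_range[0], cfg.n_distractors_range[1] + 1))
    for _ in range(n_d):
        r = rng.uniform(1.0, 2.5) * cfg.particle_radius_range[1]
        cx = rng.uniform(0, w0 - 1)
        cy = rng.uniform(0, h0 - 1)
        rx, ry = r, r * rng.uniform(0.3, 0.8)
        theta = rng.uniform(0, np.pi)
        img += cfg.distractor_contrast * _soft_blob(h0, w0, cx, cy, rx, ry, theta)

    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)

    return Micrograph(id=mic_id, pixels=img, pixel_size=1.0), annotations


def particle_mask(cfg: SimConfig, index: int) -> np.ndarray:
    """Boolean union of the noiseless particle supports of micrograph
    ``index`` (distractors excluded); used to verify annotation fidelity."""
    noiseless = SimConfig(
        **{
            **cfg.__dict__,
            "noise_sd": 0.0,
            "n_distractors_range": (0, 0),
            "background_gradient_amplitude": 0.0,
        }
    )
    mic, _ = simulate_micrograph(noiseless, index)
    deviation = np.abs(mic.pixels - noiseless.background_level)
    return deviation > 0.5 * abs(cfg.particle_contrast)


def simulate_dataset(
    cfg: SimConfig,
    n_train: int,
    n_val: int,
    n_test: int,
    out_dir: str | Path,
) -> tuple[AnnotationSet, AnnotationSet, AnnotationSet]:
    """Write a full split (MRC micrographs + three COCO JSONs) to disk.

    Micrograph indices are disjoint across splits; each split's COCO file
    is ``annotations_<split>.json`` and images live under ``images/``.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    splits = {
        "train": range(0, n_train),
        "validation": range(n_train, n_train + n_val),
        "test": range(n_train + n_val, n_train + n_val + n_test),
    }
    sets = []
    for split, indices in splits.items():
        mics, annos = [], []
        for idx in indices:
            mic, ann = simulate_micrograph(cfg, idx)
            write_mrc(mic, out_dir / "images" / f"{mic.id}.mrc")
            mics.append((mic.id, mic.pixels.shape[0], mic.pixels.shape[1]))
            annos.extend(ann)
        aset = AnnotationSet(micrographs=mics, annotations=annos, split_tag=split)
        (out_dir / f"annotations_{split}.json").write_text(build_coco(aset))
        sets.append(aset)
    return tuple(sets)
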