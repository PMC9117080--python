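"""Synthetic three-class grayscale image cohorts.

Stands in for a real MRI cohort so every pipeline stage is exercisable
without downloading data.  Two phantom kinds:

``ring_phantom``
    An elliptical "brain" of roughly uniform tissue intensity with a
    brighter cortical rim and a central dark cavity (ventricle proxy)
    whose area grows HC -> MCI -> AD in proportion to ``class_signal`` —
    mimicking the atrophy gradient that separates the diagnostic groups.
``texture``
    The same elliptical mask filled with a sinusoidal grating whose
    dominant spatial frequency shifts with the class.

Gaussian noise is applied inside the brain mask only, so background (and
cavity) pixels are exactly zero — which is what makes the zero-stripping
step of the descriptor stage meaningful.  Images are quantized to 8 bits
before use or writing, matching the declared PNG input format.  All
randomness flows from the mandatory seed; a fixed spec reproduces the
cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigurationError
from .wavelet import ImageSample

#: Class listing order (and label coding HC=1, AD=2, MCI=3).
CLASS_NAMES = ("HC", "AD", "MCI")

#: Atrophy severity rank driving the cavity-area gradient.
ATROPHY_RANK = {"HC": 0, "MCI": 1, "AD": 2}


@dataclass
class SyntheticSpec:
    """Generation parameters of one synthetic cohort."""

    n_per_class: int = 200
    image_size: int = 256
    class_signal: float = 1.0
    noise_sigma: float = 5.0
    seed: int = 0
    phantom_kind: str = "ring_phantom"

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigurationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.image_size % 2 or self.image_size < 16:
            raise ConfigurationError(
                f"image_size must be even and >= 16, got {self.image_size}"
            )
        if not 0.0 <= self.class_signal <= 1.0:
            raise ConfigurationError(
                f"class_signal must be in [0, 1], got {self.class_signal}"
            )
        if self.phantom_kind not in ("ring_phantom", "texture"):
            raise ConfigurationError(f"unknown phantom_kind {self.phantom_kind!r}")


def _ellipse_mask(size, cx, cy, a, b):
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2


def _one_ring_phantom(size, rank, signal, sigma, rng):
    # emulates spatially normalized scans: outer size varies little,
    # the class signal sits in the ventricle-proxy cavity area
    cx = size / 2 + rng.normal(0, 0.005 * size)
    cy = size / 2 + rng.normal(0, 0.005 * size)
    a = 0.42 * size * (1 + rng.normal(0, 0.005))
    b = 0.36 * size * (1 + rng.normal(0, 0.005))
    d2 = _ellipse_mask(size, cx, cy, a, b)
    brain = d2 <= 1.0
    rim = (d2 > 0.78) & brain

    # cavity radius: common base plus a class offset scaled by the signal
    r = (0.05 + 0.05 * signal * rank) * size * (1 + rng.normal(0, 0.05))
    cav = _ellipse_mask(size, cx, cy, 1.3 * r, 0.9 * r) <= 1.0

    img = np.zeros((size, size))
    img[brain] = 150.0
    img[rim] = 190.0
    img[brain] += rng.normal(0, sigma, size=int(brain.sum()))
    img[cav] = 0.0
    cavity_area = int((cav & brain).sum())
    return img, {"cavity_area": cavity_area, "outer_a": a, "outer_b": b}


def _one_texture(size, rank, signal, sigma, rng):
    cx = size / 2 + rng.normal(0, 0.005 * size)
    cy = size / 2 + rng.normal(0, 0.005 * size)
    a = 0.42 * size * (1 + rng.normal(0, 0.005))
    b = 0.36 * size * (1 + rng.normal(0, 0.005))
    brain = _ellipse_mask(size, cx, cy, a, b) <= 1.0

    freq = 0.03 * (1 + 0.8 * signal * rank) * (1 + rng.normal(0, 0.03))
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    phase = rng.uniform(0, 2 * np.pi)
    grating = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)

    img = np.zeros((size, size))
    img[brain] = 128.0 + 60.0 * grating[brain]
    img[brain] += rng.normal(0, sigma, size=int(brain.sum()))
    return img, {"frequency": freq, "theta": theta}


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate(spec: SyntheticSpec) -> tuple[list[ImageSample], pd.DataFrame]:
    """Generate the cohort in memory.

    Returns the image samples (8-bit-quantized intensities as floats) and a
    manifest with one row per image recording id, label and the generation
    parameters actually drawn.
    """
    rng = np.random.default_rng(spec.seed)
    make = _one_ring_phantom if spec.phantom_kind == "ring_phantom" else _one_texture
    samples: list[ImageSample] = []
    records = []
    for label in CLASS_NAMES:
        rank = ATROPHY_RANK[label]
        for i in range(spec.n_per_class):
            img, params = make(
                spec.image_size, rank, spec.class_signal, spec.noise_sigma, rng
            )
            q = _quantize(img)
            image_id = f"{label}_{i:04d}"
            samples.append(ImageSample(q.astype(np.float64), label=label, id=image_id))
            records.append(
                {
                    "id": image_id,
                    "label": label,
                    "phantom_kind": spec.phantom_kind,
                    "class_signal": spec.class_signal,
                    "noise_sigma": spec.noise_sigma,
                    "seed": spec.seed,
                }
                | params
            )
    return samples, pd.DataFrame(records)


def write_cohort(spec: SyntheticSpec, out_dir: Union[str, Path]) -> pd.DataFrame:
    """Generate and write the cohort as class-per-subdirectory 8-bit PNGs.

    The manifest (with a ``path`` column) is written as ``manifest.csv`` in
    ``out_dir`` and returned.  Byte-identical across runs for a fixed spec.
    """
    out_dir = Path(out_dir)
    samples, manifest = generate(spec)
    paths = []
    for sample in samples:
        class_dir = out_dir / sample.label
        class_dir.mkdir(parents=True, exist_ok=True)
        path = class_dir / f"{sample.id}.png"
        Image.fromarray(sample.pixels.astype(np.uint8), mode="L").save(path)
        paths.append(str(path))
    manifest = manifest.assign(path=paths)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
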