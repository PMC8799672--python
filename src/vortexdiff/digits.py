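"""Procedural rotated-digits corpus.

Emulates a handwritten-digits collection (28x28, 8-bit, class-balanced, each
sample rotated by a random angle) without any download: every glyph 0-9 is a
set of polyline strokes in a unit box, rasterised with a Gaussian pen profile
after a small random affine jitter (scale, shear, translation) plus the
per-sample rotation.  The whole corpus is a pure function of its seed.

An import hook (:func:`load_idx_corpus`) accepts any external 28x28 grayscale
corpus in IDX layout for users who want real handwriting.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import zoom as _ndi_zoom

__all__ = [
    "GlyphSample",
    "DatasetManifest",
    "generate_corpus",
    "upscale_to_object",
    "split_dataset",
    "load_idx_corpus",
]

GLYPH_SIZE = 28

# Stroke skeletons per digit, unit box [0,1]^2 with y pointing up.
_C = [(0.5 + 0.32 * math.cos(t), 0.5 + 0.42 * math.sin(t)) for t in np.linspace(0, 2 * math.pi, 24)]
_STROKES: dict[int, list[list[tuple[float, float]]]] = {
    0: [_C],
    1: [[(0.35, 0.72), (0.52, 0.88), (0.52, 0.12)], [(0.35, 0.12), (0.68, 0.12)]],
    2: [
        [(0.25, 0.72)]
        + [(0.5 + 0.25 * math.cos(t), 0.66 + 0.22 * math.sin(t)) for t in np.linspace(2.6, -0.9, 10)]
        + [(0.28, 0.12), (0.75, 0.12)]
    ],
    3: [
        [(0.28, 0.82)]
        + [(0.48 + 0.22 * math.cos(t), 0.68 + 0.18 * math.sin(t)) for t in np.linspace(1.8, -1.4, 9)]
        + [(0.48 + 0.24 * math.cos(t), 0.30 + 0.20 * math.sin(t)) for t in np.linspace(1.4, -1.9, 9)]
        + [(0.27, 0.15)]
    ],
    4: [[(0.62, 0.12), (0.62, 0.88), (0.25, 0.35), (0.78, 0.35)]],
    5: [
        [(0.72, 0.85), (0.32, 0.85), (0.30, 0.52)]
        + [(0.48 + 0.25 * math.cos(t), 0.33 + 0.21 * math.sin(t)) for t in np.linspace(1.25, -1.9, 10)]
        + [(0.27, 0.15)]
    ],
    6: [
        [(0.62, 0.85), (0.38, 0.55)]
        + [(0.5 + 0.22 * math.cos(t), 0.32 + 0.21 * math.sin(t)) for t in np.linspace(2.4, -3.6, 16)]
    ],
    7: [[(0.25, 0.85), (0.75, 0.85), (0.42, 0.12)], [(0.36, 0.5), (0.66, 0.5)]],
    8: [
        [(0.5 + 0.20 * math.cos(t), 0.67 + 0.165 * math.sin(t)) for t in np.linspace(0.5 * math.pi, 2.5 * math.pi, 16)],
        [(0.5 + 0.24 * math.cos(t), 0.30 + 0.19 * math.sin(t)) for t in np.linspace(0.5 * math.pi, 2.5 * math.pi, 16)],
    ],
    9: [
        [(0.66, 0.60)]
        + [(0.48 + 0.19 * math.cos(t), 0.63 + 0.18 * math.sin(t)) for t in np.linspace(0.1, 2 * math.pi - 0.3, 14)],
        [(0.66, 0.68), (0.62, 0.15)],
    ],
}


@dataclass(frozen=True)
class GlyphSample:
    image: np.ndarray  # (28, 28) uint8
    digit_class: int
    rotation_deg: float
    sample_id: int


@dataclass(frozen=True)
class DatasetManifest:
    """Disjoint train/validation/test id partition: 10% of all ids are held
    out for testing, 10% of the remaining training pool for validation."""

    n_total: int
    per_class: int
    seed: int
    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray

    def __post_init__(self):
        ids = np.concatenate([self.train_ids, self.val_ids, self.test_ids])
        if len(np.unique(ids)) != self.n_total or len(ids) != self.n_total:
            raise ValueError("splits must be disjoint and cover all ids")


def _rasterize(strokes, width: float, oversample: int = 2) -> np.ndarray:
    """Distance-to-polyline rasterisation with a Gaussian pen of sigma=width,
    rendered oversampled then block-averaged for antialiasing."""
    n = GLYPH_SIZE * oversample
    xs = (np.arange(n) + 0.5) / n
    X, Y = np.meshgrid(xs, 1.0 - xs, indexing="xy")
    P = np.stack([X, Y], axis=-1)  # pixel centers, y up
    d2 = np.full((n, n), np.inf)
    for poly in strokes:
        pts = np.asarray(poly)
        a, b = pts[:-1], pts[1:]
        for i in range(len(a)):
            ab = b[i] - a[i]
            denom = float(ab @ ab)
            ap = P - a[i]
            t = np.clip((ap @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
            closest = a[i] + t[..., None] * ab if denom > 0 else a[i]
            diff = P - closest
            d2 = np.minimum(d2, np.einsum("...k,...k->...", diff, diff))
    img = np.exp(-d2 / (2.0 * width**2))
    img = img.reshape(GLYPH_SIZE, oversample, GLYPH_SIZE, oversample).mean(axis=(1, 3))
    img = img / img.max()
    return np.round(255.0 * img).astype(np.uint8)


def _jitter(strokes, rng: np.random.Generator, rotation_deg: float):
    """Apply rotation + mild random scale/shear/translation about the glyph
    center in the continuous stroke domain (no resampling artifacts)."""
    th = math.radians(rotation_deg)
    c, s = math.cos(th), math.sin(th)
    sx, sy = rng.uniform(0.9, 1.1, size=2)
    shear = rng.uniform(-0.08, 0.08)
    tx, ty = rng.uniform(-0.04, 0.04, size=2)
    A = np.array([[c, -s], [s, c]]) @ np.array([[sx, shear], [0.0, sy]])
    out = []
    for poly in strokes:
        pts = np.asarray(poly) - 0.5
        pts = pts @ A.T + [0.5 + tx, 0.5 + ty]
        out.append(pts)
    return out


def generate_corpus(
    n_per_class: int,
    rotation_range: tuple[float, float] = (-45.0, 45.0),
    seed: int = 0,
) -> list[GlyphSample]:
    """Render 10 * n_per_class rotated digit glyphs, class-balanced by
    construction, deterministic under seed.  rotation_range = (0, 0) disables
    rotation."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    lo, hi = rotation_range
    rng = np.random.default_rng(seed)
    samples: list[GlyphSample] = []
    sid = 0
    for digit in range(10):
        for _ in range(n_per_class):
            rot = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            width = float(rng.uniform(0.035, 0.055))
            strokes = _jitter(_STROKES[digit], rng, rot)
            img = _rasterize(strokes, width)
            samples.append(GlyphSample(img, digit, rot, sid))
            sid += 1
    return samples


def upscale_to_object(sample, side: int = 512) -> np.ndarray:
    """Bilinearly resize a 28x28 glyph (GlyphSample or raw array) to
    side x side, 8-bit range preserved — the displayed phase-object image."""
    img = sample.image if isinstance(sample, GlyphSample) else np.asarray(sample)
    if side < GLYPH_SIZE:
        raise ValueError(f"side must be >= {GLYPH_SIZE}")
    if side % 4:
        raise ValueError("side must be a multiple of 4")
    out = _ndi_zoom(img.astype(float), side / img.shape[0], order=1, grid_mode=True, mode="nearest")
    return np.clip(out, 0.0, 255.0)


def split_dataset(n_total: int, seed: int) -> DatasetManifest:
    """Random disjoint 90/10 split with 10% of the training pool held out for
    validation: test = round(0.1 n), val = round(0.1 (n - test)), train = rest.
    At n = 10,000 this forces train 8100 / val 900 / test 1000."""
    n_test = round(0.10 * n_total)
    pool = n_total - n_test
    n_val = round(0.10 * pool)
    n_train = pool - n_val
    if min(n_test, n_val, n_train) < 1:
        raise ValueError(f"n_total = {n_total} too small for non-empty splits")
    perm = np.random.default_rng(seed).permutation(n_total)
    return DatasetManifest(
        n_total=n_total,
        per_class=n_total // 10,
        seed=seed,
        test_ids=np.sort(perm[:n_test]),
        val_ids=np.sort(perm[n_test : n_test + n_val]),
        train_ids=np.sort(perm[n_test + n_val :]),
    )


def load_idx_corpus(images_path: str | Path, labels_path: str | Path) -> list[GlyphSample]:
    """Import an external 28x28 grayscale corpus in IDX (ubyte) layout."""
    with open(images_path, "rb") as f:
        magic, n, rows, cols = struct.unpack(">IIII", f.read(16))
        if magic != 2051 or (rows, cols) != (GLYPH_SIZE, GLYPH_SIZE):
            raise ValueError("not a 28x28 IDX image file")
        data = np.frombuffer(f.read(), dtype=np.uint8).reshape(n, rows, cols)
    with open(labels_path, "rb") as f:
        magic, nl = struct.unpack(">II", f.read(8))
        if magic != 2049 or nl != n:
            raise ValueError("IDX label file does not match image file")
        labels = np.frombuffer(f.read(), dtype=np.uint8)
    return [GlyphSample(data[i], int(labels[i]), 0.0, i) for i in range(n)]
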