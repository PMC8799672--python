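"""Reconstruction quality metrics: NPCC, MSE, PSNR and Sørensen-Dice.

NPCC — the negative Pearson correlation coefficient over the two pixel
populations — doubles as the training loss: it is invariant to positive
affine rescaling of either image, reaches −1 exactly when the reconstruction
is a positive affine map of the truth, and +1 for perfect anticorrelation.
MSE is reported on the 0–255 intensity scale and PSNR as
10 log10(255^2 / MSE), the convention under which the two are consistent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = ["MetricReport", "npcc", "mse", "psnr", "dice", "normalize_to", "evaluate_set"]


def npcc(Y: np.ndarray, G: np.ndarray) -> float:
    """Negative Pearson correlation of the pixel populations of Y (output)
    and G (ground truth):

        NPCC = - sum (Y - mean Y)(G - mean G) /
                 sqrt(sum (Y - mean Y)^2) sqrt(sum (G - mean G)^2)

    npcc(Y, Y) = -1; npcc(Y, -Y) = +1; constant images are rejected."""
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    if Y.shape != G.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {G.shape}")
    y = Y - Y.mean()
    g = G - G.mean()
    sy = math.sqrt(float(np.sum(y * y)))
    sg = math.sqrt(float(np.sum(g * g)))
    if sy == 0.0 or sg == 0.0:
        raise ValueError("NPCC is undefined for a constant image (zero variance)")
    return float(-np.sum(y * g) / (sy * sg))


def mse(Y: np.ndarray, G: np.ndarray) -> float:
    """Mean squared pixel difference (images on a common scale)."""
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    if Y.shape != G.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {G.shape}")
    return float(np.mean((Y - G) ** 2))


def psnr(mse_value: float, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10 log10(max^2 / MSE) in dB; an MSE of zero
    yields +inf (flagged, not raised, so report aggregation can proceed)."""
    if mse_value < 0:
        raise ValueError("MSE cannot be negative")
    if mse_value == 0.0:
        return math.inf
    return 10.0 * math.log10(max_value**2 / mse_value)


def normalize_to(Y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Affine-map Y onto the intensity range of G (used before MSE/Dice so a
    scale-free network output is compared on the truth's 0–255 scale)."""
    Y = np.asarray(Y, dtype=float)
    lo, hi = float(Y.min()), float(Y.max())
    glo, ghi = float(np.min(G)), float(np.max(G))
    if hi == lo:
        return np.full_like(Y, (glo + ghi) / 2.0)
    return (Y - lo) / (hi - lo) * (ghi - glo) + glo


def dice(Y: np.ndarray, G: np.ndarray, threshold: float = 127.5) -> float:
    """Sørensen-Dice overlap 2|A∩B| / (|A| + |B|) of the two images binarised
    at the threshold; two empty masks count as perfect agreement (1.0)."""
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    if Y.shape != G.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {G.shape}")
    a = Y > threshold
    b = G > threshold
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


@dataclass
class MetricReport:
    """Aggregate evaluation over a set of reconstruction/truth pairs.

    psnr_db is derived from the averaged MSE (one MSE/PSNR pair per
    condition); psnr_infinite flags a zero average MSE."""

    npcc: float
    mse: float
    psnr_db: float
    dice: float
    n_images: int
    psnr_infinite: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        d = self.to_dict()
        if self.psnr_infinite:
            d["psnr_db"] = None
        return json.dumps(d, **kw)


def evaluate_set(
    reconstructions: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    dice_threshold: float = 127.5,
) -> MetricReport:
    """Per-image NPCC/MSE/Dice averaged over the set; PSNR computed from the
    averaged MSE.  Each reconstruction is affine-normalised to its truth's
    range before MSE and Dice (NPCC needs no normalisation)."""
    if len(reconstructions) != len(truths):
        raise ValueError("reconstructions and truths must pair up")
    if len(reconstructions) == 0:
        raise ValueError("cannot evaluate an empty set")
    npccs, mses, dices = [], [], []
    for Y, G in zip(reconstructions, truths):
        Yn = normalize_to(Y, G)
        npccs.append(npcc(Y, G))
        mses.append(mse(Yn, G))
        dices.append(dice(Yn, G, dice_threshold))
    mean_mse = float(np.mean(mses))
    p = psnr(mean_mse)
    return MetricReport(
        npcc=float(np.mean(npccs)),
        mse=mean_mse,
        psnr_db=p if math.isfinite(p) else math.inf,
        dice=float(np.mean(dices)),
        n_images=len(reconstructions),
        psnr_infinite=not math.isfinite(p),
    )
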