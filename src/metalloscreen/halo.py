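"""Solid CAS-agar halo scoring by dual intensity thresholding.

On a CAS plate, secreted metallophores strip iron from the blue Fe-CAS dye
and leave a bright decolourised halo around each dark colony, on a mid-gray
dye background.  The score for one colony is the dimensionless area ratio

    ratio = (n_colony + n_halo) / n_colony

where ``n_colony`` counts pixels strictly darker than a colony threshold tC
and ``n_halo`` counts pixels strictly brighter than a halo threshold tH.
Pixels with tC <= g <= tH are background and count in neither region.

Coordinates are 0-based and row-major; crop regions use half-open
``[row_start, row_end) x [col_start, col_end)`` semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CropRegion",
    "ThresholdPair",
    "HaloMeasurement",
    "CropEntry",
    "PlateQuantification",
    "load_image",
    "to_grayscale",
    "crop",
    "histogram",
    "suggest_thresholds",
    "measure_halo",
    "quantify_plate",
]

# ITU-R BT.601 luminance weights for RGB -> grayscale.
_GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class CropRegion:
    row_start: int
    col_start: int
    row_end: int
    col_end: int

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("crop start indices must be nonnegative")
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise ValueError("crop end indices must exceed start indices")


@dataclass(frozen=True)
class ThresholdPair:
    """Colony upper bound tC and halo lower bound tH (strict inequalities)."""

    tc: int
    th: int

    def __post_init__(self) -> None:
        if not 0 <= self.tc < self.th <= 255:
            raise ValueError("thresholds must satisfy 0 <= tC < tH <= 255")


@dataclass(frozen=True)
class HaloMeasurement:
    n_colony: int
    n_halo: int
    ratio: float
    crop_id: str | None = None
    condition: str | None = None


@dataclass(frozen=True)
class CropEntry:
    """One colony to score: crop window, optional fixed thresholds, labels."""

    region: CropRegion
    thresholds: ThresholdPair | None = None
    condition: str | None = None
    crop_id: str | None = None


@dataclass
class PlateQuantification:
    measurements: list[HaloMeasurement]
    failures: list[tuple[str | None, str]]  # (crop_id, reason)
    aggregates: pd.DataFrame  # per condition: n, mean_ratio, se_ratio

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "crop_id": m.crop_id,
                    "condition": m.condition,
                    "n_colony": m.n_colony,
                    "n_halo": m.n_halo,
                    "ratio": m.ratio,
                }
                for m in self.measurements
            ]
        )


def _check_grayscale(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    return image


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF plate photo; RGB is converted to grayscale."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return to_grayscale(arr)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luminance conversion; grayscale input passes through unchanged."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        gray = image.astype(float) @ _GRAY_WEIGHTS
        # round half up, as floor(x + 0.5)
        return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)
    raise ValueError(f"expected a 2-D or HxWx3 image, got shape {image.shape}")


def crop(image: np.ndarray, region: CropRegion) -> np.ndarray:
    image = _check_grayscale(image)
    h, w = image.shape
    if region.row_end > h or region.col_end > w:
        raise ValueError(
            f"crop {region} exceeds image extent {h}x{w}"
        )
    return image[region.row_start : region.row_end, region.col_start : region.col_end].copy()


def histogram(image: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram; bins sum to the pixel count."""
    image = _check_grayscale(image)
    return np.bincount(image.astype(np.int64).ravel(), minlength=256)[:256]


def suggest_thresholds(hist: np.ndarray) -> ThresholdPair:
    """Three-class Otsu split of a 256-bin histogram.

    Exhaustively searches all cut pairs (a, b), a < b, assigning levels
    <= a, (a, b] and > b to the colony, background and halo classes, and
    maximizes the between-class variance; ties go to the lexicographically
    smallest (tC, tH).  Returns tC = a + 1 and tH = b, so that the strict
    rules g < tC and g > tH reproduce the Otsu classes exactly.

    Raises ValueError when fewer than three intensity levels are present
    (manual thresholds are then required).
    """
    hist = np.asarray(hist, dtype=float)
    if hist.shape != (256,) or np.any(hist < 0):
        raise ValueError("expected a 256-bin nonnegative histogram")
    if np.count_nonzero(hist) < 3:
        raise ValueError(
            "fewer than 3 distinct intensities: manual thresholds required"
        )
    levels = np.arange(256, dtype=float)
    w = np.cumsum(hist)
    m = np.cumsum(hist * levels)
    total_w, total_m = w[-1], m[-1]
    mu = total_m / total_w

    a = np.arange(256)
    # class weights/sums for every (a, b) pair via broadcasting
    w0 = w[a][:, None]  # depends on a only
    m0 = m[a][:, None]
    w1 = w[a][None, :] - w0  # w[b] - w[a]
    m1 = m[a][None, :] - m0
    w2 = total_w - w[a][None, :]
    m2 = total_m - m[a][None, :]

    def _term(wk: np.ndarray, mk: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(wk > 0, wk * (mk / np.where(wk > 0, wk, 1.0) - mu) ** 2, 0.0)
        return t

    score = _term(w0, m0) + _term(w1, m1) + _term(w2, m2)
    valid = a[:, None] < a[None, :]
    score = np.where(valid, score, -np.inf)
    best = score.max()
    ia, ib = min(zip(*np.nonzero(score == best)))
    return ThresholdPair(tc=int(ia) + 1, th=int(ib))


def measure_halo(
    image: np.ndarray,
    thresholds: ThresholdPair,
    crop_id: str | None = None,
    condition: str | None = None,
) -> HaloMeasurement:
    """Count colony and halo pixels in a crop and form the area ratio."""
    image = _check_grayscale(image)
    n_colony = int(np.count_nonzero(image < thresholds.tc))
    n_halo = int(np.count_nonzero(image > thresholds.th))
    if n_colony == 0:
        raise ValueError("no colony detected (no pixels below tC); ratio undefined")
    ratio = (n_colony + n_halo) / n_colony
    return HaloMeasurement(n_colony, n_halo, ratio, crop_id=crop_id, condition=condition)


def quantify_plate(image: np.ndarray, crops: Sequence[CropEntry]) -> PlateQuantification:
    """Score every listed colony and aggregate ratios per condition.

    Thresholds given in an entry are authoritative; otherwise they are
    suggested from the crop's histogram.  Crops that fail (no colony, too
    few intensity classes, bad region) are flagged and excluded from the
    aggregates.  Aggregates report the mean ratio and the standard error
    sd/sqrt(n) over replicate colonies; a single replicate has no SE.
    """
    if not crops:
        raise ValueError("at least one crop is required")
    measurements: list[HaloMeasurement] = []
    failures: list[tuple[str | None, str]] = []
    for i, entry in enumerate(crops):
        crop_id = entry.crop_id if entry.crop_id is not None else f"crop{i}"
        try:
            sub = crop(image, entry.region)
            thresholds = entry.thresholds
            if thresholds is None:
                thresholds = suggest_thresholds(histogram(sub))
            measurements.append(
                measure_halo(sub, thresholds, crop_id=crop_id, condition=entry.condition)
            )
        except ValueError as exc:
            failures.append((crop_id, str(exc)))
    if not measurements:
        raise ValueError(
            "all crops failed: " + "; ".join(f"{cid}: {msg}" for cid, msg in failures)
        )
    frame = pd.DataFrame(
        [{"condition": m.condition, "ratio": m.ratio} for m in measurements]
    )
    rows = []
    for condition, sub in frame.groupby("condition", dropna=False):
        n = len(sub)
        mean = float(sub["ratio"].mean())
        se = float(sub["ratio"].std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append({"condition": condition, "n": n, "mean_ratio": mean, "se_ratio": se})
    aggregates = pd.DataFrame(rows)
    return PlateQuantification(measurements, failures, aggregates)
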