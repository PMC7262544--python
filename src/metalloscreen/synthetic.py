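"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data the screening workflow consumes: grayscale
CAS agar plate photographs with three well separated intensity populations
(dark colonies, bright decolourised halos, mid-gray Fe-CAS background),
exponential decolourisation calibration responses of a DFOB dilution series,
long-format ICP-MS element tables with group effects, and nonnegative
spectral-count profile vectors per cultivation condition.

Every generator is a pure function of its parameters and a seed, so each
downstream stage can be tested offline against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColonySpec",
    "PlateSpec",
    "GroundTruth",
    "generate_plate",
    "random_plate_spec",
    "DEFAULT_CALIBRATION_CONCENTRATIONS",
    "generate_calibration",
    "generate_element_table",
    "generate_profiles",
]

# Default gray levels; chosen well apart so the three populations remain
# separable under moderate additive noise.
COLONY_GRAY = 20
BACKGROUND_GRAY = 128
HALO_GRAY = 235


@dataclass(frozen=True)
class ColonySpec:
    """One colony with its surrounding decolourised halo annulus."""

    center_row: float
    center_col: float
    colony_radius: float
    halo_outer_radius: float
    colony_gray: int = COLONY_GRAY
    halo_gray: int = HALO_GRAY


@dataclass(frozen=True)
class PlateSpec:
    """Geometry and intensity description of a synthetic CAS plate."""

    image_height: int
    image_width: int
    background_gray: int = BACKGROUND_GRAY
    colonies: tuple[ColonySpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("plate must be at least 1x1 pixels")
        if not 0 <= self.background_gray <= 255:
            raise ValueError("background_gray must be in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for i, c in enumerate(self.colonies):
            if not (0 <= c.colony_gray <= 255 and 0 <= c.halo_gray <= 255):
                raise ValueError(f"colony {i}: gray levels must be in [0, 255]")
            if not c.colony_gray < self.background_gray < c.halo_gray:
                raise ValueError(
                    f"colony {i}: need colony_gray < background_gray < halo_gray "
                    f"({c.colony_gray} < {self.background_gray} < {c.halo_gray} fails)"
                )
            if c.halo_outer_radius < c.colony_radius:
                raise ValueError(f"colony {i}: halo_outer_radius < colony_radius")
            if c.colony_radius <= 0:
                raise ValueError(f"colony {i}: colony_radius must be positive")
            r = c.halo_outer_radius
            if (
                c.center_row - r < 0
                or c.center_col - r < 0
                or c.center_row + r > self.image_height - 1
                or c.center_col + r > self.image_width - 1
            ):
                raise ValueError(f"colony {i}: halo disc extends outside the image")
        for i in range(len(self.colonies)):
            for j in range(i + 1, len(self.colonies)):
                a, b = self.colonies[i], self.colonies[j]
                d = np.hypot(a.center_row - b.center_row, a.center_col - b.center_col)
                if d <= a.halo_outer_radius + b.halo_outer_radius:
                    raise ValueError(
                        f"colonies {i} and {j} overlap; ground truth would be ambiguous"
                    )


@dataclass
class GroundTruth:
    """Exact pixel-level truth for a generated plate (from noiseless masks)."""

    colony_mask: np.ndarray  # bool, True on any colony pixel
    halo_mask: np.ndarray  # bool, True on any halo-annulus pixel
    colony_counts: list[int] = field(default_factory=list)  # per colony
    halo_counts: list[int] = field(default_factory=list)

    def ratio(self, index: int) -> float:
        """Ground-truth (colony + halo) / colony area ratio for one colony."""
        nc = self.colony_counts[index]
        return (nc + self.halo_counts[index]) / nc


def _distance_grid(spec: PlateSpec, colony: ColonySpec) -> np.ndarray:
    rows = np.arange(spec.image_height)[:, None] - colony.center_row
    cols = np.arange(spec.image_width)[None, :] - colony.center_col
    return np.hypot(rows, cols)


def generate_plate(spec: PlateSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a plate image plus exact ground truth.

    Discs are rasterized on pixel centers: a pixel belongs to the colony when
    its Euclidean distance to the colony center is <= colony_radius, and to
    the halo when colony_radius < distance <= halo_outer_radius.  Ground
    truth counts come from these noiseless masks.  Gaussian noise of standard
    deviation ``spec.noise_sd`` is then added, and the image is clipped to
    [0, 255] and rounded to 8-bit.  The same spec (including seed) always
    yields the identical image.
    """
    spec.validate()
    base = np.full((spec.image_height, spec.image_width), float(spec.background_gray))
    colony_mask = np.zeros(base.shape, dtype=bool)
    halo_mask = np.zeros(base.shape, dtype=bool)
    truth = GroundTruth(colony_mask=colony_mask, halo_mask=halo_mask)
    for colony in spec.colonies:
        d = _distance_grid(spec, colony)
        cmask = d <= colony.colony_radius
        hmask = (d > colony.colony_radius) & (d <= colony.halo_outer_radius)
        base[cmask] = colony.colony_gray
        base[hmask] = colony.halo_gray
        colony_mask |= cmask
        halo_mask |= hmask
        truth.colony_counts.append(int(cmask.sum()))
        truth.halo_counts.append(int(hmask.sum()))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        base = base + rng.normal(0.0, spec.noise_sd, base.shape)
    image = np.clip(np.rint(base), 0, 255).astype(np.uint8)
    return image, truth


def random_plate_spec(
    rng: np.random.Generator,
    n_colonies: int = 3,
    cell: int = 64,
    noise_sd: float = 0.0,
    colony_radius_range: tuple[float, float] = (6.0, 12.0),
    halo_width_range: tuple[float, float] = (4.0, 10.0),
) -> tuple[PlateSpec, list[tuple[int, int, int, int]]]:
    """Randomized plate: one colony per square cell, plus per-cell crop regions.

    Cells are laid out in a single row; each halo disc stays strictly inside
    its own cell, so a crop equal to the cell contains exactly one colony and
    only its own halo pixels.  Returns the spec and the matching crop list as
    (row_start, col_start, row_end, col_end) half-open tuples.
    """
    colonies = []
    crops = []
    for i in range(n_colonies):
        r = rng.uniform(*colony_radius_range)
        outer = r + rng.uniform(*halo_width_range)
        # keep the halo disc >= 2 px inside the cell
        margin = outer + 2.0
        lo, hi = margin, cell - 1 - margin
        if lo > hi:
            raise ValueError("cell too small for requested colony sizes")
        cr = rng.uniform(lo, hi)
        cc = i * cell + rng.uniform(lo, hi)
        colonies.append(
            ColonySpec(center_row=cr, center_col=cc, colony_radius=r, halo_outer_radius=outer)
        )
        crops.append((0, i * cell, cell, (i + 1) * cell))
    spec = PlateSpec(
        image_height=cell,
        image_width=cell * n_colonies,
        colonies=tuple(colonies),
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return spec, crops


# The liquid assay calibrates DFOB standards over 1-500 uM; a log-spaced
# dilution series over that range is the default standard grid.
DEFAULT_CALIBRATION_CONCENTRATIONS = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0)


def generate_calibration(
    true_k: float,
    concentrations: Sequence[float] = DEFAULT_CALIBRATION_CONCENTRATIONS,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a DFOB calibration series.

    The noiseless response follows the saturating exponential decolourisation
    model ``100 * (1 - exp(-true_k * c))`` (percent); additive Gaussian noise
    of ``noise_sd`` percentage points is applied independently to each well.
    Each standard concentration is read in ``n_replicates`` wells (triplicate
    by default, the usual microplate practice).

    Returns a DataFrame with columns ``conc_uM`` and ``response_pct``.
    """
    if true_k <= 0:
        raise ValueError("true_k must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    conc = np.asarray(concentrations, dtype=float)
    if conc.ndim != 1 or conc.size == 0:
        raise ValueError("concentrations must be a nonempty 1-D sequence")
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    conc = np.repeat(conc, n_replicates)
    response = 100.0 * (1.0 - np.exp(-true_k * conc))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, conc.shape)
    return pd.DataFrame({"conc_uM": conc, "response_pct": response})


def generate_element_table(
    groups: Mapping[str, Mapping[str, float]],
    n_per_group: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format ICP-MS element concentration table.

    ``groups`` maps a group label to per-element mean concentrations
    (ug/mL).  Each sample value is mean + Gaussian(0, noise_sd), truncated at
    zero (concentrations cannot be negative).  Deterministic under ``seed``.
    """
    if not groups:
        raise ValueError("at least one group is required")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    for label, means in groups.items():
        for element, mean in means.items():
            if mean < 0:
                raise ValueError(f"group {label!r}, element {element!r}: mean must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for label, means in groups.items():
        for rep in range(n_per_group):
            sample = f"{label}_{rep + 1}"
            for element, mean in means.items():
                value = mean
                if noise_sd > 0:
                    value = value + rng.normal(0.0, noise_sd)
                records.append(
                    {
                        "sample": sample,
                        "group": label,
                        "element": element,
                        "concentration_ug_ml": max(0.0, float(value)),
                    }
                )
    return pd.DataFrame.from_records(records)


def generate_profiles(
    n_features: int,
    condition_effects: Mapping[str, float],
    seed: int = 0,
    base_mean: float = 20.0,
    supports: Mapping[str, Sequence[int]] | None = None,
    noise: str = "none",
) -> pd.DataFrame:
    """Simulate per-condition spectral-count profile vectors.

    A base integer count profile of length ``n_features`` is drawn once from
    the seed; each condition scales it by its nonnegative effect multiplier
    (restricted to that condition's feature support, if given).  With
    ``noise="none"`` counts are ``rint(effect * base)``, so integer effects
    on a shared support give exactly proportional vectors (cosine similarity
    1 downstream).  With ``noise="poisson"`` counts are Poisson draws with
    those means.

    Returns a DataFrame of shape (n_features, n_conditions), one column per
    condition, nonnegative integer counts.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if not condition_effects:
        raise ValueError("at least one condition is required")
    for label, effect in condition_effects.items():
        if effect < 0:
            raise ValueError(f"condition {label!r}: effect must be nonnegative")
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    rng = np.random.default_rng(seed)
    base = rng.integers(1, max(2, int(2 * base_mean)), size=n_features).astype(float)
    columns = {}
    for label, effect in condition_effects.items():
        mean = effect * base
        if supports is not None and label in supports:
            mask = np.zeros(n_features, dtype=bool)
            mask[np.asarray(supports[label], dtype=int)] = True
            mean = np.where(mask, mean, 0.0)
        if noise == "poisson":
            counts = rng.poisson(mean)
        else:
            counts = np.rint(mean)
        columns[label] = counts.astype(int)
    return pd.DataFrame(columns, index=pd.RangeIndex(n_features, name="feature"))
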