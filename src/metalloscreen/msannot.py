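"""Light mass-spectrometric annotation utilities.

Adduct mass arithmetic, parts-per-million mass error, nearest-reference
matching, desferrioxamine-class counting, and cosine/diversity summaries of
secreted-metabolome spectral-count profiles.  Spectral networking and
in-silico fragmentation are upstream of this package; class membership of
unnamed features arrives as a tag on the input tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MSFeature",
    "ReferenceCompound",
    "ADDUCT_SHIFTS",
    "adduct_mz",
    "neutral_from_adduct",
    "ppm_error",
    "match_features",
    "count_class",
    "cosine_profile",
    "cosine_matrix",
    "profile_summary",
]

# monoisotopic masses (u)
PROTON_MASS = 1.007276  # H+ (hydrogen atom minus one electron)
HYDROGEN_MASS = 1.007825
IRON_MASS = 55.934936
ELECTRON_MASS = 0.000549

#: m/z shift from the neutral monoisotopic mass, singly charged ions.
#: [M+Fe-2H]+ is the ferric complex: Fe(III) replaces two protons and
#: carries the +1 charge, so the shift is Fe - 2H minus one electron.
ADDUCT_SHIFTS: dict[str, float] = {
    "[M+H]+": +PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
    "[M+Fe-2H]+": IRON_MASS - 2.0 * HYDROGEN_MASS - ELECTRON_MASS,
}

_MODES = ("positive", "negative")


@dataclass(frozen=True)
class MSFeature:
    mz: float
    mode: str  # "positive" | "negative"
    adduct: str | None = None
    fractions: tuple[str, ...] = ()
    name: str | None = None
    class_tag: str | None = None  # e.g. network-derived "desferrioxamine-like"
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")


@dataclass(frozen=True)
class ReferenceCompound:
    name: str
    neutral_mass: float | None = None
    adduct_mass: float | None = None  # theoretical m/z for `adduct`
    adduct: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.neutral_mass is None and self.adduct_mass is None:
            raise ValueError("reference needs a neutral or an adduct mass")
        for m in (self.neutral_mass, self.adduct_mass):
            if m is not None and m <= 0:
                raise ValueError("masses must be positive")

    def theoretical_mz(self, adduct: str) -> float | None:
        """Theoretical m/z of this compound under the given adduct."""
        if self.adduct_mass is not None and self.adduct == adduct:
            return self.adduct_mass
        if self.neutral_mass is not None:
            return adduct_mz(self.neutral_mass, adduct)
        return None


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct ion from the neutral monoisotopic mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    try:
        return neutral_mass + ADDUCT_SHIFTS[adduct]
    except KeyError:
        raise ValueError(
            f"unknown adduct {adduct!r}; supported: {sorted(ADDUCT_SHIFTS)}"
        ) from None


def neutral_from_adduct(mz: float, adduct: str) -> float:
    """Inverse of :func:`adduct_mz`."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    try:
        return mz - ADDUCT_SHIFTS[adduct]
    except KeyError:
        raise ValueError(
            f"unknown adduct {adduct!r}; supported: {sorted(ADDUCT_SHIFTS)}"
        ) from None


def ppm_error(measured: float, theoretical: float) -> float:
    """|measured - theoretical| / theoretical * 1e6.

    The theoretical mass is the denominator by convention; swapping the
    arguments changes the value by O(ppm^2) and is not equivalent.
    """
    if measured <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    return 1e6 * abs(measured - theoretical) / theoretical


def match_features(
    features: Sequence[MSFeature],
    refs: Sequence[ReferenceCompound],
    tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Annotate features against reference compounds by mass within tol_ppm.

    Each feature collects every reference whose adduct-corrected theoretical
    mass lies within ``tol_ppm``; the nearest one becomes ``best_match``.
    Features without a match are labeled ``"unknown, network-member"`` when
    they carry a class tag (network membership established upstream) and
    ``"unknown"`` otherwise.  An empty reference list is allowed and yields
    an all-unknown table.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    rows = []
    for feat in features:
        candidates = []
        for ref in refs:
            adduct = feat.adduct
            if adduct is None:
                continue
            theo = ref.theoretical_mz(adduct)
            if theo is None:
                continue
            err = ppm_error(feat.mz, theo)
            if err <= tol_ppm:
                candidates.append((err, ref.name, theo, ref.class_label))
        candidates.sort(key=lambda c: (c[0], c[1]))
        if candidates:
            best = candidates[0]
            annotation = best[1]
            best_theo, best_ppm, cls = best[2], best[0], best[3] or feat.class_tag
        elif feat.class_tag:
            annotation, best_theo, best_ppm, cls = (
                "unknown, network-member",
                None,
                None,
                feat.class_tag,
            )
        else:
            annotation, best_theo, best_ppm, cls = "unknown", None, None, None
        rows.append(
            {
                "mz": feat.mz,
                "mode": feat.mode,
                "adduct": feat.adduct,
                "name": feat.name,
                "annotation": annotation,
                "best_match": candidates[0][1] if candidates else None,
                "theoretical_mz": best_theo,
                "ppm": best_ppm,
                "n_matches": len(candidates),
                "all_matches": ";".join(c[1] for c in candidates),
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


def count_class(
    annotations: pd.DataFrame,
    class_filter: str,
    mode: str,
    exclude_names: Sequence[str] = ("Citric acid",),
) -> int:
    """Count distinct annotated features of a class in one ion mode.

    ``annotations`` needs ``mode``, ``class`` and (for the exclusion list)
    ``name`` columns — either a curated annotation table or the output of
    :func:`match_features`.  Compounds on the exclusion list (citric acid by
    default, a chelator but not a siderophore) never count.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if annotations.empty:
        return 0
    sel = annotations[
        (annotations["mode"] == mode) & (annotations["class"] == class_filter)
    ]
    if "name" in sel.columns and exclude_names:
        sel = sel[~sel["name"].isin(list(exclude_names))]
    return int(len(sel))


def cosine_profile(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine similarity of two equal-length nonnegative profile vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("profiles must be matched 1-D vectors")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("profile entries must be nonnegative")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for an all-zero profile")
    return float(np.dot(u, v) / (nu * nv))


def cosine_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity of profile columns (conditions)."""
    cols = list(profiles.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            c = cosine_profile(profiles[a].to_numpy(), profiles[b].to_numpy())
            out.loc[a, b] = out.loc[b, a] = c
    return out


def profile_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-condition diversity and abundance summaries.

    For each column: the number of unique signals (bins with count > 0), the
    total spectral counts, and the largest m/z among observed bins when the
    index is numeric (NaN otherwise or when nothing is observed).
    """
    if profiles.shape[1] < 1:
        raise ValueError("at least one profile is required")
    numeric_index = pd.api.types.is_numeric_dtype(profiles.index)
    rows = []
    for cond in profiles.columns:
        counts = profiles[cond].to_numpy(dtype=float)
        observed = counts > 0
        if numeric_index and observed.any():
            max_mz = float(np.asarray(profiles.index, dtype=float)[observed].max())
        else:
            max_mz = float("nan")
        rows.append(
            {
                "condition": cond,
                "unique_signals": int(observed.sum()),
                "total_counts": float(counts.sum()),
                "max_mz": max_mz,
            }
        )
    return pd.DataFrame(rows)
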