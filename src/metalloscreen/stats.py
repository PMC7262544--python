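"""Group statistics for metal-stress and biosorption screens.

Covers the statistical layer the screening workflow relies on: the
Kruskal-Wallis rank test with a Dunn-Bonferroni post hoc, one-way ANOVA
with a Fisher LSD post hoc and compact letter display (groups sharing a
letter are not significantly different at level alpha), PCA of per-sample
element concentration profiles, metal enrichment factors of eluates over a
blank carrier, and biosorption mass balances.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "PCAResult",
    "EnrichmentFactor",
    "BiosorptionResult",
    "kruskal_wallis",
    "dunn_bonferroni",
    "anova_oneway",
    "fisher_lsd",
    "compact_letter_display",
    "pivot_elements",
    "pca",
    "enrichment_factor",
    "enrichment_factors_from_summary",
    "biosorption_balance",
]

logger = logging.getLogger(__name__)

GroupsLike = Sequence[Sequence[float]] | Mapping[str, Sequence[float]]


def _as_groups(groups: GroupsLike) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        labels = [str(k) for k in groups.keys()]
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for lab, arr in zip(labels, arrays):
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError(f"group {lab!r} must be a nonempty 1-D vector")
    return labels, arrays


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    df: tuple[int, ...]
    pvalue: float
    alpha: float | None = None
    pairwise: pd.DataFrame | None = None
    letters: dict[str, str] | None = None


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components, orthonormal columns
    variance_explained_pct: np.ndarray  # sums to 100 over all components


class EnrichmentFactor(NamedTuple):
    factor: float
    se: float | None


class BiosorptionResult(NamedTuple):
    sorbed_fraction: float
    amount_ug_per_g: float


# ---------------------------------------------------------------------------
# rank-based tests


def _tie_sum(pooled: np.ndarray) -> float:
    """Sum of (t^3 - t) over groups of tied values."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: GroupsLike) -> GroupTestResult:
    """Kruskal-Wallis H test with mid-ranks and the standard tie correction.

    H = [12/(N(N+1)) * sum R_j^2/n_j - 3(N+1)] / [1 - sum(t^3 - t)/(N^3 - N)],
    referred to a chi-square distribution with k - 1 degrees of freedom.
    When every pooled value is identical the tie correction degenerates; the
    statistic is reported as 0 with p = 1.
    """
    labels, arrays = _as_groups(groups)
    pooled = np.concatenate(arrays)
    n = pooled.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    offsets = np.cumsum([0] + sizes)
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[offsets[i] : offsets[i + 1]].sum() ** 2 / sizes[i] for i in range(len(sizes))
    ) - 3.0 * (n + 1)
    correction = 1.0 - _tie_sum(pooled) / (n**3 - n)
    k = len(arrays)
    if correction <= 0:  # all values identical
        return GroupTestResult("kruskal-wallis", 0.0, (k - 1,), 1.0)
    h /= correction
    h = max(h, 0.0)
    return GroupTestResult(
        "kruskal-wallis", float(h), (k - 1,), float(sps.chi2.sf(h, k - 1))
    )


def dunn_bonferroni(groups: GroupsLike, alpha: float = 0.05) -> GroupTestResult:
    """Dunn's rank post hoc with Bonferroni correction over all pairs.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - sum(t^3-t)/(12(N-1))]
    * (1/n_i + 1/n_j)); two-sided normal p-values multiplied by the family
    size k(k-1)/2 and capped at 1.  Letters come from the insert-absorb
    compact letter display: groups share a letter iff their adjusted p
    exceeds alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    labels, arrays = _as_groups(groups)
    omnibus = kruskal_wallis(groups)
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(sizes))
    ]
    sigma2 = n * (n + 1) / 12.0 - _tie_sum(pooled) / (12.0 * (n - 1))
    k = len(arrays)
    m = k * (k - 1) // 2
    rows = []
    sig_pairs = []
    for i, j in itertools.combinations(range(k), 2):
        var = sigma2 * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)
        significant = p_adj <= alpha
        if significant:
            sig_pairs.append((i, j))
        rows.append(
            {
                "group_i": labels[i],
                "group_j": labels[j],
                "z": z,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": significant,
            }
        )
    letters = compact_letter_display(labels, sig_pairs)
    return GroupTestResult(
        "dunn-bonferroni",
        omnibus.statistic,
        omnibus.df,
        omnibus.pvalue,
        alpha=alpha,
        pairwise=pd.DataFrame(rows),
        letters=letters,
    )


# ---------------------------------------------------------------------------
# ANOVA / LSD


def anova_oneway(groups: GroupsLike) -> GroupTestResult:
    """One-way ANOVA; F = MSB/MSW against F(k-1, N-k).

    Degenerate variance cases follow explicit conventions: zero within- and
    between-group variance gives p = 1, zero within- with nonzero
    between-group variance gives p = 0; both are logged.
    """
    labels, arrays = _as_groups(groups)
    for lab, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {lab!r} needs n >= 2 for ANOVA")
    n = sum(a.size for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    df = (k - 1, n - k)
    if ssw == 0:
        if ssb == 0:
            logger.warning("ANOVA degenerate: all observations identical; p set to 1")
            return GroupTestResult("anova", 0.0, df, 1.0)
        logger.warning(
            "ANOVA degenerate: zero within-group variance with distinct means; p set to 0"
        )
        return GroupTestResult("anova", float("inf"), df, 0.0)
    f = (ssb / df[0]) / (ssw / df[1])
    return GroupTestResult("anova", float(f), df, float(sps.f.sf(f, *df)))


def fisher_lsd(
    groups: GroupsLike,
    anova_result: GroupTestResult | None = None,
    alpha: float = 0.05,
    protected: bool = True,
) -> GroupTestResult:
    """Fisher least-significant-difference post hoc with letter display.

    A pair differs when |mean_i - mean_j| exceeds
    t_{1-alpha/2, N-k} * sqrt(MSW * (1/n_i + 1/n_j)).  With
    ``protected=True`` (default) all pairs are declared non-different when
    the omnibus ANOVA p exceeds alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    labels, arrays = _as_groups(groups)
    if anova_result is None:
        anova_result = anova_oneway(groups)
    n = sum(a.size for a in arrays)
    k = len(arrays)
    ssw = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    df_within = n - k
    if ssw == 0:
        raise ValueError(
            "zero within-group variance: LSD undefined, handle exact ties separately"
        )
    msw = ssw / df_within
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df_within)
    omnibus_blocks = protected and anova_result.pvalue > alpha
    rows = []
    sig_pairs = []
    for i, j in itertools.combinations(range(k), 2):
        diff = arrays[i].mean() - arrays[j].mean()
        se = math.sqrt(msw * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        lsd = t_crit * se
        p = 2.0 * sps.t.sf(abs(diff) / se, df_within)
        significant = (abs(diff) > lsd) and not omnibus_blocks
        if significant:
            sig_pairs.append((i, j))
        rows.append(
            {
                "group_i": labels[i],
                "group_j": labels[j],
                "mean_diff": diff,
                "lsd": lsd,
                "p": p,
                "significant": significant,
            }
        )
    letters = compact_letter_display(labels, sig_pairs)
    return GroupTestResult(
        "fisher-lsd",
        anova_result.statistic,
        anova_result.df,
        anova_result.pvalue,
        alpha=alpha,
        pairwise=pd.DataFrame(rows),
        letters=letters,
    )


def compact_letter_display(
    labels: Sequence[str], significant_pairs: Sequence[tuple[int, int]]
) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Starts from one letter covering every group; each significantly
    different pair splits any letter set containing both members, and sets
    contained in another are absorbed.  Letters are assigned a, b, c, ... in
    group-input order (sets ordered by their smallest member index).  Two
    groups share a letter iff their comparison is non-significant.
    """
    k = len(labels)
    sets: list[set[int]] = [set(range(k))]
    for i, j in significant_pairs:
        new_sets: list[set[int]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.append(s - {i})
                new_sets.append(s - {j})
            else:
                new_sets.append(s)
        # absorb sets contained in (or duplicating) another
        kept: list[set[int]] = []
        for idx, s in enumerate(new_sets):
            if not s:
                continue
            absorbed = any(
                idx != jdx and (s < t or (s == t and idx > jdx))
                for jdx, t in enumerate(new_sets)
            )
            if not absorbed:
                kept.append(s)
        sets = kept
    sets.sort(key=lambda s: (min(s), sorted(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[int, list[str]] = {i: [] for i in range(k)}
    for idx, s in enumerate(sets):
        letter = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for member in s:
            assigned[member].append(letter)
    return {labels[i]: "".join(sorted(assigned[i])) for i in range(k)}


# ---------------------------------------------------------------------------
# PCA


def pivot_elements(
    table: pd.DataFrame,
    sample_col: str = "sample",
    element_col: str = "element",
    value_col: str = "concentration_ug_ml",
) -> pd.DataFrame:
    """Long-format element table -> samples x elements matrix."""
    if table.duplicated(subset=[sample_col, element_col]).any():
        raise ValueError("duplicate (sample, element) pairs in element table")
    return table.pivot(index=sample_col, columns=element_col, values=value_col)


def pca(data: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA of a samples-by-elements concentration matrix.

    Columns are centered and, with ``standardize=True`` (default, since
    elements span very different concentration scales), scaled to unit
    variance.  Components come from the SVD of the processed matrix;
    variance explained derives from the singular values and sums to 100 %
    over all computed components.  Sign convention: the largest-magnitude
    loading of each component is positive.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, dtype=float))
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    if data.isna().any().any():
        raise ValueError("missing cells are not supported")
    x = data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = ", ".join(str(data.columns[i]) for i in zero)
            raise ValueError(f"constant column(s) cannot be standardized: {names}")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest |loading| per component is positive
    for j in range(s.size):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    var = s**2
    total = var.sum()
    explained = 100.0 * var / total if total > 0 else np.zeros_like(var)
    comp_names = [f"PC{j + 1}" for j in range(s.size)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=data.index, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=data.columns, columns=comp_names),
        variance_explained_pct=explained,
    )


# ---------------------------------------------------------------------------
# enrichment and biosorption


def _summary(values) -> tuple[float, float | None, int | None]:
    """(mean, sd, n) from raw values or an already-summarized triple."""
    if isinstance(values, tuple) and len(values) == 3:
        mean, sd, n = values
        return float(mean), (float(sd) if sd is not None else None), (int(n) if n else None)
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("expected a nonempty 1-D value vector or a (mean, sd, n) triple")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return float(arr.mean()), sd, int(arr.size)


def enrichment_factor(eluate, blank) -> EnrichmentFactor:
    """Fold enrichment of an eluate over the blank carrier for one element.

    factor = mean(eluate) / mean(blank).  Inputs are raw replicate vectors
    or (mean, sd, n) triples; when spread information is available a
    delta-method standard error is attached:
    SE = factor * sqrt(SE_e^2/mean_e^2 + SE_b^2/mean_b^2).
    """
    mean_e, sd_e, n_e = _summary(eluate)
    mean_b, sd_b, n_b = _summary(blank)
    if mean_b <= 0:
        raise ValueError("blank mean must be positive")
    factor = mean_e / mean_b
    se = None
    if sd_e is not None and sd_b is not None and n_e and n_b and mean_e != 0:
        se_e = sd_e / math.sqrt(n_e)
        se_b = sd_b / math.sqrt(n_b)
        se = abs(factor) * math.sqrt((se_e / mean_e) ** 2 + (se_b / mean_b) ** 2)
    return EnrichmentFactor(factor=factor, se=se)


def enrichment_factors_from_summary(
    summary: pd.DataFrame,
    blank_label: str,
    material_col: str = "material",
    element_col: str = "element",
    mean_col: str = "mean_ug_ml",
    sd_col: str = "sd_ug_ml",
    n_col: str = "n",
) -> pd.DataFrame:
    """Per-(material, element) enrichment factors from a summary-stats table."""
    blanks = summary[summary[material_col] == blank_label].set_index(element_col)
    if blanks.empty:
        raise ValueError(f"no rows with {material_col} == {blank_label!r}")
    rows = []
    for _, row in summary[summary[material_col] != blank_label].iterrows():
        element = row[element_col]
        if element not in blanks.index:
            continue
        b = blanks.loc[element]
        ef = enrichment_factor(
            (row[mean_col], row.get(sd_col), row.get(n_col)),
            (b[mean_col], b.get(sd_col), b.get(n_col)),
        )
        rows.append(
            {
                material_col: row[material_col],
                element_col: element,
                "factor": ef.factor,
                "se": ef.se,
            }
        )
    return pd.DataFrame(rows)


def biosorption_balance(
    initial_ug_ml: float,
    supernatant_ug_ml: float,
    volume_ml: float = 10.0,
    biomass_g: float = 0.1,
) -> BiosorptionResult:
    """Sorbed fraction and metal load per unit biomass from a batch assay.

    fraction = (initial - supernatant) / initial;
    amount = (initial - supernatant) [ug/mL] * volume [mL] / biomass [g].
    A supernatant above the initial concentration (release or measurement
    noise) floors both at zero with a warning.
    """
    if initial_ug_ml <= 0:
        raise ValueError("initial concentration must be positive")
    if supernatant_ug_ml < 0:
        raise ValueError("supernatant concentration must be nonnegative")
    if volume_ml <= 0 or biomass_g <= 0:
        raise ValueError("volume and biomass must be positive")
    delta = initial_ug_ml - supernatant_ug_ml
    if delta < 0:
        warnings.warn(
            "supernatant exceeds initial concentration (release or measurement "
            "noise); sorbed amount floored at 0",
            UserWarning,
            stacklevel=2,
        )
        delta = 0.0
    return BiosorptionResult(
        sorbed_fraction=delta / initial_ug_ml,
        amount_ug_per_g=delta * volume_ml / biomass_g,
    )
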