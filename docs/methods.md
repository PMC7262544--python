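# Methods

This note documents the models and procedures `metalloscreen` implements,
the defaults and conventions it commits to, and what its synthetic-data
tests do and do not demonstrate about real screening data.

## Halo scoring on CAS agar

A photographed CAS plate separates, in grayscale, into three intensity
populations: dark colonies, a mid-gray Fe-CAS dye background, and bright
decolourised halos. Scoring is purely threshold-based. For a crop around
one colony with thresholds `0 ≤ tC < tH ≤ 255`:

- colony pixels: `g < tC` (strict),
- halo pixels: `g > tH` (strict),
- background: `tC ≤ g ≤ tH`, counted in neither region,
- score: `ratio = (nC + nH) / nC`, dimensionless, ≥ 1, equal to 1 iff no
  halo pixels exist. A crop with `nC = 0` is an error ("no colony
  detected"), not a zero.

Conventions: images are 0-based, row-major; crops are half-open
`[r0, r1) × [c0, c1)` windows, so chained crops compose by index
arithmetic. RGB input is converted with ITU-R BT.601 luminance weights
(0.299, 0.587, 0.114), rounding half up. Halo pixels are counted anywhere
in the crop, not only in an annulus: the crop window, not a geometric
model, delimits the colony's halo. Consequently crops must be drawn so
that each contains one colony and only its own halo — the same discipline
an interactive user applies when cutting out colonies.

When a crop entry supplies no thresholds, a three-class Otsu split of the
256-bin crop histogram is used: all cut pairs `(a, b)` with `a < b` are
searched exhaustively, maximizing between-class variance of the classes
`≤ a`, `(a, b]`, `> b`; ties resolve to the lexicographically smallest
pair. The returned pair is `tC = a + 1`, `tH = b`, which makes the strict
threshold rules reproduce the Otsu classes exactly. Histograms with fewer
than three distinct intensities raise an error directing the user to
manual thresholds; user-supplied thresholds always override the
suggestion. Replicate colonies aggregate per condition as mean ratio and
standard error `sd/√n` (undefined, reported as NaN, for n = 1); failed
crops are flagged, logged and excluded.

## Liquid CAS assay

The percentage CAS response of a sample against the Fe-CAS blank read in
the same medium is `100·(A_ref − A_sample)/A_ref`, clipped to [0, 100]
(small negative differences are read noise, not signal). Kinetic traces
yield an initial decolourisation velocity as the sign-flipped
least-squares slope of reading vs time over a leading window (default
3600 s), in reading units per hour, with the regression standard error
attached.

Calibration uses the saturating exponential decolourisation model

    response(c) = A · (1 − exp(−k·c)),   A = 100 % unless freed,

chosen because the response is a percentage bounded at 100 and the model
is invertible in closed form. The rate `k` (per µM DFOB) is fitted by
nonlinear least squares, initialized from the through-origin regression of
`−ln(1 − r/100)` on `c`. Points with response ≥ 100 % are excluded with a
warning (the log transform is undefined there); at least three distinct
usable concentrations are required. Whether the ceiling should be
estimated rather than fixed is genuinely open; the default fixes it at
100 % with `free_ceiling=True` as the alternative.

Inverse prediction is `c = −ln(1 − r/A)/k`, multiplied by the dilution
factor after inversion; predictions outside the fitted concentration range
raise an `ExtrapolationWarning`. The round trip predict-then-invert is
exact to floating point. Yields convert as
`mg L⁻¹ = c[µM]·10⁻⁶·V_extract[L]·M[g/mol]·10³ / V_culture[L]`, with the
DFOB molar mass 560.68 g/mol as default.

## Group statistics

**Kruskal–Wallis.** Mid-ranks over the pooled data;
`H = [12/(N(N+1))·Σ R_j²/n_j − 3(N+1)] / [1 − Σ(t³−t)/(N³−N)]`, p from
χ²(k−1). When all observations are identical the tie correction
degenerates and the result is defined as H = 0, p = 1. The implementation
is verified against an independent rank-variance formulation,
`H = (N−1)·Σ n_j(R̄_j−R̄)² / Σ(r_i−R̄)²`, exhaustively over all two-group
splits of values from {1, 2, 3} for N = 3..8 (~64k tie-rich datasets), and
against `scipy.stats.kruskal`.

**Dunn–Bonferroni.** `z_ij = (R̄_i − R̄_j) / √[(N(N+1)/12 −
Σ(t³−t)/(12(N−1)))·(1/n_i + 1/n_j)]`; two-sided normal p-values multiplied
by the full pairwise family size `k(k−1)/2` and capped at 1.

**ANOVA + Fisher LSD.** Standard one-way sums of squares; degenerate
variance cases use explicit conventions (all identical → p = 1; zero
within-group variance with distinct means → p = 0; both logged). LSD
declares pair (i, j) different when `|ȳ_i − ȳ_j| >
t_{1−α/2, N−k}·√(MSW·(1/n_i + 1/n_j))`; the protected variant (default)
suppresses all pairwise calls when the omnibus F is not significant, since
the screen's published letter displays do not reveal which variant
produced them.

**Compact letter display.** The insert-absorb algorithm: one letter set
initially covers all groups; each significant pair splits every set
containing both members and subset/duplicate sets are absorbed; letters
are assigned in group-input order. By construction two groups share a
letter iff their pairwise comparison is non-significant at α.

**PCA.** Columns are centered and, by default, scaled to unit variance —
elements span orders of magnitude in µg/mL, so unstandardized PCA would be
dominated by the most concentrated metal. Components come from the SVD of
the processed matrix (numerically equivalent to eigendecomposition of its
covariance); variance explained sums to 100 % over all computed
components; the sign convention makes the largest-magnitude loading of
each component positive. Constant columns under standardization raise an
error naming the column.

**Enrichment and biosorption.** The enrichment factor of an eluate over
the blank carrier is the ratio of means, with a delta-method standard
error `f·√(SE_e²/m_e² + SE_b²/m_b²)` when spreads are available. The
biosorption balance reports the sorbed fraction
`(c_init − c_sup)/c_init` and the load `(c_init − c_sup)·V/m_biomass`
(µg per g dry biomass; defaults V = 10 mL, m = 0.1 g). A supernatant
exceeding the initial concentration — release or measurement noise —
floors both at zero with a warning rather than reporting negative
sorption.

## MS annotation

Δppm is `10⁶·|m_measured − m_theoretical|/m_theoretical`; the theoretical
mass is fixed as denominator (the two conventions differ only at O(ppm²),
but the choice is documented and tested). Adduct shifts for singly charged
ions: `[M+H]+` = +1.007276, `[M−H]−` = −1.007276, and the ferric complex
`[M+Fe−2H]+` = +55.934936 − 2·1.007825 − 0.000549 (Fe(III) replaces two
protons and carries the charge; the electron mass is subtracted
explicitly, since conventions for metal adducts vary — all constants live
in one editable table). Matching annotates each feature with every
reference within a ppm tolerance and flags the nearest; unmatched features
carrying a network-membership class tag are labeled
"unknown, network-member". Desferrioxamine-class counts operate per ion
mode on distinct features, honoring an exclusion list (citric acid by
default — a chelator, but not a siderophore). Cosine similarity of
spectral-count profiles is the standard normalized dot product, undefined
(error) for all-zero profiles; diversity summaries report unique signals,
total counts, and the largest observed m/z per condition.

The printed Δppm column of the negative-mode reference table is internally
inconsistent with its own mass pairs under any standard formula; those
printed values are carried for completeness but never used as correctness
anchors. Class membership of unnamed features is taken from the curated
class tags (standing in for fragment-spectrum network membership), not
recomputed — spectral networking is out of scope.

## Synthetic data: what it emulates, and what it does not

- **Plates**: three-population grayscale images (defaults: colony 20,
  background 128, halo 235) with colonies rasterized as Euclidean discs on
  pixel centers — ground truth counts follow this rasterization, not πr².
  Additive Gaussian noise (clipped to [0, 255], rounded) models sensor
  noise; overlap and out-of-bounds geometries are rejected so ground truth
  stays unambiguous. Randomized plates place one colony per 64-px cell so
  each crop provably contains only its own halo. Not emulated: uneven
  illumination, color (the analysis is grayscale), dye gradients, fuzzy
  halo edges, colony texture. Passing the recovery suite therefore shows
  the counting and thresholding machinery is exact, not that Otsu
  thresholds are adequate for every real photograph — the config override
  exists precisely for the plates where they are not.
- **Calibration**: responses from the exponential model over the assay
  range 1–500 µM (default grid 1, 2, 5, 10, 20, 50, 100, 200, 500 µM) with
  additive Gaussian noise in percentage points, default true rate
  k = 0.01 µM⁻¹ (63.2 % response at 100 µM). Each standard is read in
  triplicate wells by default, the usual microplate practice; with single
  wells the information content of a 9-point series bounds the precision
  of k̂ near 3–4 % relative, so replication is what makes 5 %-accurate
  rate recovery reliably attainable.
- **Element tables**: group means plus Gaussian noise truncated at zero,
  long format, default n = 4 replicates per group (matching the eluate
  assays).
- **Profiles**: a seeded integer base profile scaled by per-condition
  effect multipliers on optional feature supports, with optional Poisson
  noise; integer effects on a shared support give exactly proportional
  vectors, pinning the cosine at 1.

All generators are pure functions of (spec, seed).

## Pipeline

A single YAML config per run: seed, α, output directory, ordered stage
list. Every output CSV carries the SHA-256 of the canonicalized config and
the seed as comment lines; a rerun with an identical config is
byte-identical for deterministic stages. Validation aggregates every
violation into one error list; input paths must exist, except files an
earlier stage of the same run declares as outputs. Stage failures halt
the run naming the stage. CLI exit codes: 0 success, 1 validation error,
2 runtime failure.

## Problem sizes in the shipped checks

The reproduction script and test suite use 100 randomized noiseless plates
plus 30 noisy ones (≈ 200–300 colonies), 200 seeded calibration
replicates, the ~64k-dataset exhaustive rank-test sweep, and small dense
matrices for the PCA identities — sizes chosen so the whole suite runs in
well under a minute while the exhaustive and exact checks remain genuinely
exhaustive and exact.

## Known limitations

- No automatic colony detection: the crop list is part of the input, by
  design (determinism over convenience).
- The halo/colony ratio conflates halo brightness with area; faint halos
  below `tH` are invisible to it.
- The calibration model assumes a 100 % ceiling unless freed, and a single
  exponential rate; multi-phasic decolourisation kinetics are only
  captured through the initial-velocity utility.
- Enrichment standard errors assume independent group means
  (delta method); correlated batch effects are not modeled.
- The yield conversion is a pure unit conversion; it does not attempt to
  reconcile extract concentration, recovery losses and culture volume
  bookkeeping beyond the stated formula.
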