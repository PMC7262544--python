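"""Packaged reference tables.

Small curated CSVs distributed with the package: LC-MS/MS feature
annotations (positive and negative ion mode) for the secreted siderophores
of *Gordonia rubripertincta* CWB2, ICP-MS summary statistics for the
TMOS-carrier eluates and the biosorption supernatants, the metal model
solution, and neutral monoisotopic masses for the identified reference
compounds.  They let the annotation, enrichment and biosorption analytics
run end to end without any external download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_lcms_annotations",
    "load_tmos_eluates",
    "load_biosorption_supernatants",
    "load_model_solution",
    "load_reference_compounds",
]


def _read(name: str) -> pd.DataFrame:
    path = resources.files("metalloscreen") / "data" / name
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def load_lcms_annotations(mode: str = "positive") -> pd.DataFrame:
    """Curated LC-MS/MS feature annotation table for one ion mode.

    Columns: name (blank for unnamed network members), measured_mz,
    theoretical_mz (named compounds only), adduct, mode, class
    (``desferrioxamine-like`` or ``citrate``), hplc_fractions
    (semicolon-separated).
    """
    if mode not in ("positive", "negative"):
        raise ValueError("mode must be 'positive' or 'negative'")
    return _read(f"lcms_features_{mode}.csv")


def load_tmos_eluates() -> pd.DataFrame:
    """EDTA/DTPA eluate concentrations (mean, sd, n) per carrier material.

    Materials: blank TMOS carrier, DFOB-loaded TMOS, and TMOS loaded with
    C18-purified or crude XAD extract of strain CWB2; elements V, Ga, Mo,
    Nd in ug/mL eluate.
    """
    return _read("tmos_eluates.csv")


def load_biosorption_supernatants() -> pd.DataFrame:
    """Supernatant element concentrations after the biosorption batch assay.

    Groups: the initial multi-element solution, the wild type, and the
    Er/Mn-adapted variant; concentrations in ug/mL (mean, sd where
    replicated).
    """
    return _read("biosorption_supernatants.csv")


def load_model_solution() -> pd.DataFrame:
    """Element concentrations of the pH 4 adsorption model solution (ug/mL)."""
    return _read("model_solution.csv")


def load_reference_compounds() -> pd.DataFrame:
    """Neutral monoisotopic masses and class labels of reference compounds."""
    return _read("reference_compounds.csv")
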