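"""Packaged reference tables for the 12-drug nephrotoxicity screening panel.

Two small fixtures ship with the package so the full classification and
ranking stages run without any external download:

* the compound annotation table — human serum Cmax ranges (µM), the in vivo
  nephrotoxicity risk class (High / Intermediate / Low) and the dosing
  vehicle for each of the 12 drugs;
* the per-cell-source in vitro call matrix — the binary
  positive / negative viability calls for the 9 screened cell sources.

High- and intermediate-risk compounds count as in vivo positives, low-risk
as negatives.  Gentamicin and Streptomycin are excluded from confusion
matrices because the tested concentrations were subtoxic for them.  Rows of
the call matrix carry a ``verified`` flag: calls the study narrative
enumerates drug-by-drug are True; for the remaining cell sources only the
marginal TP/FN/FP/TN counts are pinned down, and the stored per-drug
assignment is one consistent choice (flagged False).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Drugs excluded from confusion-matrix scoring (tested at subtoxic levels).
EXCLUDED_DRUGS: frozenset[str] = frozenset({"Gentamicin", "Streptomycin"})

#: Screened cell sources, parental lines and their OAT1-overexpressing
#: variants, two primary-donor lots, and the hepatic comparator.
CELL_SOURCES: tuple[str, ...] = (
    "ciPTEC",
    "ciPTEC-OAT1",
    "TERT1",
    "TERT1-OAT1",
    "HEK",
    "HEK-OAT1",
    "Lonza340",
    "Lonza405",
    "HepG2",
)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("nephroscreen.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def compound_annotations() -> pd.DataFrame:
    """The 12-drug panel annotation table.

    Columns: ``drug``, ``cmax_min_uM``, ``cmax_max_uM`` (range endpoints of
    the human serum Cmax; equal when a single value was reported),
    ``risk_class`` and ``vehicle``.
    """
    return _read_packaged("compound_annotations.csv")


def in_vivo_labels(annotations: pd.DataFrame | None = None) -> dict[str, str]:
    """Map drug → in vivo label ('positive' / 'negative').

    High and Intermediate risk classes are positives; Low is negative.
    """
    ann = compound_annotations() if annotations is None else annotations
    return {
        row.drug: ("negative" if row.risk_class == "Low" else "positive")
        for row in ann.itertuples()
    }


def call_matrix() -> pd.DataFrame:
    """Per (cell_source, drug) in vitro viability calls.

    Columns: ``cell_source``, ``drug``, ``in_vitro_call`` ('positive' /
    'negative'), ``verified`` (bool; see module docstring).
    """
    df = _read_packaged("call_matrix.csv")
    df["verified"] = df["verified"].astype(bool)
    return df


def calls_for(cell_source: str, matrix: pd.DataFrame | None = None) -> dict[str, str]:
    """Drug → call mapping for one cell source from the packaged matrix."""
    mat = call_matrix() if matrix is None else matrix
    sub = mat[mat["cell_source"] == cell_source]
    if sub.empty:
        raise KeyError(f"unknown cell source: {cell_source!r}")
    return dict(zip(sub["drug"], sub["in_vitro_call"]))
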