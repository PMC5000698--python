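"""Packaged wash-series moment tables for four household detergents.

The package ships the published P1/P2 central-moment tables of silk samples
washed 0-6 times with fabric softener (F), laundry powder (L), toilet soap
(T) and color stain net (C); elements m12, m22, m23, m32, m33.  They serve
both as user-facing example data and as fixtures for the derived-parameter
arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fdh import ElementMoments, MomentSet, WashSeries

__all__ = ["DETERGENTS", "load_paper_table", "load_table_frame"]

DETERGENTS = {
    "F": "fabric softener",
    "L": "laundry powder",
    "T": "toilet soap",
    "C": "color stain net",
}
TABLE_ELEMENTS = ("m12", "m22", "m23", "m32", "m33")
N_WASHES = 6


def _table_path(detergent: str):
    if detergent not in DETERGENTS:
        raise KeyError(
            f"unknown detergent {detergent!r}; expected one of {sorted(DETERGENTS)}"
        )
    return resources.files("silkpol.data").joinpath(f"table_{detergent}.csv")


def load_table_frame(detergent: str) -> pd.DataFrame:
    """Raw table as a DataFrame indexed by the printed row label."""
    path = _table_path(detergent)
    if not path.is_file():
        raise FileNotFoundError(
            f"packaged table for {detergent!r} missing; broken installation"
        )
    return pd.read_csv(path, index_col="row")


def load_paper_table(detergent: str) -> WashSeries:
    """WashSeries (P1/P2 moments, wash counts 0..6) for one detergent."""
    frame = load_table_frame(detergent)
    momsets = []
    for wash in range(N_WASHES + 1):
        p1 = frame.loc[f"{detergent}/P1_{wash}"]
        p2 = frame.loc[f"{detergent}/P2_{wash}"]
        momsets.append(
            MomentSet(
                moments={
                    el: ElementMoments(p1=float(p1[el]), p2=float(p2[el]))
                    for el in TABLE_ELEMENTS
                }
            )
        )
    return WashSeries(detergent_label=DETERGENTS[detergent], moments=momsets)
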