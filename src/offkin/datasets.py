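"""Packaged kinome-panel fixtures and their loaders.

Two competitive-binding panels ship with the package, one per BRAF
inhibitor (PLX4720 and vemurafenib), each covering the same 38 kinases —
MAP3K/MAP4K/STE-family kinases upstream of JNK plus previously profiled
off-targets — at the standard four-concentration series (50, 200, 1000,
10000 nM).  Alongside the percent-of-control readings each row carries the
vendor-reported averaged pointwise estimate (where one was reported) and,
where available, an independently published biochemical IC50 for
cross-validation of the binding readout.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .binding import (
    DEFAULT_SERIES_NM,
    ConcentrationSeries,
    PercentControlProfile,
    parse_panel_table,
)

__all__ = ["panel_path", "load_panel", "load_panel_profiles", "PANEL_DRUGS"]

PANEL_DRUGS = ("PLX4720", "vemurafenib")

_FILES = {
    "PLX4720": "plx4720_panel.tsv",
    "vemurafenib": "vemurafenib_panel.tsv",
}


def panel_path(drug: str) -> Path:
    """Filesystem path of the packaged panel TSV for ``drug``."""
    try:
        fname = _FILES[drug]
    except KeyError:
        raise ValueError(
            f"no packaged panel for {drug!r}; available: {sorted(_FILES)}"
        ) from None
    with resources.as_file(resources.files("offkin.data") / fname) as p:
        return Path(p)


def load_panel(drug: str) -> pd.DataFrame:
    """Raw panel table as a DataFrame (reported estimates kept as strings,
    so the censor token ``">10000"`` survives)."""
    return pd.read_csv(panel_path(drug), sep="\t", comment="#", dtype=str)


def load_panel_profiles(
    drug: str,
) -> tuple[ConcentrationSeries, list[PercentControlProfile]]:
    """Validated percent-of-control profiles plus their concentration series."""
    series = ConcentrationSeries(DEFAULT_SERIES_NM)
    return series, parse_panel_table(panel_path(drug), drug=drug)
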