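"""Binding-constant estimation from kinome-panel percent-of-control profiles.

A competitive binding panel reports, for each kinase, the percent of kinase
remaining bound to an immobilized probe in the presence of drug relative to
vehicle ("percent of control", PC): PC = 100 means the drug displaces
nothing, PC = 0 means complete displacement.  Under single-site competitive
binding with unit Hill slope,

    PC(c) = 100 / (1 + c / Kd),

which rearranges to one Kd estimate per tested concentration c:

    Kd = c * PC / (100 - PC).

The panel-level estimate is the arithmetic mean of the pointwise estimates
over the concentration series, after excluding points with PC >= 100 (no
displacement carries no information and the transform is undefined there).
A profile whose every point is at or above 100 is censored: the affinity is
reported only as exceeding the highest tested concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "EXCLUSION_THRESHOLD",
    "ConcentrationSeries",
    "PercentControlProfile",
    "AffinityEstimate",
    "SelectivityRecord",
    "PanelFormat",
    "PanelParseError",
    "pointwise_kd",
    "estimate_kd",
    "classify_affinity",
    "selectivity_table",
    "parse_panel_table",
    "round_half_up",
]

#: Percent-of-control at or above which a point is excluded from averaging.
EXCLUSION_THRESHOLD = 100.0

#: Default concentration series of the packaged panels, nM.
DEFAULT_SERIES_NM = (50.0, 200.0, 1000.0, 10000.0)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching table formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConcentrationSeries:
    """Strictly increasing positive drug concentrations, nM."""

    values: tuple[float, ...]

    def __init__(self, values: Iterable[float] = DEFAULT_SERIES_NM) -> None:
        vals = tuple(float(v) for v in values)
        if not vals:
            raise ValueError("concentration series must be non-empty")
        if any(v <= 0 for v in vals):
            raise ValueError("concentrations must be positive")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    @property
    def top_nM(self) -> float:
        return self.values[-1]


@dataclass(frozen=True)
class PercentControlProfile:
    """One kinase's percent-of-control readings for one drug.

    ``pc`` holds one reading per concentration of the series the profile
    was measured against, on the 0-100 scale.  Values above 100 occur as
    assay noise; they are accepted here and excluded during estimation.
    """

    kinase_name: str
    gene_symbol: str
    drug: str
    pc: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pc", tuple(float(p) for p in self.pc))
        if not self.pc:
            raise ValueError(f"{self.kinase_name}: empty percent-control profile")
        if any(p < 0 for p in self.pc):
            raise ValueError(f"{self.kinase_name}: negative percent-of-control value")

    @property
    def flagged_points(self) -> tuple[int, ...]:
        """Indices of readings above 100 (assay noise, excluded downstream)."""
        return tuple(i for i, p in enumerate(self.pc) if p > 100.0)


@dataclass(frozen=True)
class AffinityEstimate:
    """Averaged pointwise binding-constant estimate for one kinase.

    ``kd_nM`` is the full-precision arithmetic mean of the included
    pointwise estimates; it is ``None`` when every point was excluded, in
    which case the estimate is censored at ``censor_bound_nM`` (the top
    tested concentration).  ``pointwise_nM`` keeps one entry per
    concentration, ``None`` where the point was excluded.
    """

    kinase_name: str
    gene_symbol: str
    drug: str
    kd_nM: float | None
    pointwise_nM: tuple[float | None, ...]
    n_used: int
    censored: bool
    censor_bound_nM: float | None = None

    def __post_init__(self) -> None:
        present = sum(1 for v in self.pointwise_nM if v is not None)
        if present != self.n_used:
            raise ValueError("n_used inconsistent with pointwise entries")
        if self.censored != (self.n_used == 0):
            raise ValueError("censored flag inconsistent with n_used")
        if (self.kd_nM is None) != self.censored:
            raise ValueError("kd_nM must be present exactly when uncensored")

    @property
    def kd_rounded(self) -> float | None:
        """Kd rounded half-up to 2 decimals, as reported in panel tables."""
        return None if self.kd_nM is None else round_half_up(self.kd_nM, 2)

    def render(self) -> str:
        """Table-style rendering: '9.47', '14,179.29' or '>10,000'."""
        if self.censored:
            return f">{self.censor_bound_nM:,.0f}"
        return f"{self.kd_rounded:,.2f}"


@dataclass(frozen=True)
class SelectivityRecord:
    kinase_name: str
    kd_nM: float | None
    reference_kd_nM: float
    ratio: float | None
    category: str


def pointwise_kd(conc_nM: float, pc: float) -> float | None:
    """Single-concentration Kd estimate ``c * PC / (100 - PC)``, nM.

    Returns ``None`` (point excluded) for PC at or above 100, where no
    displacement was measured.  PC = 0 (complete displacement) gives 0.

    Parameters
    ----------
    conc_nM : drug concentration, nM, > 0.
    pc : percent of control on the 0-100 scale (values above 100 tolerated).
    """
    if conc_nM <= 0:
        raise ValueError(f"concentration must be positive, got {conc_nM}")
    if pc < 0:
        raise ValueError(f"percent-of-control must be non-negative, got {pc}")
    if pc >= EXCLUSION_THRESHOLD:
        return None
    return conc_nM * pc / (100.0 - pc)


def estimate_kd(
    profile: PercentControlProfile,
    series: ConcentrationSeries | Sequence[float] = DEFAULT_SERIES_NM,
) -> AffinityEstimate:
    """Averaged pointwise transformed-Hill binding-constant estimate.

    Computes ``Kd_i = c_i * PC_i / (100 - PC_i)`` at each concentration,
    drops points with PC >= 100, and averages the rest (arithmetic mean,
    PC = 0 contributing 0).  When every point is dropped the estimate is
    censored at the top concentration of the series.
    """
    if not isinstance(series, ConcentrationSeries):
        series = ConcentrationSeries(series)
    if len(profile.pc) != len(series):
        raise ValueError(
            f"{profile.kinase_name}: profile has {len(profile.pc)} readings "
            f"but the series has {len(series)} concentrations"
        )
    pointwise = tuple(pointwise_kd(c, p) for c, p in zip(series, profile.pc))
    used = [v for v in pointwise if v is not None]
    if not used:
        return AffinityEstimate(
            kinase_name=profile.kinase_name,
            gene_symbol=profile.gene_symbol,
            drug=profile.drug,
            kd_nM=None,
            pointwise_nM=pointwise,
            n_used=0,
            censored=True,
            censor_bound_nM=series.top_nM,
        )
    return AffinityEstimate(
        kinase_name=profile.kinase_name,
        gene_symbol=profile.gene_symbol,
        drug=profile.drug,
        kd_nM=math.fsum(used) / len(used),
        pointwise_nM=pointwise,
        n_used=len(used),
        censored=False,
    )


def classify_affinity(
    estimate: AffinityEstimate,
    threshold_nM: float = 50.0,
    intermediate_cut_nM: float = 1000.0,
) -> str:
    """Affinity category for an estimate.

    ``high_affinity`` for Kd strictly below ``threshold_nM`` (the cut used
    to call a kinase "very tightly bound"), ``above_range`` when censored,
    and ``intermediate`` / ``weak`` on either side of
    ``intermediate_cut_nM`` otherwise.
    """
    if threshold_nM <= 0 or intermediate_cut_nM <= 0:
        raise ValueError("classification thresholds must be positive")
    if threshold_nM >= intermediate_cut_nM:
        raise ValueError("high-affinity cut must lie below the intermediate cut")
    if estimate.censored:
        return "above_range"
    kd = estimate.kd_nM
    if kd < threshold_nM:
        return "high_affinity"
    if kd < intermediate_cut_nM:
        return "intermediate"
    return "weak"


def selectivity_table(
    panel: Sequence[AffinityEstimate],
    reference: str,
    threshold_nM: float = 50.0,
    intermediate_cut_nM: float = 1000.0,
) -> list[SelectivityRecord]:
    """Rank a panel by affinity relative to a reference kinase.

    Returns one record per uncensored kinase with ``ratio = Kd / Kd_ref``
    (ratio < 1 means tighter binding than the intended target), sorted
    ascending by Kd; censored kinases follow with category ``above_range``.
    """
    ref = next((e for e in panel if e.kinase_name == reference), None)
    if ref is None:
        raise ValueError(f"reference kinase {reference!r} not in panel")
    if ref.censored:
        raise ValueError(f"reference kinase {reference!r} has a censored estimate")
    records = []
    for est in sorted(
        (e for e in panel if not e.censored), key=lambda e: e.kd_nM
    ):
        records.append(
            SelectivityRecord(
                kinase_name=est.kinase_name,
                kd_nM=est.kd_nM,
                reference_kd_nM=ref.kd_nM,
                ratio=est.kd_nM / ref.kd_nM,
                category=classify_affinity(est, threshold_nM, intermediate_cut_nM),
            )
        )
    for est in (e for e in panel if e.censored):
        records.append(
            SelectivityRecord(
                kinase_name=est.kinase_name,
                kd_nM=None,
                reference_kd_nM=ref.kd_nM,
                ratio=None,
                category="above_range",
            )
        )
    return records


class PanelParseError(ValueError):
    """Malformed panel table: names the offending row and column."""


@dataclass(frozen=True)
class PanelFormat:
    """Column layout of a percent-of-control panel table.

    ``pc_columns`` maps header names to the concentrations (nM) they were
    measured at, in the order of the concentration series.
    """

    kinase_column: str = "kinase_name"
    gene_column: str = "gene_symbol"
    pc_columns: tuple[tuple[str, float], ...] = field(
        default_factory=lambda: tuple(
            (f"pc_{int(c)}", c) for c in DEFAULT_SERIES_NM
        )
    )
    sep: str = "\t"
    comment: str = "#"

    @property
    def series(self) -> ConcentrationSeries:
        return ConcentrationSeries(c for _, c in self.pc_columns)


def parse_panel_table(
    path: str | Path,
    drug: str,
    fmt: PanelFormat | None = None,
) -> list[PercentControlProfile]:
    """Read a TSV/CSV percent-of-control panel into validated profiles.

    Rows with missing or non-numeric percent-control cells are rejected
    with a :class:`PanelParseError` naming the row and column.
    """
    fmt = fmt or PanelFormat()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=fmt.sep, comment=fmt.comment, dtype=str)
    needed = [fmt.kinase_column, fmt.gene_column] + [c for c, _ in fmt.pc_columns]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise PanelParseError(f"{path.name}: missing columns {missing}")
    profiles: list[PercentControlProfile] = []
    for idx, row in df.iterrows():
        pcs = []
        for col, _ in fmt.pc_columns:
            cell = row[col]
            if pd.isna(cell) or str(cell).strip() == "":
                raise PanelParseError(
                    f"{path.name} row {idx + 1} ({row[fmt.kinase_column]}): "
                    f"missing value in column {col!r}"
                )
            try:
                pcs.append(float(cell))
            except ValueError:
                raise PanelParseError(
                    f"{path.name} row {idx + 1} ({row[fmt.kinase_column]}): "
                    f"non-numeric value {cell!r} in column {col!r}"
                ) from None
        profiles.append(
            PercentControlProfile(
                kinase_name=str(row[fmt.kinase_column]),
                gene_symbol=str(row[fmt.gene_column]),
                drug=drug,
                pc=tuple(pcs),
            )
        )
    return profiles
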