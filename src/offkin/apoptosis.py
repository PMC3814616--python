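"""Apoptosis quantification from two-channel cytometry events and histology counts.

Events carry an Annexin V intensity (surface phosphatidylserine exposure)
and a TMRE intensity (mitochondrial membrane potential).  Apoptotic cells
are Annexin V-positive and TMRE-low — the upper-left quadrant of the
standard two-channel plot.  Gating partitions each sample's events into
the four quadrants; downstream statistics (apoptotic fraction, suppression
percentage relative to a reference condition, fold change) and the
histology-count normalizations operate on the gated counts.

Gate thresholds can be given explicitly or placed automatically at the
valley between the two components of a Gaussian mixture fitted to each
log-transformed channel, mimicking manual valley gating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "QuadrantGate",
    "SuppressionResult",
    "TestResult",
    "DensityRecord",
    "UndefinedSuppressionError",
    "auto_gate",
    "apply_quadrant_gate",
    "apoptotic_fraction",
    "suppression_percent",
    "fold_change_apoptosis",
    "density_normalize",
    "two_sample_test",
]

QUADRANTS = (
    "annexin_pos_tmre_low",   # apoptotic (upper left)
    "annexin_pos_tmre_high",
    "annexin_neg_tmre_low",
    "annexin_neg_tmre_high",  # viable
)
APOPTOTIC_QUADRANT = "annexin_pos_tmre_low"


class UndefinedSuppressionError(ValueError):
    """Raised when the stimulus produced no excess apoptosis to suppress."""


@dataclass(frozen=True)
class QuadrantGate:
    """Intensity thresholds splitting the two channels into quadrants."""

    annexin_threshold: float
    tmre_threshold: float

    def __post_init__(self) -> None:
        if self.annexin_threshold <= 0 or self.tmre_threshold <= 0:
            raise ValueError("gate thresholds must be positive")


@dataclass(frozen=True)
class SuppressionResult:
    suppression_pct: float          # clamped to [0, 100] for reporting
    raw_pct: float                  # unclamped; negative = enhancement
    formula: str                    # "subtracted" or "raw"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    significant: bool
    degenerate: bool = False
    note: str = ""


@dataclass(frozen=True)
class DensityRecord:
    marker: str
    count: int
    normalizer: float
    unit: str                       # "mm2" or "mm"

    def __post_init__(self) -> None:
        if self.normalizer <= 0:
            raise ValueError("normalizer (area or length) must be positive")
        if self.count < 0:
            raise ValueError("count must be non-negative")

    @property
    def density(self) -> float:
        return self.count / self.normalizer


def _valley_threshold(values: np.ndarray, floor: float, seed: int) -> float:
    """Threshold at the mixture-density minimum between two fitted
    log-normal components of one channel."""
    logv = np.log10(np.clip(values, floor, None)).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(logv)
    m = np.sort(gm.means_.ravel())
    if m[1] - m[0] < 1e-6:
        return float(10.0 ** m[0])
    grid = np.linspace(m[0], m[1], 512).reshape(-1, 1)
    dens = gm.score_samples(grid)
    return float(10.0 ** grid[np.argmin(dens), 0])


def auto_gate(
    events: pd.DataFrame, floor: float = 1.0, seed: int = 0
) -> QuadrantGate:
    """Place quadrant thresholds at the valley of each channel's bimodal
    log-intensity distribution (pooled over all events)."""
    return QuadrantGate(
        annexin_threshold=_valley_threshold(
            events["annexin"].to_numpy(float), floor, seed
        ),
        tmre_threshold=_valley_threshold(
            events["tmre"].to_numpy(float), floor, seed
        ),
    )


def apply_quadrant_gate(
    events: pd.DataFrame,
    gate: QuadrantGate,
    exclude_viability_positive: bool = True,
    viability_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-sample quadrant counts for an event table.

    ``events`` needs columns ``sample_id``, ``annexin``, ``tmre`` and may
    carry a ``viability`` dead-cell channel; when present (and
    ``exclude_viability_positive``), events at or above
    ``viability_threshold`` (default: the gate's annexin threshold) are
    dropped before gating.  Counts over the four quadrants sum to the
    per-sample event total.  A sample with zero events is an error.
    """
    required = {"sample_id", "annexin", "tmre"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    if (events[["annexin", "tmre"]].to_numpy(float) < 0).any():
        raise ValueError("intensities must be non-negative")

    df = events
    if exclude_viability_positive and "viability" in df.columns:
        cut = viability_threshold if viability_threshold is not None else gate.annexin_threshold
        df = df[df["viability"].astype(float) < cut]

    rows = []
    for sample, g in df.groupby("sample_id", sort=True):
        n = len(g)
        if n == 0:
            raise ValueError(f"sample {sample!r} has zero events after exclusion")
        a_pos = g["annexin"].to_numpy(float) >= gate.annexin_threshold
        t_low = g["tmre"].to_numpy(float) < gate.tmre_threshold
        rows.append(
            {
                "sample_id": sample,
                "annexin_pos_tmre_low": int(np.sum(a_pos & t_low)),
                "annexin_pos_tmre_high": int(np.sum(a_pos & ~t_low)),
                "annexin_neg_tmre_low": int(np.sum(~a_pos & t_low)),
                "annexin_neg_tmre_high": int(np.sum(~a_pos & ~t_low)),
                "total": n,
            }
        )
    empty = set(events["sample_id"].unique()) - {r["sample_id"] for r in rows}
    if empty:
        raise ValueError(f"samples with zero events after exclusion: {sorted(empty)}")
    if not rows:
        raise ValueError("event table is empty")
    return pd.DataFrame(rows).set_index("sample_id")


def apoptotic_fraction(counts: pd.Series | pd.DataFrame | dict) -> float | pd.Series:
    """Apoptotic-quadrant share of total events, in [0, 1].

    Accepts one row of quadrant counts (Series/dict) or the whole per-sample
    frame, in which case a Series of fractions is returned.
    """
    if isinstance(counts, pd.DataFrame):
        if (counts["total"] == 0).any():
            raise ValueError("zero total events")
        return counts[APOPTOTIC_QUADRANT] / counts["total"]
    total = counts["total"]
    if total == 0:
        raise ValueError("zero total events")
    return counts[APOPTOTIC_QUADRANT] / total


def suppression_percent(
    f_ctrl_stim: float,
    f_drug_stim: float,
    f_ctrl_base: float = 0.0,
    f_drug_base: float = 0.0,
    formula: str = "subtracted",
    clamp: bool = True,
) -> SuppressionResult:
    """Percent suppression of stimulus-induced apoptosis by a treatment.

    The default baseline-subtracted form compares the stimulus-induced
    excess over each arm's own unstimulated baseline:

        100 * (1 - (f_drug_stim - f_drug_base) / (f_ctrl_stim - f_ctrl_base))

    The ``"raw"`` form ignores baselines: ``100 * (1 - f_drug_stim /
    f_ctrl_stim)``.  The reference ("ctrl") condition is whichever arm the
    comparison is anchored to — vehicle, or a drug-treated control line
    when the contrast is between genotypes under drug.  With zero
    baselines the two formulas coincide.  Reported values are clamped to
    [0, 100]; the unclamped value (negative = enhancement of apoptosis)
    is retained in ``raw_pct``.
    """
    if formula not in ("subtracted", "raw"):
        raise ValueError(f"unknown suppression formula {formula!r}")
    for name, f in (
        ("f_ctrl_stim", f_ctrl_stim),
        ("f_drug_stim", f_drug_stim),
        ("f_ctrl_base", f_ctrl_base),
        ("f_drug_base", f_drug_base),
    ):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be a fraction in [0, 1], got {f}")
    if formula == "raw":
        if f_ctrl_stim <= 0:
            raise UndefinedSuppressionError("reference apoptotic fraction is zero")
        raw = 100.0 * (1.0 - f_drug_stim / f_ctrl_stim)
    else:
        denom = f_ctrl_stim - f_ctrl_base
        if denom <= 0:
            raise UndefinedSuppressionError(
                "no stimulus effect in the reference arm: "
                f"f_ctrl_stim={f_ctrl_stim} <= f_ctrl_base={f_ctrl_base}"
            )
        raw = 100.0 * (1.0 - (f_drug_stim - f_drug_base) / denom)
    value = min(100.0, max(0.0, raw)) if clamp else raw
    return SuppressionResult(suppression_pct=value, raw_pct=raw, formula=formula)


def fold_change_apoptosis(
    f_a: float,
    f_b: float,
    baseline_a: float = 0.0,
    baseline_b: float = 0.0,
    subtract_baseline: bool = False,
) -> float:
    """Fold change in apoptotic fraction, ``f_a / f_b``, optionally on
    baseline-subtracted fractions."""
    if subtract_baseline:
        f_a, f_b = f_a - baseline_a, f_b - baseline_b
    if f_b <= 0:
        raise ValueError("denominator fraction must be positive")
    return f_a / f_b


def density_normalize(count: int, normalizer: float, unit: str = "mm2",
                      marker: str = "") -> DensityRecord:
    """Positive-cell count per unit tumor area (per mm2) or epidermal
    length (per mm)."""
    if unit not in ("mm2", "mm"):
        raise ValueError(f"unit must be 'mm2' or 'mm', got {unit!r}")
    return DensityRecord(marker=marker, count=count, normalizer=normalizer, unit=unit)


def two_sample_test(
    values_a,
    values_b,
    paired: bool = False,
    alpha: float = 0.05,
) -> TestResult:
    """Two-sided Student's t-test between two groups (paired on request).

    Degenerate inputs are resolved explicitly rather than returning NaN:
    identical groups give statistic 0 and p = 1; a paired comparison with
    a constant non-zero difference (zero within-pair variance) is flagged
    and reported as p = 0 in the limit.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        d = a - b
        if np.ptp(d) == 0:
            if d[0] == 0:
                return TestResult(0.0, 1.0, False, degenerate=True,
                                  note="identical pairs")
            return TestResult(
                float("inf") if d[0] > 0 else float("-inf"),
                0.0, True, degenerate=True,
                note="constant non-zero paired difference; p -> 0 limit",
            )
        stat, p = stats.ttest_rel(a, b)
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                return TestResult(0.0, 1.0, False, degenerate=True,
                                  note="identical constant groups")
            return TestResult(
                float("inf") if a[0] > b[0] else float("-inf"),
                0.0, True, degenerate=True,
                note="zero variance, unequal means; p -> 0 limit",
            )
        stat, p = stats.ttest_ind(a, b)
    return TestResult(float(stat), float(p), bool(p <= alpha))
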