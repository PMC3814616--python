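"""Decomposition of drug-induced colony-formation advantage.

BRAF inhibitors accelerate anchorage-independent growth of BRAF-wild-type
cells through two separable mechanisms: CRAF-dependent paradoxical ERK
activation, and off-target inhibition of the JNK stress pathway.  Two
experimental contrasts isolate them:

* WT vs Craf-null cells under drug — paradoxical ERK activation requires
  intact CRAF, so the drop in drug-induced advantage in Craf-null cells
  measures the ERK share of the total effect.
* Untreated JNK-pathway triple-knockdown (TKD) vs scrambled-control (SCR)
  cells — the advantage conferred by genetic JNK-pathway loss without any
  drug measures the JNK-inhibition share.

Effects are measured as the excess advantage ``delta = fold - 1`` where
``fold`` is the ratio of mean colony counts (drug/control, or TKD/SCR);
a fold of 1 is zero effect, which makes shares of a total well defined.
Because each contrast bounds its share only from one side, the two shares
combine into complementary ranges: the JNK share lies in
``[jnk, 100 - erk]`` percent and the ERK share in ``[erk, 100 - jnk]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AdvantageEstimate",
    "ShareEstimate",
    "PartitionResult",
    "growth_advantage",
    "partition_craf",
    "partition_jnk",
    "combine_partitions",
    "bootstrap_share",
    "read_colony_counts",
]


@dataclass(frozen=True)
class AdvantageEstimate:
    """Drug-induced colony-formation advantage for one genotype and dose."""

    genotype: str
    dose_uM: float
    fold_change: float
    delta: float                    # fold_change - 1: excess advantage
    se_fold: float | None
    n_control: int
    n_drug: int

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


@dataclass(frozen=True)
class ShareEstimate:
    share_pct: float                # clamped to [0, 100]
    raw_pct: float                  # unclamped diagnostic value
    method: str
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class PartitionResult:
    erk_share_pct: float
    jnk_share_pct: float
    other_share_pct: float
    erk_range: tuple[float, float]
    jnk_range: tuple[float, float]
    consistent: bool
    method: str


def _require_counts(counts, name: str) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.size < 2:
        raise ValueError(f"{name}: at least 2 replicates required")
    if np.any(arr < 0):
        raise ValueError(f"{name}: colony counts must be non-negative")
    return arr


def growth_advantage(
    control_counts,
    drug_counts,
    genotype: str = "",
    dose_uM: float = float("nan"),
    n_boot: int = 2000,
    seed: int | None = None,
) -> AdvantageEstimate:
    """Fold change of mean colony count under drug over control.

    ``se_fold`` is a nonparametric bootstrap standard error over
    replicates (``n_boot`` resamples, seeded; 0 skips it).
    """
    ctrl = _require_counts(control_counts, "control")
    drug = _require_counts(drug_counts, "drug")
    if ctrl.mean() <= 0:
        raise ValueError("control mean colony count must be positive")
    fold = drug.mean() / ctrl.mean()
    se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        bc = rng.choice(ctrl, size=(n_boot, len(ctrl)), replace=True).mean(axis=1)
        bd = rng.choice(drug, size=(n_boot, len(drug)), replace=True).mean(axis=1)
        ok = bc > 0
        se = float(np.std(bd[ok] / bc[ok], ddof=1))
    return AdvantageEstimate(
        genotype=genotype,
        dose_uM=dose_uM,
        fold_change=float(fold),
        delta=float(fold - 1.0),
        se_fold=se,
        n_control=len(ctrl),
        n_drug=len(drug),
    )


def _clamped_share(raw: float, method: str) -> ShareEstimate:
    return ShareEstimate(
        share_pct=min(100.0, max(0.0, raw)), raw_pct=raw, method=method
    )


def partition_craf(delta_wt: float, delta_ko: float) -> ShareEstimate:
    """CRAF-dependent (paradoxical ERK) share of the total drug effect.

    ``100 * (delta_wt - delta_ko) / delta_wt``: the part of the wild-type
    excess advantage that disappears when CRAF is absent.
    """
    if delta_wt <= 0:
        raise ValueError("total (wild-type) excess advantage must be positive")
    raw = 100.0 * (delta_wt - delta_ko) / delta_wt
    return _clamped_share(raw, "craf_contrast: 100*(delta_WT - delta_KO)/delta_WT")


def partition_jnk(delta_tkd_untreated: float, delta_total: float) -> ShareEstimate:
    """JNK-pathway-inhibition share of the total drug effect.

    ``100 * delta_tkd_untreated / delta_total``, where the numerator is
    the excess advantage of untreated JNK-pathway-knockdown cells over
    untreated controls and the denominator the drug-induced excess
    (by default averaged over the SCR and TKD arms, which reach similar
    totals under drug).
    """
    if delta_total <= 0:
        raise ValueError("total drug-induced excess advantage must be positive")
    if delta_tkd_untreated < 0:
        raise ValueError("knockdown excess advantage must be non-negative")
    raw = 100.0 * delta_tkd_untreated / delta_total
    return _clamped_share(raw, "jnk_contrast: 100*delta_TKD_untreated/delta_total")


def combine_partitions(
    craf: ShareEstimate | float, jnk: ShareEstimate | float
) -> PartitionResult:
    """Merge the two one-sided contrasts into complementary share ranges.

    Each contrast bounds its mechanism's share from below; whatever the
    other contrast does not claim is the upper bound.  Hence JNK in
    ``[jnk, 100 - erk]`` and ERK in ``[erk, 100 - jnk]``; the ranges are
    complementary by construction.  Shares that overlap (jnk > 100 - erk)
    are flagged inconsistent and reported unmodified.
    """
    erk = craf.share_pct if isinstance(craf, ShareEstimate) else float(craf)
    jnk_s = jnk.share_pct if isinstance(jnk, ShareEstimate) else float(jnk)
    for name, s in (("erk", erk), ("jnk", jnk_s)):
        if not 0.0 <= s <= 100.0:
            raise ValueError(f"{name} share must be in [0, 100], got {s}")
    consistent = bool(jnk_s <= 100.0 - erk)
    return PartitionResult(
        erk_share_pct=erk,
        jnk_share_pct=jnk_s,
        other_share_pct=max(0.0, 100.0 - erk - jnk_s),
        erk_range=(erk, 100.0 - jnk_s),
        jnk_range=(jnk_s, 100.0 - erk),
        consistent=consistent,
        method="one-sided contrasts combined into complementary ranges",
    )


def bootstrap_share(
    numerator_groups: tuple,
    denominator_groups: tuple,
    kind: str,
    n_boot: int = 2000,
    seed: int | None = None,
    ci: float = 0.95,
) -> ShareEstimate:
    """Bootstrap a partition share from raw replicate colony counts.

    ``kind="craf"``: ``numerator_groups = (wt_ctrl, wt_drug)``,
    ``denominator_groups = (ko_ctrl, ko_drug)``; the share is
    ``100*(delta_wt - delta_ko)/delta_wt``.

    ``kind="jnk"``: ``numerator_groups = (scr_ctrl, tkd_ctrl)`` giving the
    untreated-knockdown excess, ``denominator_groups = (scr_drug,
    tkd_drug)``; the drug-induced total is averaged over the SCR and TKD
    arms and the share is ``100*delta_tkd_untreated/delta_total``.

    Replicates are resampled within each group; the percentile interval
    at level ``ci`` is attached to the point estimate computed from the
    observed means.
    """
    if kind not in ("craf", "jnk"):
        raise ValueError(f"unknown partition kind {kind!r}")
    groups = [
        _require_counts(g, f"group {i}")
        for i, g in enumerate(tuple(numerator_groups) + tuple(denominator_groups))
    ]
    rng = np.random.default_rng(seed)

    def share_from_means(means: list[float]) -> float:
        if kind == "craf":
            wt_c, wt_d, ko_c, ko_d = means
            delta_wt = wt_d / wt_c - 1.0
            delta_ko = ko_d / ko_c - 1.0
            if delta_wt <= 0:
                return np.nan
            return 100.0 * (delta_wt - delta_ko) / delta_wt
        scr_c, tkd_c, scr_d, tkd_d = means
        delta_kd = tkd_c / scr_c - 1.0
        delta_total = ((scr_d / scr_c - 1.0) + (tkd_d / tkd_c - 1.0)) / 2.0
        if delta_total <= 0:
            return np.nan
        return 100.0 * delta_kd / delta_total

    point = share_from_means([g.mean() for g in groups])
    if np.isnan(point):
        raise ValueError("observed data give no positive total effect")
    draws = np.empty(n_boot)
    for i in range(n_boot):
        draws[i] = share_from_means(
            [rng.choice(g, size=len(g), replace=True).mean() for g in groups]
        )
    draws = draws[~np.isnan(draws)]
    lo, hi = np.percentile(draws, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    method = (
        "craf_contrast (bootstrap)" if kind == "craf" else "jnk_contrast (bootstrap)"
    )
    return ShareEstimate(
        share_pct=min(100.0, max(0.0, point)),
        raw_pct=float(point),
        method=method,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def read_colony_counts(path) -> pd.DataFrame:
    """Read a colony-count CSV with columns genotype, treatment, dose_uM,
    replicate, colony_count."""
    df = pd.read_csv(path, comment="#")
    needed = {"genotype", "treatment", "dose_uM", "replicate", "colony_count"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"colony table missing columns {sorted(missing)}")
    if (df["colony_count"] < 0).any():
        raise ValueError("colony counts must be non-negative")
    return df
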