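"""Hill-type dose-response fitting for in-vitro kinase activity assays.

Activity is modelled with the four-parameter logistic (Hill) curve

    A(c) = bottom + (top - bottom) / (1 + (c / IC50)^h),

fit by least squares in log10-concentration space.  The default
constraints — bottom fixed at 0, top fixed at 100, slope free in
[0.3, 4] — reflect activity expressed as percent of the uninhibited
control.  Uncertainty on the IC50 comes from a nonparametric bootstrap
over replicates within each concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseDataset",
    "HillFit",
    "ResidualActivity",
    "ConcordanceRecord",
    "hill_activity",
    "fit_hill",
    "residual_activity_at",
    "compare_binding_vs_activity",
    "read_dose_response",
]


def hill_activity(
    conc_nM: float | np.ndarray,
    ic50_nM: float,
    slope: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
) -> float | np.ndarray:
    """Four-parameter logistic activity at ``conc_nM``, percent.

    ``conc = 0`` returns ``top`` (the uninhibited limit) for any positive
    slope.
    """
    if ic50_nM <= 0:
        raise ValueError(f"ic50 must be positive, got {ic50_nM}")
    c = np.asarray(conc_nM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    with np.errstate(divide="ignore"):
        out = bottom + (top - bottom) / (1.0 + (c / ic50_nM) ** slope)
    out = np.where(c == 0, top, out)
    return float(out) if np.isscalar(conc_nM) or out.ndim == 0 else out


@dataclass(frozen=True)
class DoseResponseDataset:
    """Long-form activity data: one row per (concentration, replicate)."""

    kinase_name: str
    drug: str
    conc_nM: np.ndarray
    activity_pct: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.conc_nM, dtype=float)
        a = np.asarray(self.activity_pct, dtype=float)
        r = np.asarray(self.replicate)
        if not (len(c) == len(a) == len(r)):
            raise ValueError("conc, activity and replicate must align")
        if np.any(c < 0) or np.any(a < 0):
            raise ValueError("concentrations and activities must be non-negative")
        if len(np.unique(c)) < 4:
            raise ValueError("at least 4 distinct concentrations required")
        object.__setattr__(self, "conc_nM", c)
        object.__setattr__(self, "activity_pct", a)
        object.__setattr__(self, "replicate", r)

    @property
    def concentrations(self) -> np.ndarray:
        return np.unique(self.conc_nM)


@dataclass(frozen=True)
class HillFit:
    kinase_name: str
    drug: str
    ic50_nM: float
    hill_slope: float
    top: float
    bottom: float
    se_ic50_nM: float | None
    converged: bool
    n_boot: int
    rss: float
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and self.ic50_nM <= 0:
            raise ValueError("fitted ic50 must be positive")
        if self.bottom > self.top:
            raise ValueError("bottom must not exceed top")


@dataclass(frozen=True)
class ResidualActivity:
    conc_nM: float
    activity_pct: float


@dataclass(frozen=True)
class ConcordanceRecord:
    kd_nM: float
    ic50_nM: float
    fold: float
    log10_fold: float
    concordant: bool


def _fit_once(
    logc: np.ndarray,
    act: np.ndarray,
    fix_top: float | None,
    fix_bottom: float | None,
    slope_bounds: tuple[float, float],
) -> tuple[dict, bool, float, str]:
    amax, amin = float(act.max()), float(act.min())
    if amax - amin < 1e-9:
        return {}, False, float("nan"), "no variation in activity; curve unidentifiable"

    top0 = fix_top if fix_top is not None else amax
    bot0 = fix_bottom if fix_bottom is not None else amin
    # initial log-IC50 from the concentration nearest half-maximal activity
    half = (top0 + bot0) / 2.0
    log_ic50_0 = float(logc[np.argmin(np.abs(act - half))])

    free_names: list[str] = ["log_ic50", "slope"]
    x0 = [log_ic50_0, 1.0]
    lo = [logc.min() - 3.0, slope_bounds[0]]
    hi = [logc.max() + 3.0, slope_bounds[1]]
    if fix_top is None:
        free_names.append("top")
        x0.append(amax)
        lo.append(amin)
        hi.append(amax * 1.5 + 1.0)
    if fix_bottom is None:
        free_names.append("bottom")
        x0.append(amin)
        lo.append(0.0)
        hi.append(amax)

    def unpack(x: np.ndarray) -> tuple[float, float, float, float]:
        d = dict(zip(free_names, x))
        return (
            d["log_ic50"],
            d["slope"],
            d.get("top", fix_top),
            d.get("bottom", fix_bottom),
        )

    def resid(x: np.ndarray) -> np.ndarray:
        log_ic50, slope, top, bottom = unpack(x)
        pred = bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logc - log_ic50)))
        return pred - act

    sol = least_squares(
        resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-8, max_nfev=10_000
    )
    log_ic50, slope, top, bottom = unpack(sol.x)
    rss = float(np.sum(sol.fun**2))
    params = {
        "ic50": 10.0**log_ic50,
        "slope": slope,
        "top": float(top),
        "bottom": float(bottom),
    }
    ok = sol.success and bottom <= top
    return params, ok, rss, sol.message


def fit_hill(
    data: DoseResponseDataset,
    fix_top: float | None = 100.0,
    fix_bottom: float | None = 0.0,
    slope_bounds: tuple[float, float] = (0.3, 4.0),
    n_boot: int = 500,
    seed: int | None = None,
) -> HillFit:
    """Least-squares Hill fit with bootstrap standard error on the IC50.

    Concentration 0 rows (untreated wells) are mapped to the model's upper
    limit by assigning them a pseudo-log-concentration three decades below
    the lowest treated dose.  The bootstrap resamples replicate activities
    within each concentration (``n_boot`` resamples, seeded); set
    ``n_boot=0`` to skip it.  A dataset with no activity variation is
    reported as unconverged rather than fit silently.
    """
    conc = data.conc_nM
    act = data.activity_pct
    pos = conc[conc > 0]
    floor = (pos.min() / 1000.0) if len(pos) else 1e-3
    logc = np.log10(np.where(conc > 0, conc, floor))

    params, ok, rss, msg = _fit_once(logc, act, fix_top, fix_bottom, slope_bounds)
    if not ok:
        return HillFit(
            kinase_name=data.kinase_name,
            drug=data.drug,
            ic50_nM=float("nan"),
            hill_slope=float("nan"),
            top=fix_top if fix_top is not None else float("nan"),
            bottom=fix_bottom if fix_bottom is not None else 0.0,
            se_ic50_nM=None,
            converged=False,
            n_boot=0,
            rss=rss,
            message=msg,
        )

    se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        groups = [np.flatnonzero(conc == c) for c in np.unique(conc)]
        boots = []
        for _ in range(n_boot):
            idx = np.concatenate(
                [rng.choice(g, size=len(g), replace=True) for g in groups]
            )
            p, bok, _, _ = _fit_once(
                logc[idx], act[idx], fix_top, fix_bottom, slope_bounds
            )
            if bok:
                boots.append(p["ic50"])
        if len(boots) >= 2:
            se = float(np.std(boots, ddof=1))

    return HillFit(
        kinase_name=data.kinase_name,
        drug=data.drug,
        ic50_nM=params["ic50"],
        hill_slope=params["slope"],
        top=params["top"],
        bottom=params["bottom"],
        se_ic50_nM=se,
        converged=True,
        n_boot=n_boot if se is not None else 0,
        rss=rss,
    )


def residual_activity_at(
    fit_or_ic50: HillFit | float,
    conc_nM: float,
    slope: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
) -> ResidualActivity:
    """Percent of uninhibited activity remaining at ``conc_nM``.

    Accepts either a :class:`HillFit` (its own parameters are used) or a
    bare IC50 in nM, in which case a unit Hill slope between 0 and 100%
    is assumed unless overridden.
    """
    if conc_nM < 0:
        raise ValueError("concentration must be non-negative")
    if isinstance(fit_or_ic50, HillFit):
        f = fit_or_ic50
        if not f.converged:
            raise ValueError("cannot predict from an unconverged fit")
        act = hill_activity(conc_nM, f.ic50_nM, f.hill_slope, f.top, f.bottom)
    else:
        act = hill_activity(conc_nM, float(fit_or_ic50), slope, top, bottom)
    return ResidualActivity(conc_nM=conc_nM, activity_pct=float(act))


def compare_binding_vs_activity(
    kd_nM: float, ic50_nM: float, fold_window: float = 10.0
) -> ConcordanceRecord:
    """Concordance between a binding-assay Kd and a biochemical IC50.

    The two readouts measure the same interaction through different
    assays; they are called concordant when within ``fold_window``-fold of
    each other (default one order of magnitude).
    """
    if kd_nM <= 0 or ic50_nM <= 0:
        raise ValueError("kd and ic50 must be positive")
    if fold_window < 1:
        raise ValueError("fold window must be >= 1")
    fold = max(kd_nM / ic50_nM, ic50_nM / kd_nM)
    return ConcordanceRecord(
        kd_nM=kd_nM,
        ic50_nM=ic50_nM,
        fold=fold,
        log10_fold=math.log10(fold),
        concordant=fold <= fold_window,
    )


def read_dose_response(path: str | Path) -> list[DoseResponseDataset]:
    """Read long-form TSV/CSV activity data, one dataset per (kinase, drug).

    Expected columns: kinase_name, drug, conc_nM, activity_pct, replicate_id.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    needed = {"kinase_name", "drug", "conc_nM", "activity_pct", "replicate_id"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    out = []
    for (kin, drug), g in df.groupby(["kinase_name", "drug"], sort=True):
        out.append(
            DoseResponseDataset(
                kinase_name=str(kin),
                drug=str(drug),
                conc_nM=g["conc_nM"].to_numpy(float),
                activity_pct=g["activity_pct"].to_numpy(float),
                replicate=g["replicate_id"].to_numpy(),
            )
        )
    return out
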