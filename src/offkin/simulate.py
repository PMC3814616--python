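"""Synthetic assay data with the statistical structure of each pipeline stage.

Each generator is a deterministic function of its parameters and a seed,
and emits exactly the in-memory objects (and, via the CLI, the CSV/TSV
dialects) the corresponding analysis stage consumes:

* percent-of-control profiles from the single-site competitive binding
  model ``PC(c) = 100/(1 + c/Kd)`` with signal-proportional (constant-CV)
  Gaussian noise, truncated to [0, 100] and rounded the way panel tables
  print values;
* Hill-curve activity data over the standard 10-point, 0.05-1000 nM
  triplicate design with Gaussian replicate noise;
* two-channel cytometry event clouds as two log-normal components —
  viable (Annexin-low / TMRE-high) and apoptotic (Annexin-high /
  TMRE-low) — mixed at a planted apoptotic fraction;
* colony counts drawn Poisson (or negative binomial when overdispersed)
  around ``base_rate * multiplier`` per genotype x treatment condition.

These emulate the statistical shape of each assay, not its biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .binding import ConcentrationSeries, DEFAULT_SERIES_NM, PercentControlProfile
from .doseresponse import DoseResponseDataset, hill_activity

__all__ = [
    "SimulationConfig",
    "DEFAULT_DOSE_SERIES_NM",
    "simulate_percent_control",
    "simulate_dose_response",
    "simulate_facs_events",
    "simulate_colony_counts",
]

#: 10-point log-spaced concentration series, 0.05-1000 nM, mirroring the
#: standard in-vitro kinase assay design.
DEFAULT_DOSE_SERIES_NM = tuple(
    float(c) for c in np.geomspace(0.05, 1000.0, 10).round(4)
)

#: Log10-scale component parameters of the two-channel event clouds:
#: (annexin mean, tmre mean, sd) per population.
DEFAULT_VIABLE_COMPONENT = (1.5, 3.0, 0.25)
DEFAULT_APOPTOTIC_COMPONENT = (3.0, 1.5, 0.25)


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of every distribution parameter the generators use."""

    seed: int = 0
    binding_noise_sd: float = 0.0
    activity_noise_sd: float = 3.0
    viable_component: tuple[float, float, float] = DEFAULT_VIABLE_COMPONENT
    apoptotic_component: tuple[float, float, float] = DEFAULT_APOPTOTIC_COMPONENT
    colony_dispersion: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.binding_noise_sd < 0 or self.activity_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.colony_dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw.pop(k) for k in list(raw) if k in cls.__dataclass_fields__}
        for key in ("viable_component", "apoptotic_component"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known, extra=raw) if "extra" not in known else cls(**known)


def _table_round(pc: float) -> float:
    # panel tables print one decimal below 10 percent, integers above
    return round(pc, 1) if pc < 10 else float(round(pc))


def simulate_percent_control(
    true_kd_nM: float,
    series: ConcentrationSeries | tuple = DEFAULT_SERIES_NM,
    noise_sd: float = 0.0,
    seed: int | None = None,
    kinase_name: str = "SYN1",
    drug: str = "synthetic",
    round_to_table: bool = True,
) -> PercentControlProfile:
    """Percent-of-control profile from single-site competitive binding.

    ``PC(c) = 100/(1 + c/Kd)`` with multiplicative Gaussian noise of
    coefficient of variation ``noise_sd`` percent — the readouts of
    amplification-based competition assays scale with signal, which is
    also why real panel tables report (and use) values as small as 0.05.
    Values are truncated to [0, 100] and then rounded to the precision
    panel tables print (integers above 10 percent, one decimal below);
    pass ``round_to_table=False`` to keep full precision.
    """
    if true_kd_nM <= 0:
        raise ValueError("true Kd must be positive")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if not isinstance(series, ConcentrationSeries):
        series = ConcentrationSeries(series)
    rng = np.random.default_rng(seed)
    conc = np.asarray(series.values)
    pc = 100.0 / (1.0 + conc / true_kd_nM)
    if noise_sd > 0:
        pc = pc * (1.0 + rng.normal(0.0, noise_sd / 100.0, size=len(conc)))
    pc = np.clip(pc, 0.0, 100.0)
    return PercentControlProfile(
        kinase_name=kinase_name,
        gene_symbol=kinase_name,
        drug=drug,
        pc=tuple((_table_round(p) if round_to_table else float(p)) for p in pc),
    )


def simulate_dose_response(
    ic50_nM: float,
    slope: float = 1.0,
    series: tuple = DEFAULT_DOSE_SERIES_NM,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
    top: float = 100.0,
    bottom: float = 0.0,
    kinase_name: str = "SYN1",
    drug: str = "synthetic",
) -> DoseResponseDataset:
    """Hill-curve activity data with Gaussian replicate noise (percent
    scale, floored at 0)."""
    if ic50_nM <= 0:
        raise ValueError("ic50 must be positive")
    if replicates < 1:
        raise ValueError("at least one replicate required")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    conc = np.repeat(np.asarray(series, dtype=float), replicates)
    rep = np.tile(np.arange(1, replicates + 1), len(series))
    act = hill_activity(conc, ic50_nM, slope, top, bottom)
    if noise_sd > 0:
        act = act + rng.normal(0.0, noise_sd, size=len(conc))
    act = np.clip(act, 0.0, None)
    return DoseResponseDataset(
        kinase_name=kinase_name,
        drug=drug,
        conc_nM=conc,
        activity_pct=act,
        replicate=rep,
    )


def simulate_facs_events(
    n: int,
    apoptotic_fraction: float,
    viable_component: tuple[float, float, float] = DEFAULT_VIABLE_COMPONENT,
    apoptotic_component: tuple[float, float, float] = DEFAULT_APOPTOTIC_COMPONENT,
    seed: int | None = None,
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Two-channel event cloud with a planted apoptotic mixture fraction.

    Components are log-normal per channel; ``(a_mean, t_mean, sd)`` are
    log10-scale Annexin and TMRE means and the common log10 sd.  The
    number of apoptotic events is drawn binomially, so the realized
    fraction fluctuates around the planted one as in a real acquisition.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= apoptotic_fraction <= 1.0:
        raise ValueError("apoptotic fraction must be in [0, 1]")
    va, vt, vsd = viable_component
    aa, at, asd = apoptotic_component
    if vsd <= 0 and asd <= 0:
        raise ValueError("degenerate components: both sds are zero")
    rng = np.random.default_rng(seed)
    n_apo = int(rng.binomial(n, apoptotic_fraction))
    n_via = n - n_apo
    annexin = np.concatenate(
        [rng.normal(va, vsd, n_via), rng.normal(aa, asd, n_apo)]
    )
    tmre = np.concatenate(
        [rng.normal(vt, vsd, n_via), rng.normal(at, asd, n_apo)]
    )
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "annexin": 10.0**annexin,
            "tmre": 10.0**tmre,
            "apoptotic_truth": np.r_[np.zeros(n_via, bool), np.ones(n_apo, bool)],
        }
    )
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def simulate_colony_counts(
    base_rate: float,
    multipliers: dict[tuple[str, str], float],
    replicates: int = 20,
    dispersion: float = 0.0,
    seed: int | None = None,
    dose_uM: float = 1.0,
) -> pd.DataFrame:
    """Colony-count experiment with planted per-condition effect multipliers.

    ``multipliers`` maps ``(genotype, treatment)`` to the multiple of
    ``base_rate`` for that condition.  Counts are Poisson with mean
    ``base_rate * multiplier``; with ``dispersion`` k > 0 they are
    negative binomial with that mean and variance ``mean + mean**2/k``
    (gamma-Poisson mixture), matching the overdispersion of real
    soft-agar replicates.
    """
    if base_rate <= 0:
        raise ValueError("base rate must be positive")
    if any(m <= 0 for m in multipliers.values()):
        raise ValueError("multipliers must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if replicates < 1:
        raise ValueError("at least one replicate required")
    rng = np.random.default_rng(seed)
    rows = []
    for (genotype, treatment), mult in sorted(multipliers.items()):
        mean = base_rate * mult
        if dispersion > 0:
            lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=replicates)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mean, size=replicates)
        for r, c in enumerate(counts, start=1):
            rows.append(
                {
                    "genotype": genotype,
                    "treatment": treatment,
                    "dose_uM": dose_uM if treatment != "control" else 0.0,
                    "replicate": r,
                    "colony_count": int(c),
                }
            )
    return pd.DataFrame(rows)
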