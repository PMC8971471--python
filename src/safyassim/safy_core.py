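"""Daily light-use-efficiency simulation of wheat LAI, dry aerial mass and yield.

The model runs from an emergence day ``d0`` to the end of leaf senescence,
driven by daily mean temperature and global radiation.  Above-ground dry
mass (DAM, g m^-2) grows with absorbed photosynthetically active radiation
modulated by a temperature stress function; a declining fraction of each
daily increment is allocated to leaves (LAI growth); once accumulated
thermal time passes a senescence threshold the canopy decays at a fixed
rate.  Grain yield is a harvest-index fraction of peak biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SafyParams",
    "WeatherSeries",
    "SafyState",
    "SafyTrajectory",
    "temperature_stress",
    "compute_apar",
    "partition_fraction",
    "daily_step",
    "simulate",
    "grain_yield",
    "MAX_SEASON_DAYS",
    "SENESCENCE_END_LAI",
]

#: hard cap on simulated days after emergence (guards non-terminating runs)
MAX_SEASON_DAYS = 300

#: LAI below which senescence (and hence the simulation) ends
SENESCENCE_END_LAI = 0.1

# Shipped default bounds for the optimizable parameters.
PLA_BOUNDS = (0.01, 0.3)
PLB_BOUNDS = (1e-5, 1e-2)
ELUE_BOUNDS = (1.3, 2.5)
STT_BOUNDS = (600.0, 1500.0)


@dataclass(frozen=True)
class SafyParams:
    """Full parameter vector: fixed constants, calibrated partition
    coefficients and the three plot-specific sensitive parameters.

    Units: temperatures in degC, thermal time in degC day, ``sla`` in
    m^2 g^-1, ``elue`` in g MJ^-1, ``dam0`` in g m^-2.
    """

    climate_efficiency: float = 0.48
    light_interception: float = 0.5
    t_min: float = 0.0
    t_opt: float = 18.0
    t_max: float = 26.0
    sla: float = 0.022
    senescence_rate: float = 6875.0
    dam0: float = 4.2
    partition_a: float = 0.16
    partition_b: float = 0.0025
    d0: int = 0
    elue: float = 1.9
    senescence_threshold: float = 1000.0
    harvest_index: float = 0.5
    pla_bounds: tuple[float, float] = PLA_BOUNDS
    plb_bounds: tuple[float, float] = PLB_BOUNDS
    elue_bounds: tuple[float, float] = ELUE_BOUNDS
    stt_bounds: tuple[float, float] = STT_BOUNDS
    d0_bounds: tuple[int, int] = (0, 365)

    def __post_init__(self) -> None:
        if not (self.climate_efficiency > 0 and self.light_interception > 0):
            raise ValueError("climate_efficiency and light_interception must be > 0")
        if not self.t_min < self.t_opt < self.t_max:
            raise ValueError("require t_min < t_opt < t_max")
        if self.sla <= 0:
            raise ValueError("sla must be > 0")
        if not 0 < self.harvest_index <= 1:
            raise ValueError("harvest_index must be in (0, 1]")
        if not self.pla_bounds[0] <= self.partition_a <= self.pla_bounds[1]:
            raise ValueError(f"partition_a {self.partition_a} outside {self.pla_bounds}")
        if not self.plb_bounds[0] <= self.partition_b <= self.plb_bounds[1]:
            raise ValueError(f"partition_b {self.partition_b} outside {self.plb_bounds}")
        if not self.elue_bounds[0] <= self.elue <= self.elue_bounds[1]:
            raise ValueError(f"elue {self.elue} outside {self.elue_bounds}")
        if not self.stt_bounds[0] <= self.senescence_threshold <= self.stt_bounds[1]:
            raise ValueError(
                f"senescence_threshold {self.senescence_threshold} outside {self.stt_bounds}"
            )

    def with_sensitive(self, d0: int, elue: float, stt: float) -> "SafyParams":
        """Return a copy with the three sensitive parameters replaced."""
        return replace(self, d0=int(round(d0)), elue=elue, senescence_threshold=stt)

    @property
    def initial_lai(self) -> float:
        return self.dam0 * self.sla


@dataclass(frozen=True)
class WeatherSeries:
    """Daily mean temperature (degC) and global radiation (MJ m^-2 day^-1),
    indexed by contiguous integer day-of-season."""

    day: np.ndarray
    ta: np.ndarray
    rg: np.ndarray

    def __post_init__(self) -> None:
        day = np.asarray(self.day, dtype=int)
        ta = np.asarray(self.ta, dtype=float)
        rg = np.asarray(self.rg, dtype=float)
        object.__setattr__(self, "day", day)
        object.__setattr__(self, "ta", ta)
        object.__setattr__(self, "rg", rg)
        if not (day.shape == ta.shape == rg.shape) or day.ndim != 1 or day.size == 0:
            raise ValueError("day, ta, rg must be equal-length 1-D arrays")
        if not np.all(np.diff(day) == 1):
            gaps = day[:-1][np.diff(day) != 1]
            raise ValueError(f"days must be contiguous; gap after day {gaps[0]}")
        if np.any(rg < 0):
            raise ValueError("radiation must be non-negative")

    @classmethod
    def from_min_max(
        cls, day: np.ndarray, tmin: np.ndarray, tmax: np.ndarray, rg: np.ndarray
    ) -> "WeatherSeries":
        """Build from daily min/max temperature; mean temperature is their average."""
        tmin = np.asarray(tmin, dtype=float)
        tmax = np.asarray(tmax, dtype=float)
        return cls(day=np.asarray(day), ta=(tmin + tmax) / 2.0, rg=np.asarray(rg))

    def __len__(self) -> int:
        return int(self.day.size)

    def index_of(self, day: int) -> int:
        i = int(day) - int(self.day[0])
        if i < 0 or i >= len(self):
            raise KeyError(f"day {day} outside weather range [{self.day[0]}, {self.day[-1]}]")
        return i


@dataclass(frozen=True)
class SafyState:
    """Model state at the end of one day."""

    day: int
    lai: float
    dam: float
    smt: float
    in_senescence: bool = False


@dataclass(frozen=True)
class SafyTrajectory:
    """Daily states from emergence to termination, with summary fields."""

    days: np.ndarray
    lai: np.ndarray
    dam: np.ndarray
    smt: np.ndarray
    dam_max: float
    day_of_peak_lai: int
    smt_at_peak_lai: float
    params: SafyParams = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.days.size == 0:
            raise ValueError("trajectory must be non-empty")

    def lai_at(self, day: int, *, before: float | None = None, after: float = 0.0) -> float:
        """Simulated LAI on ``day``; days before emergence map to the initial
        LAI (or ``before`` if given), days after termination to ``after``."""
        if day < self.days[0]:
            return float(self.lai[0]) if before is None else before
        if day > self.days[-1]:
            return after
        return float(self.lai[day - self.days[0]])

    def states(self) -> list[SafyState]:
        stt = self.params.senescence_threshold if self.params is not None else math.inf
        return [
            SafyState(int(d), float(l), float(m), float(s), bool(s > stt))
            for d, l, m, s in zip(self.days, self.lai, self.dam, self.smt)
        ]


def temperature_stress(ta: float, params: SafyParams) -> float:
    """Quadratic temperature stress factor in [0, 1].

    Exactly 1 at the optimum temperature, exactly 0 at or beyond the
    minimum/maximum growth temperatures.
    """
    tmin, topt, tmax = params.t_min, params.t_opt, params.t_max
    if ta <= tmin or ta >= tmax:
        return 0.0
    if ta < topt:
        f = 1.0 - ((topt - ta) / (topt - tmin)) ** 2
    else:
        f = 1.0 - ((ta - topt) / (tmax - topt)) ** 2
    return f


def compute_apar(lai: float, rg: float, params: SafyParams) -> float:
    """Absorbed photosynthetically active radiation (MJ m^-2 day^-1).

    Beer-law interception of the photosynthetically active fraction of
    global radiation; saturates at ``climate_efficiency * rg``.
    """
    if lai < 0 or rg < 0:
        raise ValueError("lai and rg must be non-negative")
    return (1.0 - math.exp(-params.light_interception * lai)) * params.climate_efficiency * rg


def partition_fraction(smt: float, params: SafyParams) -> float:
    """Fraction of the daily biomass increment allocated to leaves.

    Declines from ``1 - partition_a`` at emergence and is clamped at 0 once
    the raw expression turns negative (leaf allocation stops).
    """
    pl = 1.0 - params.partition_a * math.exp(params.partition_b * smt)
    return pl if pl > 0.0 else 0.0


def daily_step(state: SafyState, ta: float, rg: float, params: SafyParams) -> SafyState:
    """Advance the model by one day.

    Order of updates: biomass increment (light-use efficiency x stress x
    APAR at the current LAI), thermal-time accumulation (clamped at 0 on
    cold days), leaf growth at the updated thermal time, then senescence
    decay if the threshold has been passed.  LAI is floored at 0.
    """
    ft = temperature_stress(ta, params)
    ddam = params.elue * ft * compute_apar(state.lai, rg, params)
    dam = state.dam + ddam
    smt = state.smt + max(ta - params.t_min, 0.0)
    lai = state.lai
    pl = partition_fraction(smt, params)
    if pl > 0.0:
        lai += ddam * pl * params.sla
    senescing = smt > params.senescence_threshold
    if senescing:
        lai -= lai * (smt - params.senescence_threshold) / params.senescence_rate
        if lai < 0.0:
            lai = 0.0
    return SafyState(day=state.day + 1, lai=lai, dam=dam, smt=smt, in_senescence=senescing)


def simulate(weather: WeatherSeries, params: SafyParams) -> SafyTrajectory:
    """Run the daily model from emergence until senescence ends.

    Starts at day ``params.d0`` with ``dam = dam0`` and
    ``lai = dam0 * sla``; terminates when thermal time has passed the
    senescence threshold and LAI has fallen below ``SENESCENCE_END_LAI``,
    when the weather series is exhausted, or at ``MAX_SEASON_DAYS`` days
    after emergence.
    """
    d0 = int(params.d0)
    i0 = weather.index_of(d0)  # raises if d0 outside weather

    # Hot loop: local floats only; must stay arithmetically identical to
    # daily_step (cross-checked by tests).
    ta_arr = weather.ta
    rg_arr = weather.rg
    n = len(weather)
    elue = params.elue
    k = params.light_interception
    ec = params.climate_efficiency
    tmin, topt, tmax = params.t_min, params.t_opt, params.t_max
    inv_lo = 1.0 / (topt - tmin)
    inv_hi = 1.0 / (tmax - topt)
    pla, plb = params.partition_a, params.partition_b
    sla = params.sla
    stt = params.senescence_threshold
    rs = params.senescence_rate
    exp = math.exp

    lai = params.dam0 * sla
    dam = params.dam0
    smt = 0.0
    days = [d0]
    lai_seq = [lai]
    dam_seq = [dam]
    smt_seq = [smt]

    i = i0
    last_i = min(n - 1, i0 + MAX_SEASON_DAYS)
    while i < last_i:
        i += 1
        ta = ta_arr[i]
        rg = rg_arr[i]
        if ta <= tmin or ta >= tmax:
            ft = 0.0
        elif ta < topt:
            ft = 1.0 - ((topt - ta) * inv_lo) ** 2
        else:
            ft = 1.0 - ((ta - topt) * inv_hi) ** 2
        ddam = elue * ft * (1.0 - exp(-k * lai)) * ec * rg
        dam += ddam
        dsmt = ta - tmin
        if dsmt > 0.0:
            smt += dsmt
        pl = 1.0 - pla * exp(plb * smt)
        if pl > 0.0:
            lai += ddam * pl * sla
        if smt > stt:
            lai -= lai * (smt - stt) / rs
            if lai < 0.0:
                lai = 0.0
        days.append(d0 + (i - i0))
        lai_seq.append(lai)
        dam_seq.append(dam)
        smt_seq.append(smt)
        if smt > stt and lai < SENESCENCE_END_LAI:
            break

    lai_np = np.asarray(lai_seq)
    dam_np = np.asarray(dam_seq)
    peak = int(np.argmax(lai_np))
    return SafyTrajectory(
        days=np.asarray(days, dtype=int),
        lai=lai_np,
        dam=dam_np,
        smt=np.asarray(smt_seq),
        dam_max=float(dam_np.max()),
        day_of_peak_lai=int(days[peak]),
        smt_at_peak_lai=float(smt_seq[peak]),
        params=params,
    )


def grain_yield(traj: SafyTrajectory, params: SafyParams) -> float:
    """Grain yield in t ha^-1: harvest index times peak biomass (g m^-2 -> t ha^-1)."""
    return traj.dam_max * params.harvest_index * 0.01
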