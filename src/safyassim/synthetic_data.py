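"""Synthetic winter-wheat field trials for end-to-end pipeline testing.

Generates a deterministic factorial trial (2 varieties x 4 nitrogen x 3
water levels x 2 replicates = 48 plots by default): a sinusoidal weather
season, per-plot true growth parameters with treatment effects on
light-use efficiency and senescence threshold, noisy LAI / biomass / yield
observations at sparse dates, and band reflectances constructed so the
exponential OSAVI inversion model recovers the true LAI exactly in the
noise-free limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from safyassim.assimilation import PlotObservations
from safyassim.safy_core import SafyParams, SafyTrajectory, WeatherSeries, grain_yield, simulate

__all__ = [
    "TrialDesign",
    "SyntheticTruth",
    "generate_weather",
    "generate_trial",
    "synthesize_reflectance",
    "OSAVI_MODEL_A",
    "OSAVI_MODEL_B",
]

# coefficients of the exponential OSAVI->LAI model used for reflectance
# construction (and recovered by the inversion round-trip tests)
OSAVI_MODEL_A = 0.21
OSAVI_MODEL_B = 4.68

VARIETY_ELUE_BASE = {"P1": 1.75, "P2": 1.95}
NITROGEN_ELUE_MULT = {"N1": 0.85, "N2": 0.95, "N3": 1.05, "N4": 1.10}
WATER_STT_OFFSET = {"W1": -100.0, "W2": 0.0, "W3": 100.0}


@dataclass(frozen=True)
class TrialDesign:
    """Factorial layout and noise settings of one synthetic trial."""

    varieties: tuple[str, ...] = ("P1", "P2")
    nitrogen_levels: tuple[str, ...] = ("N1", "N2", "N3", "N4")
    water_levels: tuple[str, ...] = ("W1", "W2", "W3")
    replicates: int = 2
    sowing_day: int = 0
    season_length: int = 280
    n_acquisitions: int = 7
    n_stages: int = 6
    stt_base: float = 1000.0
    partition_a: float = 0.16
    partition_b: float = 0.0025
    harvest_index: float = 0.5
    sigma_lai: float = 0.3
    dam_cv: float = 0.10
    sigma_yield: float = 0.3
    sigma_reflectance: float = 0.002
    seed: int = 0

    @property
    def n_plots(self) -> int:
        return (
            len(self.varieties) * len(self.nitrogen_levels) * len(self.water_levels) * self.replicates
        )

    @property
    def acquisition_days(self) -> np.ndarray:
        """Roughly uniform satellite acquisition days over the active season."""
        lo = self.sowing_day + 60
        hi = self.sowing_day + min(245, self.season_length - 20)
        return np.unique(np.linspace(lo, hi, self.n_acquisitions).round().astype(int))

    @property
    def stage_days(self) -> np.ndarray:
        """Destructive-sampling days (growth stages)."""
        lo = self.sowing_day + 90
        hi = self.sowing_day + min(250, self.season_length - 15)
        return np.unique(np.linspace(lo, hi, self.n_stages).round().astype(int))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated trial: per-plot parameters, the noise-free
    trajectories and the true yields."""

    table: pd.DataFrame  # plot_id, variety, nitrogen, water, d0, elue, stt, pla, plb, hi, yield_t_ha
    trajectories: dict[str, SafyTrajectory] = field(repr=False)
    weather: WeatherSeries = field(repr=False, default=None)


def generate_weather(
    season_length: int = 280, seed: int = 0, start_day: int = 0
) -> WeatherSeries:
    """Sinusoidal winter-wheat season: autumn start, cold mid-season, warm
    spring, with day-to-day Gaussian noise; radiation co-varies with the
    smooth temperature curve and is floored at 0."""
    rng = np.random.default_rng(seed)
    day = np.arange(start_day, start_day + season_length)
    t = day - start_day
    ta_smooth = 12.0 - 7.0 * np.cos(2.0 * math.pi * (t - 90.0) / 365.0)
    ta = ta_smooth + rng.normal(0.0, 1.5, size=season_length)
    rg = np.maximum(10.0 + 0.9 * ta_smooth + rng.normal(0.0, 1.0, size=season_length), 0.0)
    return WeatherSeries(day=day, ta=ta, rg=rg)


def synthesize_reflectance(
    lai: float, rng: np.random.Generator, sigma: float = 0.0
) -> tuple[float, float, float, float]:
    """Blue/green/red/NIR reflectance whose OSAVI maps back to ``lai``
    through the exponential inversion model.

    Red reflectance decreases with canopy density; NIR is solved from the
    OSAVI definition; blue and green are fixed fractions of red.  Gaussian
    noise ``sigma`` is added to every band (clipped to [0, 1]).
    """
    osavi = math.log(max(lai, OSAVI_MODEL_A) / OSAVI_MODEL_A) / OSAVI_MODEL_B
    if osavi >= 1.0:
        raise ValueError(f"LAI {lai} maps to OSAVI >= 1 (outside the index's range)")
    red = 0.15 - 0.12 * min(max(lai, 0.0), 6.0) / 6.0
    nir = (red + 0.16 * osavi + red * osavi) / (1.0 - osavi)
    blue = 0.5 * red
    green = 0.8 * red
    bands = np.array([blue, green, red, nir])
    if sigma > 0.0:
        bands = bands + rng.normal(0.0, sigma, size=4)
    bands = np.clip(bands, 0.0, 1.0)
    return tuple(float(v) for v in bands)


def generate_trial(
    design: TrialDesign, weather: WeatherSeries
) -> tuple[SyntheticTruth, list[PlotObservations], pd.DataFrame]:
    """Generate the full trial: truth, per-plot observations and reflectances.

    All randomness flows from per-plot streams spawned off the design seed,
    so results are independent of plot evaluation order.
    """
    master = np.random.SeedSequence(design.seed)
    plot_seeds = master.spawn(design.n_plots)
    acq_days = design.acquisition_days
    stage_days = design.stage_days

    truth_rows = []
    trajectories: dict[str, SafyTrajectory] = {}
    plots: list[PlotObservations] = []
    refl_rows = []

    i = 0
    for variety in design.varieties:
        for nitrogen in design.nitrogen_levels:
            for water in design.water_levels:
                for rep in range(1, design.replicates + 1):
                    plot_id = f"{variety}-{nitrogen}-{water}-R{rep}"
                    rng = np.random.default_rng(plot_seeds[i])
                    i += 1

                    d0 = design.sowing_day + int(rng.integers(8, 15))
                    elue = float(
                        np.clip(
                            VARIETY_ELUE_BASE[variety] * NITROGEN_ELUE_MULT[nitrogen],
                            1.3,
                            2.5,
                        )
                    )
                    stt = float(np.clip(design.stt_base + WATER_STT_OFFSET[water], 600.0, 1500.0))
                    params = SafyParams(
                        partition_a=design.partition_a,
                        partition_b=design.partition_b,
                        d0=d0,
                        elue=elue,
                        senescence_threshold=stt,
                        harvest_index=design.harvest_index,
                    )
                    traj = simulate(weather, params)
                    trajectories[plot_id] = traj
                    true_yield = grain_yield(traj, params)

                    true_lai = np.array([traj.lai_at(int(d), before=0.0) for d in acq_days])
                    lai_obs = np.maximum(
                        true_lai + rng.normal(0.0, design.sigma_lai, size=true_lai.size), 0.0
                    )
                    true_dam = np.array(
                        [
                            float(traj.dam[int(d) - int(traj.days[0])])
                            if traj.days[0] <= d <= traj.days[-1]
                            else (params.dam0 if d < traj.days[0] else float(traj.dam[-1]))
                            for d in stage_days
                        ]
                    ) * 0.01
                    dam_obs = np.maximum(
                        true_dam * (1.0 + rng.normal(0.0, design.dam_cv, size=true_dam.size)), 0.0
                    )
                    yield_obs = max(true_yield + rng.normal(0.0, design.sigma_yield), 0.0)

                    plots.append(
                        PlotObservations(
                            plot_id=plot_id,
                            lai_days=acq_days,
                            lai_values=lai_obs,
                            dam_days=stage_days,
                            dam_values=dam_obs,
                            yield_t_ha=yield_obs,
                            variety=variety,
                            nitrogen=nitrogen,
                            water=water,
                        )
                    )
                    for d, lai in zip(acq_days, true_lai):
                        b, g, r, nir = synthesize_reflectance(
                            lai, rng, sigma=design.sigma_reflectance
                        )
                        refl_rows.append(
                            {
                                "plot_id": plot_id,
                                "date": int(d),
                                "b_blue": b,
                                "b_green": g,
                                "b_red": r,
                                "b_nir": nir,
                            }
                        )
                    truth_rows.append(
                        {
                            "plot_id": plot_id,
                            "variety": variety,
                            "nitrogen": nitrogen,
                            "water": water,
                            "d0": d0,
                            "elue": elue,
                            "stt": stt,
                            "pla": design.partition_a,
                            "plb": design.partition_b,
                            "hi": design.harvest_index,
                            "yield_t_ha": true_yield,
                        }
                    )

    truth = SyntheticTruth(
        table=pd.DataFrame(truth_rows), trajectories=trajectories, weather=weather
    )
    return truth, plots, pd.DataFrame(refl_rows)
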