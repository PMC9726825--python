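"""Seeded synthetic-data generators with ground-truth manifests.

Every generator is a pure function of (scenario config, seed) and returns
``(table, manifest)`` where the manifest records all ground-truth
parameters and per-cell truths needed to score downstream estimators.
The generators emulate the statistical structure the analysis assumes:
log-normal ROS levels with threshold-governed division/bursting, linear
cell-size growth to a burst size, gamma-jittered cell-cycle phase
durations sampled at a fixed movie cadence, logistic / birth-death
population dynamics, and saturating-exponential labeling and induction
kinetics with Poisson or Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import core_model
from .errors import InvalidInputError
from .units import HOURS_PER_DAY, kelvin

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "load_scenario",
    "gen_cell_tracks",
    "gen_cycle_traces",
    "gen_population_series",
    "gen_labeling_timecourse",
    "gen_induction_traces",
    "gen_oxidation_series",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one named study condition.

    Phase means are hours; rates are per day (population) or per hour
    (kinetics); sizes and fluorescence are arbitrary units.
    """

    name: str
    temperature_C: float
    ros_mu_log: float
    ros_sigma_log: float = 1.0
    ros_threshold: float = 6000.0
    phase_means_h: dict = field(
        default_factory=lambda: {"g1": 32.0, "s": 25.0, "g2": 6.0, "m": 22.0}
    )
    phase_cv: float = 0.2
    non_divider_fraction: float = 0.2
    whi5_high: float = 2.5
    whi5_low: float = 0.8
    noise_cv: float = 0.05
    cadence_per_day: float = 2.0
    horizon_days: float = 30.0
    birth_size_au: float = 20.0
    burst_size_au: float = 120.0
    growth_rate_au_per_h: float = 0.15
    begin_as_bud_fraction: float = 0.15
    g_per_day: float = 0.12
    d_per_day: float = 0.04
    carrying_capacity: float = 1.0e5  # saturating density of frigid cultures, cells/ml
    density_threshold: float = 3000.0
    k_syn_per_h: float = 2000.0
    mrna_half_life_h: float = 7.0
    induction_A_au: float = 100.0
    induction_k_per_h: float = 0.02
    induction_t0_h: float = 12.0
    oxidation_fold: float = 1.0

    @property
    def temperature_K(self) -> float:
        return kelvin(self.temperature_C)

    @property
    def ros_dist(self) -> core_model.RosDistribution:
        return core_model.RosDistribution(
            mu_log=self.ros_mu_log, sigma_log=self.ros_sigma_log, label=self.name
        )

    @property
    def frame_h(self) -> float:
        return HOURS_PER_DAY / self.cadence_per_day

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidInputError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**data)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


#: Names of the scenario YAML files shipped with the package.
SCENARIOS = (
    "low_GSH_5C",
    "high_GSH_5C",
    "wildtype_1C",
    "wildtype_30C",
    "grx2_gtt2_KO_5C",
    "trolox_medium",
    "dilute_medium_0.2x",
)


def load_scenario(name: str) -> ScenarioConfig:
    """Load a named scenario from the packaged YAML library."""
    if name not in SCENARIOS:
        raise InvalidInputError(f"unknown scenario {name!r}; available: {list(SCENARIOS)}")
    text = resources.files("coldlife.scenarios").joinpath(f"{name}.yaml").read_text()
    return ScenarioConfig.from_dict(yaml.safe_load(text))


def _manifest(cfg: ScenarioConfig, seed: int, **extra) -> dict:
    return {"scenario": cfg.asdict(), "seed": int(seed), **extra}


def _gamma(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Gamma-distributed positive durations with the given mean and CV."""
    if cv <= 0:
        return np.full(size, mean) if size is not None else mean
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=size)


def gen_cell_tracks(
    cfg: ScenarioConfig, n: int, seed: int, noise_cv: float | None = None
) -> tuple[pd.DataFrame, dict]:
    """Synthetic time-lapse track table (one row per cell per frame).

    Each cell draws a ROS level from the scenario log-normal; cells below
    the division threshold divide with bud events spaced by gamma-jittered
    model doubling times, cells above it grow until the burst size and
    die.  A fraction of cells begin the movie as buds and separate
    (birth annotation).  All cells grow linearly in size; annotations are
    recorded at the nearest movie frame; tracks are right-censored at the
    horizon.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    noise = cfg.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    params = dataclasses.replace(core_model.default_params(), ros_threshold=cfg.ros_threshold)
    horizon_h = cfg.horizon_days * HOURS_PER_DAY
    frames = np.arange(0.0, horizon_h + 1e-9, cfg.frame_h)

    def nearest_frame(t: float) -> float:
        return float(frames[np.argmin(np.abs(frames - t))])

    rows = []
    truth_rows = []
    for i in range(n):
        cid = f"cell{i:04d}"
        ros = float(rng.lognormal(cfg.ros_mu_log, cfg.ros_sigma_log))
        s0 = cfg.birth_size_au * float(rng.normal(1.0, 0.05))
        rate = cfg.growth_rate_au_per_h * float(_gamma(rng, 1.0, 0.1))
        begins_as_bud = rng.random() < cfg.begin_as_bud_fraction
        born_at = nearest_frame(float(rng.uniform(0, 0.1 * horizon_h))) if begins_as_bud else None

        bud_times: list[float] = []
        true_intervals: list[float] = []
        death_time = None
        if ros < cfg.ros_threshold:
            tau_mean = core_model.doubling_time(ros, cfg.temperature_K, params)
            t_cursor = born_at if born_at is not None else 0.0
            while True:
                gap = float(_gamma(rng, tau_mean, cfg.phase_cv))
                t_cursor += gap
                if t_cursor > horizon_h:
                    break
                bud_times.append(nearest_frame(t_cursor))
                true_intervals.append(gap)
        else:
            death_time = (cfg.burst_size_au - s0) / rate
            death_time = nearest_frame(death_time) if death_time <= horizon_h else None
        end = death_time if death_time is not None else horizon_h
        cell_frames = frames[frames <= end + 1e-9]
        size = s0 + rate * cell_frames
        if noise > 0:
            size = size * np.exp(rng.normal(0.0, noise, size=size.size))
        for t, sz in zip(cell_frames, size):
            rows.append(
                {
                    "cell_id": cid,
                    "time_h": t,
                    "size_au": sz,
                    "ros_au": ros,
                    "bud_flag": int(t in bud_times),
                    "birth_flag": int(born_at is not None and t == born_at),
                    "death_flag": int(death_time is not None and t == death_time),
                    "censored_flag": int(death_time is None),
                }
            )
        if death_time is not None:
            label = "dies"
        elif bud_times:
            label = "duplicates"
        elif born_at is not None:
            label = "begins_life"
        else:
            label = "grows"
        truth_rows.append(
            {
                "cell_id": cid,
                "ros": ros,
                "label": label,
                "n_buds": len(bud_times),
                "true_bud_intervals_h": true_intervals,
                "death_time_h": death_time,
                "growth_rate_au_per_h": rate,
            }
        )
    df = pd.DataFrame(rows)
    manifest = _manifest(
        cfg,
        seed,
        kind="cell_tracks",
        n=n,
        noise_cv=noise,
        cells=truth_rows,
        model_params=dataclasses.asdict(params),
    )
    return df, manifest


def gen_cycle_traces(
    cfg: ScenarioConfig, n: int, seed: int, noise_cv: float | None = None
) -> tuple[pd.DataFrame, dict]:
    """Synthetic Whi5-ratio / DNA-copy traces at the movie cadence.

    Dividing cells: the Whi5 nuclear ratio sits on a high plateau through
    G1 and drops to the low plateau at G1 exit; the DNA copy number ramps
    linearly from 1 to 2 across S; bud (mitosis onset) and division
    (separation) annotations are placed at the nearest frame.  Phase
    durations are gamma-jittered around the scenario means.  Non-dividers
    stay on the high Whi5 plateau with constant DNA for the whole horizon.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    noise = cfg.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    horizon_h = cfg.horizon_days * HOURS_PER_DAY
    frame = cfg.frame_h
    m = cfg.phase_means_h

    rows = []
    truth_rows = []
    for i in range(n):
        cid = f"cell{i:04d}"
        divider = rng.random() >= cfg.non_divider_fraction
        if divider:
            g1 = float(_gamma(rng, m["g1"], cfg.phase_cv))
            s = float(_gamma(rng, m["s"], cfg.phase_cv))
            g2 = float(_gamma(rng, m["g2"], cfg.phase_cv))
            mphase = float(_gamma(rng, m["m"], cfg.phase_cv))
            s_start, s_end = g1, g1 + s
            onset, division = g1 + s + g2, g1 + s + g2 + mphase
            end = min(division + 2 * frame, horizon_h)
            complete = division <= horizon_h
        else:
            g1 = s = g2 = mphase = float("nan")
            s_start = s_end = onset = division = float("inf")
            end = horizon_h
            complete = False
        t = np.arange(0.0, end + 1e-9, frame)
        whi5 = np.where(t < (g1 if divider else np.inf), cfg.whi5_high, cfg.whi5_low)
        dna = np.interp(t, [0.0, s_start, s_end, max(end, s_end) + 1.0], [1.0, 1.0, 2.0, 2.0]) \
            if divider else np.ones_like(t)
        if noise > 0:
            whi5 = whi5 * np.exp(rng.normal(0.0, noise, t.size))
            dna = dna * np.exp(rng.normal(0.0, noise, t.size))
        onset_frame = frame * round(onset / frame) if divider and complete else None
        division_frame = frame * round(division / frame) if divider and complete else None
        for j, tj in enumerate(t):
            rows.append(
                {
                    "cell_id": cid,
                    "time_h": tj,
                    "whi5_ratio": whi5[j],
                    "dna_copy": dna[j],
                    "bud_flag": int(onset_frame is not None and abs(tj - onset_frame) < 1e-6),
                    "division_flag": int(division_frame is not None and abs(tj - division_frame) < 1e-6),
                }
            )
        truth_rows.append(
            {
                "cell_id": cid,
                "divider": divider,
                "complete": bool(divider and complete),
                "g1_h": g1,
                "s_h": s,
                "g2_h": g2,
                "m_h": mphase,
            }
        )
    df = pd.DataFrame(rows)
    manifest = _manifest(cfg, seed, kind="cycle_traces", n=n, noise_cv=noise, cells=truth_rows)
    return df, manifest


def gen_population_series(
    cfg: ScenarioConfig,
    seed: int,
    initial_densities=(250.0, 1000.0, 3000.0, 6250.0),
    horizon_days: float = 60.0,
    every_days: float = 2.0,
    noise_cv: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Synthetic population density and viability tables.

    Populations starting at or above the scenario density threshold grow
    logistically to the carrying capacity at net rate ``g - d``; below it
    they decline (death exceeds division).  Viability counts follow the
    closed-form birth-death means with log-normal measurement noise.
    """
    noise = cfg.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, horizon_days + 1e-9, every_days)
    pop_rows, via_rows, truth = [], [], []
    for N0 in initial_densities:
        grows = N0 >= cfg.density_threshold
        if grows:
            g, d = cfg.g_per_day, cfg.d_per_day
            net = g - d
            K = cfg.carrying_capacity
            density = K / (1.0 + (K / N0 - 1.0) * np.exp(-net * t))
        else:
            g, d = 0.2 * cfg.d_per_day, cfg.d_per_day  # death dominates
            net = g - d
            density = N0 * np.exp(net * t)
        live_mean, dead_mean = _bd_mean(g, d, N0, t, cap=cfg.carrying_capacity if grows else None)
        if noise > 0:
            density = density * np.exp(rng.normal(0.0, noise, t.size))
            live_mean = live_mean * np.exp(rng.normal(0.0, noise, t.size))
            dead_mean = dead_mean * np.exp(rng.normal(0.0, noise, t.size))
        cond = f"{cfg.name}_N0_{int(N0)}"
        for ti, ni, li, di in zip(t, density, live_mean, dead_mean):
            pop_rows.append(
                {
                    "condition_id": cond,
                    "temperature_C": cfg.temperature_C,
                    "t_day": ti,
                    "density_per_ml": ni,
                    "initial_density_per_ml": N0,
                    "carrying_capacity_per_ml": cfg.carrying_capacity,
                }
            )
            via_rows.append(
                {"condition_id": cond, "t_day": ti, "live_per_ml": li, "dead_per_ml": di}
            )
        truth.append(
            {
                "condition_id": cond,
                "initial_density": N0,
                "grows": bool(grows),
                "g_per_day": g,
                "d_per_day": d,
                "doubling_days": float(np.log(2) / net) if net > 0 else None,
            }
        )
    manifest = _manifest(cfg, seed, kind="population_series", noise_cv=noise, conditions=truth)
    return pd.DataFrame(pop_rows), pd.DataFrame(via_rows), manifest


def _bd_mean(g, d, N0, t, cap=None):
    net = g - d
    live = N0 * np.exp(net * np.asarray(t, dtype=float))
    if cap is not None:
        live = cap / (1.0 + (cap / N0 - 1.0) * np.exp(-net * np.asarray(t, dtype=float)))
    if abs(net) < 1e-12:
        dead = d * N0 * np.asarray(t, dtype=float)
    else:
        dead = d * N0 * (np.exp(net * np.asarray(t, dtype=float)) - 1.0) / net
    return live, dead


def gen_labeling_timecourse(
    cfg: ScenarioConfig,
    seed: int,
    t_points_h=None,
    n_replicates: int = 3,
    noise: str = "poisson",
) -> tuple[pd.DataFrame, dict]:
    """Synthetic 4tU-labeled mRNA-per-cell time course.

    Counts follow ``M(t) = (k_syn/k_deg)(1 - exp(-k_deg t))`` with the
    scenario's synthesis rate and half-life; ``noise`` is ``"poisson"``
    (counts) or ``"none"`` (exact closed form).
    """
    if t_points_h is None:
        t_points_h = np.arange(6.0, 48.0 + 1e-9, 6.0)  # 8 points over 48 h
    t = np.asarray(t_points_h, dtype=float)
    k_deg = np.log(2.0) / cfg.mrna_half_life_h
    k_syn = cfg.k_syn_per_h
    mean = (k_syn / k_deg) * (1.0 - np.exp(-k_deg * t))
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        if noise == "poisson":
            counts = rng.poisson(mean).astype(float)
        elif noise == "none":
            counts = mean.copy()
        else:
            raise InvalidInputError(f"unknown noise model {noise!r}")
        for ti, ci in zip(t, counts):
            rows.append(
                {
                    "temperature_C": cfg.temperature_C,
                    "t_h": ti,
                    "labeled_copies_per_cell": ci,
                    "replicate": rep,
                }
            )
    manifest = _manifest(
        cfg, seed, kind="labeling", noise=noise,
        k_syn_per_h=k_syn, k_deg_per_h=float(k_deg), half_life_h=cfg.mrna_half_life_h,
    )
    return pd.DataFrame(rows), manifest


def gen_induction_traces(
    cfg: ScenarioConfig,
    seed: int,
    horizon_days: float = 14.0,
    n_replicates: int = 3,
    noise_cv: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic reporter-induction traces after galactose addition.

    Signal follows ``A (1 - exp(-k (t - t0)))`` past the onset delay,
    sampled at the movie cadence with multiplicative Gaussian noise.
    """
    noise = cfg.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, horizon_days * HOURS_PER_DAY + 1e-9, cfg.frame_h)
    A, k, t0 = cfg.induction_A_au, cfg.induction_k_per_h, cfg.induction_t0_h
    mean = np.where(t > t0, A * (1.0 - np.exp(-k * np.maximum(t - t0, 0.0))), 0.0)
    rows = []
    for rep in range(n_replicates):
        sig = mean.copy()
        if noise > 0:
            sig = sig * np.exp(rng.normal(0.0, noise, t.size))
        for ti, si in zip(t, sig):
            rows.append(
                {"temperature_C": cfg.temperature_C, "t_h": ti, "signal_au": si, "replicate": rep}
            )
    manifest = _manifest(
        cfg, seed, kind="induction", noise_cv=noise,
        A_au=A, k_per_h=k, t0_h=t0, rate_au_per_h=A * k,
    )
    return pd.DataFrame(rows), manifest


def gen_oxidation_series(
    cfg: ScenarioConfig,
    seed: int,
    base_slope_au_per_s: float = 1.0,
    duration_s: float = 7200.0,
    every_s: float = 180.0,
    noise_sd_au: float = 20.0,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic medium-oxidation fluorescence curves (scenario vs control).

    The scenario curve's slope is ``base_slope * oxidation_fold`` (e.g.
    a superoxide scavenger gives fold 1/6); both curves are linear with
    additive Gaussian noise, sampled every 3 minutes.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + 1e-9, every_s)
    rows = []
    for cond, slope in (("control", base_slope_au_per_s),
                        ("scenario", base_slope_au_per_s * cfg.oxidation_fold)):
        sig = 100.0 + slope * t + rng.normal(0.0, noise_sd_au, t.size)
        for ti, si in zip(t, sig):
            rows.append({"condition": cond, "t_s": ti, "signal_au": si})
    manifest = _manifest(
        cfg, seed, kind="oxidation",
        control_slope=base_slope_au_per_s,
        scenario_slope=base_slope_au_per_s * cfg.oxidation_fold,
        fold=cfg.oxidation_fold,
    )
    return pd.DataFrame(rows), manifest
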