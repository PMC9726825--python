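"""Single-cell event, doubling-time, cell-cycle-phase, and lifespan analysis.

Inputs are pre-segmented per-cell tables from time-lapse microscopy:

* *tracks* — one row per (cell, frame) with size, a ROS fluorescence
  reading taken at the start of the movie, and bud / birth / death
  annotations.  From these we classify each cell's observed fate, measure
  bud-to-bud doubling times (with right-censoring at movie end), and build
  event-probability curves against ROS or size.
* *traces* — per-cell Whi5 nuclear/cytoplasmic ratio and normalized DNA
  copy number.  Whi5 leaving the nucleus marks the G1-to-S transition;
  the DNA signal ramping from one to two copies delimits S phase; bud and
  division annotations delimit G2 and mitosis+cytokinesis.

Durations are hours internally; ages and lifespans are reported in days
where noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import InsufficientDataError, InvalidInputError
from .units import HOURS_PER_DAY

__all__ = [
    "EVENTS",
    "CellTrack",
    "CycleTrace",
    "EventProbabilityCurve",
    "PhaseDurations",
    "PhaseSummary",
    "LifeCurve",
    "tracks_from_table",
    "traces_from_table",
    "classify_events",
    "bud_to_bud_doubling_times",
    "mean_doubling_time",
    "event_probabilities",
    "extract_phases",
    "phase_summary",
    "reconstruct_life_curve",
    "replicative_lifespan",
]

#: The four mutually exclusive fates observed for a cell during a movie.
EVENTS = ("begins_life", "duplicates", "grows", "dies")

TRACKS_COLUMNS = (
    "cell_id", "time_h", "size_au", "ros_au",
    "bud_flag", "birth_flag", "death_flag", "censored_flag",
)
TRACES_COLUMNS = ("cell_id", "time_h", "whi5_ratio", "dna_copy", "bud_flag", "division_flag")


@dataclass
class CellTrack:
    """One cell's observed trajectory during a time-lapse movie."""

    cell_id: str
    time_h: np.ndarray
    size_au: np.ndarray
    ros_au: float
    bud_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    born_at: float | None = None
    death_time: float | None = None
    censored: bool = True

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.size_au = np.asarray(self.size_au, dtype=float)
        self.bud_times = np.asarray(self.bud_times, dtype=float)
        if self.time_h.size == 0:
            raise InvalidInputError(f"track {self.cell_id!r} is empty")
        if np.any(np.diff(self.time_h) <= 0):
            raise InvalidInputError(f"track {self.cell_id!r}: times must be strictly increasing")
        if np.any(self.size_au <= 0):
            raise InvalidInputError(f"track {self.cell_id!r}: sizes must be positive")
        if self.death_time is not None and self.bud_times.size and self.death_time < self.bud_times.max():
            raise InvalidInputError(f"track {self.cell_id!r}: death precedes last bud event")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time_h[0]), float(self.time_h[-1])


@dataclass
class CycleTrace:
    """Per-cell Whi5 nuclear-ratio and DNA-copy time series."""

    cell_id: str
    time_h: np.ndarray
    whi5_ratio: np.ndarray
    dna_copy: np.ndarray
    bud_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    division_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.whi5_ratio = np.asarray(self.whi5_ratio, dtype=float)
        self.dna_copy = np.asarray(self.dna_copy, dtype=float)
        self.bud_times = np.asarray(self.bud_times, dtype=float)
        self.division_times = np.asarray(self.division_times, dtype=float)
        if np.any(np.diff(self.time_h) <= 0):
            raise InvalidInputError(f"trace {self.cell_id!r}: times must be strictly increasing")
        if np.any(self.whi5_ratio <= 0):
            raise InvalidInputError(f"trace {self.cell_id!r}: Whi5 ratio must be positive")


def tracks_from_table(df: pd.DataFrame) -> list[CellTrack]:
    """Build :class:`CellTrack` objects from a long-format tracks table."""
    missing = [c for c in TRACKS_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"tracks table is missing columns: {missing}")
    tracks = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_h")
        births = sub.loc[sub["birth_flag"] > 0, "time_h"]
        deaths = sub.loc[sub["death_flag"] > 0, "time_h"]
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                time_h=sub["time_h"].to_numpy(),
                size_au=sub["size_au"].to_numpy(),
                ros_au=float(sub["ros_au"].iloc[0]),
                bud_times=sub.loc[sub["bud_flag"] > 0, "time_h"].to_numpy(),
                born_at=float(births.iloc[0]) if len(births) else None,
                death_time=float(deaths.iloc[0]) if len(deaths) else None,
                censored=bool(sub["censored_flag"].iloc[-1]),
            )
        )
    return tracks


def traces_from_table(df: pd.DataFrame) -> list[CycleTrace]:
    """Build :class:`CycleTrace` objects from a long-format traces table."""
    missing = [c for c in TRACES_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"traces table is missing columns: {missing}")
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_h")
        traces.append(
            CycleTrace(
                cell_id=str(cell_id),
                time_h=sub["time_h"].to_numpy(),
                whi5_ratio=sub["whi5_ratio"].to_numpy(),
                dna_copy=sub["dna_copy"].to_numpy(),
                bud_times=sub.loc[sub["bud_flag"] > 0, "time_h"].to_numpy(),
                division_times=sub.loc[sub["division_flag"] > 0, "time_h"].to_numpy(),
            )
        )
    return traces


def classify_events(track: CellTrack, window: tuple[float, float] | None = None) -> str:
    """Primary fate of a cell during the observation window.

    The four outcomes are treated as mutually exclusive with precedence
    ``dies > duplicates > begins_life > grows``: a death always dominates;
    a cell that formed at least one bud duplicated; a cell that started as
    a bud and separated from its mother (birth annotation) without budding
    itself begins life; anything else only grew.
    """
    lo, hi = window if window is not None else track.span
    if hi < track.span[0] or lo > track.span[1]:
        raise InvalidInputError(f"window {window} does not overlap track {track.cell_id!r}")
    in_window = lambda t: t is not None and lo <= t <= hi
    if in_window(track.death_time):
        return "dies"
    if np.any((track.bud_times >= lo) & (track.bud_times <= hi)):
        return "duplicates"
    if in_window(track.born_at):
        return "begins_life"
    return "grows"


def bud_to_bud_doubling_times(
    tracks: Iterable[CellTrack], movie_end: float | None = None
) -> pd.DataFrame:
    """Bud-to-bud doubling times with right-censoring.

    A single-cell doubling time runs from one bud appearance to the next
    qualifying bud on the same mother.  A division still unfinished when
    the movie ends contributes its elapsed time as a censored value.
    Returns a frame with columns ``cell_id``, ``duration_h``, ``censored``.
    """
    tracks = list(tracks)
    if movie_end is None:
        movie_end = max((t.span[1] for t in tracks), default=0.0)
    rows = []
    for track in tracks:
        buds = np.sort(track.bud_times)
        for a, b in zip(buds[:-1], buds[1:]):
            rows.append((track.cell_id, b - a, False))
        if buds.size and track.censored and track.death_time is None:
            elapsed = min(movie_end, track.span[1]) - buds[-1]
            if elapsed > 0:
                rows.append((track.cell_id, elapsed, True))
    return pd.DataFrame(rows, columns=["cell_id", "duration_h", "censored"])


def mean_doubling_time(durations: pd.DataFrame, method: str = "elapsed") -> float:
    """Mean doubling time in hours.

    ``elapsed`` (default) includes censored intervals at their elapsed
    value, as the movie-based definition implies; ``km`` returns the
    restricted mean of the Kaplan-Meier survival curve instead.
    """
    if durations.empty:
        raise InsufficientDataError("no doubling-time observations")
    if method == "elapsed":
        return float(durations["duration_h"].mean())
    if method == "km":
        t = durations["duration_h"].to_numpy()
        observed = ~durations["censored"].to_numpy(dtype=bool)
        order = np.argsort(t)
        t, observed = t[order], observed[order]
        n = t.size
        at_risk = n - np.arange(n)
        surv = np.cumprod(1.0 - observed / at_risk)
        # restricted mean = area under the KM curve up to the last time
        times = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], surv])
        return float(np.sum(s[:-1] * np.diff(times)))
    raise InvalidInputError(f"unknown method {method!r}")


@dataclass
class EventProbabilityCurve:
    """Per-bin probabilities of each cell fate against ROS or size."""

    covariate: str
    edges: np.ndarray
    table: pd.DataFrame  # bin_lo, bin_hi, n, p_<event>, sem_<event>

    def prob(self, event: str):
        return self.table[f"p_{event}"].to_numpy()

    def interp_prob(self, event: str, x) -> np.ndarray:
        """Probability of ``event`` at covariate value(s) ``x`` (bin-center interpolation)."""
        centers = 0.5 * (self.table["bin_lo"] + self.table["bin_hi"]).to_numpy()
        return np.interp(np.asarray(x, dtype=float), centers, self.prob(event))


def event_probabilities(
    tracks: Iterable[CellTrack],
    covariate: str,
    bins: int | Sequence[float] = 8,
    n_boot: int = 1000,
    seed: int = 0,
    min_count: int = 10,
    window: tuple[float, float] | None = None,
) -> EventProbabilityCurve:
    """Empirical probability of each fate as a function of ROS or cell size.

    ROS uses log-spaced bins (fluorescence spans orders of magnitude),
    size linear bins.  Standard errors come from a seeded bootstrap over
    cells; bins with fewer than ``min_count`` cells are dropped.
    """
    tracks = list(tracks)
    if covariate == "ros":
        values = np.array([t.ros_au for t in tracks])
    elif covariate == "size":
        values = np.array([t.size_au[0] for t in tracks])
    else:
        raise InvalidInputError(f"unknown covariate {covariate!r}; use 'ros' or 'size'")
    labels = np.array([classify_events(t, window) for t in tracks])

    if np.isscalar(bins):
        lo, hi = values.min(), values.max()
        if covariate == "ros":
            edges = np.logspace(math.log10(max(lo, 1e-12)), math.log10(hi), int(bins) + 1)
        else:
            edges = np.linspace(lo, hi, int(bins) + 1)
        edges[-1] = np.nextafter(edges[-1], np.inf)
    else:
        edges = np.asarray(bins, dtype=float)
    idx = np.digitize(values, edges) - 1

    rng = np.random.default_rng(seed)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        if n < min_count:
            continue
        bin_labels = labels[mask]
        row = {"bin_lo": edges[b], "bin_hi": edges[b + 1], "n": n}
        probs = {ev: float(np.mean(bin_labels == ev)) for ev in EVENTS}
        boot = rng.integers(0, n, size=(n_boot, n))
        for ev in EVENTS:
            hits = (bin_labels == ev).astype(float)
            row[f"p_{ev}"] = probs[ev]
            row[f"sem_{ev}"] = float(np.std(hits[boot].mean(axis=1), ddof=1)) if n > 1 else 0.0
        rows.append(row)
    if not rows:
        raise InsufficientDataError(f"no bin holds at least {min_count} cells")
    table = pd.DataFrame(rows)
    total = table[[f"p_{ev}" for ev in EVENTS]].sum(axis=1)
    assert np.allclose(total, 1.0, atol=1e-9)
    return EventProbabilityCurve(covariate=covariate, edges=edges, table=table)


@dataclass
class PhaseDurations:
    """Cell-cycle phase durations for one cell, hours.

    ``g1_censored`` flags a cell whose Whi5 never left the nucleus (stuck
    in G1): ``g1_h`` is then a lower bound equal to the trace span.
    ``complete`` is True when every phase boundary was recovered.
    """

    cell_id: str
    g1_h: float
    s_h: float = math.nan
    g2_h: float = math.nan
    m_h: float = math.nan
    g1_censored: bool = False
    complete: bool = False

    @property
    def replicative_h(self) -> float:
        """Total S-G2-M duration, hours."""
        return self.s_h + self.g2_h + self.m_h


def _smooth(y: np.ndarray) -> np.ndarray:
    return median_filter(y, size=3, mode="nearest") if y.size >= 3 else y.copy()


def _two_level(y: np.ndarray, n_iter: int = 10) -> tuple[float, float]:
    """Low/high plateau means by iterated two-means thresholding.

    Unlike percentiles, cluster means do not depend on what fraction of
    the trace sits on each plateau, so long post-transition tails do not
    bias the midpoint.
    """
    thr = 0.5 * (float(y.min()) + float(y.max()))
    lo_mean = hi_mean = float(y.mean())
    for _ in range(n_iter):
        lo = y[y <= thr]
        hi = y[y > thr]
        if lo.size == 0 or hi.size == 0:
            return float(y.mean()), float(y.mean())
        lo_mean, hi_mean = float(lo.mean()), float(hi.mean())
        new_thr = 0.5 * (lo_mean + hi_mean)
        if new_thr == thr:
            break
        thr = new_thr
    return lo_mean, hi_mean


def _cross_down(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First downward crossing time of ``level``, linearly interpolated."""
    below = y < level
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (y0 - level) / (y0 - y1)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _fit_ramp(
    t: np.ndarray, dn: np.ndarray, bracket: tuple[float, float]
) -> tuple[float, float] | None:
    """Least-squares change-point fit of a 1 -> 2 piecewise-linear ramp.

    The model is flat at 1 before ``a``, linear between ``a`` and
    ``b = a + w``, and flat at 2 after ``b``.  The ramp start is
    constrained to ``bracket`` — the movie-frame interval containing the
    Whi5 nuclear-exit crossing, which marks the same G1-to-S transition —
    and (a, w) are found by a grid search over the bracket and a
    log-spaced width grid, refined by bounded coordinate descent.  The
    constraint removes the drift degeneracy that an unconstrained
    change-point fit suffers when the ramp spans only one or two frames.
    Returns ``(a, b)`` or None when no upward ramp is detectable.
    """
    from scipy.optimize import minimize_scalar

    if not (dn.max() > 1.5 > dn.min()):
        return None
    dt = float(np.median(np.diff(t)))
    span = float(t[-1] - t[0])
    lo_a, hi_a = bracket

    def sse(a, w):
        model = np.interp(t, [a, a + w], [1.0, 2.0])
        return float(np.sum((model - dn) ** 2))

    w_grid = np.geomspace(0.5 * dt, max(span, 1.5 * dt), 40)
    a_grid = np.linspace(lo_a, hi_a, 13)
    best = min(((sse(a0, w0), a0, w0) for a0 in a_grid for w0 in w_grid), key=lambda z: z[0])
    _, a, w = best
    a_step = (hi_a - lo_a) / 12.0
    for _ in range(3):
        # polish locally around the dense-grid optimum (the loss surface is
        # multimodal globally, so wide bounded line searches can jump valleys)
        r = minimize_scalar(lambda w_: sse(a, w_), bounds=(w / 1.3, w * 1.3), method="bounded")
        w = float(r.x)
        r = minimize_scalar(
            lambda a_: sse(a_, w),
            bounds=(max(lo_a, a - 1.5 * a_step), min(hi_a, a + 1.5 * a_step)),
            method="bounded",
        )
        a = float(r.x)
    if w <= 0 or a + w < t[0] or a > t[-1]:
        return None
    return a, a + w


def extract_phases(trace: CycleTrace) -> PhaseDurations:
    """Recover G1, S, G2 and M+cytokinesis durations from one trace.

    G1 runs from trace start (birth) to the Whi5 nuclear-exit time, found
    as the 3-point-median-smoothed ratio crossing the midpoint of its
    per-cell high/low plateau means (iterated two-means clustering, which
    is insensitive to how long the trace dwells on either plateau).  S is
    the interval over which the normalized DNA copy number ramps from 1
    to 2: the pre-S plateau is the median DNA signal during G1 and the
    post-S plateau the median after mitosis onset, and the ramp is located
    by a least-squares piecewise-linear change-point fit (flat, linear
    rise, flat).  G2 runs from S end to the
    bud/mitosis-onset annotation, and M+cytokinesis from there to the
    division (separation) annotation.  Boundaries are clamped to be
    non-decreasing so durations are non-negative and their sum telescopes.
    """
    if trace.time_h.size < 4:
        raise InsufficientDataError(f"trace {trace.cell_id!r} has fewer than 4 points")
    t = trace.time_h
    w = _smooth(trace.whi5_ratio)
    w_lo, w_hi = _two_level(w)
    if (w_hi - w_lo) < 0.3 * w_hi:
        # Whi5 never leaves its nuclear (high) plateau: stuck in G1.
        return PhaseDurations(
            cell_id=trace.cell_id, g1_h=float(t[-1] - t[0]), g1_censored=True
        )
    exit_time = _cross_down(t, w, 0.5 * (w_lo + w_hi))
    if exit_time is None:  # separation seen but no crossing (degenerate)
        return PhaseDurations(cell_id=trace.cell_id, g1_h=float(t[-1] - t[0]), g1_censored=True)
    g1 = exit_time - t[0]

    d = _smooth(trace.dna_copy)
    band_lo, band_hi = _two_level(d)
    if (band_hi - band_lo) < 0.3 * band_lo:
        # DNA copy never doubled: no S phase observed.
        return PhaseDurations(cell_id=trace.cell_id, g1_h=g1)
    # plateau levels anchored on the cell-cycle structure when available:
    # pre-S = G1 frames (before Whi5 exit), post-S = frames after mitosis onset
    pre = d[t <= exit_time]
    d_lo = float(np.median(pre)) if pre.size else band_lo
    onset_flags = trace.bud_times
    post = d[t >= onset_flags[0]] if onset_flags.size else np.empty(0)
    d_hi = float(np.median(post)) if post.size else band_hi
    if d_hi <= d_lo:
        d_lo, d_hi = band_lo, band_hi
    dn = 1.0 + (d - d_lo) / (d_hi - d_lo)  # normalized to the 1 and 2 plateaus
    # the ramp must start inside the frame interval holding the Whi5 crossing
    k = int(np.searchsorted(t, exit_time, side="right")) - 1
    k = min(max(k, 0), t.size - 2)
    ramp = _fit_ramp(t, dn, (float(t[k]), float(t[k + 1])))
    if ramp is None:
        return PhaseDurations(cell_id=trace.cell_id, g1_h=g1)
    s_start, s_end = ramp
    s_start = max(s_start, float(t[0]))
    s_end = max(s_end, s_start)
    s_h = s_end - s_start
    # The fitted ramp start marks the same G1-exit transition as the Whi5
    # crossing but with sub-frame resolution (the Whi5 drop is a step
    # between frames while the ramp spans them): use it as the G1 boundary.
    g1 = max(s_start - float(t[0]), 0.0)

    onset_candidates = trace.bud_times[trace.bud_times >= s_start]
    division_candidates = trace.division_times[trace.division_times >= s_start]
    if onset_candidates.size == 0 or division_candidates.size == 0:
        return PhaseDurations(cell_id=trace.cell_id, g1_h=g1, s_h=s_h)
    onset = max(float(onset_candidates[0]), s_end)
    division = max(float(division_candidates[-1]), onset)
    return PhaseDurations(
        cell_id=trace.cell_id,
        g1_h=g1,
        s_h=s_h,
        g2_h=onset - s_end,
        m_h=division - onset,
        complete=True,
    )


@dataclass
class PhaseSummary:
    """Per-phase means over cells, with censored G1 reported separately."""

    table: pd.DataFrame  # index: phase; columns: mean_h, sem_h, n
    total_replicative_h: float
    n_complete: int
    g1_censored_lower_bound_h: float | None = None
    n_g1_censored: int = 0

    @property
    def total_replicative_days(self) -> float:
        return self.total_replicative_h / HOURS_PER_DAY


def phase_summary(phases: Iterable[PhaseDurations]) -> PhaseSummary:
    """Average phase durations over individual cells.

    Means use completed cycles only; cells stuck in G1 contribute a
    separate lower bound on G1.  The total replicative (S-G2-M) duration
    is the mean of the per-cell sums over completed cycles.
    """
    phases = list(phases)
    complete = [p for p in phases if p.complete]
    censored = [p for p in phases if p.g1_censored]
    if len(complete) < 2:
        raise InsufficientDataError(f"need >= 2 completed cycles, got {len(complete)}")
    cols = {"G1": "g1_h", "S": "s_h", "G2": "g2_h", "M": "m_h"}
    rows = {}
    for phase, attr in cols.items():
        vals = np.array([getattr(p, attr) for p in complete])
        rows[phase] = {
            "mean_h": float(vals.mean()),
            "sem_h": float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0,
            "n": len(vals),
        }
    total = float(np.mean([p.replicative_h for p in complete]))
    return PhaseSummary(
        table=pd.DataFrame(rows).T,
        total_replicative_h=total,
        n_complete=len(complete),
        g1_censored_lower_bound_h=(
            float(np.mean([p.g1_h for p in censored])) if censored else None
        ),
        n_g1_censored=len(censored),
    )


@dataclass
class LifeCurve:
    """Mean cell size from birth to death on an age grid (days)."""

    age_d: np.ndarray
    mean_size: np.ndarray
    sem_size: np.ndarray
    lifespan_d: float | None
    birth_size: float
    burst_size: float | None

    def size_at(self, age_d) -> np.ndarray:
        return np.interp(np.asarray(age_d, dtype=float), self.age_d, self.mean_size)


def reconstruct_life_curve(
    tracks: Iterable[CellTrack],
    age_grid_d: Sequence[float] | None = None,
    min_cells: int = 3,
) -> LifeCurve:
    """Average-cell size trajectory from birth to burst.

    Tracks are aligned at birth and averaged per age bin while at least
    ``min_cells`` birth-aligned tracks cover the bin.  Beyond that, the
    curve is chained forward using the mean growth increment observed at
    each size (pooled over all tracks), until it reaches the mean size at
    burst; the age at which it does is the mean lifespan.  If no cell
    died, the lifespan is undefined (None).
    """
    tracks = list(tracks)
    born = [tr for tr in tracks if tr.born_at is not None]
    if not born:
        born = tracks  # fall back to aligning at track start
    burst_sizes = [tr.size_au[-1] for tr in tracks if tr.death_time is not None]
    burst_size = float(np.mean(burst_sizes)) if burst_sizes else None

    starts = [tr.born_at if tr.born_at is not None else tr.span[0] for tr in born]
    max_age_h = max(tr.span[1] - s for tr, s in zip(born, starts))
    if age_grid_d is None:
        age_grid_d = np.arange(0.0, max_age_h / HOURS_PER_DAY + 0.5, 0.5)
    age_grid_d = np.asarray(age_grid_d, dtype=float)
    age_h = age_grid_d * HOURS_PER_DAY

    # direct birth-aligned means while enough cells remain observed
    mean_size, sem_size, counts = [], [], []
    for a in age_h:
        vals = []
        for tr, s in zip(born, starts):
            if s + a <= tr.span[1] + 1e-9:
                vals.append(np.interp(s + a, tr.time_h, tr.size_au))
        counts.append(len(vals))
        if vals:
            vals = np.array(vals)
            mean_size.append(vals.mean())
            sem_size.append(vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0)
        else:
            mean_size.append(np.nan)
            sem_size.append(np.nan)
    mean_size = np.array(mean_size)
    sem_size = np.array(sem_size)
    direct = np.array(counts) >= min_cells
    if not direct.any():
        raise InsufficientDataError("no age bin is covered by enough birth-aligned tracks")

    # mean growth increment per size bin, pooled over every track
    sizes_all, rates_all = [], []
    for tr in tracks:
        if tr.time_h.size < 2:
            continue
        dt = np.diff(tr.time_h)
        ds = np.diff(tr.size_au)
        sizes_all.append(tr.size_au[:-1])
        rates_all.append(ds / dt)
    sizes_all = np.concatenate(sizes_all)
    rates_all = np.concatenate(rates_all)
    order = np.argsort(sizes_all)
    sizes_sorted, rates_sorted = sizes_all[order], rates_all[order]

    def growth_rate(size: float) -> float:
        # mean rate among the nearest size observations (robust local mean)
        k = min(25, sizes_sorted.size)
        i = np.searchsorted(sizes_sorted, size)
        lo = max(0, i - k // 2)
        return float(np.mean(rates_sorted[lo : lo + k]))

    # chain the mean curve beyond direct coverage
    last = int(np.max(np.nonzero(direct)))
    for i in range(last + 1, age_h.size):
        dt = age_h[i] - age_h[i - 1]
        rate = max(growth_rate(mean_size[i - 1]), 0.0)
        mean_size[i] = mean_size[i - 1] + rate * dt
        sem_size[i] = np.nan
    mean_size = np.maximum.accumulate(np.where(np.isnan(mean_size), -np.inf, mean_size))
    mean_size[np.isneginf(mean_size)] = np.nan

    lifespan_d = None
    if burst_size is not None:
        reached = mean_size >= burst_size
        if reached.any():
            j = int(np.argmax(reached))
            if j == 0:
                lifespan_d = float(age_grid_d[0])
            else:
                s0, s1 = mean_size[j - 1], mean_size[j]
                frac = (burst_size - s0) / (s1 - s0) if s1 > s0 else 1.0
                lifespan_d = float(age_grid_d[j - 1] + frac * (age_grid_d[j] - age_grid_d[j - 1]))
        else:
            lifespan_d = float(age_grid_d[-1])  # not reached within grid: lower bound
    return LifeCurve(
        age_d=age_grid_d,
        mean_size=mean_size,
        sem_size=sem_size,
        lifespan_d=lifespan_d,
        birth_size=float(mean_size[np.isfinite(mean_size)][0]),
        burst_size=burst_size,
    )


def replicative_lifespan(
    life_curve: LifeCurve,
    p_divide_vs_size: Callable[[float], float] | EventProbabilityCurve,
    mean_cycle_time_h: float,
) -> float:
    """Expected number of divisions over an average cell's lifetime.

    The lifetime is partitioned into consecutive windows of one mean cycle
    time; each window contributes the probability of dividing at the mean
    size reached in that window.
    """
    if mean_cycle_time_h <= 0:
        raise InvalidInputError("mean_cycle_time_h must be positive")
    if life_curve.lifespan_d is None:
        raise InvalidInputError("life curve has no defined lifespan (no dying cells)")
    if isinstance(p_divide_vs_size, EventProbabilityCurve):
        curve = p_divide_vs_size
        if curve.covariate != "size":
            raise InvalidInputError("probability curve must use the 'size' covariate")
        c_lo, c_hi = curve.table["bin_lo"].min(), curve.table["bin_hi"].max()
        s_lo = np.nanmin(life_curve.mean_size)
        s_hi = np.nanmax(life_curve.mean_size)
        if s_hi < c_lo or s_lo > c_hi:
            raise InvalidInputError("life curve and probability curve share no size range")
        p_func = lambda s: float(curve.interp_prob("duplicates", s))
    else:
        p_func = p_divide_vs_size
    lifespan_h = life_curve.lifespan_d * HOURS_PER_DAY
    expected = 0.0
    start = 0.0
    while start < lifespan_h:
        end = min(start + mean_cycle_time_h, lifespan_h)
        mid_age_d = 0.5 * (start + end) / HOURS_PER_DAY
        weight = (end - start) / mean_cycle_time_h  # partial final window
        expected += weight * p_func(float(life_curve.size_at(mid_age_d)))
        start = end
    return expected
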