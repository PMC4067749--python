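"""Fluorophore photophysics and exchange kinetics.

Covers the tdEos/GFP state scheme (slow maturation into the green state,
irreversible 405 nm photoconversion to red, reversible dark states with
405 nm rescue, illumination-dependent bleaching, fixation-induced
conversion), maturation half-time fitting of cycloheximide-block time
courses, pulse-chase retention classification, and recovery-time estimation
after targeted photobleaching.

All rates are per minute; illumination schedules are in minutes.  Dark-state
and bleaching defaults are order-of-magnitude placeholders (no measured
values exist); the maturation default corresponds to a 40 min half-time at
25 C.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "STATES",
    "FluorophoreStateModel",
    "IlluminationSegment",
    "IlluminationSchedule",
    "EnsembleResult",
    "MaturationFit",
    "RecoveryRecord",
    "simulate_ensemble",
    "fit_maturation_halftime",
    "classify_pulse_chase",
    "frap_recovery_time",
    "pooled_mean_recovery",
]

STATES = ("immature", "green", "green_dark", "red", "red_dark", "bleached")

CHANNELS = ("none", "green_ex", "red_ex")


@dataclass
class FluorophoreStateModel:
    """Kinetic scheme of tdEos/GFP states and transition rates (min^-1).

    ``bleached`` is absorbing.  Maturation proceeds regardless of
    illumination; bleaching and dark-state entry require the matching
    excitation channel; dark-state exit is spontaneous.  405 nm pulses act
    as instantaneous Bernoulli flips (green->red photoconversion, dark-state
    rescue).
    """

    k_mat: float = math.log(2) / 40.0  # 40 min half-time
    p_pc: float = 0.9
    k_bleach_green: float = 0.1  # placeholder, not a measured value
    k_bleach_red: float = 0.1  # placeholder
    k_dark_on: float = 0.5  # placeholder
    k_dark_off: float = 2.0  # placeholder
    p_rescue_405: float = 0.5  # placeholder
    fixation_conversion_prob: float = 0.1  # placeholder

    def __post_init__(self) -> None:
        for name in ("k_mat", "k_bleach_green", "k_bleach_red", "k_dark_on", "k_dark_off"):
            if getattr(self, name) < 0 or not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be a finite nonnegative rate")
        for name in ("p_pc", "p_rescue_405", "fixation_conversion_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def maturation_halftime(self) -> float:
        return math.log(2) / self.k_mat if self.k_mat > 0 else math.inf

    def green_fraction(self, t) -> np.ndarray:
        """Closed-form green occupancy for molecules born at t=0 (maturation only)."""
        return 1.0 - np.exp(-self.k_mat * np.asarray(t, dtype=np.float64))

    def transitions(self, channel: str) -> dict[str, list[tuple[float, str]]]:
        """Active CTMC transitions per state under one illumination channel."""
        if channel not in CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        trans: dict[str, list[tuple[float, str]]] = {s: [] for s in STATES}
        trans["immature"].append((self.k_mat, "green"))
        trans["green_dark"].append((self.k_dark_off, "green"))
        trans["red_dark"].append((self.k_dark_off, "red"))
        if channel == "green_ex":
            trans["green"].append((self.k_bleach_green, "bleached"))
            trans["green"].append((self.k_dark_on, "green_dark"))
        if channel == "red_ex":
            trans["red"].append((self.k_bleach_red, "bleached"))
            trans["red"].append((self.k_dark_on, "red_dark"))
        return trans


@dataclass(frozen=True)
class IlluminationSegment:
    duration_min: float
    channel: str = "none"
    irradiance: str | None = None

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("segment durations must be > 0")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass
class IlluminationSchedule:
    """Piecewise-constant illumination with instantaneous 405 nm pulses."""

    segments: list[IlluminationSegment] = field(default_factory=list)
    pulses_405: list[float] = field(default_factory=list)  # absolute times, min

    @property
    def total_duration(self) -> float:
        return sum(s.duration_min for s in self.segments)

    def segment_edges(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([s.duration_min for s in self.segments])])

    def time_grid(self, dt: float = 1.0) -> np.ndarray:
        """Uniform grid over the schedule, merged with segment edges and pulses."""
        grid = np.arange(0.0, self.total_duration + 0.5 * dt, dt)
        extra = np.array(list(self.segment_edges()) + list(self.pulses_405))
        return np.unique(np.round(np.concatenate([grid, extra]), 9))

    def channel_at(self, t: float) -> str:
        edges = self.segment_edges()
        idx = int(np.searchsorted(edges, t, side="right")) - 1
        idx = min(max(idx, 0), len(self.segments) - 1)
        return self.segments[idx].channel


@dataclass
class EnsembleResult:
    times: np.ndarray
    occupancy: dict[str, np.ndarray]  # state -> fraction at each time
    trajectories: list[list[tuple[float, str]]] | None = None

    def fraction(self, state: str) -> np.ndarray:
        return self.occupancy[state]


def _gillespie_segment(state, t0, t1, trans, rng, events):
    t = t0
    while True:
        active = trans[state]
        total = sum(rate for rate, _ in active)
        if total <= 0:
            return state
        t = t + rng.exponential(1.0 / total)
        if t >= t1:
            return state
        u = rng.uniform(0.0, total)
        acc = 0.0
        for rate, dest in active:
            acc += rate
            if u <= acc:
                state = dest
                break
        events.append((t, state))


def _apply_pulse(state, model, rng):
    if state == "green" and rng.uniform() < model.p_pc:
        return "red"
    if state == "green_dark" and rng.uniform() < model.p_rescue_405:
        return "green"
    if state == "red_dark" and rng.uniform() < model.p_rescue_405:
        return "red"
    return state


def simulate_ensemble(
    model: FluorophoreStateModel,
    schedule: IlluminationSchedule,
    n_fluorophores: int,
    synthesis_times: np.ndarray | None = None,
    seed: int | None = None,
    grid_dt: float = 1.0,
    initial_state: str = "immature",
    return_trajectories: bool = False,
) -> EnsembleResult:
    """Continuous-time Markov simulation of a fluorophore ensemble.

    Each molecule starts in ``initial_state`` at its synthesis time (default
    all at t=0) and evolves with exponential waiting times under the
    schedule's piecewise-constant transition rates; 405 nm pulses are applied
    as Bernoulli state flips at their scheduled instants.  Reproducible under
    ``seed``.  Returns per-state occupancies on the schedule's time grid.
    """
    if n_fluorophores < 1:
        raise ValueError("n_fluorophores must be >= 1")
    if initial_state not in STATES:
        raise ValueError(f"unknown state {initial_state!r}")
    rng = np.random.default_rng(seed)
    if synthesis_times is None:
        synthesis_times = np.zeros(n_fluorophores)
    synthesis_times = np.asarray(synthesis_times, dtype=np.float64)
    if synthesis_times.shape != (n_fluorophores,):
        raise ValueError("synthesis_times must have length n_fluorophores")

    edges = schedule.segment_edges()
    pulses = sorted(schedule.pulses_405)
    # breakpoints: segment edges and pulse instants, in order
    breaks = np.unique(np.concatenate([edges, pulses])) if pulses else edges
    grid = schedule.time_grid(grid_dt)

    trans_cache = {seg.channel: model.transitions(seg.channel) for seg in schedule.segments}
    state_index = {s: i for i, s in enumerate(STATES)}
    count_mat = np.zeros((len(STATES), grid.size))
    trajectories: list[list[tuple[float, str]]] | None = [] if return_trajectories else None

    for i in range(n_fluorophores):
        birth = synthesis_times[i]
        state = initial_state
        events: list[tuple[float, str]] = [(birth, state)]
        for j in range(len(breaks) - 1):
            t0, t1 = breaks[j], breaks[j + 1]
            if t1 <= birth:
                continue
            t0 = max(t0, birth)
            channel = schedule.channel_at(0.5 * (t0 + t1))
            state = _gillespie_segment(
                state, t0, t1, trans_cache.setdefault(channel, model.transitions(channel)), rng, events
            )
            if t1 in pulses or any(abs(t1 - p) < 1e-12 for p in pulses):
                new = _apply_pulse(state, model, rng)
                if new != state:
                    state = new
                    events.append((t1, state))
        # terminal pulses exactly at total duration already handled above
        ev_t = np.array([t for t, _ in events])
        codes = np.array([state_index[s] for _, s in events])
        idx = np.searchsorted(ev_t, grid, side="right") - 1
        valid = (idx >= 0) & (grid >= birth - 1e-12)
        sel = np.nonzero(valid)[0]
        np.add.at(count_mat, (codes[idx[sel]], sel), 1)
        if return_trajectories:
            trajectories.append(events)

    occupancy = {s: count_mat[state_index[s]] / n_fluorophores for s in STATES}
    return EnsembleResult(times=grid, occupancy=occupancy, trajectories=trajectories)


def apply_fixation(states: list[str], model: FluorophoreStateModel, rng) -> list[str]:
    """PFA fixation converts some green fluorophores to the red state."""
    out = []
    for s in states:
        if s == "green" and rng.uniform() < model.fixation_conversion_prob:
            out.append("red")
        else:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Maturation half-time fitting


@dataclass
class MaturationFit:
    t_half: float
    amplitude: float
    plateau_empirical: float | None
    t_block: float
    stderr: tuple[float, float]
    residual_rms: float


def fit_maturation_halftime(
    timepoints,
    intensities,
    t_block: float = 0.0,
    plateau_after_min: float = 100.0,
) -> MaturationFit:
    """Fit ``I(t) = A (1 - exp(-ln2 (t - t_block)/t_half))`` for t >= t_block.

    Two plateau estimates are reported: the fitted amplitude ``A`` and the
    empirical mean of all points beyond ``plateau_after_min`` (the
    normalization rule used for cycloheximide-block courses).  When no point
    lies beyond that time a warning is emitted and only the fitted amplitude
    is available.
    """
    t = np.asarray(timepoints, dtype=np.float64)
    y = np.asarray(intensities, dtype=np.float64)
    if t.shape != y.shape:
        raise ValueError("timepoints and intensities must have equal length")
    mask = t >= t_block
    t, y = t[mask], y[mask]
    if t.size < 5:
        raise ValueError("need >= 5 timepoints spanning the rise and plateau")

    def rise(tt, amp, t_half):
        return amp * (1.0 - np.exp(-math.log(2) * (tt - t_block) / t_half))

    a0 = max(float(np.max(y)), 1e-12)
    try:
        popt, pcov = curve_fit(
            rise, t, y, p0=(a0, 40.0), bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise RuntimeError(f"maturation fit did not converge: {exc}") from exc
    amp, t_half = float(popt[0]), float(popt[1])
    perr = tuple(float(e) for e in np.sqrt(np.diag(pcov)))
    resid = y - rise(t, *popt)

    late = t > plateau_after_min
    if np.any(late):
        plateau = float(np.mean(y[late]))
    else:
        warnings.warn(
            f"no timepoints beyond {plateau_after_min} min: empirical plateau "
            "rule inapplicable, using fitted amplitude",
            stacklevel=2,
        )
        plateau = None
    return MaturationFit(
        t_half=t_half,
        amplitude=amp,
        plateau_empirical=plateau,
        t_block=t_block,
        stderr=perr,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# Pulse-chase classification


def classify_pulse_chase(
    pulse_signal: float,
    chase_signal: float,
    second_pc_signal: float | None = None,
    bleach_correction: float = 1.0,
    retention_fraction: float = 0.5,
    loss_fraction: float = 0.25,
    detection_threshold: float = 0.0,
) -> str:
    """Classify one cluster as retained / lost_replaced / ambiguous.

    ``bleach_correction`` is the surviving fraction expected from imaging
    alone (supplied, or estimated from non-S cells); the chase signal is
    divided by it before thresholding.  A second-photoconversion control
    below the detection threshold flags the cluster ``out_of_range`` (the
    Z-stack missed it) and excludes it from classification.  Thresholds are
    fractions of the pulse signal, so the call is invariant to global
    intensity rescaling.
    """
    if pulse_signal is None or not np.isfinite(pulse_signal) or pulse_signal <= 0:
        raise ValueError("missing or nonpositive pulse measurement")
    if not 0 < loss_fraction < retention_fraction:
        raise ValueError("need 0 < loss_fraction < retention_fraction")
    if second_pc_signal is not None and second_pc_signal <= detection_threshold:
        return "out_of_range"
    ratio = (chase_signal / bleach_correction) / pulse_signal
    if ratio >= retention_fraction:
        return "retained"
    if ratio <= loss_fraction:
        return "lost_replaced"
    return "ambiguous"


# ---------------------------------------------------------------------------
# Recovery after targeted photobleaching


@dataclass
class RecoveryRecord:
    cell_id: str | int | None
    stage: str | None
    recovery_time_min: float | None  # None when censored
    censored: bool
    sampling_interval_min: float
    threshold: float


def frap_recovery_time(
    times_min,
    photons,
    baseline_sigma: float,
    sampling_interval_min: float,
    background: float = 0.0,
    cell_id=None,
    stage=None,
) -> RecoveryRecord:
    """First timepoint at which fluorescence is detected again.

    Detection threshold is ``background + 3 * baseline_sigma``.  The first
    post-bleach point must be below threshold (otherwise nothing was
    bleached); a series that never crosses the threshold is censored.
    """
    t = np.asarray(times_min, dtype=np.float64)
    y = np.asarray(photons, dtype=np.float64)
    if t.size == 0:
        raise ValueError("empty time series")
    if sampling_interval_min <= 0:
        raise ValueError("sampling_interval must be > 0")
    threshold = background + 3.0 * baseline_sigma
    if y[0] > threshold:
        raise ValueError("first post-bleach point is above the detection threshold")
    above = np.nonzero(y > threshold)[0]
    if above.size == 0:
        return RecoveryRecord(cell_id, stage, None, True, sampling_interval_min, threshold)
    return RecoveryRecord(
        cell_id, stage, float(t[above[0]]), False, sampling_interval_min, threshold
    )


def pooled_mean_recovery(means, sample_sizes) -> float:
    """Sample-size-weighted mean recovery time across stages."""
    means = np.asarray(means, dtype=np.float64)
    n = np.asarray(sample_sizes, dtype=np.float64)
    if means.shape != n.shape or means.size == 0:
        raise ValueError("means and sample_sizes must be equal-length, nonempty")
    if np.any(n < 1):
        raise ValueError("all sample sizes must be >= 1")
    return float(np.sum(means * n) / np.sum(n))
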