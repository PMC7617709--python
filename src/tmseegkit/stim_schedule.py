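"""Phase-locked tACS-iTBS schedule generation and validation.

Convention: the tACS current is ``envelope(t) * sin(2*pi*freq*t)``, so the
crest of the waveform sits at phase 90 degrees.  All phases below use this
sine convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TACSParams",
    "TBSParams",
    "StimSchedule",
    "tacs_waveform",
    "build_schedule",
    "pulse_phases",
    "summarize",
]

CREST_DEG = 90.0


@dataclass(frozen=True)
class TACSParams:
    """Sinusoidal tACS parameters (amplitude = peak_to_peak / 2)."""

    freq: float = 5.0
    peak_to_peak: float = 1.0
    ramp_up_s: float = 10.0
    plateau_s: float = 220.0
    ramp_down_s: float = 10.0

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise ValueError("tACS frequency must be positive")
        for name in ("peak_to_peak", "ramp_up_s", "plateau_s", "ramp_down_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def amplitude(self) -> float:
        return self.peak_to_peak / 2.0

    @property
    def total_s(self) -> float:
        return self.ramp_up_s + self.plateau_s + self.ramp_down_s


@dataclass(frozen=True)
class TBSParams:
    """Intermittent theta-burst parameters.

    Defaults: triplets of 50 Hz pulses every 200 ms; 2-s trains separated
    by 8-s breaks, 20 trains; bursts start 30 s after tACS onset with the
    second pulse of each triplet locked to the crest.
    """

    burst_freq: float = 50.0
    pulses_per_burst: int = 3
    burst_period_s: float = 0.2
    train_on_s: float = 2.0
    train_off_s: float = 8.0
    n_trains: int = 20
    start_offset_s: float = 30.0
    locked_pulse_index: int = 2

    def __post_init__(self) -> None:
        if self.pulses_per_burst < 1:
            raise ValueError("pulses_per_burst must be >= 1")
        if self.pulses_per_burst > 1 and \
                (self.pulses_per_burst - 1) / self.burst_freq >= self.burst_period_s:
            raise ValueError("burst does not fit inside burst_period_s")
        if not (1 <= self.locked_pulse_index <= self.pulses_per_burst):
            raise ValueError("locked_pulse_index out of range")

    @property
    def bursts_per_train(self) -> int:
        return int(round(self.train_on_s / self.burst_period_s))


@dataclass(frozen=True)
class StimSchedule:
    """Explicit pulse-time schedule plus tACS envelope description."""

    mode: str  # "active" | "sham"
    pulse_times: np.ndarray = field(repr=False)
    pulse_phase_deg: np.ndarray = field(repr=False)
    pulse_train: np.ndarray = field(repr=False)
    pulse_burst: np.ndarray = field(repr=False)
    pulse_in_burst: np.ndarray = field(repr=False)
    locked_mask: np.ndarray = field(repr=False)
    tacs_envelope: tuple[tuple[float, float], ...]  # (time_s, amplitude_mA)
    total_duration_s: float
    tacs: TACSParams = None
    tbs: TBSParams = None

    def __post_init__(self) -> None:
        t = np.asarray(self.pulse_times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("pulse_times must be strictly increasing")
        object.__setattr__(self, "pulse_times", t)

    @property
    def n_pulses(self) -> int:
        return self.pulse_times.size

    def table(self):
        """Pulse table as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame({
            "index": np.arange(self.n_pulses),
            "time_s": self.pulse_times,
            "phase_deg": self.pulse_phase_deg,
            "train": self.pulse_train,
            "burst": self.pulse_burst,
            "pulse_in_burst": self.pulse_in_burst,
            "locked": self.locked_mask.astype(int),
        })


def _envelope_value(envelope, t: float) -> float:
    pts = list(envelope)
    if not pts or t <= pts[0][0]:
        return pts[0][1] if pts and t == pts[0][0] else 0.0
    for (t0, a0), (t1, a1) in zip(pts[:-1], pts[1:]):
        if t0 <= t <= t1:
            if t1 == t0:
                return a1
            return a0 + (a1 - a0) * (t - t0) / (t1 - t0)
    return pts[-1][1] if t <= pts[-1][0] else 0.0


def active_envelope(params: TACSParams) -> tuple[tuple[float, float], ...]:
    a = params.amplitude
    t1 = params.ramp_up_s
    t2 = t1 + params.plateau_s
    t3 = t2 + params.ramp_down_s
    return ((0.0, 0.0), (t1, a), (t2, a), (t3, 0.0))


def sham_envelope(params: TACSParams, ramp_total_s: float = 10.0
                  ) -> tuple[tuple[float, float], ...]:
    """Sham: ramp up then immediately down over ``ramp_total_s`` seconds."""
    half = ramp_total_s / 2.0
    return ((0.0, 0.0), (half, params.amplitude), (ramp_total_s, 0.0))


def tacs_waveform(params: TACSParams, t, envelope=None):
    """tACS current (mA) at time(s) ``t`` seconds from protocol start."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be non-negative")
    env = envelope if envelope is not None else active_envelope(params)
    e = np.array([_envelope_value(env, float(x)) for x in np.atleast_1d(tt)])
    out = e * np.sin(2.0 * np.pi * params.freq * np.atleast_1d(tt))
    return out if tt.ndim else float(out[0])


def build_schedule(tacs: TACSParams = TACSParams(),
                   tbs: TBSParams = TBSParams(),
                   mode: str = "active",
                   sham_ramp_total_s: float = 10.0,
                   phase_tol_deg: float = 1e-6) -> StimSchedule:
    """Construct the pulse schedule with the locked pulse on tACS crests.

    The first locked pulse is placed on the first crest at or after
    ``start_offset_s``; trains repeat every ``train_on_s + train_off_s``.
    Sham mode uses the identical pulse grid with a short up-down tACS
    envelope at the start.
    """
    if mode not in ("active", "sham"):
        raise ValueError("mode must be 'active' or 'sham'")
    period = 1.0 / tacs.freq
    # crest and burst grids must be commensurate
    for name, interval in (("burst_period_s", tbs.burst_period_s),
                           ("train period", tbs.train_on_s + tbs.train_off_s)):
        cycles = interval / period
        if abs(cycles - round(cycles)) > 1e-9:
            raise ValueError(
                f"{name} = {interval} s is not an integer number of tACS "
                f"cycles (period {period} s); locked pulses cannot all sit "
                "on crests — periods are incommensurate"
            )
    crest0 = (CREST_DEG / 360.0) * period
    k = math.ceil((tbs.start_offset_s - crest0) / period - 1e-9)
    first_crest = crest0 + max(k, 0) * period

    times, phases, trains, bursts, in_burst, locked = [], [], [], [], [], []
    train_period = tbs.train_on_s + tbs.train_off_s
    for tr in range(tbs.n_trains):
        t_train = first_crest + tr * train_period
        for b in range(tbs.bursts_per_train):
            t_crest = t_train + b * tbs.burst_period_s
            for j in range(1, tbs.pulses_per_burst + 1):
                t_pulse = t_crest + (j - tbs.locked_pulse_index) / tbs.burst_freq
                times.append(t_pulse)
                trains.append(tr)
                bursts.append(b)
                in_burst.append(j)
                locked.append(j == tbs.locked_pulse_index)
    times = np.array(times)
    trains = np.array(trains, dtype=int)
    bursts = np.array(bursts, dtype=int)
    in_burst = np.array(in_burst, dtype=int)
    locked = np.array(locked, dtype=bool)

    phases = (360.0 * tacs.freq * times) % 360.0
    if mode == "active" and locked.any():
        err = np.abs((phases[locked] - CREST_DEG + 180.0) % 360.0 - 180.0)
        if np.any(err > max(phase_tol_deg, 1e-6)):
            raise ValueError(
                "locked pulses deviate from the crest by up to "
                f"{err.max():.3g} deg — incommensurate periods"
            )
    envelope = (active_envelope(tacs) if mode == "active"
                else sham_envelope(tacs, sham_ramp_total_s))
    last_pulse = float(times[-1]) if times.size else 0.0
    total = max(envelope[-1][0], last_pulse)
    return StimSchedule(mode, times, phases, trains, bursts, in_burst,
                        locked, envelope, total, tacs, tbs)


def pulse_phases(schedule: StimSchedule, tacs: TACSParams | None = None
                 ) -> np.ndarray:
    """Recompute the tACS phase (deg, sine convention) of every pulse."""
    params = tacs if tacs is not None else schedule.tacs
    if params is None:
        raise ValueError("tACS parameters required")
    return (360.0 * params.freq * schedule.pulse_times) % 360.0


def circular_mean_sd_deg(phases_deg: np.ndarray) -> tuple[float, float]:
    rad = np.deg2rad(np.asarray(phases_deg, dtype=float))
    z = np.exp(1j * rad).mean()
    r = min(abs(z), 1.0)
    mean = np.rad2deg(np.angle(z)) % 360.0
    sd = np.rad2deg(np.sqrt(abs(min(2.0 * np.log(r), 0.0)))) if r > 0 else np.inf
    return float(mean), float(abs(sd))


def summarize(schedule: StimSchedule) -> dict:
    """Counts, duration and locked-pulse phase statistics."""
    locked = schedule.locked_mask
    if schedule.n_pulses and locked.any():
        mean, sd = circular_mean_sd_deg(schedule.pulse_phase_deg[locked])
    else:
        mean, sd = float("nan"), float("nan")
    return {
        "mode": schedule.mode,
        "n_pulses": int(schedule.n_pulses),
        "n_trains": int(len(np.unique(schedule.pulse_train))
                        if schedule.n_pulses else 0),
        "total_duration_s": float(schedule.total_duration_s),
        "locked_phase_mean_deg": mean,
        "locked_phase_circ_sd_deg": sd,
        "phase_locked": schedule.mode == "active",
    }
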