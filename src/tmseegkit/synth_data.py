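"""Synthetic cohorts with known ground truth.

TMS-EEG cohorts: per subject x session(active/sham) x time(pre/post) x
intensity(sub/supra), each epoch the sum of spatial component templates
(early local positivity, vertex-negative N100-like wave, central
P200-like wave) times Gaussian time courses, band-limited oscillatory
bursts confined to the analysis ROIs, and 1/f background noise.

Resting cohorts: a hidden-state Markov sequence over four orthogonalized
topographies, each state emitting its template times a smooth positive
envelope, plus 1/f noise.  True labels are returned.

Determinism: every random draw derives from ``(seed, subject, cell)``
seed sequences, so the same seed reproduces the dataset exactly and
subject-level traits (e.g. baseline burst power) are shared across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .data_model import Cell, EpochedEEG
from .microstates import canonical_templates
from .montage import ChannelMontage, default_montage
from .tfr import DEFAULT_ROIS

__all__ = [
    "CohortConfig",
    "RestingConfig",
    "StudyDataset",
    "RestingDataset",
    "synth_tep_cohort",
    "synth_resting",
    "synth_resting_cohort",
    "ground_truth",
]

SESSIONS = ("active", "sham")
TIMES = ("pre", "post")
INTENSITIES = ("sub", "supra")

_BAND_FREQ = {"theta": 5.5, "beta": 18.0, "gamma": 45.0}


def _zero_by_cond() -> dict:
    return {"active": 0.0, "sham": 0.0}


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for a TMS-EEG cohort."""

    n_subjects: int = 24
    srate: float = 1000.0
    n_trials: int = 20
    epoch_ms: tuple[float, float] = (-500.0, 500.0)
    # component amplitudes (microvolts) and per-condition post shifts
    amp_early: float = 4.0
    amp_n100: float = -6.0
    amp_p200: float = 5.0
    n100_post_delta: Mapping[str, float] = field(default_factory=_zero_by_cond)
    p200_post_delta: Mapping[str, float] = field(default_factory=_zero_by_cond)
    # oscillatory bursts (amplitude in microvolts at ROI electrodes)
    burst_amp: Mapping[str, float] = field(
        default_factory=lambda: {"theta": 1.5, "beta": 1.2, "gamma": 1.2})
    burst_subject_sd_db: float = 0.0
    burst_change_slope: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {b: _zero_by_cond() for b in _BAND_FREQ})
    burst_post_delta_db: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {b: _zero_by_cond() for b in _BAND_FREQ})
    intensity_gain: Mapping[str, float] = field(
        default_factory=lambda: {"sub": 1.0, "supra": 1.3})
    noise_sd: float = 1.0
    noise_exponent: float = 1.0
    intensities: tuple[str, ...] = INTENSITIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.burst_subject_sd_db < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.srate < 2 * 70.0 * 2:
            raise ValueError("srate must be at least 280 samples/s")


@dataclass(frozen=True)
class RestingConfig:
    """Generating parameters for resting-state EEG with hidden states."""

    n_subjects: int = 25
    srate: float = 250.0
    k: int = 4
    mean_dwell_ms: float = 65.0
    duration_s: float = 120.0
    snr: float = 4.0
    carrier_hz: float = 10.5
    noise_exponent: float = 1.0
    dwell_modifiers: Mapping[tuple[str, str], tuple[float, ...]] = field(
        default_factory=dict)  # (session, time) -> per-class multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_dwell_ms <= 0:
            raise ValueError("mean dwell must be positive")


@dataclass
class StudyDataset:
    epochs: dict  # (subject, session, time, intensity) -> EpochedEEG
    truth: dict
    montage: ChannelMontage

    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.epochs})


@dataclass
class RestingDataset:
    recordings: dict  # (subject, session, time) -> (data ch x samp, labels)
    truth: dict
    montage: ChannelMontage
    srate: float


# ---------------------------------------------------------------------------
# building blocks


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                srate: float, sd: float, exponent: float) -> np.ndarray:
    """1/f^alpha noise, per-channel independent, unit-free scaling to sd."""
    if sd == 0:
        return np.zeros((n_ch, n_samp))
    freqs = np.fft.rfftfreq(n_samp, 1.0 / srate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    spec = (rng.standard_normal((n_ch, freqs.size))
            + 1j * rng.standard_normal((n_ch, freqs.size))) * shaping
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    x = x / x.std(axis=1, keepdims=True)
    return x * sd


def _gauss_map(montage: ChannelMontage, anchor_label: str,
               width_rad: float = 0.6) -> np.ndarray:
    d = montage.geodesic_distances(
        montage.positions[montage.index(anchor_label)])
    return np.exp(-(d ** 2) / (2 * width_rad ** 2))


def _roi_map(montage: ChannelMontage, electrodes, width_rad: float = 0.35
             ) -> np.ndarray:
    m = np.zeros(montage.n_channels)
    for e in electrodes:
        m += _gauss_map(montage, e, width_rad)
    return m / m.max()


def _gauss_env(t_ms: np.ndarray, center_ms: float, sd_ms: float) -> np.ndarray:
    return np.exp(-((t_ms - center_ms) ** 2) / (2 * sd_ms ** 2))


_COMPONENTS = (  # (anchor, center_ms, sd_ms)
    ("early", "F3", 30.0, 10.0),
    ("n100", "Cz", 130.0, 25.0),
    ("p200", "CPz", 200.0, 30.0),
)


# ---------------------------------------------------------------------------
# TMS-EEG cohort


def _subject_traits(config: CohortConfig, si: int) -> dict:
    rng = np.random.default_rng([config.seed, 1000 + si])
    return {band: float(rng.normal(0.0, config.burst_subject_sd_db))
            for band in _BAND_FREQ}


def _cell_amplitudes(config: CohortConfig, session: str, time: str,
                     intensity: str, traits: dict) -> dict:
    gain = config.intensity_gain[intensity]
    amp_n100 = config.amp_n100 * gain
    amp_p200 = config.amp_p200 * gain
    if time == "post":
        amp_n100 += config.n100_post_delta[session]
        amp_p200 += config.p200_post_delta[session]
    bursts = {}
    for band, base in config.burst_amp.items():
        db = traits[band]
        if time == "post":
            db = (db + config.burst_post_delta_db[band][session]
                  + config.burst_change_slope[band][session] * traits[band])
        bursts[band] = base * gain * 10.0 ** (db / 20.0)
    return {"early": config.amp_early * gain, "n100": amp_n100,
            "p200": amp_p200, "bursts": bursts,
            "burst_db_offsets": {band: (traits[band] if time == "pre" else
                                        traits[band]
                                        + config.burst_post_delta_db[band][session]
                                        + config.burst_change_slope[band][session]
                                        * traits[band])
                                 for band in config.burst_amp}}


def synth_tep_cohort(config: CohortConfig = CohortConfig()) -> StudyDataset:
    """Generate the full subject x session x time x intensity TMS cohort."""
    montage = default_montage()
    n_samp = int(round((config.epoch_ms[1] - config.epoch_ms[0])
                       / 1000.0 * config.srate))
    t0 = int(round(-config.epoch_ms[0] / 1000.0 * config.srate))
    t_ms = (np.arange(n_samp) - t0) / config.srate * 1000.0
    comp_maps = {name: _gauss_map(montage, anchor)
                 for name, anchor, _, _ in _COMPONENTS}
    comp_envs = {name: _gauss_env(t_ms, c, s)
                 for name, _, c, s in _COMPONENTS}
    roi_maps = {band: _roi_map(montage, DEFAULT_ROIS[band].electrodes)
                for band in _BAND_FREQ}
    band_envs = {}
    for band, roi in DEFAULT_ROIS.items():
        lo, hi = roi.t_window_ms
        band_envs[band] = _gauss_env(t_ms, (lo + hi) / 2.0, (hi - lo) / 4.0)

    epochs: dict = {}
    truth: dict = {"config": _config_dict(config), "cells": {}}
    for si in range(config.n_subjects):
        subject = f"S{si + 1:02d}"
        traits = _subject_traits(config, si)
        truth.setdefault("subjects", {})[subject] = traits
        for ci, session in enumerate(SESSIONS):
            for ti, time in enumerate(TIMES):
                for intensity in config.intensities:
                    ii = INTENSITIES.index(intensity)
                    amps = _cell_amplitudes(config, session, time,
                                            intensity, traits)
                    rng = np.random.default_rng(
                        [config.seed, si, ci, ti, ii])
                    det = np.zeros((montage.n_channels, n_samp))
                    for name in comp_maps:
                        det += amps[name] * np.outer(comp_maps[name],
                                                     comp_envs[name])
                    data = np.empty((montage.n_channels, n_samp,
                                     config.n_trials))
                    for tr in range(config.n_trials):
                        trial = det.copy()
                        for band, f in _BAND_FREQ.items():
                            phase = rng.uniform(0, 2 * np.pi)
                            osc = np.sin(2 * np.pi * f * t_ms / 1000.0
                                         + phase) * band_envs[band]
                            trial += amps["bursts"][band] * np.outer(
                                roi_maps[band], osc)
                        trial += _pink_noise(rng, montage.n_channels, n_samp,
                                             config.srate, config.noise_sd,
                                             config.noise_exponent)
                        data[:, :, tr] = trial
                    cell = Cell(subject, session, time, intensity)
                    key = (subject, session, time, intensity)
                    epochs[key] = EpochedEEG(data, config.srate, t0,
                                             montage, cell)
                    truth["cells"]["|".join(key)] = {
                        "amp_early": amps["early"],
                        "amp_n100": amps["n100"],
                        "amp_p200": amps["p200"],
                        "burst_amp": amps["bursts"],
                        "burst_db_offsets": amps["burst_db_offsets"],
                    }
    return StudyDataset(epochs, truth, montage)


def _config_dict(config) -> dict:
    d = asdict(config)
    return {k: ({str(kk): vv for kk, vv in v.items()}
                if isinstance(v, Mapping) else v)
            for k, v in d.items()}


# ---------------------------------------------------------------------------
# resting-state EEG


def _markov_labels(rng: np.random.Generator, n_samp: int, k: int,
                   dwell_samples: np.ndarray) -> np.ndarray:
    """Markov chain with geometric dwell of per-class mean lengths."""
    labels = np.empty(n_samp, dtype=int)
    state = int(rng.integers(k))
    i = 0
    while i < n_samp:
        run = int(rng.geometric(1.0 / max(dwell_samples[state], 1.0001)))
        run = min(run, n_samp - i)
        labels[i:i + run] = state
        i += run
        nxt = int(rng.integers(k - 1))
        state = nxt if nxt < state else nxt + 1
    return labels


def synth_resting(config: RestingConfig = RestingConfig(),
                  cell: tuple[str, str] = ("active", "pre"),
                  subject_index: int = 0
                  ) -> tuple[np.ndarray, np.ndarray, ChannelMontage]:
    """One continuous resting recording; returns (data, true_labels, montage)."""
    montage = default_montage()
    templates = canonical_templates(montage).templates[: config.k]
    n_samp = int(round(config.duration_s * config.srate))
    rng = np.random.default_rng(
        [config.seed, 2000 + subject_index,
         SESSIONS.index(cell[0]), TIMES.index(cell[1])])
    mods = np.asarray(config.dwell_modifiers.get(tuple(cell),
                                                 (1.0,) * config.k))
    dwell = config.mean_dwell_ms / 1000.0 * config.srate * mods
    labels = _markov_labels(rng, n_samp, config.k, dwell)
    t = np.arange(n_samp) / config.srate
    phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.5 * np.sin(2 * np.pi * config.carrier_hz * t + phase)
    sig = templates[labels].T * envelope[None, :]
    noise = _pink_noise(rng, montage.n_channels, n_samp, config.srate,
                        1.0, config.noise_exponent)
    sig_rms = float(np.sqrt(np.mean(sig ** 2)))
    noise_rms = float(np.sqrt(np.mean(noise ** 2)))
    if config.snr > 0 and noise_rms > 0:
        noise *= sig_rms / (config.snr * noise_rms)
    else:
        noise *= 0.0
    return sig + noise, labels, montage


def synth_resting_cohort(config: RestingConfig = RestingConfig()
                         ) -> RestingDataset:
    """Resting recordings for every subject x session x time cell."""
    recordings: dict = {}
    truth: dict = {"config": {
        k: (dict({str(kk): list(vv) for kk, vv in v.items()})
            if isinstance(v, Mapping) else v)
        for k, v in asdict(config).items()}}
    montage = default_montage()
    for si in range(config.n_subjects):
        subject = f"R{si + 1:02d}"
        for session in SESSIONS:
            for time in TIMES:
                data, labels, montage = synth_resting(
                    config, (session, time), si)
                recordings[(subject, session, time)] = (data, labels)
    return RestingDataset(recordings, truth, montage, config.srate)


def ground_truth(config) -> dict:
    """JSON-serializable ledger of all generating parameters."""
    if isinstance(config, CohortConfig):
        return synth_tep_cohort_truth(config)
    if isinstance(config, RestingConfig):
        return {"kind": "resting", "config": {
            k: ({str(kk): list(v[kk]) for kk in v}
                if isinstance(v, Mapping) else v)
            for k, v in asdict(config).items()}}
    raise TypeError("config must be CohortConfig or RestingConfig")


def synth_tep_cohort_truth(config: CohortConfig) -> dict:
    """Deterministic generating-parameter ledger without building the data."""
    out = {"kind": "tep", "config": _config_dict(config), "cells": {},
           "subjects": {}}
    for si in range(config.n_subjects):
        subject = f"S{si + 1:02d}"
        traits = _subject_traits(config, si)
        out["subjects"][subject] = traits
        for session in SESSIONS:
            for time in TIMES:
                for intensity in config.intensities:
                    amps = _cell_amplitudes(config, session, time,
                                            intensity, traits)
                    key = "|".join((subject, session, time, intensity))
                    out["cells"][key] = {
                        "amp_early": amps["early"],
                        "amp_n100": amps["n100"],
                        "amp_p200": amps["p200"],
                        "burst_amp": dict(amps["bursts"]),
                        "burst_db_offsets": dict(amps["burst_db_offsets"]),
                    }
    return out
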