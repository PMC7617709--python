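"""Morlet time-frequency decomposition of TMS epochs, dB baseline
normalization, band/ROI power extraction and the oscillation statistics
(three-way RM ANOVA, Wilcoxon post-hocs, Huber change-score regression).

The gamma ROI deliberately starts 20 ms before stimulus onset: wavelet
kernels leak post-stimulus gamma backwards in time (temporal smudging),
so the pre-zero bin carries stimulus-related power, not precognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .data_model import EpochedEEG
from .stats_util import RobustFit, huber_irls, rm_anova, wilcoxon_signed_rank

__all__ = [
    "WaveletSpec",
    "TFRPower",
    "BandROI",
    "DEFAULT_ROIS",
    "morlet_decompose",
    "db_normalize",
    "roi_power",
    "three_way_rm_anova",
    "wilcoxon_posthoc",
    "change_score_regression",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Log-spaced frequency grid with log-spaced cycle counts.

    Defaults: 30 frequencies from 3 to 70 Hz, cycles from 3 to 10.
    """

    f_min: float = 3.0
    f_max: float = 70.0
    n_freqs: int = 30
    cycles_min: float = 3.0
    cycles_max: float = 10.0

    @property
    def freqs(self) -> np.ndarray:
        return np.geomspace(self.f_min, self.f_max, self.n_freqs)

    @property
    def cycles(self) -> np.ndarray:
        return np.geomspace(self.cycles_min, self.cycles_max, self.n_freqs)


@dataclass(frozen=True)
class TFRPower:
    """Trial-averaged total power, frequency x time x channel."""

    power: np.ndarray = field(repr=False)
    freqs: np.ndarray = field(repr=False)
    times_ms: np.ndarray = field(repr=False)  # left edges of 20-ms steps
    step_ms: float
    is_db: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        if not self.is_db and np.any(p < 0):
            raise ValueError("raw power must be non-negative")
        object.__setattr__(self, "power", p)

    def time_mask(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Steps whose left edge lies in [lo_ms, hi_ms)."""
        t = self.times_ms
        return (t >= lo_ms - 1e-9) & (t < hi_ms - 1e-9)

    def freq_mask(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        return (self.freqs >= lo_hz - 1e-9) & (self.freqs <= hi_hz + 1e-9)


@dataclass(frozen=True)
class BandROI:
    """Named time x frequency x electrode box of interest."""

    name: str
    t_window_ms: tuple[float, float]
    f_window_hz: tuple[float, float]
    electrodes: tuple[str, ...]


DEFAULT_ROIS: dict[str, BandROI] = {
    "theta": BandROI("theta", (100.0, 240.0), (4.0, 7.0),
                     ("C1", "Cz", "C2", "FC1", "FCz", "FC2")),
    "beta": BandROI("beta", (0.0, 60.0), (15.0, 21.0), ("AF3", "F3", "F1")),
    "gamma": BandROI("gamma", (-20.0, 40.0), (30.0, 70.0),
                     ("AF3", "F3", "F1")),
}


def _bandpass(data: np.ndarray, srate: float, lo: float, hi: float
              ) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the sample axis."""
    hi = min(hi, 0.499 * srate)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=srate, output="sos")
    return signal.sosfiltfilt(sos, data, axis=1)


def _morlet_kernel(freq: float, n_cycles: float, srate: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * srate))
    t = np.arange(-half, half + 1) / srate
    win = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    kern = win * np.exp(2j * np.pi * freq * t)
    return kern / np.sqrt(np.sum(np.abs(kern) ** 2))


def morlet_decompose(epochs: EpochedEEG, spec: WaveletSpec = WaveletSpec(),
                     step_ms: float = 20.0, concat: bool = True,
                     bandpass: tuple[float, float] | None = (3.0, 100.0),
                     decimate_after_average: bool = True) -> TFRPower:
    """Total-power Morlet decomposition with 20-ms time steps.

    ``concat=True`` convolves the trial-concatenated signal so edge
    leakage between neighbouring trials matches the concatenated-trial
    pipeline; ``False`` convolves each trial separately (zero padding).
    Power is the squared magnitude averaged over trials, then averaged
    within ``step_ms`` windows (left-edge labeled).
    """
    freqs = spec.freqs
    nyq = epochs.srate / 2.0
    if freqs[-1] >= nyq:
        raise ValueError(
            f"max frequency {freqs[-1]:.1f} Hz >= Nyquist {nyq:.1f} Hz"
        )
    data = epochs.data  # ch x samp x trial
    if bandpass is not None:
        data = _bandpass(data, epochs.srate, *bandpass)
    n_ch, n_samp, n_trial = data.shape
    power = np.zeros((len(freqs), n_samp, n_ch))
    if concat:
        sig = np.concatenate([data[:, :, k] for k in range(n_trial)], axis=1)
    for fi, (f, c) in enumerate(zip(freqs, spec.cycles)):
        kern = _morlet_kernel(f, c, epochs.srate)
        if concat:
            conv = _fft_convolve_same(sig, kern)
            per_trial = conv.reshape(n_ch, n_trial, n_samp)
            power[fi] = np.mean(np.abs(per_trial) ** 2, axis=1).T
        else:
            acc = np.zeros((n_ch, n_samp))
            for k in range(n_trial):
                acc += np.abs(_fft_convolve_same(data[:, :, k], kern)) ** 2
            power[fi] = (acc / n_trial).T
    # decimate to step_ms by averaging within left-edge-labeled windows
    t = epochs.times_ms
    step = step_ms
    first = np.floor(t[0] / step) * step
    edges = np.arange(first, t[-1] + step / 2, step)
    out = np.empty((len(freqs), len(edges), n_ch))
    keep = []
    for i, lo in enumerate(edges):
        mask = (t >= lo - 1e-9) & (t < lo + step - 1e-9)
        if mask.any():
            keep.append(i)
            out[:, len(keep) - 1] = power[:, mask].mean(axis=1)
    return TFRPower(out[:, :len(keep)], freqs, edges[keep], step, is_db=False)


def _fft_convolve_same(x: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Complex 'same'-mode convolution of rows of x with kern."""
    n = x.shape[1]
    m = kern.size
    nfft = int(2 ** np.ceil(np.log2(n + m - 1)))
    X = np.fft.fft(x, nfft, axis=1)
    K = np.fft.fft(kern, nfft)
    full = np.fft.ifft(X * K[None, :], axis=1)
    start = (m - 1) // 2
    return full[:, start:start + n]


def db_normalize(tfr: TFRPower, baseline_ms: tuple[float, float] = (-400.0, -200.0)
                 ) -> TFRPower:
    """10*log10(power / mean baseline power), per channel and frequency."""
    if tfr.is_db:
        raise ValueError("already in dB")
    mask = tfr.time_mask(*baseline_ms)
    if not mask.any():
        raise ValueError(
            f"baseline window {baseline_ms} ms outside the epoch "
            f"[{tfr.times_ms[0]}, {tfr.times_ms[-1]}] ms"
        )
    base = tfr.power[:, mask].mean(axis=1, keepdims=True)  # freq x 1 x ch
    if np.any(base <= 0):
        raise ValueError("zero baseline mean power")
    db = 10.0 * np.log10(tfr.power / base)
    return TFRPower(db, tfr.freqs, tfr.times_ms, tfr.step_ms, is_db=True)


def roi_power(tfr_db: TFRPower, roi: BandROI, channel_names) -> float:
    """Mean dB over the ROI time x frequency x electrode box."""
    tm = tfr_db.time_mask(*roi.t_window_ms)
    fm = tfr_db.freq_mask(*roi.f_window_hz)
    names = list(channel_names)
    missing = [e for e in roi.electrodes if e not in names]
    if missing:
        raise ValueError(f"ROI electrodes not in montage: {missing}")
    ci = [names.index(e) for e in roi.electrodes]
    if not tm.any() or not fm.any():
        raise ValueError(f"ROI {roi.name!r} selects no time/frequency samples")
    box = tfr_db.power[np.ix_(fm, tm, ci)]
    return float(box.mean())


def three_way_rm_anova(values: np.ndarray) -> pd.DataFrame:
    """RM ANOVA over subjects x time(2) x condition(2) x intensity(2)."""
    effects = rm_anova(np.asarray(values, dtype=float),
                       ["time", "condition", "intensity"])
    return pd.DataFrame([{"effect": e.effect, "F": e.F, "df1": e.df_num,
                          "df2": e.df_den, "p": e.p, "eta_sq_g": e.eta_sq_g}
                         for e in effects])


def wilcoxon_posthoc(pre, post) -> tuple[float, float]:
    """Paired signed-rank post-hoc on (pre, post) ROI power; (z, p)."""
    return wilcoxon_signed_rank(post, pre)


def change_score_regression(baseline, post, condition,
                            tuning: float = 1.345) -> RobustFit:
    """Huber regression of change = post - baseline on mean-centered
    baseline, condition (coded +/-0.5) and their interaction.

    The +/-0.5 condition coding makes the interaction coefficient the
    difference in baseline slope between conditions.
    """
    b = np.asarray(baseline, dtype=float)
    y = np.asarray(post, dtype=float) - b
    cond = np.asarray(condition)
    levels = sorted(set(cond.tolist()))
    if len(levels) != 2:
        raise ValueError("condition must have exactly 2 levels, both present")
    if b.size < 8:
        raise ValueError("need at least 8 observations")
    code = np.where(cond == levels[0], 0.5, -0.5).astype(float)
    bc = b - b.mean()
    cc = code - code.mean()
    X = np.column_stack([np.ones_like(bc), bc, cc, bc * cc])
    names = ["intercept", "baseline", "condition", "baseline:condition"]
    return huber_irls(X, y, tuning=tuning, names=names)
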