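"""Global mean field power, 20-ms binning, and per-bin / per-channel
2x2 within-subject ANOVAs.

GMFP is the population (divide-by-k) standard deviation of the potentials
across channels at each sample — the Lehmann-Skrandies global field power.
The channel-wise maps are exploratory and uncorrected; familywise
protection over electrodes and time comes from the TANOVA stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import EvokedResponse
from .stats_util import rm_anova

__all__ = [
    "GMFPSeries",
    "BinnedSeries",
    "gmfp",
    "bin_time_series",
    "per_bin_rm_anova",
    "channelwise_rm_anova",
]


@dataclass(frozen=True)
class GMFPSeries:
    values: np.ndarray = field(repr=False)
    times_ms: np.ndarray = field(repr=False)
    srate: float
    k: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-12):
            raise ValueError("GMFP values must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BinnedSeries:
    """Per-bin means over contiguous half-open time bins of uniform width."""

    bin_edges: np.ndarray = field(repr=False)  # (n_bins, 2) ms
    bin_means: np.ndarray = field(repr=False)  # (n_bins,) or (n_ch, n_bins)

    @property
    def n_bins(self) -> int:
        return self.bin_edges.shape[0]

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return self.bin_edges.mean(axis=1)


def gmfp(evoked: EvokedResponse) -> GMFPSeries:
    """Per-sample standard deviation across channels (population form)."""
    if evoked.n_channels < 2:
        raise ValueError("GMFP requires at least 2 channels")
    v = evoked.data
    out = np.sqrt(np.mean((v - v.mean(axis=0, keepdims=True)) ** 2, axis=0))
    return GMFPSeries(out, evoked.times_ms, evoked.srate, evoked.n_channels)


def bin_time_series(series, width_ms: float = 20.0,
                    range_ms: tuple[float, float] = (-20.0, 400.0)
                    ) -> BinnedSeries:
    """Mean over samples with t in [edge, edge + width) per bin.

    ``series`` is a GMFPSeries (1-D) or EvokedResponse (channel x sample).
    """
    start, end = range_ms
    span = end - start
    n_bins = span / width_ms
    if abs(n_bins - round(n_bins)) > 1e-9 or n_bins <= 0:
        lo = start + width_ms * np.floor(span / width_ms)
        raise ValueError(
            f"bin width {width_ms} ms does not divide range ({start}, {end}) "
            f"ms; nearest achievable end points: {lo} or {lo + width_ms} ms"
        )
    n_bins = int(round(n_bins))
    if isinstance(series, GMFPSeries):
        times, values = series.times_ms, series.values[None, :]
        squeeze = True
    else:
        times, values = series.times_ms, series.data
        squeeze = False
    if start < times[0] - 1e-9 or end > times[-1] + 1e-9 + 1e3 / _srate(series):
        raise ValueError(
            f"range ({start}, {end}) ms outside series span "
            f"[{times[0]:.3f}, {times[-1]:.3f}] ms"
        )
    edges = np.array([[start + i * width_ms, start + (i + 1) * width_ms]
                      for i in range(n_bins)])
    means = np.empty((values.shape[0], n_bins))
    for i, (lo, hi) in enumerate(edges):
        mask = (times >= lo - 1e-9) & (times < hi - 1e-9)
        if not mask.any():
            raise ValueError(f"bin [{lo}, {hi}) ms contains no samples")
        means[:, i] = values[:, mask].mean(axis=1)
    return BinnedSeries(edges, means[0] if squeeze else means)


def _srate(series) -> float:
    return series.srate


_EFFECTS = ("time", "condition", "time:condition")


def _assemble_2x2(cells: dict, subjects, extract) -> np.ndarray:
    """Stack per-subject 2x2 arrays; ``cells[(subject, session, time)]``."""
    out = []
    for s in subjects:
        block = []
        for t in ("pre", "post"):
            row = []
            for c in ("active", "sham"):
                key = (s, c, t)
                if key not in cells:
                    raise ValueError(
                        f"incomplete design: subject {s!r} missing cell "
                        f"(session={c!r}, time={t!r})"
                    )
                row.append(extract(cells[key]))
            block.append(row)
        out.append(block)
    return np.asarray(out, dtype=float)


def per_bin_rm_anova(binned: dict, from_ms: float = 40.0,
                     to_ms: float | None = None) -> pd.DataFrame:
    """2x2 (time x condition) RM ANOVA per time bin.

    Parameters
    ----------
    binned : dict
        ``{(subject, session, time): BinnedSeries}`` with scalar bins,
        complete over sessions {active, sham} and times {pre, post}.
    from_ms : float
        First bin (by left edge) entering the analysis.
    to_ms : float, optional
        Exclusive upper limit on bin left edges.
    """
    subjects = sorted({k[0] for k in binned})
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    ref = next(iter(binned.values()))
    rows = []
    for b in range(ref.n_bins):
        lo, hi = ref.bin_edges[b]
        if lo < from_ms - 1e-9 or (to_ms is not None and lo >= to_ms - 1e-9):
            continue
        y = _assemble_2x2(binned, subjects, lambda bs, b=b: bs.bin_means[b])
        for eff in rm_anova(y, ["time", "condition"]):
            rows.append({"bin_start_ms": lo, "bin_end_ms": hi,
                         "effect": eff.effect, "F": eff.F, "df1": eff.df_num,
                         "df2": eff.df_den, "p": eff.p,
                         "eta_sq_g": eff.eta_sq_g})
    return pd.DataFrame(rows)


def channelwise_rm_anova(binned: dict, from_ms: float = 40.0,
                         to_ms: float | None = None,
                         channel_names=None) -> pd.DataFrame:
    """Per-electrode x bin 2x2 RM ANOVA (exploratory, uncorrected).

    ``binned`` maps ``(subject, session, time)`` to BinnedSeries whose
    ``bin_means`` are channel x bin.
    """
    subjects = sorted({k[0] for k in binned})
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    ref = next(iter(binned.values()))
    n_ch = ref.bin_means.shape[0]
    names = (list(channel_names) if channel_names is not None
             else [f"ch{i}" for i in range(n_ch)])
    rows = []
    for b in range(ref.n_bins):
        lo, hi = ref.bin_edges[b]
        if lo < from_ms - 1e-9 or (to_ms is not None and lo >= to_ms - 1e-9):
            continue
        # subjects x time x condition x channel in one pass
        y = _assemble_2x2(binned, subjects,
                          lambda bs, b=b: bs.bin_means[:, b])
        for ci in range(n_ch):
            for eff in rm_anova(y[..., ci], ["time", "condition"]):
                rows.append({"channel": names[ci], "bin_start_ms": lo,
                             "bin_end_ms": hi, "effect": eff.effect,
                             "F": eff.F, "p": eff.p,
                             "eta_sq_g": eff.eta_sq_g})
    return pd.DataFrame(rows)
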