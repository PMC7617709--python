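"""Topographic permutation ANOVA on GMFP-normalized maps with
duration-based multiple-comparison control.

Design: 2 (time) x 2 (condition), fully within subject.  The test
statistic at a timepoint is the global field power of the effect-specific
contrast of subject-mean maps.  Main effects are permuted by shuffling the
factor's labels independently within each subject (equivalently random
sign flips of each subject's difference map after collapsing the other
factor); the interaction permutes by sign-flipping each subject's
double-difference map.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MapEnsemble",
    "TanovaResult",
    "normalize_gmfp",
    "tanova_timepoint",
    "tanova_series",
    "duration_threshold",
    "map_gfp",
]

EFFECTS = ("time", "condition", "interaction")


def map_gfp(maps: np.ndarray) -> np.ndarray:
    """Global field power of map vectors along the last axis."""
    m = np.asarray(maps, dtype=float)
    return np.sqrt(np.mean((m - m.mean(axis=-1, keepdims=True)) ** 2, axis=-1))


@dataclass(frozen=True)
class MapEnsemble:
    """Scalp maps per subject x time(2) x condition(2) [x timepoint].

    ``maps`` has shape (n_subjects, 2, 2, n_channels) for a single
    timepoint or (n_subjects, 2, 2, n_timepoints, n_channels).
    """

    maps: np.ndarray = field(repr=False)
    times_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=float)
        if m.ndim not in (4, 5) or m.shape[1] != 2 or m.shape[2] != 2:
            raise ValueError(
                "maps must be subjects x 2 x 2 x [timepoints x] channels"
            )
        object.__setattr__(self, "maps", m)

    @property
    def n_subjects(self) -> int:
        return self.maps.shape[0]

    @property
    def n_timepoints(self) -> int:
        return 1 if self.maps.ndim == 4 else self.maps.shape[3]


def normalize_gmfp(maps: MapEnsemble, tol: float = 1e-12) -> MapEnsemble:
    """Scale every map to unit global field power."""
    m = maps.maps
    g = map_gfp(m)
    if np.any(g <= tol):
        idx = tuple(int(i) for i in np.argwhere(g <= tol)[0])
        raise ValueError(f"zero-GMFP map at cell index {idx}")
    return MapEnsemble(m / g[..., None], maps.times_ms)


def _subject_contrasts(m: np.ndarray, effect: str) -> np.ndarray:
    """Per-subject contrast maps; m: subj x 2 x 2 x channels.

    Main effects collapse the other factor first; the interaction is the
    double-difference map.  The statistic downstream is GFP(mean)/2 — half
    the contrast GFP equals the mean deviation of the two level maps from
    their grand mean.
    """
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    if effect == "time":
        d = m.mean(axis=2)
        return d[:, 0] - d[:, 1]
    if effect == "condition":
        d = m.mean(axis=1)
        return d[:, 0] - d[:, 1]
    return (m[:, 0, 0] - m[:, 0, 1]) - (m[:, 1, 0] - m[:, 1, 1])


def _perm_stats(contrasts: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """GFP/2 of sign-flipped mean contrast; signs: (n_perm, n_subjects)."""
    mean = np.einsum("ps,sc->pc", signs, contrasts) / contrasts.shape[0]
    return map_gfp(mean) / 2.0


def tanova_timepoint(maps: MapEnsemble, effect: str, n_perm: int = 1000,
                     seed: int | None = 0, exhaustive: bool = False,
                     rng: np.random.Generator | None = None) -> float:
    """Permutation p-value for one effect at a single timepoint.

    With ``exhaustive=True`` all 2**n_subjects sign assignments are
    enumerated instead of sampled (p then uses the full ensemble).
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    m = maps.maps
    if m.ndim == 5:
        raise ValueError("tanova_timepoint expects a single-timepoint ensemble")
    if not np.all(np.isfinite(m)):
        raise ValueError("incomplete design: non-finite map values")
    if n_perm < 100 and not exhaustive:
        import warnings

        warnings.warn("n_perm < 100 gives a coarse p-value", stacklevel=2)
    contrasts = _subject_contrasts(m, effect)
    n = contrasts.shape[0]
    obs = float(map_gfp(contrasts.mean(axis=0)) / 2.0)
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        stats = _perm_stats(contrasts, signs)
        # identity assignment is part of the ensemble
        return float(np.mean(stats >= obs - 1e-12))
    if rng is None:
        rng = np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    stats = _perm_stats(contrasts, signs)
    return float((1 + np.sum(stats >= obs - 1e-12)) / (1 + n_perm))


@dataclass(frozen=True)
class TanovaResult:
    p_series: dict
    n_perm: int
    alpha: float
    duration_threshold_ms: dict
    significant_periods: dict
    times_ms: np.ndarray = field(repr=False)
    seed: int | None = None


def _runs_below(p: np.ndarray, alpha: float) -> list[tuple[int, int]]:
    """Half-open index runs where p < alpha."""
    below = p < alpha
    runs = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(below)))
    return runs


def longest_run_length(p: np.ndarray, alpha: float) -> int:
    runs = _runs_below(np.asarray(p, dtype=float), alpha)
    return max((b - a for a, b in runs), default=0)


def duration_threshold(p_matrix: np.ndarray, alpha: float = 0.05,
                       dt_ms: float = 1.0, percentile: float = 95.0
                       ) -> tuple[float, np.ndarray]:
    """Run-length threshold from a permutation x timepoint p matrix.

    Row 0 must hold the observed p-series and the remaining rows the
    per-permutation p-series from the same ensemble.  Returns the
    ``percentile`` of the per-permutation longest sub-alpha run (in ms)
    and the run-length distribution (samples).
    """
    P = np.asarray(p_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] < 21:
        raise ValueError("need >= 20 permutation rows plus the observed row")
    lengths = np.array([longest_run_length(P[i], alpha)
                        for i in range(1, P.shape[0])])
    thresh = float(np.percentile(lengths, percentile) * dt_ms)
    return thresh, lengths


def tanova_series(maps: MapEnsemble, n_perm: int = 1000, seed: int = 0,
                  alpha: float = 0.05) -> TanovaResult:
    """Full TANOVA over timepoints with duration correction per effect.

    The same sign-flip ensemble is used at every timepoint so that
    per-permutation p-series are coherent across time (rank-based p's),
    which the duration threshold requires.
    """
    m = maps.maps
    if m.ndim == 4:
        m = m[:, :, :, None, :]
    n_sub, _, _, n_t, n_ch = m.shape
    times = (maps.times_ms if maps.times_ms is not None
             else np.arange(n_t, dtype=float))
    dt_ms = float(times[1] - times[0]) if n_t > 1 else 1.0
    rng = np.random.default_rng(seed)
    signs = np.vstack([np.ones((1, n_sub)),
                       rng.choice([1.0, -1.0], size=(n_perm, n_sub))])
    p_series: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    periods: dict[str, list[tuple[float, float]]] = {}
    for effect in EFFECTS:
        # contrasts: subj x time x ch
        contrasts = np.stack(
            [_subject_contrasts(m[:, :, :, t, :], effect) for t in range(n_t)],
            axis=1)
        # stats: (n_perm+1) x time
        mean = np.einsum("ps,stc->ptc", signs, contrasts) / n_sub
        stats = map_gfp(mean) / 2.0
        # rank-based p per row: fraction of ensemble >= that row's stat
        p_mat = np.empty_like(stats)
        for t in range(stats.shape[1]):
            col = stats[:, t]
            # p = proportion of ensemble values >= this value (incl. self)
            p_mat[:, t] = np.mean(col[None, :] >= col[:, None] - 1e-12, axis=1)
        p_series[effect] = p_mat[0]
        thr_ms, _ = duration_threshold(p_mat, alpha, dt_ms)
        thresholds[effect] = thr_ms
        obs_runs = _runs_below(p_mat[0], alpha)
        keep = [(float(times[a]), float(times[b - 1] + dt_ms))
                for a, b in obs_runs if (b - a) * dt_ms > thr_ms]
        periods[effect] = keep
    return TanovaResult(p_series, n_perm, alpha, thresholds, periods,
                        np.asarray(times, dtype=float), seed)
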