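"""Resting-state EEG microstate pipeline.

GFP-peak map extraction, polarity-invariant modified k-means, grand-mean
templates, canonical A-D sorting, winner-take-all backfitting, and
occurrence / duration / coverage parameters with their 2x2 RM ANOVA.

All spatial correlations are computed on average-referenced maps and in
absolute value: a template and its sign-flip describe the same microstate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .montage import ChannelMontage, default_montage
from .stats_util import rm_anova
from .tanova import map_gfp

__all__ = [
    "MicrostateModel",
    "LabelSequence",
    "gmfp_peaks",
    "modified_kmeans",
    "grand_mean_templates",
    "sort_templates",
    "backfit",
    "ms_parameters",
    "ms_rm_anova",
    "canonical_templates",
    "spatial_correlation",
]


def _avg_ref(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=-1, keepdims=True)


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of average-referenced maps along the last axis."""
    a = _avg_ref(np.asarray(a, dtype=float))
    b = _avg_ref(np.asarray(b, dtype=float))
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.sum(a * b, axis=-1) / denom
    return np.where(denom > 0, c, 0.0)


@dataclass(frozen=True)
class MicrostateModel:
    """k template maps with unit GFP and free polarity."""

    templates: np.ndarray = field(repr=False)  # k x channels
    labels: tuple[str, ...]
    montage: ChannelMontage | None = None
    gev: float | None = None
    shared_variance: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.templates, dtype=float)
        if t.ndim != 2 or t.shape[0] < 1:
            raise ValueError("templates must be k x channels with k >= 1")
        if len(self.labels) != t.shape[0]:
            raise ValueError("one label per template required")
        object.__setattr__(self, "templates", t)

    @property
    def k(self) -> int:
        return self.templates.shape[0]


@dataclass(frozen=True)
class LabelSequence:
    """Per-sample winning template index."""

    labels: np.ndarray = field(repr=False)
    srate: float
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.size == 0:
            raise ValueError("empty label sequence")
        object.__setattr__(self, "labels", lab)


def _unit_gfp(maps: np.ndarray) -> np.ndarray:
    g = map_gfp(maps)
    g = np.where(g > 0, g, 1.0)
    return _avg_ref(maps) / g[..., None]


def gmfp_peaks(data: np.ndarray, srate: float,
               min_separation_ms: float = 0.0) -> np.ndarray:
    """Maps at local maxima of the GFP time course.

    ``data`` is channel x sample continuous EEG (already 2-30 Hz filtered
    upstream).  Returns peaks x channels.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[1] / srate < 2.0:
        raise ValueError("need at least 2 s of data")
    g = map_gfp(data.T)
    dist = max(int(round(min_separation_ms / 1000.0 * srate)), 1)
    idx, _ = sp_signal.find_peaks(g, distance=dist)
    if idx.size == 0:
        raise ValueError("no GFP peaks found")
    return data[:, idx].T


def _assign(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Winner-take-all by squared spatial correlation."""
    c = spatial_correlation(maps[:, None, :], templates[None, :, :])
    return np.argmax(c ** 2, axis=1)


def _principal_map(maps: np.ndarray) -> np.ndarray:
    """First principal axis of a set of maps (polarity-invariant mean)."""
    m = _avg_ref(maps)
    # leading eigenvector of m.T @ m without forming channels^2 when small
    _, _, vt = np.linalg.svd(m, full_matrices=False)
    return vt[0]


def _gev(maps: np.ndarray, templates: np.ndarray,
         assignment: np.ndarray) -> float:
    """Global explained variance of the assignment."""
    g = map_gfp(maps)
    c = spatial_correlation(maps, templates[assignment])
    denom = float(np.sum(g ** 2))
    return float(np.sum((g * c) ** 2) / denom) if denom > 0 else 0.0


def modified_kmeans(maps: np.ndarray, k: int = 4, restarts: int = 10,
                    seed: int = 0, max_iter: int = 200) -> MicrostateModel:
    """Polarity-invariant modified k-means on GFP-peak maps.

    Assignment maximizes squared spatial correlation; the template update
    is the first principal axis of each cluster's members; iteration stops
    at label stability.  The best of ``restarts`` runs by global explained
    variance (GEV) wins.  An emptied cluster is reseeded from the current
    worst-fit map.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} maps for k={k}")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    for _ in range(restarts):
        templates = _unit_gfp(maps[rng.choice(n, size=k, replace=False)])
        prev = None
        for _ in range(max_iter):
            assignment = _assign(maps, templates)
            for j in range(k):
                members = maps[assignment == j]
                if members.shape[0] == 0:
                    c = spatial_correlation(maps, templates[assignment])
                    worst = int(np.argmin(np.abs(c)))
                    templates[j] = _unit_gfp(maps[worst][None, :])[0]
                    assignment[worst] = j
                    continue
                templates[j] = _unit_gfp(_principal_map(members)[None, :])[0]
            if prev is not None and np.array_equal(prev, assignment):
                break
            prev = assignment
        score = _gev(maps, templates, _assign(maps, templates))
        if best is None or score > best[0]:
            best = (score, templates.copy())
    gev, templates = best
    labels = tuple(f"C{i + 1}" for i in range(k))
    return MicrostateModel(templates, labels, gev=gev)


def grand_mean_templates(models: list[MicrostateModel],
                         max_iter: int = 20) -> MicrostateModel:
    """Sign-aligned average of individual templates per class.

    Each individual template is matched to the running mean by best
    permutation and flipped to positive correlation before averaging; the
    result is renormalized to unit GFP.  ``shared_variance`` is the mean
    squared spatial correlation of individual templates with their matched
    grand-mean template.
    """
    if not models:
        raise ValueError("no models given")
    k = models[0].k
    n_ch = models[0].templates.shape[1]
    for m in models:
        if m.k != k or m.templates.shape[1] != n_ch:
            raise ValueError("all models must share k and montage")
    ref = _unit_gfp(models[0].templates.copy())
    for _ in range(max_iter):
        acc = np.zeros_like(ref)
        for m in models:
            perm, signs = _match(m.templates, ref)
            acc += signs[:, None] * _unit_gfp(m.templates[perm])
        new = _unit_gfp(acc / len(models))
        if np.allclose(np.abs(spatial_correlation(new, ref)), 1.0, atol=1e-10):
            ref = new
            break
        ref = new
    cors = []
    for m in models:
        perm, _ = _match(m.templates, ref)
        cors.extend(spatial_correlation(m.templates[perm], ref) ** 2)
    labels = tuple(f"C{i + 1}" for i in range(k))
    return MicrostateModel(ref, labels,
                           shared_variance=float(np.mean(cors)))


def _match(templates: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one assignment of templates to reference classes.

    Returns (perm, signs): ``templates[perm][j]`` matches reference class j
    with sign ``signs[j]``.  Exact enumeration (k <= 8).
    """
    k = reference.shape[0]
    if templates.shape[0] != k:
        raise ValueError("template count does not match reference")
    if k > 8:
        raise ValueError("exact matching supported for k <= 8 only")
    C = spatial_correlation(templates[:, None, :], reference[None, :, :])
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(abs(C[perm[j], j]) for j in range(k))
        if score > best_score:
            best_perm, best_score = perm, score
    perm = np.array(best_perm, dtype=int)
    signs = np.sign(np.array([C[perm[j], j] for j in range(k)]))
    signs[signs == 0] = 1.0
    return perm, signs


def sort_templates(model: MicrostateModel,
                   reference: MicrostateModel) -> MicrostateModel:
    """Reorder (and label) templates to best match a labeled reference."""
    if model.k != reference.k:
        raise ValueError(f"k mismatch: {model.k} vs {reference.k}")
    if model.templates.shape[1] != reference.templates.shape[1]:
        raise ValueError("montage (channel count) mismatch")
    perm, signs = _match(model.templates, reference.templates)
    return MicrostateModel(signs[:, None] * model.templates[perm],
                           reference.labels, model.montage, model.gev,
                           model.shared_variance)


def backfit(data: np.ndarray, model: MicrostateModel,
            srate: float) -> LabelSequence:
    """Label every sample with the template of highest squared spatial
    correlation; zero-variance samples carry the previous label."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] != model.templates.shape[1]:
        raise ValueError("montage (channel count) mismatch")
    maps = data.T
    g = map_gfp(maps)
    lab = _assign(maps, model.templates)
    flat = g <= 1e-14
    if flat.any():
        for i in np.flatnonzero(flat):
            lab[i] = lab[i - 1] if i > 0 else lab[~flat][0] if (~flat).any() else 0
    return LabelSequence(lab, srate, model.labels)


@dataclass(frozen=True)
class MSParameters:
    """Occurrence (1/s), duration (ms) and coverage (%) per class."""

    table: pd.DataFrame

    def value(self, class_name: str, parameter: str) -> float:
        row = self.table[self.table["class"] == class_name]
        return float(row[parameter].iloc[0])


def _segments(labels: np.ndarray) -> list[tuple[int, int]]:
    """(label, run_length) segments of the sequence."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((int(labels[start]), i - start))
            start = i
    return out


def ms_parameters(seq: LabelSequence) -> MSParameters:
    """Occurrence, mean duration, coverage per class.

    Segments touching the recording edges are included in the duration
    averages.  Coverage sums to 100% because every sample is labeled.
    """
    labels = seq.labels
    total_s = labels.size / seq.srate
    segs = _segments(labels)
    rows = []
    for j, name in enumerate(seq.class_names):
        runs = [ln for lab, ln in segs if lab == j]
        n_seg = len(runs)
        occurrence = n_seg / total_s
        duration = (np.mean(runs) / seq.srate * 1000.0) if runs else 0.0
        coverage = sum(runs) / labels.size * 100.0
        rows.append({"class": name, "occurrence": occurrence,
                     "duration": duration, "coverage": coverage})
    return MSParameters(pd.DataFrame(rows))


def ms_rm_anova(parameters: dict) -> pd.DataFrame:
    """2x2 (time x condition) RM ANOVA per parameter and class.

    ``parameters`` maps ``(subject, session, time)`` to MSParameters.
    Also emits Table-style deltas (post minus pre) per condition.
    """
    subjects = sorted({k[0] for k in parameters})
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    ref = next(iter(parameters.values()))
    classes = list(ref.table["class"])
    rows = []
    for cls in classes:
        for par in ("occurrence", "duration", "coverage"):
            y = np.empty((len(subjects), 2, 2))
            for si, s in enumerate(subjects):
                for ti, t in enumerate(("pre", "post")):
                    for ci, c in enumerate(("active", "sham")):
                        key = (s, c, t)
                        if key not in parameters:
                            raise ValueError(
                                f"incomplete design: subject {s!r} missing "
                                f"cell (session={c!r}, time={t!r})"
                            )
                        y[si, ti, ci] = parameters[key].value(cls, par)
            deltas = {c: float(np.mean(y[:, 1, ci] - y[:, 0, ci]))
                      for ci, c in enumerate(("active", "sham"))}
            for eff in rm_anova(y, ["time", "condition"]):
                rows.append({"class": cls, "parameter": par,
                             "effect": eff.effect, "F": eff.F,
                             "df1": eff.df_num, "df2": eff.df_den,
                             "p": eff.p, "eta_sq_g": eff.eta_sq_g,
                             "delta_active": deltas["active"],
                             "delta_sham": deltas["sham"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# canonical reference templates


def canonical_templates(montage: ChannelMontage | None = None
                        ) -> MicrostateModel:
    """Canonical A-D reference maps on the template montage.

    A: left-posterior to right-anterior diagonal gradient; B: the mirror
    image; C: occipito-frontal gradient; D: fronto-central focal map.
    Built from smooth functions of the schematic electrode positions.
    """
    mont = montage if montage is not None else default_montage()
    pos = mont.positions
    x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
    a = -(x + y) / np.sqrt(2.0)  # left-anterior negative -> diagonal
    b = (x - y) / np.sqrt(2.0)
    c = -y + 0.3 * z
    d = np.exp(-mont.geodesic_distances(np.array([0.0, 0.35, 0.94])) ** 2
               / (2 * 0.5 ** 2))
    maps = _unit_gfp(np.vstack([a, b, c, d]))
    return MicrostateModel(maps, ("A", "B", "C", "D"), mont)
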