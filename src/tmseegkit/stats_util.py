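"""Within-subject statistics engine.

Fully-crossed repeated-measures ANOVA for two-level factors (with
generalized eta squared), Wilcoxon signed rank (exact for small n, normal
approximation otherwise), Huber IRLS robust regression, and the exact
two-sided binomial test.

All factors here are two-level, so every effect has numerator df = 1 and
sphericity corrections are moot.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "rm_anova",
    "wilcoxon_signed_rank",
    "huber_irls",
    "RobustFit",
    "binomial_two_sided",
    "BinomialResult",
]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_sq_g: float


def _effect_ss(y: np.ndarray) -> dict[tuple[int, ...], float]:
    """Sum of squares per term of the full factorial decomposition.

    ``y`` has shape (n_subjects, 2, 2[, 2]).  Keys are tuples of axis
    indices (0 = subjects, 1.. = factors); the empty tuple (grand mean) is
    omitted.  Uses Möbius inversion on marginal means.
    """
    axes = tuple(range(y.ndim))
    n_total = y.size
    terms: dict[tuple[int, ...], float] = {}
    est: dict[tuple[int, ...], np.ndarray] = {(): np.array(y.mean())}
    for r in range(1, y.ndim + 1):
        for subset in itertools.combinations(axes, r):
            other = tuple(a for a in axes if a not in subset)
            marg = y.mean(axis=other, keepdims=True)
            for sub in est:
                if set(sub) <= set(subset) and sub != subset:
                    marg = marg - est[sub]
            est[subset] = marg
            mult = n_total / marg.size
            terms[subset] = float(mult * np.sum(np.asarray(marg) ** 2))
    terms.pop((), None)
    return terms


def rm_anova(data: np.ndarray, factor_names: list[str] | None = None
             ) -> list[AnovaEffect]:
    """Classical fully-within ANOVA for 2 or 3 two-level factors.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, 2, 2) or (n_subjects, 2, 2, 2)
        One scalar per subject and design cell.
    factor_names : list of str, optional
        One name per factor axis, in order.

    Each effect is tested against its own subject-by-effect interaction
    mean square, F(1, n_subjects - 1).  Generalized eta squared follows
    the within-design form: SS_effect over SS_effect plus all
    subject-related sums of squares.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim not in (3, 4):
        raise ValueError("data must be subjects x 2 x 2 (x 2)")
    if any(s != 2 for s in y.shape[1:]):
        raise ValueError("all factors must have exactly two levels")
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(y)):
        bad = np.argwhere(~np.isfinite(y))
        raise ValueError(f"incomplete design: non-finite cell at index {bad[0]}")
    n_fac = y.ndim - 1
    if factor_names is None:
        factor_names = [f"f{i + 1}" for i in range(n_fac)]
    if len(factor_names) != n_fac:
        raise ValueError("one factor name per factor axis required")

    ss = _effect_ss(y)
    subj_related = sum(v for k, v in ss.items() if 0 in k)
    # numerical floor: marginal-mean round-off produces SS ~ eps^2 * total
    total_ss = float(np.sum((y - y.mean()) ** 2))
    floor = total_ss * 1e-20

    out: list[AnovaEffect] = []
    for r in range(1, n_fac + 1):
        for subset in itertools.combinations(range(1, n_fac + 1), r):
            name = ":".join(factor_names[a - 1] for a in subset)
            ss_eff = ss[subset]
            ss_err = ss[(0,) + subset]
            df_den = n - 1
            if ss_eff <= floor and ss_err <= floor:
                F, p = 0.0, 1.0
            elif ss_err <= 0:
                F, p = np.inf, 0.0
            else:
                F = ss_eff / (ss_err / df_den)  # df_num = 1
                p = float(sps.f.sf(F, 1, df_den))
            ges = ss_eff / (ss_eff + subj_related) if (ss_eff + subj_related) > 0 else 0.0
            out.append(AnovaEffect(name, float(F), 1, df_den, p, float(ges)))
    return out


def anova_table(effects: list[AnovaEffect]):
    """Long-format pandas table of ANOVA effects."""
    import pandas as pd

    return pd.DataFrame(
        [{"effect": e.effect, "F": e.F, "df1": e.df_num, "df2": e.df_den,
          "p": e.p, "eta_sq_g": e.eta_sq_g} for e in effects]
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def wilcoxon_signed_rank(x, y, exact_max_n: int = 12
                         ) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test; returns (z, p).

    Zero differences are dropped (Wilcoxon's convention); ties share
    midranks.  For n (non-zero differences) <= ``exact_max_n`` the p-value
    is computed by exhaustive enumeration of all sign assignments of the
    observed ranks; otherwise the normal approximation with tie correction
    and a 0.5 continuity correction is used.  z is always reported from
    the normal approximation so its sign carries the direction.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size < 5:
        raise ValueError("need at least 5 pairs")
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    n = d.size
    mu = n * (n + 1) / 4.0
    # tie correction for the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    diff = w_pos - mu
    cc = min(0.5, abs(diff))  # continuity correction toward the mean
    z = 0.0 if sigma2 == 0 else (diff - math.copysign(cc, diff)) / math.sqrt(sigma2)

    if n <= exact_max_n:
        # enumerate all 2^n sign assignments of the observed (tied) ranks
        stats_all = np.zeros(1)
        for r in ranks:
            stats_all = np.concatenate([stats_all, stats_all + r])
        dev_obs = abs(w_pos - mu)
        p = float(np.mean(np.abs(stats_all - mu) >= dev_obs - 1e-12))
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return z, min(p, 1.0)


# ---------------------------------------------------------------------------
# Huber IRLS robust regression


@dataclass(frozen=True)
class RobustFit:
    params: np.ndarray
    bse: np.ndarray
    names: list[str]
    weights: np.ndarray = field(repr=False)
    scale: float
    model_F: float
    df_model: int
    df_resid: int
    p_model: float
    n_iter: int

    def summary_rows(self) -> list[dict]:
        rows = []
        for name, b, se in zip(self.names, self.params, self.bse):
            t = b / se if se > 0 else np.inf
            p = float(2.0 * sps.t.sf(abs(t), self.df_resid))
            rows.append({"term": name, "estimate": float(b), "se": float(se),
                         "t": float(t), "p": p, "stars": _stars(p)})
        return rows


def _stars(p: float) -> str:
    return "***" if p <= 0.001 else "**" if p <= 0.01 else "*" if p <= 0.05 else ""


def _huber_psi(r: np.ndarray, c: float) -> np.ndarray:
    return np.clip(r, -c, c)


def huber_irls(X: np.ndarray, y: np.ndarray, tuning: float = 1.345,
               names: list[str] | None = None, max_iter: int = 50,
               tol: float = 1e-8) -> RobustFit:
    """Huber M-estimation by iteratively reweighted least squares.

    Scale is re-estimated each iteration as the scaled MAD of residuals.
    Convergence: relative coefficient change < ``tol``; exceeding
    ``max_iter`` raises with the iteration trace.  Standard errors use the
    standard Huber sandwich-free (H1) asymptotic form; the model F is a
    robust Wald test of all non-intercept coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2 * p:
        raise ValueError(f"need at least {2 * p} observations for {p} terms")
    if names is None:
        names = [f"b{j}" for j in range(p)]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    trace = []
    w = np.ones(n)
    scale = 1.0
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        scale = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        if scale <= 0:
            scale = max(float(np.std(resid)), np.finfo(float).tiny)
        u = resid / scale
        au = np.maximum(np.abs(u), np.finfo(float).tiny)
        w = np.where(au <= tuning, 1.0, tuning / au)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        rel = np.max(np.abs(beta_new - beta)) / max(np.max(np.abs(beta)), 1e-12)
        trace.append(rel)
        beta = beta_new
        if rel < tol:
            break
    else:
        raise RuntimeError(
            f"Huber IRLS did not converge in {max_iter} iterations; "
            f"relative-change trace: {trace}"
        )
    resid = y - X @ beta
    u = resid / scale
    psi = _huber_psi(u, tuning)
    dpsi = (np.abs(u) <= tuning).astype(float)
    k = float(dpsi.mean())
    # H1 correction factor (Huber 1981, statsmodels RLM default)
    h1 = 1.0 + (p / n) * (1.0 - k) / k
    s2 = (scale ** 2) * float(np.sum(psi ** 2)) / (n - p) / (k ** 2) * h1 ** 2
    cov = s2 * np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.diag(cov))
    # robust Wald F over all non-intercept terms
    has_icept = np.allclose(X[:, 0], 1.0)
    sel = np.arange(1 if has_icept else 0, p)
    q = len(sel)
    b_sub = beta[sel]
    V_sub = cov[np.ix_(sel, sel)]
    Fstat = float(b_sub @ np.linalg.solve(V_sub, b_sub) / q) if q else 0.0
    df_resid = n - p
    p_model = float(sps.f.sf(Fstat, q, df_resid)) if q else 1.0
    return RobustFit(beta, bse, list(names), w, scale, Fstat, q, df_resid,
                     p_model, it)


# ---------------------------------------------------------------------------
# exact binomial test


@dataclass(frozen=True)
class BinomialResult:
    k: int
    n: int
    p0: float
    p_value: float


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> BinomialResult:
    """Exact two-sided binomial test (minimum-likelihood method).

    p = sum of P(X = j) over all j whose point probability does not exceed
    P(X = k) (with a small relative tolerance).  For p0 = 0.5 this equals
    the doubled smaller tail, capped at 1.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    j = np.arange(n + 1)
    pmf = sps.binom.pmf(j, n, p0)
    p_obs = pmf[k]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return BinomialResult(k, n, p0, min(p, 1.0))
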