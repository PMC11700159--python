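"""Group-comparison statistics for per-cell electrophysiology endpoints.

* ROUT outlier removal (Q = 0.05): robust center/scale plus an
  FDR-controlled outside-in t-test on the most extreme residuals.
* Kruskal-Wallis omnibus with post-hoc Dunn pairwise z-tests (Holm
  adjustment by default; Bonferroni and Sidak available).
* Mann-Whitney U (exact for small samples without ties, tie-corrected
  normal approximation otherwise).
* Mixed-design (split-plot) two-way ANOVA with Greenhouse-Geisser
  epsilon-corrected degrees of freedom for the within-subject effects,
  plus Tukey HSD on the between-group marginal means.
* Origin-constrained one-phase association fits
  Y = Plateau * (1 - exp(-K * x)) and lines through the origin, compared
  between groups by extra-sum-of-squares F-tests.

Significance is defined as p < 0.05 throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit

from .trace_model import ClampKitError

__all__ = [
    "StatsError",
    "GroupSample",
    "rout_outliers",
    "kruskal_dunn",
    "mann_whitney",
    "rm_anova_gg",
    "tukey_posthoc",
    "one_phase_f_test",
    "line_f_test",
    "MixedAnovaResult",
]

ALPHA = 0.05


class StatsError(ClampKitError):
    pass


@dataclass(frozen=True)
class GroupSample:
    """Per-cell measurements for one genotype x treatment group."""

    label: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 1:
            raise ValueError(f"group {self.label!r} has no finite values")
        object.__setattr__(self, "values", arr)


# ---------------------------------------------------------------------------
# ROUT outlier removal
# ---------------------------------------------------------------------------

def rout_outliers(
    values: Sequence[float], q: float = 0.05, max_fraction: float = 0.3
) -> Tuple[np.ndarray, np.ndarray]:
    """Partition a univariate sample into (kept, removed) by ROUT at rate Q.

    Residuals are taken from the median; the robust scale is the 68.27th
    percentile of the absolute residuals (the robust standard deviation of
    a Gaussian core).  The most extreme candidates — at most
    ``max_fraction`` of the sample — are tested outside-in with two-sided
    t-tests under Benjamini-Hochberg-style thresholds p_j <= Q * j / n
    (j = 1 for the most extreme point), and every point at least as extreme
    as the innermost significant one is removed.  The partition does not
    depend on input order.  Samples of fewer than four points are returned
    untouched with a warning.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 4:
        warnings.warn("ROUT needs n >= 4; returning all values", stacklevel=2)
        return arr.copy(), np.empty(0)
    center = float(np.median(arr))
    resid = arr - center
    rsdr = float(np.percentile(np.abs(resid), 68.27))
    if rsdr <= 0:
        return arr.copy(), np.empty(0)
    rsdr *= np.sqrt(n / (n - 1.0))  # small-sample inflation

    order = np.argsort(-np.abs(resid), kind="stable")
    df = n - 1
    n_candidates = max(1, int(np.floor(max_fraction * n)))
    n_remove = 0
    for j in range(1, n_candidates + 1):
        t = abs(resid[order[j - 1]]) / rsdr
        p = 2.0 * sps.t.sf(t, df)
        if p <= q * j / n:
            n_remove = j
    removed_idx = order[:n_remove]
    mask = np.ones(n, dtype=bool)
    mask[removed_idx] = False
    return arr[mask], arr[~mask]


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

ADJUSTMENTS = ("holm", "bonferroni", "sidak", "none")


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "sidak":
        return 1.0 - (1.0 - p) ** m
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise StatsError(f"unknown adjustment {method!r}")


def kruskal_dunn(
    groups: Sequence[GroupSample], adjustment: str = "holm"
) -> Dict:
    """Kruskal-Wallis omnibus plus Dunn pairwise rank z-tests.

    Returns a dict with ``H``, ``p`` and a ``pairwise`` DataFrame (z, raw
    and adjusted p per group pair).  All values tied across all groups
    gives H = 0, p = 1.
    """
    if len(groups) < 3:
        raise StatsError("Kruskal-Wallis here expects >= 3 groups")
    for g in groups:
        if g.values.size < 3:
            raise StatsError(f"group {g.label!r} has fewer than 3 values")

    pooled = np.concatenate([g.values for g in groups])
    n = pooled.size
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
        ranks = np.full(n, (n + 1) / 2.0)
    else:
        h, p = sps.kruskal(*[g.values for g in groups])
        ranks = sps.rankdata(pooled)

    # tie correction factor for the pooled rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sizes = [g.values.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]

    rows = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(groups), 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)))
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        rows.append((gi.label, gj.label, z, 2.0 * sps.norm.sf(abs(z))))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    pairwise["p_adj"] = _adjust(pairwise["p_raw"].to_numpy(), adjustment)
    return {"H": float(h), "p": float(p), "pairwise": pairwise}


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for n <= 8 per group without ties,
    tie-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise StatsError("Mann-Whitney here expects n >= 3 per group")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# mixed-design ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------

@dataclass
class MixedAnovaResult:
    """Split-plot ANOVA table plus the sphericity correction factor."""

    table: pd.DataFrame  # effect, ss, df1, df2, F, p, p_gg
    epsilon: float  # Greenhouse-Geisser epsilon-hat, in [1/(k-1), 1]
    n_subjects: int
    n_levels: int


def _gg_epsilon(within_matrix: np.ndarray, group_codes: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    k = within_matrix.shape[1]
    if k == 2:
        return 1.0
    centered = within_matrix.astype(float).copy()
    for g in np.unique(group_codes):
        sel = group_codes == g
        centered[sel] -= centered[sel].mean(axis=0, keepdims=True)
    n = within_matrix.shape[0]
    dof = max(n - np.unique(group_codes).size, 1)
    s = centered.T @ centered / dof
    c = np.eye(k) - np.ones((k, k)) / k
    sc = c @ s @ c
    tr = np.trace(sc)
    tr2 = np.trace(sc @ sc)
    if tr2 <= 0:
        return 1.0 / (k - 1)
    eps = tr**2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    subject: str = "subject",
    between: str = "group",
) -> MixedAnovaResult:
    """Mixed two-way ANOVA (between groups x repeated within levels).

    Subjects missing any within level are excluded listwise with a warning.
    The Greenhouse-Geisser epsilon-hat deflates the degrees of freedom of
    the within and interaction F-tests; epsilon is exactly 1 for two within
    levels, where sphericity holds trivially.
    """
    wide = data.pivot_table(index=[subject, between], columns=within, values=dv)
    if wide.isna().any().any():
        n_drop = int(wide.isna().any(axis=1).sum())
        warnings.warn(
            f"excluding {n_drop} subject(s) with incomplete within-level data",
            stacklevel=2,
        )
        wide = wide.dropna()
    subjects = wide.index.get_level_values(subject)
    groups = wide.index.get_level_values(between).to_numpy()
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    glabels, gcodes = np.unique(groups, return_inverse=True)
    g = glabels.size
    if g < 2 or k < 2 or n < 2 * g:
        raise StatsError(
            "mixed ANOVA needs >= 2 groups, >= 2 within levels and >= 2 "
            "subjects per group"
        )

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_sizes = np.array([(gcodes == i).sum() for i in range(g)])
    group_means = np.array([subj_means[gcodes == i].mean() for i in range(g)])
    level_means = y.mean(axis=0)
    cell_means = np.array([y[gcodes == i].mean(axis=0) for i in range(g)])

    ss_between_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_group = k * float(np.sum(group_sizes * (group_means - grand) ** 2))
    ss_subj_err = ss_between_subj - ss_group
    ss_total = float(np.sum((y - grand) ** 2))
    ss_within_subj = ss_total - ss_between_subj
    ss_level = n * float(np.sum((level_means - grand) ** 2))
    ss_cells = float(np.sum(group_sizes[:, None] * (cell_means - grand) ** 2))
    ss_inter = ss_cells - ss_group - ss_level
    ss_err_within = ss_within_subj - ss_level - ss_inter

    eps = _gg_epsilon(y, gcodes)

    def frow(effect, ss, df1, ss_err, df2, corrected):
        ms, ms_err = ss / df1, ss_err / df2
        f = ms / ms_err if ms_err > 0 else np.inf
        p = float(sps.f.sf(f, df1, df2))
        p_gg = float(sps.f.sf(f, df1 * eps, df2 * eps)) if corrected else np.nan
        return (effect, ss, df1, df2, f, p, p_gg)

    rows = [
        frow("group", ss_group, g - 1, ss_subj_err, n - g, False),
        frow("within", ss_level, k - 1, ss_err_within, (n - g) * (k - 1), True),
        frow("interaction", ss_inter, (g - 1) * (k - 1), ss_err_within, (n - g) * (k - 1), True),
    ]
    table = pd.DataFrame(rows, columns=["effect", "ss", "df1", "df2", "F", "p", "p_gg"])
    return MixedAnovaResult(table=table, epsilon=eps, n_subjects=n, n_levels=k)


def tukey_posthoc(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    subject: str = "subject",
    between: str = "group",
) -> pd.DataFrame:
    """Tukey HSD on group marginal means (subject means across within levels)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    subj = data.groupby([subject, between], observed=True)[dv].mean().reset_index()
    res = pairwise_tukeyhsd(subj[dv].to_numpy(), subj[between].to_numpy())
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[c.strip() for c in res.summary().data[0]]
    )
    frame = frame.rename(
        columns={"group1": "group_a", "group2": "group_b", "p-adj": "p_adj"}
    )
    return frame[["group_a", "group_b", "meandiff", "p_adj", "reject"]]


# ---------------------------------------------------------------------------
# origin-constrained curve fits and extra-sum-of-squares F-tests
# ---------------------------------------------------------------------------

def _one_phase(x, plateau, k):
    return plateau * (1.0 - np.exp(-k * x))


def _fit_one_phase(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Least-squares (Plateau, K) with the curve constrained through the
    origin; returns (plateau, k, rss)."""
    if x.size < 4:
        raise StatsError("one-phase fit needs >= 4 points")
    xpos = x[x > 0]
    k0 = 1.0 / float(np.median(xpos)) if xpos.size else 1.0
    p0 = (max(float(np.max(y)), 1e-6), k0)
    try:
        popt, _ = curve_fit(
            _one_phase,
            x,
            y,
            p0=p0,
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=20_000,
            xtol=1e-12,
            ftol=1e-12,
        )
    except RuntimeError as exc:
        raise StatsError(f"one-phase fit did not converge: {exc}") from exc
    rss = float(np.sum((y - _one_phase(x, *popt)) ** 2))
    return float(popt[0]), float(popt[1]), rss


def _extra_ss_f(
    rss_shared: float, df_shared: int, rss_sep: float, df_sep: int
) -> Tuple[float, float]:
    if df_sep <= 0 or rss_sep <= 0:
        raise StatsError("separate-fit degrees of freedom exhausted")
    f = ((rss_shared - rss_sep) / (df_shared - df_sep)) / (rss_sep / df_sep)
    f = max(f, 0.0)
    p = float(sps.f.sf(f, df_shared - df_sep, df_sep))
    return float(f), p


def one_phase_f_test(
    x: Sequence[float], y: Sequence[float], labels: Sequence
) -> Dict:
    """Compare one-phase association curves through the origin between groups.

    Fits Y = Plateau * (1 - exp(-K x)) to the pooled data (shared
    parameters) and to each group separately, and compares the two models
    by an extra-sum-of-squares F-test.  Returns per-group and shared
    parameters, F, and p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    if np.any(x < 0):
        raise StatsError("x must be non-negative")
    glabels = np.unique(labels)
    if glabels.size < 2:
        raise StatsError("need >= 2 groups to compare")

    _, _, rss_shared = _fit_one_phase(x, y)
    shared = _fit_one_phase(x, y)
    per_group = {}
    rss_sep = 0.0
    for gl in glabels:
        sel = labels == gl
        pl, k, rss = _fit_one_phase(x[sel], y[sel])
        per_group[gl] = {"plateau": pl, "k": k, "rss": rss}
        rss_sep += rss
    n_params = 2
    df_shared = x.size - n_params
    df_sep = x.size - n_params * glabels.size
    f, p = _extra_ss_f(rss_shared, df_shared, rss_sep, df_sep)
    return {
        "shared": {"plateau": shared[0], "k": shared[1], "rss": rss_shared},
        "groups": per_group,
        "F": f,
        "p": p,
        "df": (df_shared - df_sep, df_sep),
    }


def line_f_test(x: Sequence[float], y: Sequence[float], labels: Sequence) -> Dict:
    """Same model comparison for lines through the origin (Y = slope * x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    glabels = np.unique(labels)
    if glabels.size < 2:
        raise StatsError("need >= 2 groups to compare")

    def fit(xs, ys):
        denom = float(np.sum(xs * xs))
        if denom == 0:
            raise StatsError("all x are zero; slope undefined")
        slope = float(np.sum(xs * ys) / denom)
        return slope, float(np.sum((ys - slope * xs) ** 2))

    slope_sh, rss_shared = fit(x, y)
    per_group = {}
    rss_sep = 0.0
    for gl in glabels:
        sel = labels == gl
        slope, rss = fit(x[sel], y[sel])
        per_group[gl] = {"slope": slope, "rss": rss}
        rss_sep += rss
    df_shared = x.size - 1
    df_sep = x.size - glabels.size
    f, p = _extra_ss_f(rss_shared, df_shared, rss_sep, df_sep)
    return {
        "shared": {"slope": slope_sh, "rss": rss_shared},
        "groups": per_group,
        "F": f,
        "p": p,
        "df": (df_shared - df_sep, df_sep),
    }
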