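"""Group statistics: unpaired t-test, one-way ANOVA, Duncan's multiple range.

Duncan's multiple range test compares ordered group means step-down: a
stretch of ``p`` adjacent ordered means is tested against the critical range

    R_p = q(alpha_p, p, df_error) * sqrt(MSE / n_h),

where ``q`` is the upper-``alpha_p`` studentized-range quantile at the
protection level ``alpha_p = 1 - (1 - alpha)^(p-1)``, MSE / df_error come
from the one-way ANOVA, and ``n_h`` is the harmonic mean of the two compared
group sizes (Kramer adjustment for unequal n).  A pair differs significantly
iff its difference exceeds R_p and no enclosing stretch has already been
declared homogeneous.  No correction across markers is applied on top.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .panel_io import EventMatrix


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float


def unpaired_ttest(a, b, variant: str = "student") -> TTestResult:
    """Two-sided unpaired t-test of two samples.

    ``student`` pools variances (df = n_a + n_b - 2); ``welch`` uses the
    Satterthwaite approximation.  Two identical constant samples give
    t = 0, p = 1 by convention; zero combined variance with unequal means is
    a hard error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    ma, mb = a.mean(), b.mean()
    diff = ma - mb
    if va + vb == 0.0:
        if diff == 0.0:
            df = (a.size + b.size - 2) if variant == "student" else np.nan
            return TTestResult(0.0, float(df), 1.0, float(ma), float(mb))
        raise ValueError("zero variance with unequal means")
    if variant == "student":
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    elif variant == "welch":
        sa2, sb2 = va / a.size, vb / b.size
        se = np.sqrt(sa2 + sb2)
        df = (sa2 + sb2) ** 2 / (
            sa2 ** 2 / (a.size - 1) + sb2 ** 2 / (b.size - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), float(ma), float(mb))


def one_way_anova(values, groups):
    """Standard one-way decomposition.

    Returns ``(ms_between, ms_within, df_error, F, p)``; MSE (= ms_within)
    and df_error feed :func:`duncan_mrt`.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels, inverse = np.unique(groups, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    ns = np.bincount(inverse)
    if (ns < 2).any():
        small = labels[ns < 2]
        raise ValueError(f"group(s) with < 2 values: {list(small)}")
    grand = values.mean()
    means = np.array([values[inverse == g].mean() for g in range(k)])
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(
        ((values[inverse == g] - means[g]) ** 2).sum() for g in range(k)))
    df_between = k - 1
    df_error = values.size - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_error
    if ms_within == 0.0:
        F = 0.0 if ms_between == 0.0 else np.inf
    else:
        F = ms_between / ms_within
    p = float(stats.f.sf(F, df_between, df_error)) if np.isfinite(F) else 0.0
    return ms_between, ms_within, df_error, float(F), p


_INF_DF = 1e5  # above this, use the normal-limit range distribution


def _range_sf_normal(q: float, k: int) -> float:
    """Upper-tail P(range of k iid N(0,1) > q)."""
    if q <= 0:
        return 1.0

    def integrand(z: float) -> float:
        return stats.norm.pdf(z) * (
            stats.norm.cdf(z) - stats.norm.cdf(z - q)) ** (k - 1)

    cdf, _ = integrate.quad(integrand, -8.0 - q, 8.0, limit=200)
    return float(np.clip(1.0 - k * cdf, 0.0, 1.0))


@lru_cache(maxsize=4096)
def studentized_range_quantile(prob: float, k: int, df: float) -> float:
    """Upper-tail quantile q with P(Q_{k,df} > q) = prob.

    Finite df delegates to scipy's studentized-range distribution; very large
    df (> 1e5) uses the exact normal-limit integral, where the range of k
    standard normals replaces the studentized range.
    """
    if not (0.0 < prob < 1.0):
        raise ValueError("prob must be in (0, 1)")
    if k < 2 or df < 1:
        raise ValueError("need k >= 2 and df >= 1")
    if df > _INF_DF:
        f = lambda q: _range_sf_normal(q, k) - prob  # noqa: E731
        return float(optimize.brentq(f, 1e-6, 60.0, xtol=1e-6))
    q = float(stats.studentized_range.isf(prob, k, df))
    if not np.isfinite(q):
        raise RuntimeError(
            f"studentized range quantile failed for prob={prob}, k={k}, "
            f"df={df}")
    return q


@dataclass
class MRTResult:
    """Duncan multiple-range outcome for one response variable."""

    groups: list            # labels ordered by descending mean
    means: np.ndarray       # sorted descending
    ns: np.ndarray          # group sizes in the same order
    mse: float
    df_error: int
    alpha: float
    critical_ranges: dict   # p -> R_p at the overall harmonic mean n
    significant: np.ndarray  # symmetric boolean matrix in sorted order
    homogeneous_subsets: list

    def pairs_table(self) -> pd.DataFrame:
        rows = []
        k = len(self.groups)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append({
                    "group_a": self.groups[i], "group_b": self.groups[j],
                    "diff": self.means[i] - self.means[j],
                    "significant": bool(self.significant[i, j]),
                })
        return pd.DataFrame(rows)


def duncan_alpha_p(alpha: float, p: int) -> float:
    """Duncan protection level for a stretch of p means."""
    return 1.0 - (1.0 - alpha) ** (p - 1)


def duncan_mrt(values, groups, alpha: float = 0.05) -> MRTResult:
    """Duncan's multiple range test; see the module docstring."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    _, mse, df_error, _, _ = one_way_anova(values, groups)
    labels = np.unique(groups)
    means = np.array([values[groups == g].mean() for g in labels])
    ns = np.array([(groups == g).sum() for g in labels])
    order = np.argsort(-means, kind="stable")
    labels, means, ns = labels[order], means[order], ns[order]
    k = labels.size

    def critical_range(p: int, n_h: float) -> float:
        q = studentized_range_quantile(duncan_alpha_p(alpha, p), p,
                                       float(df_error))
        return q * np.sqrt(mse / n_h)

    significant = np.zeros((k, k), dtype=bool)
    homogeneous: list[tuple[int, int]] = []

    def blocked(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in homogeneous)

    # widest stretches first: step-down protection
    for p in range(k, 1, -1):
        for i in range(0, k - p + 1):
            j = i + p - 1
            if blocked(i, j):
                continue
            n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
            if (means[i] - means[j]) > critical_range(p, n_h):
                significant[i, j] = significant[j, i] = True
            else:
                homogeneous.append((i, j))

    # maximal intervals of sorted means containing no significant pair
    spans = []
    for i in range(k):
        j = i
        while j + 1 < k and not significant[i: j + 2, i: j + 2].any():
            j += 1
        spans.append((i, j))
    maximal = [
        list(labels[a: b + 1]) for a, b in spans
        if not any(c <= a and b <= d and (c, d) != (a, b) for c, d in spans)
    ]

    n_h_all = k / (1.0 / ns).sum()
    crit = {p: critical_range(p, n_h_all) for p in range(2, k + 1)}
    return MRTResult(
        groups=list(labels), means=means, ns=ns, mse=float(mse),
        df_error=int(df_error), alpha=alpha, critical_ranges=crit,
        significant=significant, homogeneous_subsets=maximal,
    )


def marker_contrasts(pooled: EventMatrix, markers: list[str],
                     grouping: str = "ilc_type",
                     alpha: float = 0.05,
                     min_group_size: int = 2):
    """Per-marker Duncan comparisons across ILC subsets or clusters.

    ``grouping`` selects the ``phenotype`` (ILC subsets only) or ``cluster``
    annotation.  Groups with fewer than ``min_group_size`` events are
    excluded with a warning; fewer than two surviving groups is an error.
    Returns ``(results, group_means)`` where ``results`` maps marker ->
    :class:`MRTResult` and ``group_means`` is the per-group mean table.
    """
    import logging
    logger = logging.getLogger(__name__)
    ann = pooled.annotations
    if grouping == "ilc_type":
        if "phenotype" not in ann.columns:
            raise ValueError("events are not classified")
        keep = ann["phenotype"] != "nonILC"
        labels = ann.loc[keep, "phenotype"].to_numpy()
        data = pooled.data.loc[keep.to_numpy()]
    elif grouping == "cluster":
        if "cluster" not in ann.columns:
            raise ValueError("events are not clustered")
        labels = ann["cluster"].to_numpy()
        data = pooled.data
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    uniq, counts = np.unique(labels, return_counts=True)
    small = uniq[counts < min_group_size]
    if small.size:
        logger.warning("excluding %d group(s) with < %d events: %s",
                       small.size, min_group_size, list(small))
        keep2 = ~np.isin(labels, small)
        labels = labels[keep2]
        data = data.loc[keep2]
    if np.unique(labels).size < 2:
        raise ValueError("marker contrasts need >= 2 non-empty groups")

    results: dict[str, MRTResult] = {}
    mean_rows = []
    for m in markers:
        if m not in data.columns:
            raise KeyError(f"marker {m!r} not in events")
        v = data[m].to_numpy(dtype=float)
        results[m] = duncan_mrt(v, labels, alpha=alpha)
        for g in np.unique(labels):
            mean_rows.append({"marker": m, "group": g,
                              "mean": float(v[labels == g].mean()),
                              "n": int((labels == g).sum())})
    return results, pd.DataFrame(mean_rows)
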