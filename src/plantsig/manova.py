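"""Multivariate comparison of metric distributions between feature spaces.

The per-draw (balanced accuracy, F1, MCC) triples of the Monte Carlo
benchmark form multivariate samples, one group per feature space (15D
raw features vs 7D principal components). Whether the group centroids
differ is tested with one-way MANOVA: eigenvalues lambda_i of W^-1 B —
W the pooled within-group scatter, B the between-group scatter — yield
the four classical trace statistics

* Pillai-Bartlett trace  V = sum lambda / (1 + lambda)
* Hotelling-Lawley trace U = sum lambda
* Wilks' lambda          L = prod 1 / (1 + lambda)
* Roy's greatest root    T = max lambda

with s = min(p, g - 1) nonzero discriminant variates. Because the
benchmark uses common random numbers, the paired per-draw difference
vector (15D - 7D) can also be tested directly with the one-sample
location test :class:`GroupLocationTest`, which is the repeated-measure
reading of the comparison; for a single group it reduces to Hotelling's
one-sample T^2.

F approximations follow standard references (Rao's formula for Wilks;
the usual Pillai / Hotelling-Lawley approximations; an upper-bound F
for Roy). For two groups all four statistics carry the same exact
two-sample Hotelling T^2 F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats


@dataclass(frozen=True)
class GroupedMetrics:
    """One group's R x p matrix of per-draw metric vectors."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite metric values")
        if v.shape[0] < v.shape[1] + 2:
            raise ValueError("need at least p + 2 rows per group")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ManovaResult:
    """Eigenvalues and the four trace statistics with F approximations.

    One row per statistic in :meth:`summary`, mirroring the usual MANOVA
    table layout (Statistic, Value, F, R^2, df1, df2, p). R^2 is the
    Pillai-type effect size V / s.
    """

    eigenvalues: np.ndarray
    statistics: dict[str, float]       # pillai, wilks, hotelling, roy
    f_stats: dict[str, float]
    df1: dict[str, float]
    df2: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    effect: str = "group"

    def summary(self) -> pd.DataFrame:
        names = {"pillai": "Pillai (V)", "wilks": "Wilks (Lambda)",
                 "hotelling": "Hotelling (U)", "roy": "Roy (Theta)"}
        rows = []
        for key, label in names.items():
            rows.append({
                "Between": self.effect,
                "Statistic": label,
                "Value": self.statistics[key],
                "F": self.f_stats[key],
                "R2": self.r_squared,
                "df1": self.df1[key],
                "df2": self.df2[key],
                "p": self.p_values[key],
            })
        return pd.DataFrame(rows)


def scatter_matrices(groups: list[GroupedMetrics]) -> tuple[np.ndarray, np.ndarray]:
    """Within (W) and between (B) scatter matrices of the groups.

    W + B equals the total scatter about the grand mean (up to
    roundoff).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    all_x = np.vstack([g.values for g in groups])
    grand = all_x.mean(axis=0)
    p = all_x.shape[1]
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for g in groups:
        x = g.values
        mean = x.mean(axis=0)
        dev = x - mean
        w += dev.T @ dev
        dm = (mean - grand)[:, None]
        b += x.shape[0] * (dm @ dm.T)
    return w, b


def manova_eigenvalues(w: np.ndarray, b: np.ndarray,
                       s: int | None = None) -> np.ndarray:
    """Descending eigenvalues of W^-1 B (clipped at 0).

    ``s`` truncates to the number of discriminant variates,
    min(p, g - 1); rank(B) bounds the nonzero count anyway.
    """
    if np.linalg.cond(w) > 1e10:
        raise ValueError("within-group scatter is singular or ill-conditioned; "
                         "de-duplicate or drop collinear metrics")
    solved = linalg.solve(w, b)
    eigs = linalg.eigvals(solved).real
    eigs = np.where(eigs < 0, np.where(eigs > -1e-10, 0.0, eigs), eigs)
    if np.any(eigs < 0):
        eigs = np.clip(eigs, 0.0, None)
    eigs = np.sort(eigs)[::-1]
    if s is not None:
        eigs = eigs[:s]
    return eigs


def trace_statistics(eigenvalues) -> dict[str, float]:
    """The four MANOVA trace statistics of an eigenvalue set.

    V = sum l/(1+l); U = sum l; Lambda = prod 1/(1+l); Theta = max l.
    """
    lam = np.asarray(eigenvalues, float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    return {
        "pillai": float(np.sum(lam / (1.0 + lam))),
        "hotelling": float(np.sum(lam)),
        "wilks": float(np.prod(1.0 / (1.0 + lam))),
        "roy": float(lam.max()) if lam.size else 0.0,
    }


def _f_approximations(stats_: dict[str, float], lam: np.ndarray,
                      p: int, q: int, v_e: float) -> ManovaResult:
    """Standard F approximations for the four statistics.

    p dependent variables, q hypothesis degrees of freedom, v_e error
    degrees of freedom.
    """
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    n_e = (v_e - p - 1) / 2.0
    f_stats, df1, df2, pvals = {}, {}, {}, {}

    v = stats_["pillai"]
    d1 = s * (2 * m + s + 1)
    d2 = s * (2 * n_e + s + 1)
    f_stats["pillai"] = (v / (s - v)) * (d2 / d1) if s > v else np.inf
    df1["pillai"], df2["pillai"] = d1, d2

    lam_w = stats_["wilks"]
    t_num = p**2 * q**2 - 4
    t_den = p**2 + q**2 - 5
    t = np.sqrt(t_num / t_den) if t_den > 0 else 1.0
    df1_w = p * q
    df2_w = (v_e + q - (p + q + 1) / 2.0) * t - (p * q - 2) / 2.0
    lw_t = lam_w ** (1.0 / t)
    f_stats["wilks"] = ((1 - lw_t) / lw_t) * (df2_w / df1_w) if lw_t > 0 else np.inf
    df1["wilks"], df2["wilks"] = df1_w, df2_w

    u = stats_["hotelling"]
    if n_e > 0:
        # SAS's F approximation (McKeon) for the Hotelling-Lawley trace
        b_c = (p + 2 * n_e) * (q + 2 * n_e) / (2 * (2 * n_e + 1) * (n_e - 1))
        d1_h = p * q
        d2_h = 4 + (p * q + 2) / (b_c - 1)
        c_c = (d2_h - 2) / (2 * n_e)
        f_stats["hotelling"] = (d2_h / d1_h) * u / c_c
    else:
        d1_h = s * (2 * m + s + 1)
        d2_h = s * (s * n_e + 1)
        f_stats["hotelling"] = u * d2_h / (s * d1_h) if d1_h > 0 else np.inf
    df1["hotelling"], df2["hotelling"] = d1_h, d2_h

    theta = stats_["roy"]
    r = max(p, q)
    d2_r = v_e - r + q
    f_stats["roy"] = theta * d2_r / r
    df1["roy"], df2["roy"] = r, d2_r

    if q == 1:
        # two-group (or one-sample) case: all four carry the exact
        # Hotelling T^2 F with df (p, v_e - p + 1)
        lam1 = lam[0] if lam.size else 0.0
        d2_e = v_e - p + 1
        f_exact = lam1 * d2_e / p
        for key in f_stats:
            f_stats[key] = f_exact
            df1[key], df2[key] = p, d2_e

    for key in f_stats:
        if df2[key] > 0 and np.isfinite(f_stats[key]):
            pvals[key] = float(stats.f.sf(f_stats[key], df1[key], df2[key]))
        else:
            pvals[key] = np.nan
    return ManovaResult(
        eigenvalues=lam,
        statistics=stats_,
        f_stats=f_stats,
        df1=df1,
        df2=df2,
        p_values=pvals,
        r_squared=stats_["pillai"] / s,
    )


def oneway_manova(groups: list[GroupedMetrics]) -> ManovaResult:
    """One-way MANOVA of the null that all group mean vectors coincide."""
    w, b = scatter_matrices(groups)
    g = len(groups)
    n_total = sum(gr.values.shape[0] for gr in groups)
    p = groups[0].values.shape[1]
    q = g - 1
    s = min(p, q)
    lam = manova_eigenvalues(w, b, s=s)
    stats_ = trace_statistics(lam)
    return _f_approximations(stats_, lam, p, q, v_e=n_total - g)


def group_location_test(group: GroupedMetrics,
                        reference: np.ndarray | float = 0.0) -> ManovaResult:
    """One-sample multivariate location test of a group mean.

    Hotelling's one-sample T^2 = n m'S^-1 m (m the mean deviation from
    the reference, S the sample covariance) cast into the eigenvalue
    form lambda = T^2 / (n - 1), so the four trace statistics follow
    from :func:`trace_statistics` on the single eigenvalue.
    """
    x = group.values
    n, p = x.shape
    if n <= p:
        raise ValueError("need n > p observations")
    ref = np.broadcast_to(np.asarray(reference, float), (p,))
    m = x.mean(axis=0) - ref
    s_cov = np.cov(x, rowvar=False, ddof=1)
    if np.linalg.cond(s_cov) > 1e10:
        raise ValueError("singular or ill-conditioned covariance matrix; "
                         "de-duplicate or drop collinear metrics")
    t2 = float(n * m @ linalg.solve(s_cov, m))
    lam = np.array([t2 / (n - 1)])
    stats_ = trace_statistics(lam)
    result = _f_approximations(stats_, lam, p=p, q=1, v_e=n - 1)
    return ManovaResult(
        eigenvalues=result.eigenvalues,
        statistics=result.statistics,
        f_stats=result.f_stats,
        df1=result.df1,
        df2=result.df2,
        p_values=result.p_values,
        r_squared=result.r_squared,
        effect=f"location({group.label})",
    )


# ---------------------------------------------------------------------------
# Model / Results presentation
# ---------------------------------------------------------------------------

class Manova:
    """MANOVA model over groups of per-draw metric vectors.

    ``Manova.from_benchmark(results, classifier)`` builds the two-group
    (15D vs 7D) comparison of (bal_acc, f1, mcc) triples for one
    classifier directly from fitted :class:`~plantsig.resample.BenchmarkResults`.
    """

    METRICS = ("bal_acc", "f1", "mcc")

    def __init__(self, groups: list[GroupedMetrics]):
        self.groups = groups

    @classmethod
    def from_benchmark(cls, results, classifier: str,
                       spaces: tuple[str, str] = ("15d", "7d")) -> "Manova":
        groups = [
            GroupedMetrics(space, results.distribution(space, classifier)
                           .values[list(cls.METRICS)].to_numpy())
            for space in spaces
        ]
        return cls(groups)

    def fit(self) -> "ManovaResults":
        oneway = oneway_manova(self.groups)
        per_group = [group_location_test(g) for g in self.groups]
        paired = None
        sizes = {g.values.shape[0] for g in self.groups}
        if len(self.groups) == 2 and len(sizes) == 1:
            diff = self.groups[0].values - self.groups[1].values
            label = f"{self.groups[0].label}-{self.groups[1].label}"
            paired = group_location_test(GroupedMetrics(label, diff))
        return ManovaResults(self, oneway, per_group, paired)


@dataclass
class ManovaResults:
    """Fitted MANOVA comparison: one-way, per-group and paired tests."""

    model: Manova
    oneway: ManovaResult
    per_group: list[ManovaResult]
    paired: ManovaResult | None

    def summary(self) -> pd.DataFrame:
        parts = [self.oneway.summary()]
        parts += [r.summary() for r in self.per_group]
        if self.paired is not None:
            parts.append(self.paired.summary())
        return pd.concat(parts, ignore_index=True)
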