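"""The study's statistical decision procedure.

Every comparison is gated on a Lilliefors normality test (Kolmogorov–
Smirnov against a normal with estimated mean and s.d., p-value from a
seeded Monte-Carlo null):

* ≥ 3 groups → one-way ANOVA when every group passes the gate, otherwise
  Kruskal–Wallis (flagged — the non-normal multi-group branch is a
  package decision, not part of the original procedure);
* paired designs → paired t-test when the paired differences pass,
  otherwise Wilcoxon signed rank (with the positive/negative rank sums
  reported);
* one-sample comparisons against a theoretical mean (0 for the
  discrimination index, 22 for chance-level alternation percentage,
  1 for the no-enrichment microglia ratio) → one-sample t-test;
* training-course designs → mixed two-factor ANOVA with Greenhouse–
  Geisser correction (delegated to pingouin), with Šídák or Dunnett
  post-hoc comparisons.

Significance stars: * p<0.05, ** p<0.01, *** p<0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatReport",
    "lilliefors_test",
    "compare_groups",
    "compare_paired",
    "one_sample_test",
    "two_factor_report",
    "posthoc_pairwise",
    "significance_stars",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MC_REPS = 10_000


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class StatReport:
    """One comparison's result in the study's reporting schema."""

    test_name: str
    statistic: float
    df: tuple[float, ...] | float | None
    p_value: float
    normality: dict[str, float] | None = None
    normal: bool | None = None
    alpha: float = DEFAULT_ALPHA
    extras: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def as_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "normality": self.normality,
            "normal": self.normal,
            "alpha": self.alpha,
            "stars": self.stars,
            "significant": self.significant,
        }
        d.update(self.extras)
        return d


def _ks_stat_normal(x: np.ndarray) -> float:
    """KS distance between the sample ECDF and a normal with the sample's
    estimated mean and s.d. (the Lilliefors statistic)."""
    n = len(x)
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    d_plus = (np.arange(1, n + 1) / n - cdf).max()
    d_minus = (cdf - np.arange(0, n) / n).max()
    return float(max(d_plus, d_minus))


def lilliefors_test(
    sample: Sequence[float],
    n_monte_carlo: int = DEFAULT_MC_REPS,
    seed: int = 0,
) -> tuple[float, float]:
    """Lilliefors normality test with a Monte-Carlo p-value.

    The null distribution of the statistic is simulated by drawing
    ``n_monte_carlo`` standard-normal samples of the same size and
    re-estimating mean and s.d. on each replicate (estimation is what
    distinguishes Lilliefors from plain Kolmogorov–Smirnov).  The
    add-one rule ``p = (1 + #{D* ≥ D}) / (B + 1)`` keeps the p-value
    strictly positive.

    Returns ``(statistic, p_value)``.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise ValueError("Lilliefors test requires n >= 4")
    if x.std(ddof=1) == 0:
        raise ValueError("degenerate sample: zero variance")
    d_obs = _ks_stat_normal(x)
    rng = np.random.default_rng(seed)
    n = len(x)
    sims = rng.standard_normal((n_monte_carlo, n))
    # vectorised null: standardise each replicate by its own estimates
    z = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_null = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
    p = (1 + int((d_null >= d_obs).sum())) / (n_monte_carlo + 1)
    return d_obs, float(p)


def _normality_gate(
    samples: dict[str, np.ndarray],
    alpha: float,
    n_monte_carlo: int,
    seed: int,
) -> tuple[bool, dict[str, float]]:
    """Run Lilliefors per sample; all must pass to take the normal branch.
    Samples too small for the test (n < 4) are passed through with a NaN
    p-value and do not veto normality."""
    pvals: dict[str, float] = {}
    normal = True
    for k, (name, x) in enumerate(samples.items()):
        if len(x) < 4 or np.std(x, ddof=1) == 0:
            pvals[name] = float("nan")
            continue
        _, p = lilliefors_test(x, n_monte_carlo=n_monte_carlo, seed=seed + k)
        pvals[name] = p
        if p < alpha:
            normal = False
    return normal, pvals


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    value_col: str = "value",
    metric_col: str = "metric",
    alpha: float = DEFAULT_ALPHA,
    n_monte_carlo: int = 2000,
    seed: int = 0,
) -> StatReport:
    """Multi-group comparison: Lilliefors gate per group, then one-way
    ANOVA (normal branch) or Kruskal–Wallis (fallback, flagged).

    ``table`` is a tidy per-mouse table with one value per mouse for the
    requested metric.
    """
    sub = table[table[metric_col] == metric] if metric_col in table else table
    groups = {
        str(g): np.asarray(v[value_col], dtype=float)
        for g, v in sub.groupby(group_col, sort=True)
    }
    if len(groups) < 2:
        raise ValueError("compare_groups needs at least 2 groups")
    for name, x in groups.items():
        if len(x) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")
    normal, pvals = _normality_gate(groups, alpha, n_monte_carlo, seed)
    arrays = list(groups.values())
    k, n = len(arrays), sum(map(len, arrays))
    if normal:
        f, p = sps.f_oneway(*arrays)
        return StatReport(
            "one-way ANOVA", float(f), (k - 1, n - k), float(p),
            normality=pvals, normal=True, alpha=alpha,
            extras={"metric": metric, "groups": {g: len(x) for g, x in groups.items()}},
        )
    h, p = sps.kruskal(*arrays)
    return StatReport(
        "Kruskal-Wallis", float(h), float(k - 1), float(p),
        normality=pvals, normal=False, alpha=alpha,
        extras={
            "metric": metric,
            "fallback": "non-normal data: Kruskal-Wallis used instead of ANOVA",
            "groups": {g: len(x) for g, x in groups.items()},
        },
    )


def compare_paired(
    before: Sequence[float],
    after: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    n_monte_carlo: int = 2000,
    seed: int = 0,
) -> StatReport:
    """Paired comparison: Lilliefors gate on the paired differences, then
    paired t-test (normal) or Wilcoxon signed rank.

    The signed-rank branch uses the exact null for n ≤ 25 and the normal
    approximation above, and reports the positive and negative rank sums.
    All-zero differences are degenerate and reported as p = 1.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        return StatReport(
            "Wilcoxon signed rank", 0.0, None, 1.0, normal=None, alpha=alpha,
            extras={"degenerate": "all paired differences are zero"},
        )
    if d.std(ddof=1) == 0:  # constant nonzero shift: gate undefined, t exact
        normal, pvals = True, {"differences": float("nan")}
    else:
        normal, pvals = _normality_gate({"differences": d}, alpha, n_monte_carlo, seed)
    n = len(d)
    if normal:
        t, p = sps.ttest_rel(a, b)
        return StatReport(
            "paired t-test", float(t), float(n - 1), float(p),
            normality=pvals, normal=True, alpha=alpha,
        )
    nz = d[d != 0]
    ranks = sps.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    w_neg = float(ranks[nz < 0].sum())
    method = "exact" if len(nz) <= 25 else "approx"
    w, p = sps.wilcoxon(nz, method=method)
    return StatReport(
        "Wilcoxon signed rank", float(w), None, float(p),
        normality=pvals, normal=False, alpha=alpha,
        extras={"rank_sums": (w_pos, -w_neg), "method": method},
    )


def one_sample_test(
    sample: Sequence[float], reference: float, alpha: float = DEFAULT_ALPHA
) -> StatReport:
    """One-sample t-test against a theoretical mean (df = n − 1)."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 2:
        raise ValueError("one-sample test requires n >= 2")
    if not np.isfinite(reference):
        raise ValueError("reference must be finite")
    if x.std(ddof=1) == 0:
        raise ValueError("degenerate sample: zero variance")
    t, p = sps.ttest_1samp(x, reference)
    return StatReport(
        "one-sample t-test", float(t), float(len(x) - 1), float(p), alpha=alpha,
        extras={"reference": reference},
    )


def two_factor_report(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "day",
    between: str = "group",
    subject: str = "mouse_id",
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, StatReport]:
    """Mixed-design two-factor ANOVA with Greenhouse–Geisser correction.

    The sphericity-corrected F machinery is delegated to
    ``pingouin.mixed_anova``; this function owns the design validation
    and the report schema.  Returns one StatReport per effect
    (within, between, interaction), each with GG-corrected degrees of
    freedom for the within-subject effects.
    """
    import pingouin as pg

    counts = table.groupby(subject)[within].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced within-subject cells: every subject needs every level")
    aov = pg.mixed_anova(
        data=table, dv=dv, within=within, between=between, subject=subject,
        correction=True,
    )
    out: dict[str, StatReport] = {}
    for _, row in aov.iterrows():
        src = row["Source"]
        eps = float(row["eps"]) if "eps" in row and pd.notna(row.get("eps")) else 1.0
        use_gg = (
            "p_GG_corr" in row and pd.notna(row.get("p_GG_corr")) and src != between
        )
        p = float(row["p_GG_corr"]) if use_gg else float(row["p_unc"])
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        if use_gg:
            df1, df2 = df1 * eps, df2 * eps
        key = "within" if src == within else "between" if src == between else "interaction"
        out[key] = StatReport(
            f"mixed ANOVA ({src})", float(row["F"]), (df1, df2), p, alpha=alpha,
            extras={"eps": eps, "gg_corrected": bool(use_gg)},
        )
    return out


def posthoc_pairwise(
    table: pd.DataFrame,
    dv: str = "value",
    factor: str = "group",
    method: str = "sidak",
    control: str | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Post-hoc multiple comparisons: Šídák-adjusted all-pairs t-tests, or
    Dunnett's many-to-one comparisons against ``control``."""
    groups = {str(g): np.asarray(v[dv], dtype=float) for g, v in table.groupby(factor)}
    names = sorted(groups)
    if method == "sidak":
        rows = []
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        m = len(pairs)
        for a, b in pairs:
            t, p = sps.ttest_ind(groups[a], groups[b])
            p_adj = 1.0 - (1.0 - p) ** m
            rows.append({"A": a, "B": b, "t": float(t), "p_unc": float(p),
                         "p_adj": float(min(p_adj, 1.0)),
                         "stars": significance_stars(min(p_adj, 1.0))})
        return pd.DataFrame(rows)
    if method == "dunnett":
        if control is None or control not in groups:
            raise ValueError("dunnett requires a control group present in the data")
        others = [n for n in names if n != control]
        res = sps.dunnett(*(groups[n] for n in others), control=groups[control])
        return pd.DataFrame(
            {
                "A": others,
                "B": control,
                "t": res.statistic,
                "p_adj": res.pvalue,
                "stars": [significance_stars(p) for p in res.pvalue],
            }
        )
    raise ValueError(f"unknown post-hoc method {method!r}")
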