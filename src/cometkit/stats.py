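"""Nonparametric group statistics with parallel-control normalisation.

The statistical layer used for per-neuron measurement tables: values are
normalised to the center (median or mean) of same-repeat controls, groups
are compared with a tie-corrected Kruskal-Wallis test plus Dunn's
post-hoc pairwise z-tests (raw and Holm-adjusted p), two-group
comparisons use the Mann-Whitney rank-sum test (exact enumeration for
small untied samples), correlations use tie-corrected Spearman rank
correlation, and summaries report per-repeat centers alongside a pooled
center with a percentile-bootstrap confidence interval.

Rank statistics are implemented here directly (the exact small-sample
branches and Dunn's test have no counterpart in the scientific Python
stack); they are cross-validated against scipy.stats in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata, distributions
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConditionTable",
    "validate_condition_table",
    "normalise_to_control",
    "kruskal_wallis_dunn",
    "mann_whitney",
    "spearman",
    "repeat_summary",
    "KruskalDunnResult",
    "SpearmanResult",
    "RepeatSummary",
]

TABLE_COLUMNS = ["neuron_id", "genotype", "biological_repeat", "metric_name", "value"]


def validate_condition_table(table: pd.DataFrame, control: str = "ctrl") -> pd.DataFrame:
    """Validate a per-neuron measurement table (one row per neuron x metric).

    Requires the canonical columns, uniqueness of (neuron, metric), and a
    parallel control group in every biological repeat that contains any
    non-control genotype.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"condition table is missing columns {missing}")
    dup = table.duplicated(subset=["neuron_id", "metric_name"])
    if dup.any():
        raise ValueError("duplicate (neuron_id, metric_name) rows in condition table")
    for (repeat, metric), grp in table.groupby(["biological_repeat", "metric_name"]):
        genos = set(grp["genotype"])
        if genos - {control} and control not in genos:
            raise ValueError(
                f"repeat {repeat!r} has no parallel {control!r} rows for metric {metric!r}")
    return table


ConditionTable = pd.DataFrame  # canonical container; see validate_condition_table


def _center(values: np.ndarray, center: str) -> float:
    if center == "median":
        return float(np.median(values))
    if center == "mean":
        return float(np.mean(values))
    raise ValueError(f"center must be 'median' or 'mean', got {center!r}")


def normalise_to_control(table: pd.DataFrame, metric: str, control: str = "ctrl",
                         center: str = "median") -> pd.DataFrame:
    """Divide each value by the same-repeat control center for one metric.

    Returns the metric's rows with an added ``normalised`` column; the
    control group's per-repeat center is exactly 1 afterwards.
    """
    sub = table[table["metric_name"] == metric].copy()
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    out = []
    for repeat, grp in sub.groupby("biological_repeat"):
        ctrl_vals = grp.loc[grp["genotype"] == control, "value"].to_numpy()
        if len(ctrl_vals) == 0:
            raise ValueError(f"repeat {repeat!r} lacks parallel {control!r} values "
                             f"for metric {metric!r}")
        c = _center(ctrl_vals, center)
        if c == 0:
            raise ValueError(f"control center is zero in repeat {repeat!r}")
        g = grp.copy()
        g["normalised"] = g["value"] / c
        out.append(g)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

@dataclass
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    group_names: list[str]
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_holm
    degenerate: bool = False


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis_dunn(groups: dict[str, np.ndarray]) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's post-hoc pairwise z-tests.

    H = [12/(N(N+1)) * sum n_i (rbar_i - rbar)^2] / (1 - sum(t^3 - t)/(N^3 - N));
    p from the chi-squared distribution with k-1 df.  Dunn's z uses the
    pooled-rank variance (N(N+1)/12 - tie term) * (1/n_i + 1/n_j); raw
    two-sided normal p plus Holm-adjusted p are both reported.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(data) < 2 or any(len(d) < 1 for d in data):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(data)
    N = len(pooled)
    if N < 3:
        raise ValueError("need total n >= 3")
    if np.all(pooled == pooled[0]):
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        pw = pd.DataFrame([(a, b, 0.0, 1.0, 1.0) for a, b in pairs],
                          columns=["group_a", "group_b", "z", "p_raw", "p_holm"])
        return KruskalDunnResult(0.0, 1.0, names, pw, degenerate=True)

    ranks = rankdata(pooled)
    sizes = [len(d) for d in data]
    idx = np.cumsum([0] + sizes)
    rbar = [ranks[idx[i]:idx[i + 1]].mean() for i in range(len(data))]
    grand = (N + 1) / 2
    h = 12.0 / (N * (N + 1)) * sum(n * (r - grand) ** 2 for n, r in zip(sizes, rbar))
    tie = _tie_term(ranks)
    correction = 1.0 - tie / (N**3 - N)
    h = h / correction
    p = float(chi2.sf(h, len(data) - 1))

    var_factor = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    rows = []
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            se = np.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (rbar[i] - rbar[j]) / se if se > 0 else 0.0
            rows.append((names[i], names[j], float(z), float(2 * norm.sf(abs(z)))))
    pw = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    pw["p_holm"] = multipletests(pw["p_raw"], method="holm")[1]
    return KruskalDunnResult(float(h), p, names, pw)


def _mw_exact_cdf_table(n1: int, n2: int) -> np.ndarray:
    """Counts of rank configurations per U value (no ties), via the
    standard recurrence f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u)."""
    umax = n1 * n2
    f = np.zeros((n1 + 1, n2 + 1, umax + 1))
    f[0, :, 0] = 1.0
    f[:, 0, 0] = 1.0
    for a in range(1, n1 + 1):
        for b in range(1, n2 + 1):
            f[a, b] = f[a, b - 1]
            f[a, b, b:] += f[a - 1, b, :umax + 1 - b]
    return f[n1, n2]


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact enumeration of the U distribution when min(n1, n2) <= 8 with no
    ties; tie-corrected normal approximation with continuity correction
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(n1, n2) <= 8 and not has_ties:
        counts = _mw_exact_cdf_table(n1, n2)
        total = counts.sum()
        u_small = min(u1, n1 * n2 - u1)
        p = 2.0 * counts[: int(u_small) + 1].sum() / total
        return float(min(p, 1.0))
    mu = n1 * n2 / 2.0
    tie = _tie_term(ranks)
    n = n1 + n2
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * norm.sf(z)))


@dataclass
class SpearmanResult:
    r: float
    p: float
    n: int
    degenerate: bool = False


def spearman(x, y) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation with two-sided p.

    Exact permutation p for n <= 9 without ties; otherwise the
    t-approximation with n-2 degrees of freedom.  Constant x or y is
    flagged degenerate (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), len(x), degenerate=True)
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    no_ties = (len(np.unique(x)) == n) and (len(np.unique(y)) == n)
    if n <= 9 and no_ties:
        from itertools import permutations
        rx_c = rx - rx.mean()
        # without ties both rank vectors are permutations of 1..n, so the
        # two centered sums of squares are equal
        denom = float(rx_c @ rx_c)
        perms = np.array(list(permutations(ry)))  # (n!, n)
        r_all = (perms - ry.mean()) @ rx_c / denom
        p = float(np.mean(np.abs(r_all) >= abs(rho) - 1e-12))
        return SpearmanResult(rho, p, n)
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0, n)
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2 * distributions.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, p, n)


# ---------------------------------------------------------------------------
# Repeat-level summaries and bootstrap CIs
# ---------------------------------------------------------------------------

@dataclass
class RepeatSummary:
    metric: str
    center: str
    repeat_centers: dict
    pooled_center: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    seed: int


def bootstrap_ci(values: np.ndarray, center: str = "median", n_boot: int = 10000,
                 seed: int = 0, alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI for the pooled center."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    stat = np.median(values[idx], axis=1) if center == "median" \
        else np.mean(values[idx], axis=1)
    lo, hi = np.percentile(stat, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def repeat_summary(table: pd.DataFrame, metric: str, genotype: str | None = None,
                   center: str = "median", value_column: str = "value",
                   n_boot: int = 10000, seed: int = 0) -> RepeatSummary:
    """Per-repeat centers plus pooled per-neuron summary with bootstrap CI.

    Mirrors superplot-style reporting: individual neurons are the
    statistical unit, biological repeats contribute one center each.
    """
    sub = table[table["metric_name"] == metric]
    if genotype is not None:
        sub = sub[sub["genotype"] == genotype]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r} / genotype {genotype!r}")
    values = sub[value_column].to_numpy(dtype=float)
    centers = {rep: _center(grp[value_column].to_numpy(dtype=float), center)
               for rep, grp in sub.groupby("biological_repeat")}
    lo, hi = bootstrap_ci(values, center=center, n_boot=n_boot, seed=seed)
    return RepeatSummary(metric=metric, center=center, repeat_centers=centers,
                         pooled_center=_center(values, center), ci_low=lo,
                         ci_high=hi, n=len(values), n_boot=n_boot, seed=seed)
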