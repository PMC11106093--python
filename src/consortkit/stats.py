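"""Nonparametric statistical surface of the consortship analysis.

Small behavioral samples with heavy ties call for rank statistics
throughout: Spearman correlations for association, Kruskal–Wallis for
multi-group comparisons, Mann–Whitney U (reported as Z from the
tie-corrected normal approximation) for two-group and post-hoc
comparisons, and Holm's step-down procedure for every multiple-testing
family.  Each analysis adjusts within its own family: the full set of
unique variable pairs for a correlation matrix, the set of group pairs for
a post-hoc battery.
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .observations import Individual

#: below this pairwise-complete n, Spearman p-values switch from the
#: t-distribution approximation to a seeded permutation test
PERMUTATION_N_THRESHOLD = 10


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment, returned in input order.

    Equivalent to sorting ascending, multiplying the i-th smallest by
    (m − i + 1), enforcing the running maximum, and capping at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@functools.lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _spearman_p(x: np.ndarray, y: np.ndarray, rho: float, seed) -> float:
    """Two-sided p: t-approximation for n >= 10, exact permutation below.

    The permutation null enumerates all n! pairings of the rank vectors
    (vectorized Pearson on centered ranks), so small-n p-values carry no
    Monte-Carlo noise and ``seed`` is unused in that branch.
    """
    n = len(x)
    if n >= PERMUTATION_N_THRESHOLD:
        t_approx = sps.spearmanr(x, y)
        return float(t_approx.pvalue)
    cx = sps.rankdata(x) - (n + 1) / 2.0
    cy = sps.rankdata(y) - (n + 1) / 2.0
    denom = np.linalg.norm(cx) * np.linalg.norm(cy)
    perms = _all_permutations(n)
    null = (cy[perms] @ cx) / denom
    observed = cx @ cy / denom
    return float(np.mean(np.abs(null) >= abs(observed) - 1e-12))


def spearman_pair(x, y, seed=None) -> tuple[float, float, int]:
    """Spearman rho and two-sided p on pairwise-complete observations.

    Ties receive average ranks.  Returns (rho, p, n_used); (nan, nan, n)
    when fewer than 4 complete observations remain or an input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 4:
        return math.nan, math.nan, n
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return math.nan, math.nan, n
    rho = float(sps.spearmanr(x, y).statistic)
    return rho, _spearman_p(x, y, rho, seed), n


@dataclass
class CorrelationMatrixResult:
    variables: list[str]
    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n_used: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        """Unique variable pairs whose Holm-adjusted p falls below alpha."""
        out = []
        for a, b in itertools.combinations(self.variables, 2):
            p = self.p_adjusted.loc[a, b]
            if not math.isnan(p) and p < alpha:
                out.append((a, b))
        return out


def spearman_matrix(
    metrics_table: pd.DataFrame, variables: list[str], seed=None
) -> CorrelationMatrixResult:
    """Pairwise Spearman correlation matrix with Holm-corrected p-values.

    Undefined metric values (NaN) are excluded pairwise; the Holm family is
    the full set of unique variable pairs with a defined test (28 for the
    eight standard variables).  ``n_used`` records each cell's
    pairwise-complete sample size.
    """
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p_raw = pd.DataFrame(np.full((k, k), np.nan), index=variables,
                         columns=variables)
    n_used = pd.DataFrame(0, index=variables, columns=variables, dtype=int)
    for v in variables:
        n_used.loc[v, v] = int(metrics_table[v].notna().sum())

    tests: list[tuple[str, str, float]] = []
    for a, b in itertools.combinations(variables, 2):
        r, p, n = spearman_pair(metrics_table[a], metrics_table[b], seed=seed)
        rho.loc[a, b] = rho.loc[b, a] = r
        p_raw.loc[a, b] = p_raw.loc[b, a] = p
        n_used.loc[a, b] = n_used.loc[b, a] = n
        if math.isnan(r):
            rho.loc[a, b] = rho.loc[b, a] = np.nan
            warnings.warn(
                f"Spearman undefined for ({a}, {b}); reported as missing",
                stacklevel=2,
            )
        if not math.isnan(p):
            tests.append((a, b, p))

    p_adj = pd.DataFrame(np.full((k, k), np.nan), index=variables,
                         columns=variables)
    if tests:
        adjusted = holm_adjust([t[2] for t in tests])
        for (a, b, _), padj in zip(tests, adjusted):
            p_adj.loc[a, b] = p_adj.loc[b, a] = padj
    return CorrelationMatrixResult(
        variables=list(variables), rho=rho, p_raw=p_raw, p_adjusted=p_adj,
        n_used=n_used,
    )


# ---------------------------------------------------------------------------
# group comparisons

def mann_whitney_z(x, y) -> tuple[float, float, float]:
    """Mann–Whitney U with tie-corrected normal approximation.

    Returns (U of the first sample, Z, two-sided p).  Z is signed so that a
    first sample shifted upward gives Z > 0; no continuity correction is
    applied, matching the conventional "Z = ..." reporting style.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u1 = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic").statistic)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u1, 0.0, 1.0
    z = (u1 - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return u1, z, min(p, 1.0)


def kruskal_wallis(samples: list[np.ndarray]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H, its degrees of freedom, and p.

    A degenerate pooled sample (every value identical) carries no group
    signal and reports H = 0, p = 1.
    """
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, len(samples) - 1, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), len(samples) - 1, float(p)


@dataclass
class GroupComparisonResult:
    grouping: str
    response: str
    test: str  # "kruskal_wallis" | "mann_whitney"
    groups: dict[str, int]
    statistic: float
    df: int | None
    p_raw: float
    pairwise: list[dict] = field(default_factory=list)


def compare_groups(
    activity_table: pd.DataFrame,
    roster: list[Individual],
    grouping: str,
    responses: tuple[str, ...] = ("homo_consorts", "het_consorts"),
) -> list[GroupComparisonResult]:
    """Compare consort activity across age classes or reproductive statuses.

    With two groups a Mann–Whitney test is run directly (statistic = Z);
    with three or more, an omnibus Kruskal–Wallis test plus all pairwise
    Mann–Whitney post-hocs, Holm-adjusted within the family of group pairs.
    Empty groups are dropped with a warning.
    """
    if grouping not in ("age_class", "reproductive_status"):
        raise ValueError(f"unknown grouping {grouping!r}")
    results: list[GroupComparisonResult] = []
    for response in responses:
        groups: dict[str, np.ndarray] = {}
        for label, sub in activity_table.groupby(grouping, sort=True):
            vals = sub[response].to_numpy(dtype=float)
            if len(vals) == 0:
                warnings.warn(f"group {label!r} is empty; dropped", stacklevel=2)
                continue
            groups[str(label)] = vals
        if len(groups) < 2:
            raise ValueError(
                f"grouping {grouping!r} leaves fewer than two non-empty groups"
            )
        sizes = {k: len(v) for k, v in groups.items()}
        labels = list(groups)
        if len(groups) == 2:
            _, z, p = mann_whitney_z(groups[labels[0]], groups[labels[1]])
            results.append(
                GroupComparisonResult(
                    grouping=grouping, response=response, test="mann_whitney",
                    groups=sizes, statistic=z, df=None, p_raw=p,
                )
            )
            continue
        h, df, p = kruskal_wallis(list(groups.values()))
        pairs = list(itertools.combinations(labels, 2))
        raw = []
        rows = []
        for a, b in pairs:
            u, z, pp = mann_whitney_z(groups[a], groups[b])
            raw.append(pp)
            rows.append({"group_a": a, "group_b": b, "U": u, "Z": z,
                         "p_raw": pp})
        for row, padj in zip(rows, holm_adjust(raw)):
            row["p_adjusted"] = float(padj)
        results.append(
            GroupComparisonResult(
                grouping=grouping, response=response, test="kruskal_wallis",
                groups=sizes, statistic=h, df=df, p_raw=p, pairwise=rows,
            )
        )
    return results


# ---------------------------------------------------------------------------
# demographic summaries

def _mode_stats(consorts: pd.Series, partners: pd.Series) -> dict:
    """Mean ± SD and range over females active in a mode (empty if none)."""
    active = consorts > 0
    if not active.any():
        return {"n_active": 0}
    c = consorts[active]
    p = partners[active]
    return {
        "n_active": int(active.sum()),
        "consorts_mean": float(c.mean()),
        "consorts_sd": float(c.std(ddof=1)) if len(c) > 1 else 0.0,
        "consorts_range": [int(c.min()), int(c.max())],
        "partners_mean": float(p.mean()),
        "partners_sd": float(p.std(ddof=1)) if len(p) > 1 else 0.0,
        "partners_range": [int(p.min()), int(p.max())],
    }


def demographic_summary(
    roster: list[Individual], activity_table: pd.DataFrame
) -> dict:
    """Group-level demography and consort-activity summary.

    Includes the mature male : female counts and ratio, per-mode activity
    statistics over the females active in that mode, the prevalence of
    female-female consorting among all analyzed females, and matriline
    coverage.
    """
    n_males = sum(1 for i in roster if i.sex == "M" and i.is_mature)
    n_females = int(len(activity_table))
    homo_active = activity_table["homo_consorts"] > 0
    matrilines = {i.matriline for i in roster if i.sex == "F" and i.is_mature}
    homo_matrilines = set(
        activity_table.loc[homo_active, "matriline"]
    ) if n_females else set()
    overall = activity_table["total_consorts"] if n_females else pd.Series(dtype=float)
    return {
        "n_mature_males": n_males,
        "n_females_analyzed": n_females,
        "sex_ratio_m_per_f": round(n_males / n_females, 2) if n_females else None,
        "overall": _mode_stats(
            overall, activity_table["total_partners"]
        ) if n_females else {"n_active": 0},
        "homosexual": _mode_stats(
            activity_table["homo_consorts"], activity_table["homo_partners"]
        ) if n_females else {"n_active": 0},
        "heterosexual": _mode_stats(
            activity_table["het_consorts"], activity_table["het_partners"]
        ) if n_females else {"n_active": 0},
        "homosexual_prevalence": (
            float(homo_active.mean()) if n_females else None
        ),
        "n_matrilines": len(matrilines),
        "n_matrilines_homosexual": len(homo_matrilines),
    }


def access_to_males(activity_table: pd.DataFrame, seed=None) -> dict:
    """Does heterosexual access explain homosexual activity?

    Spearman correlations over *all* analyzed females (inactive females
    enter as zeros): homosexual vs heterosexual partner counts, and
    homosexual vs heterosexual consort counts.
    """
    out = {}
    for name, (a, b) in {
        "partners": ("homo_partners", "het_partners"),
        "consorts": ("homo_consorts", "het_consorts"),
    }.items():
        rho, p, n = spearman_pair(activity_table[a], activity_table[b], seed=seed)
        out[name] = {"rho": rho, "p": p, "n": n}
    return out
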