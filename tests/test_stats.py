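"""Rank statistics: Spearman matrix, Holm adjustment, group comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from consortkit.observations import Individual
from consortkit.stats import (
    access_to_males,
    compare_groups,
    demographic_summary,
    holm_adjust,
    kruskal_wallis,
    mann_whitney_z,
    spearman_matrix,
    spearman_pair,
)


def rank_pearson_oracle(x, y):
    """Independent route: average-rank transform, then plain Pearson."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# Holm

def test_holm_single_and_cap():
    assert holm_adjust([0.05]).tolist() == [0.05]
    assert holm_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]


def test_holm_hand_computed_triple():
    # sorted: .01*3=.03, .03*2=.06, .04*1=.04 -> running max -> .06
    assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])


def test_holm_rejects_bad_p():
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        holm_adjust([-0.1])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8),
       st.integers(min_value=0, max_value=7), st.floats(min_value=0, max_value=1))
def test_holm_monotone(ps, idx, bump):
    """Raising any raw p never lowers any adjusted p."""
    idx = idx % len(ps)
    raised = list(ps)
    raised[idx] = min(1.0, raised[idx] + bump)
    before, after = holm_adjust(ps), holm_adjust(raised)
    assert np.all(after >= before - 1e-12)


# ---------------------------------------------------------------------------
# Spearman

def test_spearman_perfect_monotone():
    x = np.arange(10.0)
    rho, p, n = spearman_pair(x, x**3 + 1)
    assert rho == pytest.approx(1.0) and n == 10
    rho, _, _ = spearman_pair([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
    assert rho == pytest.approx(-1.0)


def test_spearman_ties_match_rank_pearson_oracle():
    x = [1, 2, 2, 3, 3, 3, 4, 5, 6, 6, 7, 8]
    y = [2, 1, 3, 3, 5, 4, 4, 6, 8, 7, 7, 9]
    rho, _, _ = spearman_pair(x, y)
    assert rho == pytest.approx(rank_pearson_oracle(x, y), abs=1e-12)


def test_spearman_pairwise_deletion_and_small_n_permutation():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, np.nan]
    y = [1.2, 1.9, 3.5, 3.9, 5.1, 6.3, 7.0]
    rho, p, n = spearman_pair(x, y, seed=0)
    assert n == 6 and rho == pytest.approx(1.0)
    assert p < 0.01  # permutation p for n < 10


def test_spearman_constant_input_is_missing():
    with pytest.warns(UserWarning, match="constant"):
        rho, p, n = spearman_pair([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
    assert math.isnan(rho) and math.isnan(p)


def test_spearman_matrix_structure():
    rng = np.random.default_rng(7)
    df = pd.DataFrame({
        "a": rng.normal(size=20),
        "b": rng.normal(size=20),
        "c": rng.normal(size=20),
    })
    df["d"] = df["a"] + 0.01 * rng.normal(size=20)
    res = spearman_matrix(df, ["a", "b", "c", "d"], seed=0)
    assert np.allclose(np.diag(res.rho.values), 1.0)
    assert np.allclose(res.rho.values, res.rho.values.T)
    off = ~np.eye(4, dtype=bool)
    assert np.all(res.p_adjusted.values[off] >= res.p_raw.values[off] - 1e-12)
    assert np.nanmax(res.p_adjusted.values) <= 1.0
    assert ("a", "d") in res.significant(0.05)
    for a, b in [("a", "b"), ("a", "c")]:
        assert res.rho.loc[a, b] == pytest.approx(
            rank_pearson_oracle(df[a], df[b]), abs=1e-12
        )
    assert res.n_used.loc["a", "b"] == 20


def test_spearman_matrix_missing_values_excluded_pairwise():
    df = pd.DataFrame({
        "x": [1, 2, 3, 4, 5, 6.0],
        "y": [2, 1, 4, 3, 6, 5.0],
        "z": [1, 2, np.nan, np.nan, 5, 6.0],
    })
    res = spearman_matrix(df, ["x", "y", "z"], seed=0)
    assert res.n_used.loc["x", "z"] == 4
    assert res.n_used.loc["x", "y"] == 6


# ---------------------------------------------------------------------------
# group comparisons

def test_mann_whitney_identical_groups_null():
    x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
    _, z, p = mann_whitney_z(x, x)
    assert z == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_mann_whitney_direction_and_shift():
    rng = np.random.default_rng(3)
    lo = rng.normal(0, 1, size=30)
    hi = rng.normal(2, 1, size=30)
    _, z, p = mann_whitney_z(hi, lo)
    assert z > 0 and p < 1e-4


def test_kruskal_two_groups_consistent_with_mwu():
    """On tie-free data, H equals Z^2 and the p-values coincide."""
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=12), rng.normal(0.8, 1, size=15)
    h, df, p_kw = kruskal_wallis([x, y])
    _, z, p_mwu = mann_whitney_z(x, y)
    assert df == 1
    assert h == pytest.approx(z**2, abs=1e-9)
    assert p_kw == pytest.approx(p_mwu, abs=1e-9)


def _activity_frame(rng, shift_status=None, n_per=12):
    rows = []
    statuses = ["nulliparous", "parous", "lactating", "menopausal_like"]
    for status in statuses:
        for i in range(n_per):
            mu = 8.0 if status == shift_status else 2.0
            rows.append({
                "female_id": f"{status[:3]}{i}",
                "age_class": "adult" if i % 3 else "adolescent",
                "reproductive_status": status,
                "matriline": "m1",
                "homo_consorts": rng.poisson(2.0),
                "het_consorts": rng.poisson(mu),
                "homo_partners": rng.poisson(1.5),
                "het_partners": rng.poisson(mu / 2),
            })
    df = pd.DataFrame(rows)
    df["total_consorts"] = df["homo_consorts"] + df["het_consorts"]
    df["total_partners"] = df["homo_partners"] + df["het_partners"]
    return df


def test_compare_groups_four_statuses():
    rng = np.random.default_rng(11)
    table = _activity_frame(rng, shift_status="parous")
    results = compare_groups(table, [], "reproductive_status")
    het = next(r for r in results if r.response == "het_consorts")
    assert het.test == "kruskal_wallis"
    assert het.df == 3  # four status categories
    assert het.p_raw < 0.05  # large planted shift is detected
    assert len(het.pairwise) == 6
    adj = [row["p_adjusted"] for row in het.pairwise]
    raw = [row["p_raw"] for row in het.pairwise]
    assert np.all(np.asarray(adj) >= np.asarray(raw) - 1e-12)


def test_compare_groups_two_age_classes():
    rng = np.random.default_rng(11)
    table = _activity_frame(rng)
    results = compare_groups(table, [], "age_class")
    homo = next(r for r in results if r.response == "homo_consorts")
    assert homo.test == "mann_whitney"
    assert 0 <= homo.p_raw <= 1


def test_compare_groups_single_group_errors():
    rng = np.random.default_rng(1)
    table = _activity_frame(rng)
    table["age_class"] = "adult"
    with pytest.raises(ValueError, match="two"):
        compare_groups(table, [], "age_class")


# ---------------------------------------------------------------------------
# demographic summaries

def _roster(n_f=76, n_m=49):
    roster = [
        Individual(f"F{i:02d}", "F", 8.0, f"mat{i % 17:02d}", "parous")
        for i in range(n_f)
    ]
    roster += [
        Individual(f"M{i:02d}", "M", 9.0, f"mat{i % 17:02d}", "not_applicable")
        for i in range(n_m)
    ]
    return roster


def _zeros_activity(roster):
    rows = [
        {
            "female_id": i.id, "age_years": i.age_years,
            "age_class": i.age_class, "reproductive_status": i.reproductive_status,
            "matriline": i.matriline, "homo_consorts": 0, "het_consorts": 0,
            "homo_partners": 0, "het_partners": 0, "total_consorts": 0,
            "total_partners": 0,
        }
        for i in roster if i.sex == "F"
    ]
    return pd.DataFrame(rows)


def test_sex_ratio_two_decimals():
    roster = _roster()
    table = _zeros_activity(roster)
    summary = demographic_summary(roster, table)
    assert summary["n_mature_males"] == 49
    assert summary["n_females_analyzed"] == 76
    assert summary["sex_ratio_m_per_f"] == 0.64


def test_prevalence_and_empty_modes():
    roster = _roster(n_f=76)
    table = _zeros_activity(roster)
    table.loc[:34, ["homo_consorts", "homo_partners"]] = 1  # 35 active females
    table["total_consorts"] = table["homo_consorts"] + table["het_consorts"]
    table["total_partners"] = table["homo_partners"] + table["het_partners"]
    summary = demographic_summary(roster, table)
    assert summary["homosexual_prevalence"] == pytest.approx(35 / 76)
    assert summary["heterosexual"] == {"n_active": 0}  # empty, not zero
    assert summary["homosexual"]["consorts_mean"] == pytest.approx(1.0)


def test_access_to_males_identical_and_zero_females_included():
    roster = _roster(n_f=10)
    table = _zeros_activity(roster)
    table["homo_consorts"] = table["het_consorts"] = np.arange(10)
    table["homo_partners"] = table["het_partners"] = np.arange(10) % 4
    res = access_to_males(table, seed=0)
    assert res["consorts"]["rho"] == pytest.approx(1.0)
    assert res["consorts"]["n"] == 10  # inactive females enter as zeros


def test_access_to_males_independent_counts_near_zero():
    rng = np.random.default_rng(0)
    roster = _roster(n_f=76)
    table = _zeros_activity(roster)
    table["homo_consorts"] = rng.poisson(2, size=76)
    table["het_consorts"] = rng.poisson(6, size=76)
    table["homo_partners"] = rng.poisson(1.5, size=76)
    table["het_partners"] = rng.poisson(4, size=76)
    res = access_to_males(table, seed=0)
    assert abs(res["consorts"]["rho"]) < 0.3
    assert abs(res["partners"]["rho"]) < 0.3
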