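"""Normalization, fold-change floor rule, DE tests and qPCR utility."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirdeg.containers import CountMatrix
from mirdeg.expression_stats import (
    anova_across_groups,
    ddct,
    estimate_common_dispersion,
    fpkm,
    log2_fc_floored,
    nb_exact_de,
    normalize_cpm,
    ttest_pairwise,
)


def _cm(arr, samples=None, libs=None):
    arr = np.asarray(arr)
    samples = samples or [f"TL5_CG_{i + 1}" for i in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])], columns=samples)
    libsizes = pd.Series(libs, index=samples, dtype=float) if libs is not None else None
    return CountMatrix(df, libsizes)


# -------------------------------------------------------------------- CPM/FPKM

def test_cpm_unit_case():
    cm = _cm([[1], [1]], samples=["TL5_CG_1"])
    out = normalize_cpm(cm)
    assert out.iloc[0, 0] == 5e5 and out.iloc[1, 0] == 5e5


def test_cpm_zero_column_warns():
    cm = _cm([[0], [0]])
    with pytest.warns(UserWarning):
        out = normalize_cpm(cm)
    assert (out.values == 0).all()


def test_cpm_columns_sum_to_million():
    rng = np.random.default_rng(0)
    cm = _cm(rng.integers(0, 500, size=(40, 6)))
    sums = normalize_cpm(cm).sum(axis=0)
    assert np.allclose(sums, 1e6, atol=1e-6)


def test_fpkm_unit_case():
    # 10 fragments on a 1 kb feature among 1e6 mapped fragments -> 10 FPKM
    cm = _cm([[10]], samples=["TL5_CG_1"], libs=[1_000_000])
    out = fpkm(cm, pd.Series({"f0": 1000}))
    assert out.values.iloc[0, 0] == pytest.approx(10.0)
    # and with 1e3 mapped fragments -> 1e4 FPKM
    cm2 = _cm([[10]], samples=["TL5_CG_1"], libs=[1_000])
    assert fpkm(cm2, pd.Series({"f0": 1000})).values.iloc[0, 0] == pytest.approx(1e4)


def test_fpkm_zero_count_and_formula():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 100, size=(20, 4))
    lengths = pd.Series(rng.integers(200, 3000, 20), index=[f"f{i}" for i in range(20)])
    cm = _cm(counts)
    out = fpkm(cm, lengths).values.values
    libs = counts.sum(axis=0)
    expected = counts * 1e9 / lengths.values[:, None] / libs[None, :]
    assert np.allclose(out, expected)
    assert (out[counts == 0] == 0).all()


# ------------------------------------------------------------------ floor rule

def test_log2fc_simple_and_floored():
    assert log2_fc_floored(4, 2) == pytest.approx(1.0)
    assert log2_fc_floored(0, 1) == pytest.approx(math.log2(0.001))  # ~ -9.9658


def test_log2fc_inf_dialect():
    assert log2_fc_floored(0, 1, dialect="inf") == float("-inf")
    assert log2_fc_floored(1, 0, dialect="inf") == float("inf")
    assert log2_fc_floored(0, 0, dialect="inf") == 0.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.floats(0, 1e6, allow_nan=False, allow_infinity=False),
    st.floats(0, 1e6, allow_nan=False, allow_infinity=False),
)
def test_log2fc_antisymmetric(a, b):
    assert log2_fc_floored(a, b) == pytest.approx(-log2_fc_floored(b, a), abs=1e-9)


# ---------------------------------------------------------------------- ANOVA

def _design_cols(groups):
    counts = {}
    cols = []
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
        cols.append(f"TL5_{g}_{counts[g]}")
    return cols


def test_anova_degenerate_zero_variance():
    groups = ["CG", "CG", "CG", "WS", "WS", "WS"]
    cm = _cm(np.full((3, 6), 7), samples=_design_cols(groups))
    res = anova_across_groups(cm, groups)
    assert (res["p"] == 1.0).all()
    assert (res["note"] == "degenerate").all()
    assert (res["direction"] == "ns").all()


def test_anova_power_on_planted_effect():
    """3-log2-unit shift with n=3: detected at p<0.05 in >=95% of simulations."""
    rng = np.random.default_rng(7)
    hits = 0
    n_sim = 100
    groups = ["CG"] * 3 + ["WS"] * 3 + ["HS"] * 3 + ["WH"] * 3
    cols = _design_cols(groups)
    for _ in range(n_sim):
        base = 200.0
        mu = np.array([base] * 3 + [base * 8] * 3 + [base] * 6)
        counts = rng.poisson(rng.gamma(10.0, mu / 10.0))[None, :]
        res = anova_across_groups(_cm(counts, samples=cols, libs=[1e6] * 12), groups)
        hits += int(res["p"].iloc[0] < 0.05)
    assert hits / n_sim >= 0.95


def test_anova_requires_replicates():
    groups = ["CG", "WS"]
    cm = _cm([[1, 2]], samples=_design_cols(groups))
    with pytest.raises(ValueError):
        anova_across_groups(cm, groups)


# --------------------------------------------------------------------- t-test

def test_ttest_identical_groups_degenerate():
    groups = ["CG"] * 3 + ["WS"] * 3
    cm = _cm(np.full((2, 6), 5), samples=_design_cols(groups))
    res = ttest_pairwise(cm, groups, "WS", "CG")
    assert (res["p"] == 1.0).all()
    assert (res["direction"] == "ns").all()


def test_ttest_power_on_planted_effect():
    rng = np.random.default_rng(8)
    groups = ["CG"] * 3 + ["WS"] * 3
    cols = _design_cols(groups)
    hits = 0
    n_sim = 100
    for _ in range(n_sim):
        mu = np.array([200.0] * 3 + [1600.0] * 3)
        counts = rng.poisson(rng.gamma(10.0, mu / 10.0))[None, :]
        res = ttest_pairwise(_cm(counts, samples=cols, libs=[1e6] * 6), groups, "WS", "CG")
        hits += int((res["p"].iloc[0] < 0.05) and res["log2fc"].iloc[0] > 0)
    assert hits / n_sim >= 0.9


def test_de_calls_invariant_under_depth_rescale():
    """CPM normalization removes library-size nuisance: scaling one column's
    depth x10 leaves DE calls >=99% identical."""
    rng = np.random.default_rng(9)
    groups = ["CG"] * 3 + ["WS"] * 3
    cols = _design_cols(groups)
    counts = rng.negative_binomial(10, 10 / (10 + 300), size=(400, 6))
    cm1 = _cm(counts, samples=cols)
    scaled = counts.copy()
    scaled[:, 0] *= 10
    cm2 = _cm(scaled, samples=cols)
    r1 = ttest_pairwise(cm1, groups, "WS", "CG")
    r2 = ttest_pairwise(cm2, groups, "WS", "CG")
    same = (r1["direction"].values == r2["direction"].values).mean()
    assert same >= 0.99


def test_null_pvalues_uniform_ks():
    """p-value histogram uniform under the null (KS sanity check, 2000 features)."""
    rng = np.random.default_rng(10)
    groups = ["CG"] * 3 + ["WS"] * 3
    cols = _design_cols(groups)
    counts = rng.poisson(rng.gamma(10.0, 30.0, size=(2000, 6)))
    res = ttest_pairwise(_cm(counts, samples=cols), groups, "WS", "CG")
    D, _ = stats.kstest(res["p"], "uniform")
    assert D < 0.05


# ------------------------------------------------------------------- NB exact

def test_nb_exact_identical_counts_p1():
    groups = ["CG"] * 3 + ["WS"] * 3
    cm = _cm(np.tile([[40, 40, 40, 40, 40, 40]], (3, 1)), samples=_design_cols(groups))
    res = nb_exact_de(cm, groups, "WS", "CG", dispersion=0.1)
    assert (res["p"] == 1.0).all()


def test_nb_exact_poisson_limit_matches_binomial():
    """With dispersion -> 0 and equal library sizes the conditional test is
    the exact binomial test on the group-A sum."""
    groups = ["CG"] * 2 + ["WS"] * 2
    counts = np.array([[10, 14, 30, 26], [3, 1, 2, 2], [50, 50, 10, 8]])
    # equal library sizes so pseudo-counts equal raw counts
    libs = [100000] * 4
    cm = _cm(counts, samples=_design_cols(groups), libs=libs)
    res = nb_exact_de(cm, groups, "WS", "CG", dispersion=0.0)
    for i in range(3):
        ya = counts[i, 2:].sum()
        s = counts[i].sum()
        pmf = stats.binom.pmf(np.arange(s + 1), s, 0.5)
        expected = pmf[pmf <= pmf[ya] * (1 + 1e-10)].sum()
        assert res["p"].iloc[i] == pytest.approx(expected, rel=1e-6)


def test_nb_exact_detects_planted_fourfold():
    rng = np.random.default_rng(11)
    groups = ["CG"] * 3 + ["WS"] * 3
    cols = _design_cols(groups)
    hits = 0
    n_sim = 60
    for _ in range(n_sim):
        mu = np.array([100.0] * 3 + [400.0] * 3)
        row = rng.poisson(rng.gamma(10.0, mu / 10.0))
        bg = rng.poisson(rng.gamma(10.0, 20.0, size=(30, 6)))
        counts = np.vstack([row, bg])
        cm = _cm(counts, samples=cols, libs=[1e5] * 6)
        res = nb_exact_de(cm, groups, "WS", "CG", dispersion=0.1)
        hits += int(res["p"].iloc[0] < 0.05)
    assert hits / n_sim >= 0.9


def test_common_dispersion_estimate_recovers_magnitude():
    rng = np.random.default_rng(12)
    phi = 0.1
    mu = np.exp(rng.normal(np.log(300), 0.8, size=500))
    counts = rng.poisson(rng.gamma(1 / phi, (mu[:, None] * phi), size=(500, 6)))
    est = estimate_common_dispersion(counts, np.array(["A"] * 3 + ["B"] * 3))
    assert 0.03 <= est <= 0.3


# ----------------------------------------------------------------------- ddct

@pytest.mark.parametrize(
    "cts,expected",
    [((20, 18, 22, 18), 4.0), ((20, 20, 20, 20), 1.0), ((21, 19, 20, 19), 0.5)],
)
def test_ddct(cts, expected):
    assert ddct(*cts) == pytest.approx(expected)
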