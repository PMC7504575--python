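"""Normalization and differential-expression statistics.

miRNA counts are normalized to counts per million (CPM) and tested per
feature with one-way ANOVA across factor levels or a Welch t-test between two
levels, both on log2(normalized + floor).  Gene counts are tested with a
two-group negative-binomial exact test using a method-of-moments common
dispersion — a self-contained count test in the exact-conditional family
(no tagwise empirical-Bayes shrinkage).  Fold-changes use the zero-floor
rule: abundances of exactly 0 are reset to 0.001 before the log2 ratio; an
alternative reporting dialect returns a +/-inf sentinel instead.

Calls use raw p < alpha by design (matching per-contrast screening practice
with n = 3 replicates); a Benjamini-Hochberg adjusted column is always
emitted alongside for users who want FDR control.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, FPKMMatrix

DEFAULT_FLOOR = 0.001
DEFAULT_ALPHA = 0.05

DIFF_COLUMNS = ["feature", "contrast", "stat", "p", "p_adj", "log2fc", "direction", "note"]


def normalize_cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million: each column scaled by 1e6 / library size.

    All-zero columns (library size 0) are returned as zeros with a warning.
    """
    libs = cm.library_sizes.copy()
    zero = libs == 0
    if zero.any():
        warnings.warn(f"all-zero libraries left as zeros: {list(libs.index[zero])}")
        libs[zero] = 1.0
    return cm.counts * 1e6 / libs


def fpkm(cm: CountMatrix, lengths: pd.Series) -> FPKMMatrix:
    """FPKM = count * 1e9 / (length_nt * total mapped fragments)."""
    lengths = lengths.reindex(cm.counts.index).astype(float)
    if lengths.isna().any():
        raise ValueError("lengths missing for some features")
    libs = cm.library_sizes.replace(0, np.nan)
    vals = cm.counts * 1e9
    vals = vals.div(lengths, axis=0).div(libs, axis=1).fillna(0.0)
    return FPKMMatrix(vals, lengths)


def log2_fc_floored(
    stress: float,
    control: float,
    floor: float = DEFAULT_FLOOR,
    dialect: str = "floor",
) -> float:
    """log2 fold-change with the 0 -> floor reset rule.

    ``dialect='floor'`` floors both abundances at ``floor`` before the ratio
    (always finite).  ``dialect='inf'`` instead reports a +/-inf sentinel when
    exactly one side is 0 (the convention used when tabulating, e.g., a miRNA
    whose stress abundance is zero as -inf), and 0.0 when both are 0.
    """
    if stress < 0 or control < 0:
        raise ValueError("abundances must be non-negative")
    if dialect == "inf":
        if stress == 0 and control == 0:
            return 0.0
        if stress == 0:
            return float("-inf")
        if control == 0:
            return float("inf")
        return math.log2(stress / control)
    if dialect != "floor":
        raise ValueError(f"unknown dialect {dialect!r}")
    return math.log2(max(stress, floor) / max(control, floor))


def _bh(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _assemble(
    features, contrast, stat, p, log2fc, note, alpha: float
) -> pd.DataFrame:
    p = np.asarray(p, dtype=float)
    lfc = np.asarray(log2fc, dtype=float)
    direction = np.where(
        (p < alpha) & (lfc > 0), "up", np.where((p < alpha) & (lfc < 0), "down", "ns")
    )
    return pd.DataFrame(
        {
            "feature": features,
            "contrast": contrast,
            "stat": stat,
            "p": p,
            "p_adj": _bh(p),
            "log2fc": lfc,
            "direction": direction,
            "note": note,
        },
        columns=DIFF_COLUMNS,
    )


def anova_across_groups(
    cm: CountMatrix,
    groups: Sequence[str],
    floor: float = DEFAULT_FLOOR,
    alpha: float = DEFAULT_ALPHA,
    contrast: str | None = None,
) -> pd.DataFrame:
    """One-way ANOVA per feature on log2(CPM + floor) across factor levels.

    ``groups`` gives one level label per sample (column).  Features with zero
    variance everywhere get p = 1 and a 'degenerate' note; levels need >= 2
    replicates each, otherwise the whole call raises.  The reported log2fc is
    the floored fold-change of the level deviating most from the first level
    (a summary only — the test itself is the omnibus F).
    """
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValueError("ANOVA needs >= 2 levels")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"level {lv!r} has < 2 replicates")
    cpm = normalize_cpm(cm)
    X = np.log2(cpm.values + floor)
    blocks = [X[:, groups == lv] for lv in levels]
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = stats.f_oneway(*blocks, axis=1)
    degenerate = np.all(X == X[:, [0]], axis=1)
    p = np.where(np.isnan(p) | degenerate, 1.0, p)
    F = np.where(np.isnan(F), 0.0, F)

    ref = cpm.values[:, groups == levels[0]].mean(axis=1)
    dev_lfc = np.zeros(len(cpm))
    best = np.full(len(cpm), -1.0)
    for lv in levels[1:]:
        mu = cpm.values[:, groups == lv].mean(axis=1)
        lfc = np.array([log2_fc_floored(a, b, floor) for a, b in zip(mu, ref)])
        take = np.abs(lfc) > best
        dev_lfc[take] = lfc[take]
        best = np.maximum(best, np.abs(lfc))

    note = np.where(degenerate, "degenerate", "")
    out = _assemble(
        cpm.index, contrast or f"anova:{'|'.join(map(str, levels))}",
        F, p, dev_lfc, note, alpha,
    )
    out.loc[out["note"] == "degenerate", "direction"] = "ns"
    return out


def ttest_pairwise(
    cm: CountMatrix,
    groups: Sequence[str],
    level_a: str,
    level_b: str,
    floor: float = DEFAULT_FLOOR,
    alpha: float = DEFAULT_ALPHA,
    contrast: str | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per feature on log2(CPM + floor), ``level_a`` vs ``level_b``.

    The default is the pooled-variance (Student) statistic: with n = 3
    replicates per group the Welch-Satterthwaite degrees of freedom are so
    noisy that the Welch test is markedly conservative under the null, while
    the pooled test holds its nominal size on balanced log-count data; pass
    ``equal_var=False`` for Welch when group variances genuinely differ.
    log2fc is the floored ratio of mean CPM (a vs b); direction 'up' means
    more abundant under ``level_a``.  Zero-variance features with identical
    group means are degenerate (p = 1, never called).
    """
    groups = np.asarray(groups)
    A = np.log2(normalize_cpm(cm).values[:, groups == level_a] + floor)
    B = np.log2(normalize_cpm(cm).values[:, groups == level_b] + floor)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("both levels need >= 2 replicates")
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
    degenerate = (np.ptp(A, axis=1) == 0) & (np.ptp(B, axis=1) == 0) & (
        A.mean(axis=1) == B.mean(axis=1)
    )
    p = np.where(np.isnan(p) | degenerate, 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)

    cpm = normalize_cpm(cm)
    mu_a = cpm.values[:, groups == level_a].mean(axis=1)
    mu_b = cpm.values[:, groups == level_b].mean(axis=1)
    lfc = np.array([log2_fc_floored(a, b, floor) for a, b in zip(mu_a, mu_b)])
    note = np.where(degenerate, "degenerate", "")
    out = _assemble(cpm.index, contrast or f"{level_a}_vs_{level_b}", t, p, lfc, note, alpha)
    out.loc[out["note"] == "degenerate", "direction"] = "ns"
    return out


def estimate_common_dispersion(counts: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments common NB dispersion from within-group moments.

    For each feature and group with mean m > 0 and variance v, the moment
    estimate is (v - m) / m^2; the common value is the median over all
    feature-level estimates, floored at 0 (Poisson).
    """
    ests = []
    for lv in dict.fromkeys(groups):
        block = counts[:, groups == lv]
        if block.shape[1] < 2:
            continue
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        ok = m > 0
        ests.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not ests:
        return 0.0
    allests = np.concatenate(ests)
    if allests.size == 0:
        return 0.0
    return float(max(0.0, np.median(allests)))


def _nb_conditional_p(ya: int, s: int, na: int, nb: int, mu: float, phi: float) -> float:
    """Exact conditional two-sided p for the group-A sum given the total.

    Sums of iid NB(mu, phi) over n replicates are NB(n*mu, phi/n); with
    phi -> 0 the conditional law degenerates to Binomial(s, na/(na+nb)).
    The p-value sums the probabilities of all outcomes no more likely than
    the observed one (with a small relative tolerance for float ties).
    """
    y = np.arange(s + 1)
    if phi <= 1e-12:
        logp = stats.binom.logpmf(y, s, na / (na + nb))
    else:
        ra, rb = na / phi, nb / phi
        mua, mub = na * mu, nb * mu
        la = stats.nbinom.logpmf(y, ra, ra / (ra + mua))
        lb = stats.nbinom.logpmf(s - y, rb, rb / (rb + mub))
        logp = la + lb
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    return float(prob[prob <= prob[ya] * (1 + 1e-10)].sum())


def nb_exact_de(
    cm: CountMatrix,
    groups: Sequence[str],
    level_a: str,
    level_b: str,
    dispersion: float | None = None,
    floor: float = DEFAULT_FLOOR,
    alpha: float = DEFAULT_ALPHA,
    contrast: str | None = None,
    max_total: int = 200_000,
) -> pd.DataFrame:
    """Two-group negative-binomial exact test per feature.

    Counts are first scaled to a common library size (the geometric mean of
    the two groups' sizes) and rounded to pseudo-counts, so the conditional
    argument applies; the common dispersion defaults to the method-of-moments
    estimate over all features.  Features whose pseudo-count total exceeds
    ``max_total`` fall back to a normal approximation of the conditional law.
    log2fc is the floored ratio of mean CPM (a vs b).
    """
    groups = np.asarray(groups)
    sel = (groups == level_a) | (groups == level_b)
    sub = cm.subset_samples(cm.samples[sel])
    g = groups[sel]
    na, nb_ = int((g == level_a).sum()), int((g == level_b).sum())
    if na < 1 or nb_ < 1:
        raise ValueError("both levels need >= 1 sample")

    libs = sub.library_sizes.values.astype(float)
    common = float(np.exp(np.log(libs[libs > 0]).mean())) if (libs > 0).any() else 1.0
    scale = np.where(libs > 0, common / libs, 0.0)
    pseudo = np.rint(sub.counts.values * scale).astype(np.int64)

    if dispersion is None:
        dispersion = estimate_common_dispersion(pseudo, g)

    A = pseudo[:, g == level_a]
    B = pseudo[:, g == level_b]
    ya, yb = A.sum(axis=1), B.sum(axis=1)
    tot = ya + yb
    pvals = np.ones(len(pseudo))
    notes = np.array([""] * len(pseudo), dtype=object)
    for i in range(len(pseudo)):
        s = int(tot[i])
        if s == 0:
            notes[i] = "degenerate"
            continue
        mu = s / (na + nb_)
        if s <= max_total:
            pvals[i] = _nb_conditional_p(int(ya[i]), s, na, nb_, mu, dispersion)
        else:  # normal approximation to the conditional distribution
            ea = s * na / (na + nb_)
            va = s * na * nb_ / (na + nb_) ** 2 * (1 + dispersion * mu)
            z = (ya[i] - ea) / math.sqrt(max(va, 1e-12))
            pvals[i] = float(2 * stats.norm.sf(abs(z)))
            notes[i] = "normal_approx"
            pvals[i] = min(pvals[i], 1.0)

    cpm = normalize_cpm(sub)
    mu_a = cpm.values[:, g == level_a].mean(axis=1)
    mu_b = cpm.values[:, g == level_b].mean(axis=1)
    lfc = np.array([log2_fc_floored(a, b, floor) for a, b in zip(mu_a, mu_b)])
    stat = np.where(tot > 0, ya / np.maximum(tot, 1), 0.0)
    out = _assemble(sub.features, contrast or f"{level_a}_vs_{level_b}", stat, pvals, lfc, notes, alpha)
    out.loc[out["note"] == "degenerate", "direction"] = "ns"
    return out


def ddct(
    ct_target_stress: float,
    ct_ref_stress: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method against a reference gene."""
    ddct_val = (ct_target_stress - ct_ref_stress) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct_val)
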