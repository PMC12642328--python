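"""Outcome statistics: permutation chi-square, BH adjustment, permutation
difference tests, Kruskal-Wallis, and Kaplan-Meier / log-rank survival on
median-dichotomized spatial features.

All permutation p-values carry the add-one correction
p = (1 + #{perm statistic >= observed}) / (1 + n_perm), so a p-value is
never exactly zero and is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


class StatTestError(ValueError):
    pass


class SplitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Permutation chi-square for composition-by-grade
# ---------------------------------------------------------------------------

def _chisq_stat(counts: np.ndarray) -> float:
    """Pearson chi-square statistic of a contingency table (no correction)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (counts - expected) ** 2 / expected
    return float(np.nansum(terms))


def contingency_from_labels(grades, categories) -> pd.DataFrame:
    """Grade-by-category cell count table."""
    return pd.crosstab(pd.Series(grades, name="grade"),
                       pd.Series(categories, name="category"))


def permutation_chisq(grades, categories, n_perm: int = 10_000,
                      seed: int | None = 0) -> tuple[float, float]:
    """Permutation chi-square test of association between per-cell grade and
    category labels.

    The observed Pearson chi-square is referenced against the distribution
    obtained by shuffling the grade labels over cells ``n_perm`` times
    (cell-level shuffles). Grades with zero cells are dropped with a
    warning. Returns (observed chi-square, permutation p).
    """
    g = pd.Categorical(np.asarray(grades))
    c = pd.Categorical(np.asarray(categories))
    gi = np.asarray(g.codes)
    ci = np.asarray(c.codes)
    n_g, n_c = len(g.categories), len(c.categories)
    if n_g < 2 or n_c < 2:
        raise StatTestError("need >= 2 grades and >= 2 categories")
    gc = np.bincount(gi, minlength=n_g)
    if (gc == 0).any():
        warnings.warn("dropping grade level(s) with zero cells")

    def table(gcodes: np.ndarray) -> np.ndarray:
        return np.bincount(gcodes * n_c + ci, minlength=n_g * n_c
                           ).reshape(n_g, n_c)

    obs = _chisq_stat(table(gi))
    rng = np.random.default_rng(seed)
    exceed = 0
    work = gi.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        if _chisq_stat(table(work)) >= obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return obs, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# Permutation difference test and fold change
# ---------------------------------------------------------------------------

def permutation_diff_test(group_a, group_b, n_perm: int = 10_000,
                          seed: int | None = 0) -> tuple[float, float]:
    """Two-sided permutation test for a difference in medians.

    Statistic = |median(a) - median(b)|; group labels are permuted
    ``n_perm`` times, ties counted as >=. Returns (observed statistic, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise StatTestError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    na = len(a)
    obs = abs(np.median(a) - np.median(b))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(np.median(perm[:na]) - np.median(perm[na:])) >= obs - 1e-12:
            exceed += 1
    return float(obs), (1 + exceed) / (1 + n_perm)


def log_fold_change(ce_values, nce_values) -> tuple[float, float]:
    """Median ratio CE/N-CE on the linear intensity scale, with its log2.

    A fold change above 1 means higher expression in CE cells. Returns
    (nan, nan) when either median is nonpositive (undefined ratio).
    """
    ce = np.asarray(ce_values, dtype=float)
    nce = np.asarray(nce_values, dtype=float)
    m_ce, m_nce = np.median(ce), np.median(nce)
    if m_ce <= 0 or m_nce <= 0:
        return np.nan, np.nan
    fold = float(m_ce / m_nce)
    return fold, float(np.log2(fold))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H (tie-corrected) with chi-square p.

    All-identical values across groups give H = 0, p = 1 rather than an
    error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise StatTestError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Survival: median dichotomization, KM, log-rank
# ---------------------------------------------------------------------------

@dataclass
class SurvivalSplit:
    """Two-group survival data: 'far' = feature >= cohort median."""

    group: np.ndarray       # "far" | "near" per patient
    times: np.ndarray
    events: np.ndarray
    median_cutoff: float = np.nan


def dichotomize_by_median(values, times, events) -> SurvivalSplit:
    """Split patients at the cohort median of a feature.

    The far group is value >= median (a value exactly at the median is far,
    matching the >= convention of the reported cutoffs); missing feature
    values are excluded.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    ok = np.isfinite(v)
    if ok.sum() < 2:
        raise SplitError("need >= 2 finite feature values to dichotomize")
    v, t, e = v[ok], t[ok], e[ok]
    cutoff = float(np.median(v))
    group = np.where(v >= cutoff, "far", "near")
    return SurvivalSplit(group=group, times=t, events=e, median_cutoff=cutoff)


def km_logrank(split: SurvivalSplit) -> dict:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    Returns a dict with the log-rank chi-square statistic, its p-value
    (chi-square reference, 1 df), and a per-group KM curve table
    (time, survival probability).
    """
    far = split.group == "far"
    near = ~far
    if far.sum() == 0 or near.sum() == 0:
        raise StatTestError("both survival groups must be non-empty")
    if not split.events.any():
        raise StatTestError("need at least one event for a log-rank test")

    curves = {}
    for name, sel in (("far", far), ("near", near)):
        kmf = KaplanMeierFitter()
        kmf.fit(split.times[sel], split.events[sel], label=name)
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf[name].to_numpy(dtype=float)})
    res = logrank_test(split.times[far], split.times[near],
                       event_observed_A=split.events[far],
                       event_observed_B=split.events[near])
    return {"chisq": float(res.test_statistic), "p": float(res.p_value),
            "curves": curves, "median_cutoff": split.median_cutoff,
            "n_far": int(far.sum()), "n_near": int(near.sum())}
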