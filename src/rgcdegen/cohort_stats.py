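"""Cohort-level statistics for wild-type vs rd10 comparisons.

Covers: per-field responsive fractions; relative type abundance
log2(f_rd10 / f_wt) with an exact two-tailed binomial test per type
(rd10 counts against the wild-type proportion, Benjamini-Hochberg adjusted,
significant at adjusted p < 0.01); Mann-Whitney U comparisons with the
rank-biserial effect size rb = 1 - 2U / (n1 n2); Jensen-Shannon divergence
(base 2) between response-quality distributions; Pearson correlation
matrices between per-type mean responses; and the percent-difference
summaries used for headline group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "responsive_fraction",
    "relative_abundance",
    "binomial_abundance_test",
    "abundance_table",
    "mwu_with_effect",
    "bh_adjust",
    "jsd",
    "jsd_from_samples",
    "type_correlation_matrix",
    "percent_difference",
    "supergroup_mean_abundance",
]

ABUNDANCE_ALPHA = 0.01


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided Mann-Whitney U comparison with rank-biserial effect size."""

    u_statistic: float
    p_value: float
    rank_biserial: float
    n1: int
    n2: int


def responsive_fraction(
    field_ids: Sequence, responsive: Sequence[bool]
) -> Tuple[pd.Series, float, float]:
    """Fraction of responsive cells per recording field and the cohort
    mean +- SD across fields. Empty input raises."""
    df = pd.DataFrame({"field": list(field_ids), "responsive": list(responsive)})
    if df.empty:
        raise ValueError("no cells given")
    per_field = df.groupby("field")["responsive"].mean()
    return per_field, float(per_field.mean()), float(per_field.std(ddof=0))


def relative_abundance(f_rd10: float, f_wt: float) -> float:
    """log2(f_rd10 / f_wt); positive = more abundant in rd10.

    Either fraction at zero marks the type missing (NaN).
    """
    if f_rd10 < 0 or f_wt < 0 or f_rd10 > 1 or f_wt > 1:
        raise ValueError("fractions must lie in [0, 1]")
    if f_rd10 == 0 or f_wt == 0:
        return float("nan")
    return float(np.log2(f_rd10 / f_wt))


def binomial_abundance_test(k: int, n: int, p: float) -> float:
    """Exact two-tailed binomial p-value ('minlike': sum of outcome
    probabilities not exceeding that of the observed count)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p < 1:
        raise ValueError("expected proportion must be strictly inside (0, 1)")
    return float(stats.binomtest(k, n, p).pvalue)


def abundance_table(
    counts_wt: Dict[int, int],
    counts_rd10: Dict[int, int],
    alpha: float = ABUNDANCE_ALPHA,
) -> pd.DataFrame:
    """Per-type relative abundance of rd10 vs wild-type with binomial tests.

    ``counts_*`` map group id -> included-cell count. The binomial test uses
    the rd10 count per type against the wild-type proportion; p-values are
    BH-adjusted across the types testable at this age.
    """
    groups = sorted(set(counts_wt) | set(counts_rd10))
    n_wt = sum(counts_wt.values())
    n_rd = sum(counts_rd10.values())
    if n_wt == 0 or n_rd == 0:
        raise ValueError("both cohorts need at least one included cell")
    rows = []
    for g in groups:
        kw = counts_wt.get(g, 0)
        kr = counts_rd10.get(g, 0)
        fw, fr = kw / n_wt, kr / n_rd
        missing = kw == 0 or kr == 0
        p_raw = binomial_abundance_test(kr, n_rd, fw) if 0 < fw < 1 else np.nan
        rows.append({
            "group_id": g, "k_wt": kw, "k_rd10": kr,
            "f_wt": fw, "f_rd10": fr,
            "relative_abundance": relative_abundance(fr, fw) if not missing else np.nan,
            "missing": missing, "p_binomial": p_raw,
        })
    df = pd.DataFrame(rows).set_index("group_id")
    testable = df["p_binomial"].notna()
    df["p_adjusted"] = np.nan
    if testable.any():
        df.loc[testable, "p_adjusted"] = bh_adjust(df.loc[testable, "p_binomial"].to_numpy())
    df["significant"] = df["p_adjusted"] < alpha
    return df


def mwu_with_effect(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Two-sided Mann-Whitney U test (U reported for the first sample) with
    the rank-biserial correlation rb = 1 - 2U / (n1 n2)."""
    x = np.asarray(list(x), dtype=np.float64)
    y = np.asarray(list(y), dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u = float(res.statistic)
    rb = 1.0 - 2.0 * u / (x.size * y.size)
    return ComparisonResult(u_statistic=u, p_value=float(res.pvalue), rank_biserial=rb,
                            n1=x.size, n2=y.size)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    pvals = np.asarray(list(pvals), dtype=np.float64)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def jsd(p_hist: Sequence[float], q_hist: Sequence[float]) -> float:
    """Jensen-Shannon divergence (base 2, in [0, 1]) between two histograms
    on a common binning; inputs are renormalised to sum to 1."""
    p = np.asarray(list(p_hist), dtype=np.float64)
    q = np.asarray(list(q_hist), dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("histograms must share a binning")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("a histogram with zero total mass has no distribution")
    val = jensenshannon(p / p.sum(), q / q.sum(), base=2) ** 2
    return float(np.clip(np.nan_to_num(val), 0.0, 1.0))


def jsd_from_samples(
    x: Sequence[float],
    y: Sequence[float],
    bins: int = 20,
    value_range: Tuple[float, float] = (0.0, 1.0),
) -> float:
    """JSD between two samples (e.g. per-type QI values) histogrammed on a
    fixed common binning."""
    hx, _ = np.histogram(np.asarray(list(x)), bins=bins, range=value_range)
    hy, _ = np.histogram(np.asarray(list(y)), bins=bins, range=value_range)
    return jsd(hx, hy)


def type_correlation_matrix(
    means_a: Dict[int, Optional[np.ndarray]],
    means_b: Dict[int, Optional[np.ndarray]],
) -> pd.DataFrame:
    """Pearson r between per-type mean traces of two cohorts (full cross
    matrix; the diagonal is the same-type similarity). Missing types and
    constant traces give NaN rows/columns."""
    groups = sorted(set(means_a) | set(means_b))
    mat = pd.DataFrame(np.nan, index=groups, columns=groups)
    for ga in groups:
        ta = means_a.get(ga)
        if ta is None or np.std(ta) == 0:
            continue
        for gb in groups:
            tb = means_b.get(gb)
            if tb is None or np.std(tb) == 0:
                continue
            mat.loc[ga, gb] = float(np.corrcoef(ta, tb)[0, 1])
    return mat


def percent_difference(mean_wt: float, mean_rd10: float) -> float:
    """Headline percent difference 100 (mean_wt - mean_rd10) / mean_wt,
    rounded half-up to one decimal; positive = reduced (or faster) in rd10."""
    if mean_wt == 0:
        raise ValueError("wild-type baseline mean must be nonzero")
    value = 100.0 * (mean_wt - mean_rd10) / mean_wt
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def supergroup_mean_abundance(
    tables_by_age: Dict[str, pd.DataFrame],
    supergroup_of: Dict[int, str],
) -> pd.Series:
    """Mean relative abundance per super-group pooled over ages; the sort
    order (descending) is the measured resilience ranking."""
    records = []
    for age, table in tables_by_age.items():
        for g, row in table.iterrows():
            if np.isfinite(row["relative_abundance"]):
                records.append((supergroup_of[g], row["relative_abundance"]))
    df = pd.DataFrame(records, columns=["super_group", "rel_abundance"])
    return df.groupby("super_group")["rel_abundance"].mean().sort_values(ascending=False)
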