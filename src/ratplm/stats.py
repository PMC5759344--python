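"""Group summaries, ANOVA with Bonferroni post hoc, Pearson correlation,
dose-response tables, and immunoblot densitometry ratios.

A note on correlation reporting: published summaries sometimes print a
signed value labelled "R^2". A squared correlation cannot be negative, so
such values are treated here as the signed Pearson r; this module therefore
always reports r and r^2 as separate fields and never emits a signed
"R squared".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedMetricError, ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation between two metrics."""

    n: int
    r: float
    r_squared: float
    p: float


def summarize_groups(per_animal: pd.DataFrame, group_col: str = "group",
                     metrics: list | None = None) -> pd.DataFrame:
    """Mean, sample SD and n per (group, metric).

    ``per_animal`` has one row per animal, a group column and numeric metric
    columns. Single-animal groups get an SD of NaN (flagged, not silently 0).
    """
    if group_col not in per_animal.columns:
        raise ValidationError(f"missing group column {group_col!r}")
    if metrics is None:
        metrics = [c for c in per_animal.columns
                   if c != group_col and pd.api.types.is_numeric_dtype(per_animal[c])]
    rows = []
    for group, sub in per_animal.groupby(group_col, sort=False):
        for m in metrics:
            vals = sub[m].dropna().to_numpy(float)
            rows.append({
                group_col: group,
                "metric": m,
                "n": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(rows)


def pearson(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p-value from the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(n=int(x.size), r=r, r_squared=r * r,
                             p=float(res.pvalue))


def _bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def anova_posthoc(values_by_group: dict, subjects: dict | None = None) -> dict:
    """One-way ANOVA plus all-pairs t tests with Bonferroni correction.

    ``values_by_group`` maps group label -> per-animal values. When
    ``subjects`` maps each group to matching subject identifiers (the same
    animals measured under every condition), a one-way repeated-measures
    ANOVA is used; otherwise an ordinary one-way ANOVA. Pairwise p-values
    are multiplied by the number of comparisons and capped at 1.
    """
    groups = {k: np.asarray(v, float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(v.size < 2 for v in groups.values()):
        raise ValidationError("need at least two values per group")

    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        f_stat, p_omnibus = 0.0, 1.0
    elif subjects is not None:
        long = pd.DataFrame(
            [(subj, cond, val)
             for cond, vals in groups.items()
             for subj, val in zip(subjects[cond], vals)],
            columns=["subject", "condition", "value"],
        )
        from statsmodels.stats.anova import AnovaRM

        res = AnovaRM(long, depvar="value", subject="subject",
                      within=["condition"]).fit()
        f_stat = float(res.anova_table["F Value"].iloc[0])
        p_omnibus = float(res.anova_table["Pr > F"].iloc[0])
    else:
        f_stat, p_omnibus = (float(v) for v in sps.f_oneway(*groups.values()))

    pairs = list(combinations(groups, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        if np.all(groups[a] == groups[a][0]) and np.all(groups[b] == groups[b][0]) \
                and groups[a][0] == groups[b][0]:
            t_stat, p_raw = 0.0, 1.0
        elif subjects is not None:
            t_stat, p_raw = (float(v) for v in sps.ttest_rel(groups[a], groups[b]))
        else:
            t_stat, p_raw = (float(v) for v in sps.ttest_ind(groups[a], groups[b]))
        rows.append({"group_a": a, "group_b": b, "t": t_stat,
                     "p_raw": p_raw, "p_bonferroni": _bonferroni(p_raw, m)})
    return {"F": f_stat, "p": p_omnibus, "pairwise": pd.DataFrame(rows)}


def dose_response(index_by_dose: dict, dose_order: list | None = None) -> dict:
    """Mean +/- SD per dose plus a monotonic-decrease flag.

    ``index_by_dose`` maps dose label (e.g. ``baseline``, ``saline``,
    ``0.01`` ...) to per-animal index values; ``dose_order`` gives the
    labels, in increasing-dose order, over which monotonicity of the means
    is assessed (default: all labels in insertion order).
    """
    if not index_by_dose:
        raise ValidationError("no dose groups supplied")
    order = dose_order if dose_order is not None else list(index_by_dose)
    missing = [d for d in order if d not in index_by_dose]
    if missing:
        raise ValidationError(f"missing dose groups: {missing}")
    rows = []
    for label in index_by_dose:
        vals = np.asarray(index_by_dose[label], float)
        rows.append({"dose": label, "n": vals.size,
                     "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan})
    table = pd.DataFrame(rows)
    means = [table.set_index("dose").loc[d, "mean"] for d in order]
    monotonic = all(b < a for a, b in zip(means, means[1:]))
    return {"table": table, "monotonic_decreasing": bool(monotonic)}


def densitometry_ratio(records: pd.DataFrame, group_col: str = "group") -> dict:
    """Per-animal band-density ratio (target OD / actin OD) + group stats.

    ``records`` needs columns ``dat_od`` and ``actin_od`` (optical
    densities, positive). The ratio is invariant to any common exposure
    scaling of both bands.
    """
    for col in ("dat_od", "actin_od"):
        if col not in records.columns:
            raise ValidationError(f"missing column {col!r}")
        if (records[col] <= 0).any():
            raise ValidationError(f"nonpositive optical density in {col!r}")
    out = records.copy()
    out["ratio"] = out["dat_od"] / out["actin_od"]
    result = {"records": out}
    if group_col in out.columns and out[group_col].nunique() >= 2:
        by_group = {g: sub["ratio"].to_numpy(float)
                    for g, sub in out.groupby(group_col, sort=False)}
        if all(len(v) >= 2 for v in by_group.values()):
            result["comparison"] = anova_posthoc(by_group)
    return result


__all__ = [
    "CorrelationResult",
    "summarize_groups",
    "pearson",
    "anova_posthoc",
    "dose_response",
    "densitometry_ratio",
]
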