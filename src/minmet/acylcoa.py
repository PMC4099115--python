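"""Group summaries and classical tests for targeted acyl-CoA tables.

Input is a tidy concentration table (one row per mouse x species, columns
``mouse_id, group, species, concentration`` in nmol per mg wet tissue, group
labels from the 2x2 genotype-diet design).  The module computes group
means with standard errors, concentrations relative to a reference group,
fold changes in the field's reciprocal convention (ratios below one are
reported as ``1/x``), per-mouse [Acyl-CoA]/[CoASH] ratios, and pooled t /
one-way ANOVA tests (equal-variance assumption throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

GROUPS = ("WT-LF", "WT-HF", "MU-LF", "MU-HF")
REQUIRED_COLUMNS = ("mouse_id", "group", "species", "concentration")
COASH = "CoASH"


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"concentration table missing columns {missing}")
    bad_groups = set(table["group"]) - set(GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown group labels {sorted(bad_groups)}")
    if (table["concentration"].astype(float) < 0).any():
        raise ValidationError("concentrations must be >= 0")
    return table


def group_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SEM (= sd/sqrt(n)) and n per (group, species) cell.

    Cells with a single observation get ``sem = NaN`` (undefined sentinel);
    empty cells are simply absent from the output.
    """
    table = validate_table(table)
    rows = []
    for (group, species), chunk in table.groupby(["group", "species"],
                                                 sort=True):
        values = chunk["concentration"].to_numpy(dtype=float)
        n = values.size
        mean = float(values.mean())
        sem = float(values.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
        rows.append({"group": group, "species": species, "mean": mean,
                     "sem": sem, "n": n})
    return pd.DataFrame(rows, columns=["group", "species", "mean", "sem", "n"])


def relative_concentrations(summaries: pd.DataFrame,
                            reference_group: str = "WT-LF") -> pd.DataFrame:
    """Each group mean divided by the reference-group mean of its species."""
    ref = summaries[summaries["group"] == reference_group]
    if ref.empty:
        raise ValidationError(f"reference group {reference_group!r} absent")
    ref_means = dict(zip(ref["species"], ref["mean"]))
    out = summaries.copy()
    rel, rel_sem = [], []
    for _, row in out.iterrows():
        base = ref_means.get(row["species"])
        if base is None or base <= 0:
            raise ValidationError(
                f"non-positive or missing reference mean for species "
                f"{row['species']!r}"
            )
        rel.append(row["mean"] / base)
        rel_sem.append(row["sem"] / base if np.isfinite(row["sem"]) else np.nan)
    out["relative_mean"] = rel
    out["relative_sem"] = rel_sem
    return out


def fold_change(mean_a: float, mean_b: float) -> float:
    """Fold change of group A over group B (ratio of means)."""
    if mean_b <= 0:
        raise ValidationError("denominator mean must be > 0")
    return mean_a / mean_b


def format_fold_change(fc: float, decimals: int = 2) -> str:
    """Render a fold change, using the reciprocal form below 1.

    ``3.66 -> "3.66"``; ``0.3953 -> "1/2.53"``.
    """
    if fc <= 0:
        raise ValidationError("fold change must be > 0")
    if fc >= 1:
        return f"{fc:.{decimals}f}"
    return f"1/{1.0 / fc:.{decimals}f}"


def coash_ratios(table: pd.DataFrame,
                 coash_species: str = COASH) -> pd.DataFrame:
    """Per-mouse total [Acyl-CoA]/[CoASH] ratio plus group mean +- SEM.

    Mice with zero or missing CoASH get an undefined (NaN) sentinel.
    Returns a frame with per-mouse rows (``mouse_id, group, ratio``) and the
    group aggregation available via :func:`group_ratio_summaries`.
    """
    table = validate_table(table)
    rows = []
    for (mouse, group), chunk in table.groupby(["mouse_id", "group"],
                                               sort=True):
        coash = chunk.loc[chunk["species"] == coash_species, "concentration"]
        acyl = chunk.loc[chunk["species"] != coash_species, "concentration"]
        if coash.empty or float(coash.iloc[0]) == 0.0:
            ratio = float("nan")
        else:
            ratio = float(acyl.sum() / float(coash.iloc[0]))
        rows.append({"mouse_id": mouse, "group": group, "ratio": ratio})
    return pd.DataFrame(rows, columns=["mouse_id", "group", "ratio"])


def group_ratio_summaries(ratios: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for group, chunk in ratios.groupby("group", sort=True):
        values = chunk["ratio"].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        n = values.size
        rows.append({
            "group": group,
            "mean": float(values.mean()) if n else float("nan"),
            "sem": float(values.std(ddof=1) / math.sqrt(n)) if n >= 2
            else float("nan"),
            "n": n,
        })
    return pd.DataFrame(rows, columns=["group", "mean", "sem", "n"])


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    df: float
    kind: str


def group_mean_tests(table: pd.DataFrame, contrast: str,
                     groups: tuple[str, str] | None = None,
                     species: str | None = None,
                     target_group: str | None = None) -> GroupTestResult:
    """Two-group pooled t test or group-vs-overall deviation test.

    ``contrast='two_group'`` runs a pooled-variance two-sided t test between
    ``groups``; ``contrast='group_vs_overall'`` runs the one-way ANOVA over
    the four design groups and a deviation-contrast t test of
    ``target_group`` against the overall mean, returning the contrast test
    (the omnibus F is in ``df``/available via :func:`anova_omnibus`).
    Values may be restricted to one ``species``.
    """
    table = validate_table(table)
    if species is not None:
        table = table[table["species"] == species]
    by_group = {g: c["concentration"].to_numpy(dtype=float)
                for g, c in table.groupby("group")}
    for g, v in by_group.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")
    if all(np.ptp(v) == 0 for v in by_group.values()):
        raise ValidationError("zero within-group variance in every group")

    if contrast == "two_group":
        if groups is None or len(groups) != 2:
            raise ValidationError("two_group contrast needs exactly 2 groups")
        a, b = (by_group[g] for g in groups)
        res = stats.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
        return GroupTestResult(float(res.statistic), float(res.pvalue),
                               float(df), "pooled t")
    if contrast == "group_vs_overall":
        if target_group is None:
            raise ValidationError("group_vs_overall needs target_group")
        values = [by_group[g] for g in sorted(by_group)]
        names = sorted(by_group)
        k = len(values)
        n_total = sum(v.size for v in values)
        # pooled within-group variance (ANOVA mean square error)
        sse = sum(((v - v.mean()) ** 2).sum() for v in values)
        df_err = n_total - k
        mse = sse / df_err
        target = by_group[target_group]
        overall = np.concatenate(values).mean()
        # deviation contrast: target group mean minus unweighted grand mean
        coeffs = {g: -1.0 / k for g in names}
        coeffs[target_group] += 1.0
        est = sum(coeffs[g] * by_group[g].mean() for g in names)
        var = mse * sum(coeffs[g] ** 2 / by_group[g].size for g in names)
        t_stat = est / math.sqrt(var)
        p = 2.0 * stats.t.sf(abs(t_stat), df_err)
        return GroupTestResult(float(t_stat), float(p), float(df_err),
                               "deviation contrast t")
    raise ValidationError(f"unknown contrast {contrast!r}")


def anova_omnibus(table: pd.DataFrame,
                  species: str | None = None) -> GroupTestResult:
    """One-way ANOVA F test across the four design groups."""
    table = validate_table(table)
    if species is not None:
        table = table[table["species"] == species]
    values = [c["concentration"].to_numpy(dtype=float)
              for _, c in table.groupby("group")]
    if len(values) < 2:
        raise ValidationError("need at least two groups for ANOVA")
    stat, p = stats.f_oneway(*values)
    df = (len(values) - 1, sum(v.size for v in values) - len(values))
    return GroupTestResult(float(stat), float(p), float(df[1]), "one-way F")
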