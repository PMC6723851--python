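"""Descriptive and univariate comparative statistics for the cohort tables.

All continuous dietary and anthropometric variables in this setting are
non-Gaussian, so summaries are median/IQR and comparisons are rank-based:
Mann-Whitney U for two groups, Kruskal-Wallis (with Dunn's pairwise
post-test) for more than two, Pearson chi-square for categorical blocks,
and Holm-Bonferroni step-down adjustment for the food-group family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ffq_ingest import FOOD_GROUPS

__all__ = [
    "median_iqr",
    "mann_whitney",
    "kruskal_wallis",
    "dunn_posthoc",
    "chi_square",
    "holm_adjust",
    "bmi_spearman_screen",
    "build_cohort_summary",
    "SummaryRow",
]


def median_iqr(x) -> tuple[float, float, float]:
    """(median, q1, q3) with quartiles by linear interpolation between order
    statistics (the numpy default convention)."""
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires a non-empty vector")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (of the first sample) and two-sided p.

    Normal approximation with tie correction, no continuity correction —
    appropriate for cohort-scale samples far beyond exact-test range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with k-1 df."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    arrays = []
    for label, g in groups.items():
        g = np.asarray(g, dtype=float)
        if g.size == 0:
            raise ValueError(f"group {label!r} is empty")
        arrays.append(g)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # every observation tied: no evidence, H = 0
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise post-test after Kruskal-Wallis.

    For each unordered pair of groups the statistic is the difference in mean
    pooled ranks divided by its standard error under the null,

        z = (Rbar_i - Rbar_j) / sqrt(S * (1/n_i + 1/n_j)),
        S = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1)),

    where the sum runs over tie groups of the pooled data.  Raw p-values are
    two-sided normal; adjustment is Holm by default (``adjust='bonferroni'``
    or ``adjust='none'`` are accepted).
    """
    labels = list(groups.keys())
    if len(labels) < 2:
        raise ValueError("dunn_posthoc requires at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {k!r} is empty")

    pooled = np.concatenate([arrays[k] for k in labels])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction over pooled tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts)) / (12.0 * (n_total - 1))
    s2 = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = {}, {}
    start = 0
    for k in labels:
        n_k = arrays[k].size
        mean_ranks[k] = float(np.mean(ranks[start : start + n_k]))
        sizes[k] = n_k
        start += n_k

    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            se = np.sqrt(s2 * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if adjust == "none":
        out["p_adj"] = out["p_raw"]
    elif adjust == "holm":
        out["p_adj"] = holm_adjust(out["p_raw"].to_numpy())
    elif adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p_raw"].to_numpy() * len(out), 1.0)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on an r x c table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    expected = stats.contingency.expected_freq(obs)
    if (expected <= 0).any():
        raise ValueError(
            "zero expected count; merge sparse categories before testing"
        )
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="holm")
    return p_adj


def bmi_spearman_screen(
    consumption: pd.DataFrame,
    roster: pd.DataFrame,
    strata_col: str = "anthro_class",
) -> pd.DataFrame:
    """Spearman rho (and p) of each food group's grams vs BMI.

    One row per food group; one (rho, p) column pair for all individuals plus
    one per stratum.  Strata with fewer than 3 members are marked
    not-computable (NaN).
    """
    from .correlation_networks import spearman_pair

    roster = roster.set_index(roster["id"].astype(str)) if "id" in roster.columns else roster
    common = consumption.index.intersection(roster.index)
    cons = consumption.loc[common]
    ros = roster.loc[common]

    strata = ["all"] + sorted(ros[strata_col].unique().tolist())
    rows = []
    for group in FOOD_GROUPS:
        row: dict[str, float | str] = {"food_group": group}
        for s in strata:
            mask = np.ones(len(ros), dtype=bool) if s == "all" else (ros[strata_col] == s).to_numpy()
            if mask.sum() < 3:
                row[f"rho_{s}"], row[f"p_{s}"] = np.nan, np.nan
                continue
            rho, p = spearman_pair(
                cons.loc[mask, group].to_numpy(), ros.loc[mask, "bmi"].to_numpy()
            )
            row[f"rho_{s}"], row[f"p_{s}"] = rho, p
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SummaryRow:
    """One line of a cohort summary table."""

    variable: str
    kind: str  # "continuous" | "categorical"
    per_group: dict
    test: str | None
    p_raw: float | None
    p_adj: float | None


def _continuous_row(
    name: str, values: pd.Series, strat: pd.Series, labels: list[str]
) -> SummaryRow:
    per_group = {}
    groups = {}
    for g in labels:
        v = values[strat == g].to_numpy(dtype=float)
        if v.size:
            med, q1, q3 = median_iqr(v)
            per_group[g] = {"median": med, "q1": q1, "q3": q3, "n": int(v.size)}
            groups[g] = v
    if len(groups) < 2 or min(len(v) for v in groups.values()) < 1:
        return SummaryRow(name, "continuous", per_group, None, None, None)
    if len(groups) == 2:
        (a, b) = list(groups.values())
        _, p = mann_whitney(a, b)
        test = "mann_whitney"
    else:
        _, p = kruskal_wallis(groups)
        test = "kruskal_wallis"
    return SummaryRow(name, "continuous", per_group, test, p, None)


def _categorical_row(
    name: str, values: pd.Series, strat: pd.Series, labels: list[str]
) -> SummaryRow:
    tab = pd.crosstab(values, strat).reindex(columns=labels, fill_value=0)
    per_group = {}
    for g in labels:
        col = tab[g]
        total = int(col.sum())
        per_group[g] = {
            str(cat): {
                "n": int(cnt),
                "pct": (100.0 * cnt / total) if total else np.nan,
            }
            for cat, cnt in col.items()
        }
    # totals across strata, for whole-cohort percentages
    row_totals = tab.sum(axis=1)
    grand = int(row_totals.sum())
    per_group["total"] = {
        str(cat): {"n": int(cnt), "pct": 100.0 * cnt / grand if grand else np.nan}
        for cat, cnt in row_totals.items()
    }
    p = None
    test = None
    arr = tab.to_numpy()
    if arr.shape[0] >= 2 and arr.shape[1] >= 2 and (arr.sum(0) > 0).all() and (arr.sum(1) > 0).all():
        try:
            _, _, p = chi_square(arr)
            test = "chi_square"
        except ValueError:
            p = None
    return SummaryRow(name, "categorical", per_group, test, p, None)


def build_cohort_summary(
    roster: pd.DataFrame,
    consumption: pd.DataFrame | None = None,
    stratify_by: str = "anthro_class",
    adjust_demographics: bool = False,
) -> list[SummaryRow]:
    """Cohort characteristics and food-group consumption by stratum.

    Continuous variables (age, BMI, the 14 food groups) get median/IQR per
    stratum plus a Mann-Whitney (2 strata) or Kruskal-Wallis (>2) p-value;
    categorical variables (sex, SES, pubertal stage, anthropometric class)
    get counts/percentages plus a chi-square p.  The 14 food-group p-values
    form the Holm multiplicity family; demographic rows join the family only
    when ``adjust_demographics`` is set.
    """
    if stratify_by not in roster.columns:
        raise ValueError(f"unknown stratifier {stratify_by!r}")
    roster = roster.copy()
    if "id" in roster.columns:
        roster.index = roster["id"].astype(str)
    strat = roster[stratify_by]
    labels = [l for l in _canonical_order(stratify_by) if l in set(strat)]
    if not labels:
        labels = sorted(strat.unique().tolist())

    rows: list[SummaryRow] = []
    single = len(roster) < 2 or len(labels) < 2

    for var in ("age", "bmi"):
        if var in roster.columns:
            r = _continuous_row(var, roster[var], strat, labels)
            if single:
                r = SummaryRow(r.variable, r.kind, r.per_group, None, None, None)
            rows.append(r)
    for var in ("sex", "ses", "pubertal_stage", "anthro_class"):
        if var in roster.columns and var != stratify_by:
            r = _categorical_row(var, roster[var], strat, labels)
            if single:
                r = SummaryRow(r.variable, r.kind, r.per_group, None, None, None)
            rows.append(r)
    # stratifier itself: counts/percentages, no test against itself
    rows.append(_categorical_row(stratify_by, strat, strat, labels))
    rows[-1] = SummaryRow(
        rows[-1].variable, rows[-1].kind, rows[-1].per_group, None, None, None
    )

    food_rows: list[SummaryRow] = []
    if consumption is not None and not single:
        common = consumption.index.intersection(roster.index)
        cons = consumption.loc[common]
        st = strat.loc[common]
        for group in FOOD_GROUPS:
            food_rows.append(_continuous_row(group, cons[group], st, labels))

    # Holm family: the 14 food groups (optionally + demographic tests)
    family = [r for r in food_rows if r.p_raw is not None]
    if adjust_demographics:
        family += [r for r in rows if r.p_raw is not None]
    if family:
        adj = holm_adjust([r.p_raw for r in family])
        adj_map = {id(r): a for r, a in zip(family, adj)}
    else:
        adj_map = {}

    def _with_adj(r: SummaryRow) -> SummaryRow:
        return SummaryRow(
            r.variable, r.kind, r.per_group, r.test, r.p_raw, adj_map.get(id(r))
        )

    return [_with_adj(r) for r in rows + food_rows]


def summary_to_frame(rows: list[SummaryRow]) -> pd.DataFrame:
    """Flatten SummaryRows into a tidy table for CSV export."""
    records = []
    for r in rows:
        records.append(
            {
                "variable": r.variable,
                "kind": r.kind,
                "test": r.test,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "detail": repr(r.per_group),
            }
        )
    return pd.DataFrame(records)


def _canonical_order(stratifier: str) -> list[str]:
    if stratifier == "anthro_class":
        return ["underweight", "eutrophy", "overweight", "obesity"]
    if stratifier == "sex":
        return ["male", "female"]
    if stratifier == "ses":
        return ["good", "poor"]
    if stratifier == "pubertal_stage":
        return ["pre_pubertal", "pubertal", "post_pubertal"]
    return []
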