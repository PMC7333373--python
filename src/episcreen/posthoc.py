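"""Post-hoc characterisation of a significant pairwise interaction.

A significant pair (canonically pre-natal smoke exposure x socioeconomic
status) partitions the cohort into four interaction groups:

    1: v1 = 0, med/high-oriented v2 = 0   (e.g. no PSE, low SES)
    2: v1 = 0, v2 = 1                     (no PSE, med/high SES)
    3: v1 = 1, v2 = 0                     (PSE, low SES)
    4: v1 = 1, v2 = 1                     (PSE, med/high SES)

Group responder proportions are compared with the two-group test of
proportions (continuity-corrected chi-square, switching to Fisher's exact
test when any observed cell is below 5), and descriptive tables use the
continuity-corrected chi-square test of independence for dichotomous
variables and the Wilcoxon rank-sum test for continuous age.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BDR_RESPONDER_THRESHOLD, DiscreteCohort
from .permutation import run_screen

__all__ = [
    "assign_groups", "two_proportion_test", "chi2_independence",
    "ranksum_test", "group_summary", "descriptive_table", "plot_group_summary",
]

#: any observed 2x2 cell below this dispatches to Fisher's exact test
FISHER_CELL = 5


def assign_groups(v1: Sequence[int], v2: Sequence[int]) -> np.ndarray:
    """Interaction-group ids 1-4 following the printed ordering.

    ``v1`` is the exposure (e.g. PSE) and ``v2`` the med/high-oriented
    second variable (1 = med/high SES): group = 1 + 2*v1 + v2.
    """
    a = np.asarray(v1, dtype=np.int64)
    b = np.asarray(v2, dtype=np.int64)
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("group assignment requires binary variables")
    return 1 + 2 * a + b


def _check_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    return t


def two_proportion_test(table: Sequence[Sequence[int]]) -> tuple[float, str]:
    """Two-group test of proportions on a 2x2 table.

    Continuity-corrected chi-square by default; Fisher's exact (two-sided)
    when any observed cell is < 5.  Returns ``(p, method)``.
    """
    t = _check_table(np.asarray(table))
    if (t < FISHER_CELL).any():
        p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
        return p, "fisher"
    res = stats.chi2_contingency(t, correction=True)
    return float(res.pvalue), "chi2"


def chi2_independence(table: Sequence[Sequence[int]]) -> float:
    """Pearson chi-square test of independence (1 df) with continuity
    correction — the convention that reproduces printed demographic-table
    p-values."""
    t = _check_table(np.asarray(table))
    return float(stats.chi2_contingency(t, correction=True).pvalue)


def ranksum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value (normal approximation with tie
    correction and continuity correction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic", use_continuity=True).pvalue)


def group_summary(bdr_pct: Sequence[float], groups: Sequence[int],
                  sex: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Median/IQR/responder-fraction summary per interaction group.

    With ``sex`` given (1 = female) the summary is additionally stratified;
    empty group-stratum combinations are flagged, not fatal.  The
    ``above_population_median`` marker compares each group median with the
    all-sample median of the continuous response.
    """
    bdr = np.asarray(bdr_pct, dtype=float)
    grp = np.asarray(groups, dtype=np.int64)
    pop_median = float(np.median(bdr))
    strata = [("all", np.ones(len(bdr), dtype=bool))]
    if sex is not None:
        s = np.asarray(sex, dtype=np.int64)
        strata += [("female", s == 1), ("male", s == 0)]
    rows = []
    for stratum, mask in strata:
        for g in sorted(np.unique(grp)):
            sel = mask & (grp == g)
            row = {"stratum": stratum, "group": int(g), "n": int(sel.sum())}
            if sel.any():
                v = bdr[sel]
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                row.update({"median": float(med), "iqr_low": float(q1),
                            "iqr_high": float(q3),
                            "above_population_median": bool(med >= pop_median),
                            "responder_fraction": float((v >= BDR_RESPONDER_THRESHOLD).mean()),
                            "empty": False})
            else:
                row.update({"median": np.nan, "iqr_low": np.nan, "iqr_high": np.nan,
                            "above_population_median": False,
                            "responder_fraction": np.nan, "empty": True})
            rows.append(row)
    return pd.DataFrame(rows)


def group_proportion_tests(outcome: Sequence[int], groups: Sequence[int],
                           comparisons: Sequence[tuple[int, int]],
                           ) -> pd.DataFrame:
    """Pairwise two-group proportion tests between interaction groups,
    Bonferroni-corrected within the family of comparisons actually drawn."""
    y = np.asarray(outcome, dtype=np.int64)
    grp = np.asarray(groups, dtype=np.int64)
    m = len(comparisons)
    rows = []
    for g1, g2 in comparisons:
        t = np.array([[int(((grp == g) & (y == 1)).sum()),
                       int(((grp == g) & (y == 0)).sum())] for g in (g1, g2)])
        p, method = two_proportion_test(t)
        rows.append({"group_a": g1, "group_b": g2, "p_value": p, "method": method,
                     "m": m, "significant_bonferroni": p <= 0.05 / m})
    return pd.DataFrame(rows)


def descriptive_table(cohort: DiscreteCohort, B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Demographic-table-style summary: per predictor, responder /
    non-responder counts, the main-effect MI permutation p, and the
    continuity-corrected chi-square p (rank-sum for continuous age).

    The MI column shares one Bonferroni family of size m = number of
    predictors screened (0.05/8 rounds to the printed 0.006 threshold).
    """
    mi = run_screen(cohort, order=1, B=B, seed=seed).set_index("variables")
    y = cohort.outcome
    rows = []
    for name in cohort.predictors:
        x = cohort.data[name].to_numpy(dtype=np.int64)
        table = np.array([[int(((x == 1) & (y == 1)).sum()), int(((x == 1) & (y == 0)).sum())],
                          [int(((x == 0) & (y == 1)).sum()), int(((x == 0) & (y == 0)).sum())]])
        try:
            chi_p = chi2_independence(table)
        except ValueError:
            chi_p = np.nan
        rows.append({"variable": name,
                     "responders_1": table[0, 0], "nonresponders_1": table[0, 1],
                     "responders_0": table[1, 0], "nonresponders_0": table[1, 1],
                     "mi_bits": float(mi.loc[name, "bits"]),
                     "mi_permutation_p": float(mi.loc[name, "p_value"]),
                     "chi2_p": chi_p,
                     "m": int(mi.loc[name, "m"]),
                     "significance": str(mi.loc[name, "significance"])})
    if "age_years" in cohort.data.columns:
        age = cohort.data["age_years"].to_numpy(dtype=float)
        rows.append({"variable": "age_years (continuous)",
                     "responders_1": int((y == 1).sum()), "nonresponders_1": int((y == 0).sum()),
                     "responders_0": 0, "nonresponders_0": 0,
                     "mi_bits": np.nan, "mi_permutation_p": np.nan,
                     "chi2_p": ranksum_test(age[y == 1], age[y == 0]),
                     "m": len(cohort.predictors), "significance": ""})
    return pd.DataFrame(rows)


def plot_group_summary(summary: pd.DataFrame, path: str,
                       proportions: Optional[pd.DataFrame] = None) -> None:
    """Median/IQR error plot per interaction group (and optional stacked
    responder-proportion bars) with the 12% clinical threshold annotated.

    Requires matplotlib; headless (Agg) rendering.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = summary["stratum"].unique()
    ncols = 2 if proportions is not None else 1
    fig, axes = plt.subplots(1, ncols, figsize=(5 * ncols, 4), squeeze=False)
    ax = axes[0, 0]
    offsets = np.linspace(-0.2, 0.2, len(strata))
    for off, stratum in zip(offsets, strata):
        sub = summary[(summary["stratum"] == stratum) & (~summary["empty"])]
        ax.errorbar(sub["group"] + off, sub["median"],
                    yerr=[sub["median"] - sub["iqr_low"], sub["iqr_high"] - sub["median"]],
                    fmt="o", capsize=3, label=str(stratum))
    ax.axhline(BDR_RESPONDER_THRESHOLD, color="tab:blue", lw=1,
               label="12% clinical threshold")
    ax.set_xlabel("interaction group")
    ax.set_ylabel("BDR (% change in FEV1)")
    ax.set_xticks(sorted(summary["group"].unique()))
    ax.legend(fontsize=8)
    if proportions is not None:
        ax2 = axes[0, 1]
        sub = summary[(summary["stratum"] == "all") & (~summary["empty"])]
        ax2.bar(sub["group"], sub["responder_fraction"], label="responders")
        ax2.bar(sub["group"], 1 - sub["responder_fraction"],
                bottom=sub["responder_fraction"], label="non-responders")
        ax2.axhline(0.5, color="tab:blue", lw=1)
        ax2.set_xlabel("interaction group")
        ax2.set_ylabel("proportion")
        ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
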