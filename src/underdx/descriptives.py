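"""Bivariate cohort comparisons: group summaries and tests.

Categorical characteristics are compared across SMI groups with the
uncorrected Pearson chi-square test (no Yates continuity correction — the
reference statistics reproduce exactly without it) and continuous ones with
the Kruskal-Wallis rank test using mid-ranks and the standard tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

GROUP_ORDER = ("schizophrenia", "bipolar", "ptsd", "mdd", "none")
GROUP_LABELS = {"schizophrenia": "Schizophrenia", "bipolar": "Bipolar",
                "ptsd": "PTSD", "mdd": "MDD", "none": "Non-SMI"}


def pearson_chi_square(counts: np.ndarray) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square test of homogeneity/independence.

    Parameters
    ----------
    counts
        Non-negative integer matrix, groups x categories, at least 2 x 2.

    Returns
    -------
    (statistic, df, p) with ``statistic = sum (obs - exp)^2 / exp`` where the
    expected counts come from the row/column margins, ``df = (r-1)(c-1)``, and
    the p-value from the chi-square upper tail.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("counts must be a matrix with at least 2 rows and 2 columns")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("grand total must be positive")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column margin: expected counts undefined")
    expected = np.outer(rows, cols) / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(chi2.sf(stat, df))
    return stat, df, p


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Kruskal-Wallis H test with mid-ranks and tie correction.

    ``groups`` is a sequence (>= 2) of non-empty 1-d observation vectors.
    Raises ValueError when every observation is identical (the tie-correction
    denominator vanishes and H is undefined).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(groups)
    n = pooled.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = rankdata(pooled)  # mid-ranks for ties
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction: 1 - sum(t^3 - t) / (n^3 - n)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    if correction == 0.0:
        raise ValueError("all observations identical: H undefined")
    h /= correction
    df = len(groups) - 1
    return float(h), df, float(chi2.sf(h, df))


@dataclass
class Table1Summary:
    """Layered cohort summary: formatted table plus the underlying tests."""

    table: pd.DataFrame  # variables x (Total + group columns), formatted strings
    tests: pd.DataFrame  # variable, test, statistic, df, p, note
    group_sizes: dict[str, int]

    def to_csv(self, path: str | Path) -> None:
        merged = self.table.copy()
        merged.to_csv(path, index=True, index_label="variable")
        tests_path = Path(path).with_suffix(".tests.csv")
        self.tests.to_csv(tests_path, index=False)

    def to_text(self) -> str:
        """Aligned plain-text rendering with human-readable p-values."""
        tab = self.table.copy()
        stat_col, p_col = [], []
        tests = self.tests.set_index("variable")
        for var in tab.index:
            if var in tests.index and not tests.loc[var, "skipped"]:
                stat_col.append(f"{tests.loc[var, 'statistic']:.1f}")
                p = tests.loc[var, "p"]
                p_col.append("<0.01" if p < 0.01 else f"{p:.2f}")
            else:
                stat_col.append("")
                p_col.append("")
        tab["Test statistic"] = stat_col
        tab["p"] = p_col
        return tab.to_string()


def _fmt_count_pct(count: int, denom: int) -> str:
    pct = 100.0 * count / denom if denom else 0.0
    return f"{count} ({pct:.1f})"


def summarize_table1(cohort: pd.DataFrame) -> Table1Summary:
    """Group-wise cohort characteristics with chi-square / Kruskal-Wallis tests.

    Group columns are ordered schizophrenia, bipolar, PTSD, MDD, non-SMI.
    Groups that are empty in the cohort are reported with N = 0 and excluded
    from the tests; when fewer than two groups remain, tests are skipped and
    flagged not-applicable.
    """
    groups = {g: cohort[cohort["reported_smi"] == g] for g in GROUP_ORDER}
    sizes = {g: len(df) for g, df in groups.items()}
    live = [g for g in GROUP_ORDER if sizes[g] > 0]
    testable = len(live) >= 2
    n_total = len(cohort)

    columns = [f"Total (N={n_total})"] + [
        f"{GROUP_LABELS[g]} (N={sizes[g]})" for g in GROUP_ORDER]

    def per_group(fn) -> list[str]:
        return [fn(cohort)] + [fn(groups[g]) if sizes[g] else "-" for g in GROUP_ORDER]

    rows: dict[str, list[str]] = {}
    rows["Age mean (SD)"] = per_group(
        lambda d: f"{d['age_years'].mean():.1f} ({d['age_years'].std():.1f})")
    rows["Age median (min-max)"] = per_group(
        lambda d: f"{d['age_years'].median():.0f} "
                  f"({d['age_years'].min():.0f}-{d['age_years'].max():.0f})")
    rows["Female (%)"] = per_group(
        lambda d: _fmt_count_pct(int(d["female"].sum()), len(d)))
    for race in ("white", "black", "other"):
        rows[f"Race {race} (%)"] = per_group(
            lambda d, rc=race: _fmt_count_pct(int((d["race"] == rc).sum()), len(d)))
    rows["Hispanic (%)"] = per_group(
        lambda d: _fmt_count_pct(int(d["hispanic"].sum()), len(d)))
    rows["Selim mean (SD)"] = per_group(
        lambda d: f"{d['selim'].mean():.1f} ({d['selim'].std():.1f})")
    rows["Selim median (min-max)"] = per_group(
        lambda d: f"{d['selim'].median():.0f} ({d['selim'].min()}-{d['selim'].max()})")
    rows["Admission (%)"] = per_group(
        lambda d: _fmt_count_pct(int(d["admission"].sum()), len(d)))

    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)

    def cat_counts(indicator: pd.Series) -> np.ndarray:
        return np.array([[int(indicator[cohort["reported_smi"] == g].sum()),
                          sizes[g] - int(indicator[cohort["reported_smi"] == g].sum())]
                         for g in live])

    tests = []

    def add_chi2(var: str, indicator: pd.Series) -> None:
        if not testable:
            tests.append((var, "chi-square", np.nan, 0, np.nan, True,
                          "fewer than two non-empty groups"))
            return
        counts = cat_counts(indicator)
        try:
            stat, df, p = pearson_chi_square(counts)
            tests.append((var, "chi-square", stat, df, p, False, ""))
        except ValueError as e:
            tests.append((var, "chi-square", np.nan, 0, np.nan, True, str(e)))

    def add_kw(var: str, col: str) -> None:
        if not testable:
            tests.append((var, "kruskal-wallis", np.nan, 0, np.nan, True,
                          "fewer than two non-empty groups"))
            return
        samples = [groups[g][col].to_numpy(float) for g in live]
        try:
            stat, df, p = kruskal_wallis(samples)
            tests.append((var, "kruskal-wallis", stat, df, p, False, ""))
        except ValueError as e:
            tests.append((var, "kruskal-wallis", np.nan, 0, np.nan, True, str(e)))

    add_kw("Age mean (SD)", "age_years")
    add_chi2("Female (%)", cohort["female"] == 1)
    for race in ("white", "black", "other"):
        add_chi2(f"Race {race} (%)", cohort["race"] == race)
    add_chi2("Hispanic (%)", cohort["hispanic"] == 1)
    add_kw("Selim mean (SD)", "selim")
    add_chi2("Admission (%)", cohort["admission"] == 1)

    tests_df = pd.DataFrame(
        tests, columns=["variable", "test", "statistic", "df", "p", "skipped", "note"])
    return Table1Summary(table=table, tests=tests_df, group_sizes=sizes)
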