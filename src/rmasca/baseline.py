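"""Baseline cohort comparisons: chi-square tests and t-tests.

Categorical clinical variables are compared between survivors and
non-survivors with Pearson chi-square tests (no continuity correction;
``Unknown`` categories and the single lost-to-follow-up patient excluded
from testing). Continuous variables use two-sample t-tests; tumor size is
log transformed first to approximate normality.

``TABLE1_COUNTS`` carries the published baseline contingency counts of the
study cohort (209 ten-year survivors vs 40 non-survivors) so the printed
tests can be recomputed directly from counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "TABLE1_COUNTS",
    "TABLE1_PRINTED_P",
    "pearson_chi_square",
    "two_sample_t_test",
    "summarize_baseline",
    "baseline_chi_square_tests",
]


@dataclass
class ContingencyTable:
    """Counts of category levels (columns) per comparison group (rows)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if min(self.counts.shape) < 2:
            raise ValueError("need at least a 2x2 table")


# Published baseline contingency counts, survivors first then non-survivors.
# Unknown categories are already excluded (they are excluded from testing).
_SPLITS = ("survivor", "non-survivor")
TABLE1_COUNTS: dict[str, ContingencyTable] = {
    name: ContingencyTable(_SPLITS, cols, np.array(counts))
    for name, cols, counts in [
        ("location", ("left", "right", "bilateral"), [[98, 110, 1], [27, 13, 0]]),
        ("histology", ("IDC", "ILC", "DCIS/LCIS", "other"), [[157, 20, 22, 10], [33, 5, 2, 0]]),
        ("stage", ("0", "1", "2", "3"), [[18, 112, 66, 12], [2, 15, 10, 12]]),
        ("comorbidity", ("none", "cardiovascular", "other"), [[156, 26, 27], [21, 9, 10]]),
        ("estrogen_receptor", ("positive", "negative"), [[160, 30], [30, 9]]),
        ("progesterone_receptor", ("positive", "negative"), [[110, 78], [23, 16]]),
        ("her2", ("positive", "negative"), [[40, 146], [9, 30]]),
        ("lymphatic_involvement", ("positive", "negative"), [[56, 153], [18, 22]]),
        ("radiation", ("local", "locoregional"), [[144, 65], [22, 18]]),
        ("chemotherapy", ("no", "yes"), [[125, 84], [21, 19]]),
        ("endocrine", ("none", "tamoxifen", "aromatase-inhibitor"), [[99, 95, 15], [14, 18, 8]]),
        ("trastuzumab", ("no", "yes"), [[179, 30], [35, 5]]),
    ]
}

#: p-values as printed in the published baseline table (Pearson reproduces
#: all rows at 3 decimals except trastuzumab and radiation, whose original
#: test variant is not recoverable from the printed counts).
TABLE1_PRINTED_P: dict[str, float] = {
    "location": 0.055, "histology": 0.320, "stage": 0.001,
    "comorbidity": 0.018, "estrogen_receptor": 0.270,
    "progesterone_receptor": 0.958, "her2": 0.829,
    "lymphatic_involvement": 0.021, "radiation": 0.087,
    "chemotherapy": 0.390, "endocrine": 0.029, "trastuzumab": 0.766,
}


def pearson_chi_square(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, degrees of freedom, two-sided p-value). Rejects
    tables with any zero expected count.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    expected = stats.contingency.expected_freq(counts)
    if np.any(expected == 0):
        raise ValueError("table has a zero expected count; test undefined")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def two_sample_t_test(
    x, y, log_transform: bool = False, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test, optionally on the natural-log scale.

    Pooled-variance (Student) by default; pass ``equal_var=False`` for
    Welch. Returns (statistic, df, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if log_transform:
        if np.any(x <= 0) or np.any(y <= 0):
            bad = np.concatenate([x[x <= 0], y[y <= 0]])
            raise ValueError(f"log transform requires positive values; got {bad[:3]}")
        x, y = np.log(x), np.log(y)
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def baseline_chi_square_tests(
    tables: dict[str, ContingencyTable] | None = None,
) -> pd.DataFrame:
    """Chi-square tests for each baseline contingency table.

    Defaults to the published baseline counts. Returns a DataFrame with
    statistic, df and p-value per clinical variable.
    """
    tables = TABLE1_COUNTS if tables is None else tables
    rows = []
    for name, table in tables.items():
        s, df, p = pearson_chi_square(table)
        rows.append({"variable": name, "statistic": s, "df": df, "p_value": p})
    return pd.DataFrame(rows)


_CONTINUOUS = {"age": False, "bmi": False, "tumor_size": True}  # name -> log?


def summarize_baseline(
    records: pd.DataFrame,
    split: str = "survival",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Baseline-characteristics summary split by a two-level label.

    ``records`` holds one row per patient. Continuous columns (``age``,
    ``bmi`` as mean (SD); ``tumor_size`` as median (IQR), log transformed for
    testing) get t-test p-values; all other non-id columns are treated as
    categorical and get Pearson chi-square p-values with ``Unknown`` levels
    excluded. Records whose split label is missing/lost-to-follow-up are
    excluded from the comparison.
    """
    if split not in records.columns:
        raise ValueError(f"records lack split column {split!r}")
    labels = records[split].astype(str).str.lower()
    keep = records[split].notna() & ~labels.isin({"lost-to-follow-up", "lost", "unknown", "nan"})
    records = records[keep]
    present = set(records[split])
    levels = [l for l in _SPLITS if l in present] or sorted(present)
    if len(levels) != 2:
        raise ValueError(f"split column must have exactly 2 levels, found {levels}")
    a = records[records[split] == levels[0]]
    b = records[records[split] == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each split level needs at least 2 records")
    rows = []
    for col in records.columns:
        if col in (split, "patient_id"):
            continue
        if col in _CONTINUOUS:
            log = _CONTINUOUS[col]
            xa, xb = a[col].dropna(), b[col].dropna()
            stat, df, p = two_sample_t_test(xa, xb, log_transform=log, equal_var=equal_var)
            if col == "tumor_size":
                desc_a = f"{xa.median():.2f} ({xa.quantile(.75) - xa.quantile(.25):.2f})"
                desc_b = f"{xb.median():.2f} ({xb.quantile(.75) - xb.quantile(.25):.2f})"
            else:
                desc_a = f"{xa.mean():.1f} ({xa.std():.1f})"
                desc_b = f"{xb.mean():.1f} ({xb.std():.1f})"
            rows.append({
                "variable": col, "type": "continuous",
                levels[0]: desc_a, levels[1]: desc_b, "p_value": p,
            })
        else:
            sub = records[~records[col].astype(str).str.lower().eq("unknown")]
            table = pd.crosstab(sub[split], sub[col])
            table = table.reindex(index=levels)
            if table.shape[1] < 2:
                continue
            _, _, p = pearson_chi_square(table.to_numpy())
            desc = {
                lev: "; ".join(
                    f"{c}: {table.loc[lev, c]} ({100 * table.loc[lev, c] / table.loc[lev].sum():.1f}%)"
                    for c in table.columns
                )
                for lev in levels
            }
            rows.append({
                "variable": col, "type": "categorical",
                levels[0]: desc[levels[0]], levels[1]: desc[levels[1]], "p_value": p,
            })
    return pd.DataFrame(rows)
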