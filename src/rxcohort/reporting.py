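"""Descriptive summaries and significance tests for the study tables.

Cross-subgroup comparisons use the Pearson chi-square test (no continuity
correction) for categorical rows and one-way ANOVA for numeric rows, the two
tests conventionally reported for baseline tables in drug-utilization
studies.  Percentages are rendered to one decimal (half-up), p-values below
0.01 as "<0.01"; raw values stay in the machine-readable output.
"""

from __future__ import annotations

import logging
import warnings
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "median_iqr",
    "chi_square_independence",
    "one_way_anova",
    "round_half_up",
    "format_p",
    "render_report",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as printed tables use."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def median_iqr(values) -> tuple[float, tuple[float, float]]:
    """Median and [q1, q3] with linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty collection")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), (float(q1), float(q3))


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction; degrees of freedom (r-1)(c-1).  A zero row or
    column margin makes expected counts degenerate and is an error.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    row_margins = arr.sum(axis=1)
    col_margins = arr.sum(axis=0)
    if (row_margins == 0).any():
        raise ValueError(f"zero row margin at index {int(np.argmin(row_margins))}")
    if (col_margins == 0).any():
        raise ValueError(f"zero column margin at index {int(np.argmin(col_margins))}")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def one_way_anova(groups) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA F test across groups of numeric values.

    Returns (F, (df_between, df_within), p).  When every value is identical
    the decomposition is 0/0; by convention F = 0 with p = 1 and a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs at least one value")
    n_total = sum(g.size for g in groups)
    df_between, df_within = len(groups) - 1, n_total - len(groups)
    if df_within < 1:
        raise ValueError("need at least one group with two or more values")
    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0:
        logger.warning("all values identical; F = 0 by convention")
        return 0.0, (df_between, df_within), 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):
        logger.warning("degenerate ANOVA decomposition; F = 0 by convention")
        return 0.0, (df_between, df_within), 1.0
    return float(f), (df_between, df_within), float(p)


def format_p(p: float, floor: float = 0.01) -> str:
    """Render a p-value the way baseline tables print it."""
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.2f}"


def render_report(results, out_dir) -> dict[str, Path]:
    """Write the study's tables as delimited text files.

    ``results`` is a fitted :class:`rxcohort.study.StudyResults`.  Emits the
    index-drug distribution, the subgroup characteristics table with tests,
    the ATC level-1 usage table, the comorbidity prevalence table, the
    intensification summary and the adherence table, plus a plain-text
    summary.  Returns the mapping of table name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    tables = {
        "index_drug_distribution": results.index_drug_distribution,
        "subgroup_characteristics": results.subgroup_table,
        "atcl1_usage": results.atcl1_usage,
        "comorbidity_prevalence": results.comorbidity_prevalence,
        "intensification": results.intensification,
        "adherence": results.adherence,
    }
    for name, df in tables.items():
        if df is None or len(df) == 0:
            logger.warning("table %s is empty; skipped", name)
            continue
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=isinstance(df.index, pd.Index) and df.index.name is not None)
        written[name] = path

    summary_path = out_dir / "summary.txt"
    summary_path.write_text(results.summary())
    written["summary"] = summary_path
    return written
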