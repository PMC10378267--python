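"""Dataset-level statistics: contingency tables, class summaries, unpaired
t-tests and scatter exports.

The group comparisons use the pooled-variance Student t-test with two-tailed
p-values (the convention of the graphing packages this field reports with);
Welch's variant is available by flag.  No multiple-testing correction is
applied — comparisons are reported as raw two-tailed p-values.  Sample SDs
use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import LOCATION_LABELS, MORPHOLOGY_LABELS

__all__ = ["ContingencyTable", "contingency", "class_summary", "unpaired_t",
           "scatter_export", "TTestResult"]


@dataclass
class ContingencyTable:
    """Morphology x location counts, plus per-morphology swollen counts.

    Totals are computed on demand, never stored, so they cannot drift out
    of sync with the cells.
    """

    counts: pd.DataFrame            # index=morphology, columns=location
    swollen: pd.Series              # per morphology

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.row_totals
        out["Swollen"] = self.swollen
        out.loc["Total"] = list(self.col_totals) + [self.grand_total,
                                                    int(self.swollen.sum())]
        return out


def contingency(records: pd.DataFrame) -> ContingencyTable:
    """Cross-tabulate records by (morphology, location).

    Every record must carry a valid morphology and location label; a
    ``swollen`` boolean column is optional (defaults to False).
    """
    for col in ("morphology", "location"):
        if col not in records.columns:
            raise ValueError(f"records lack a {col!r} column")
    bad = ~records["morphology"].isin(MORPHOLOGY_LABELS)
    bad |= ~records["location"].isin(LOCATION_LABELS)
    if bad.any():
        raise ValueError(
            f"unclassified records: {records.loc[bad, 'id'].tolist() if 'id' in records else int(bad.sum())}")
    counts = pd.crosstab(records["morphology"], records["location"])
    counts = counts.reindex(index=list(MORPHOLOGY_LABELS),
                            columns=list(LOCATION_LABELS), fill_value=0)
    counts.index.name = "morphology"
    counts.columns.name = "location"
    if "swollen" in records.columns:
        swollen = records.groupby("morphology")["swollen"].sum()
        swollen = swollen.reindex(list(MORPHOLOGY_LABELS), fill_value=0).astype(int)
    else:
        swollen = pd.Series(0, index=list(MORPHOLOGY_LABELS))
    return ContingencyTable(counts.astype(int), swollen)


def class_summary(records: pd.DataFrame, metric: str,
                  by: str = "morphology") -> pd.DataFrame:
    """Per-class sample mean, sample SD (n-1) and n for one metric.

    Classes with a single observation report SD as NaN (undefined); empty
    classes are omitted.
    """
    if metric not in records.columns:
        raise ValueError(f"unknown metric {metric!r}; available: "
                         f"{sorted(records.columns)}")
    rows = []
    for cls, grp in records.groupby(by, sort=False):
        vals = grp[metric].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        rows.append({
            by: cls, "n": len(vals), "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
        })
    return pd.DataFrame(rows, columns=[by, "n", "mean", "sd"])


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float
    variant: str


def unpaired_t(group_a, group_b, variant: str = "pooled") -> TTestResult:
    """Unpaired two-sample t-test, two-tailed.

    ``pooled`` is the classic Student test (equal variances assumed);
    ``welch`` uses the Welch-Satterthwaite degrees of freedom.  Both groups
    need n >= 2.  If both groups are constant: equal means give the p = 1
    convention; different means are degenerate (t infinite, p = 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            df = len(a) + len(b) - 2
            return TTestResult(0.0, float(df), 1.0, variant)
        return TTestResult(float(np.sign(a.mean() - b.mean()) * np.inf),
                           float(len(a) + len(b) - 2), 0.0, variant)
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = res.df if hasattr(res, "df") else (
        len(a) + len(b) - 2 if variant == "pooled" else np.nan)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue),
                       variant)


def scatter_export(records: pd.DataFrame, x_metric: str, y_metric: str,
                   grouping: str | None = None) -> pd.DataFrame:
    """Long-format (id, class, location, x, y) table for plotting; no
    aggregation."""
    for m in (x_metric, y_metric):
        if m not in records.columns:
            raise ValueError(f"unknown metric {m!r}; available: "
                             f"{sorted(records.columns)}")
    out = pd.DataFrame({
        "id": records["id"] if "id" in records.columns
        else np.arange(len(records)),
        "x": records[x_metric].to_numpy(dtype=float),
        "y": records[y_metric].to_numpy(dtype=float),
    })
    out["x_metric"], out["y_metric"] = x_metric, y_metric
    if grouping is not None:
        if grouping not in records.columns:
            raise ValueError(f"unknown grouping column {grouping!r}")
        out["class"] = records[grouping].to_numpy()
    if "location" in records.columns:
        out["location"] = records["location"].to_numpy()
    return out
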