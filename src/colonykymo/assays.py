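"""Reporter and killing-assay arithmetic: RLU, fold changes, Student t tests.

RLU (relative light units) is bioluminescence divided by culture OD600.
Group comparisons use the classical equal-variance two-sample Student t test
(switchable to Welch), with the significance annotation convention
``**`` for P < 0.005 and ``***`` for P < 0.0005.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rlu",
    "fold_change",
    "two_tailed_t",
    "significance_stars",
    "add_rlu_column",
    "analyze_reporter_table",
]


def rlu(luminescence, od600):
    """Relative light units: luminescence / OD600 (vectorized)."""
    lum = np.asarray(luminescence, dtype=float)
    od = np.asarray(od600, dtype=float)
    if np.any(od <= 0):
        raise ValueError("od600 must be positive")
    if np.any(lum < 0):
        raise ValueError("luminescence must be non-negative")
    out = lum / od
    return float(out) if out.ndim == 0 else out


def fold_change(group_a, group_b, estimator: str = "mean") -> float:
    """Fold difference of group A over group B (ratio of means by default,
    ratio of medians with ``estimator="median"``)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if estimator == "mean":
        num, den = a.mean(), b.mean()
    elif estimator == "median":
        num, den = float(np.median(a)), float(np.median(b))
    else:
        raise ValueError("estimator must be 'mean' or 'median'")
    if num <= 0 or den <= 0:
        raise ValueError("fold change requires positive group means")
    return float(num / den)


def two_tailed_t(group_a, group_b, equal_var: bool = True
                 ) -> tuple[float, float]:
    """Two-sample Student t test (equal variance) with a two-tailed p value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    """Annotation convention: ``***`` P < 0.0005, ``**`` P < 0.005, else ns."""
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    return "ns"


def add_rlu_column(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a (strain, replicate, luminescence, od600) table
    with an ``rlu`` column appended."""
    required = {"strain", "replicate", "luminescence", "od600"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    out = table.copy()
    out["rlu"] = rlu(out["luminescence"].to_numpy(),
                     out["od600"].to_numpy())
    return out


def analyze_reporter_table(table: pd.DataFrame,
                           reference_strain: str | None = None
                           ) -> pd.DataFrame:
    """Per-strain RLU summary with fold change and t test vs a reference.

    The reference defaults to the first strain in the table. Returns one row
    per strain: n, mean RLU, SD, fold change of the reference over the
    strain (so attenuated strains show fold > 1), t statistic, two-tailed p,
    and the star annotation.
    """
    table = add_rlu_column(table)
    strains = list(dict.fromkeys(table["strain"]))
    if reference_strain is None:
        reference_strain = strains[0]
    if reference_strain not in strains:
        raise ValueError(f"reference strain {reference_strain!r} not in table")
    ref = table.loc[table["strain"] == reference_strain, "rlu"].to_numpy()
    rows = []
    for strain in strains:
        vals = table.loc[table["strain"] == strain, "rlu"].to_numpy()
        row = {
            "strain": strain,
            "n": len(vals),
            "rlu_mean": vals.mean(),
            "rlu_sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
        }
        if strain == reference_strain:
            row.update(fold_vs_reference=1.0, t=0.0, p=1.0, stars="ns")
        else:
            t, p = two_tailed_t(ref, vals)
            row.update(fold_vs_reference=fold_change(ref, vals),
                       t=t, p=p, stars=significance_stars(p))
        rows.append(row)
    return pd.DataFrame(rows)
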