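"""Age-trend quantification: grouped mean ± SD and Welch's t-test."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def trend(
    table: pd.DataFrame,
    feature: str,
    strain_col: str = "strain",
    day_col: str = "day",
    tissue_col: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(strain, day) mean/SD of ``feature`` plus per-day Welch tests.

    Returns ``(summary, tests)``.  Groups with fewer than two members get
    a flagged NaN SD and are skipped in the tests.  The t-test compares
    each strain pair at every shared day assuming unequal variances.
    """
    required = {strain_col, day_col, feature}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    group_cols = [strain_col, day_col] + ([tissue_col] if tissue_col else [])
    rows = []
    for key, grp in table.groupby(group_cols):
        vals = grp[feature].to_numpy(dtype=float)
        rows.append(
            dict(zip(group_cols, key))
            | {
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "flagged": len(vals) < 2,
            }
        )
    summary = pd.DataFrame(rows)

    tests = []
    strains = sorted(table[strain_col].unique())
    for day in sorted(table[day_col].unique()):
        sub = table[table[day_col] == day]
        for i in range(len(strains)):
            for j in range(i + 1, len(strains)):
                a = sub.loc[sub[strain_col] == strains[i], feature].to_numpy(dtype=float)
                b = sub.loc[sub[strain_col] == strains[j], feature].to_numpy(dtype=float)
                if len(a) < 2 or len(b) < 2:
                    continue
                t, p = stats.ttest_ind(a, b, equal_var=False)
                tests.append(
                    {
                        day_col: day,
                        "strain_a": strains[i],
                        "strain_b": strains[j],
                        "t": float(t),
                        "p": float(p) if np.isfinite(p) else 1.0,
                    }
                )
    return summary, pd.DataFrame(tests)


def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t statistic and two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
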