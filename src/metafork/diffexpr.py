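"""Per-feature two-group differential abundance/expression tests.

Welch's unequal-variance t-test (two-sided, Welch–Satterthwaite df) on
log-transformed values for both omics. This is also what R's default
``t.test`` computes, so transcript FPKM tables analysed "the R way" land on
the same statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CONTROL, TREATMENT, OmicsMatrix, SampleDesign

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    p_value: float
    degenerate: bool = False


def welch_test(x, y) -> WelchResult:
    """Welch two-sample t-test of x (control) vs y (treatment).

    Degenerate cases: both groups constant with equal means -> t=0, p=1;
    constant groups with unequal means -> flagged, p=0 (infinitely
    significant under the model, but unusable as evidence).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vx == 0 and vy == 0:
        if float(x.mean()) == float(y.mean()):
            return WelchResult(0.0, float(x.size + y.size - 2), 1.0)
        t = math.copysign(math.inf, x.mean() - y.mean())
        return WelchResult(t, float(x.size + y.size - 2), 0.0, degenerate=True)
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def de_table(m: OmicsMatrix, d: SampleDesign, alpha: float = 0.05) -> pd.DataFrame:
    """One Welch test per feature; direction is treatment-relative-to-control.

    A feature is "up" when significantly higher under treatment at ``alpha``,
    "down" when lower, otherwise "unchanged". Samples a feature was not
    measured in (NaN) are dropped per feature.
    """
    if not m.log_scale:
        raise ValueError("differential testing expects log-transformed values")
    control = [s for s in d.samples_for(CONTROL) if s in m.values.columns]
    treatment = [s for s in d.samples_for(TREATMENT) if s in m.values.columns]
    rows = []
    for feature in m.feature_ids:
        x = m.values.loc[feature, control].dropna().to_numpy(dtype=float)
        y = m.values.loc[feature, treatment].dropna().to_numpy(dtype=float)
        res = welch_test(x, y)
        mean_c = float(x.mean())
        mean_t = float(y.mean())
        if res.p_value < alpha and not res.degenerate:
            direction = UP if mean_t > mean_c else DOWN
        else:
            direction = UNCHANGED
        rows.append(
            {
                "feature_id": feature,
                "omic_type": m.omic_type(feature),
                "mean_control": mean_c,
                "mean_treatment": mean_t,
                "t_stat": res.t_stat,
                "df": res.df,
                "p_value": res.p_value,
                "direction": direction,
                "degenerate": res.degenerate,
            }
        )
    columns = [
        "feature_id", "omic_type", "mean_control", "mean_treatment",
        "t_stat", "df", "p_value", "direction", "degenerate",
    ]
    return pd.DataFrame(rows, columns=columns)
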