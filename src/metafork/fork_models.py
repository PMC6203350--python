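"""Condition-interaction linear models that validate screened triplets.

For a candidate triplet the screen only suggests that the coupling between
A and the log-ratio B/C differs between conditions. Validation fits, by
ordinary least squares, the two-group interaction model

    y = b0 + b1 * x + b2 * g + b3 * (x * g) + e,     g = 0 control, 1 treatment

in both directions (y = A, x = log B/C, and the reverse), and requires the
interaction coefficient b3 — the treatment-minus-control slope difference —
to be significant (two-sided t-test on n − 4 residual df, strictly below
alpha) in *both* directions. The dual rule hedges the ambiguity of which
member of the triplet is response and which is predictor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .fork_screen import ScreenedTriplet, TripletSpec, ratio_series, triplet_samples
from .io_formats import CONTROL, OmicsMatrix, SampleDesign

logger = logging.getLogger("metafork.models")

FORWARD = "A_on_ratio"
REVERSE = "ratio_on_A"

#: relative sum-of-squares below which a fit counts as zero-residual
_ZERO_RESIDUAL_RTOL = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    alpha: float = 0.05
    fdr_adjust: bool = False
    #: zero-residual (noiseless) fits report p=0 but do not count as forks
    #: unless explicitly enabled — real data never produces them.
    zero_residual_is_fork: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly between 0 and 1")


@dataclass(frozen=True)
class InteractionFit:
    """One direction's OLS fit of the design [1, x, g, x*g]."""

    direction: str
    intercept: float
    slope_control: float
    condition_offset: float
    interaction_coefficient: float  # slope difference, treatment - control
    interaction_se: float
    interaction_t: float
    interaction_p: float
    df_residual: int
    n_used: int
    zero_residual: bool = False
    degenerate: bool = False
    reason: str | None = None


def fit_interaction(
    y: Sequence[float],
    x: Sequence[float],
    condition: Sequence[int],
    direction: str = FORWARD,
) -> InteractionFit:
    """OLS fit of y on [1, x, g, x*g]; two-sided t-test on the x*g term.

    ``condition`` codes control as 0 and treatment as 1. Rank-deficient
    designs (e.g. x constant within a group) yield a degenerate fit rather
    than an exception; a numerically perfect fit is flagged zero_residual
    and reported with p = 0.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(condition, dtype=float)
    if not (y.shape == x.shape == g.shape) or y.ndim != 1:
        raise ValueError("y, x and condition must be 1-d and equal length")
    if not set(np.unique(g)) <= {0.0, 1.0}:
        raise ValueError("condition must be coded 0 (control) / 1 (treatment)")
    n = y.size
    if n - 4 <= 0:
        raise ValueError(f"n={n} leaves no residual degrees of freedom (need n > 4)")
    for level, label in ((0.0, "control"), (1.0, "treatment")):
        if int((g == level).sum()) < 3:
            raise ValueError(f"{label} group has fewer than 3 points")

    X = np.column_stack([np.ones(n), x, g, x * g])
    if np.linalg.matrix_rank(X) < 4:
        return InteractionFit(
            direction=direction,
            intercept=math.nan, slope_control=math.nan, condition_offset=math.nan,
            interaction_coefficient=math.nan, interaction_se=math.nan,
            interaction_t=math.nan, interaction_p=math.nan,
            df_residual=n - 4, n_used=n,
            degenerate=True, reason="rank_deficient",
        )

    res = sm.OLS(y, X).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    if res.ssr <= _ZERO_RESIDUAL_RTOL * max(tss, 1.0):
        coef = float(res.params[3])
        return InteractionFit(
            direction=direction,
            intercept=float(res.params[0]),
            slope_control=float(res.params[1]),
            condition_offset=float(res.params[2]),
            interaction_coefficient=coef,
            interaction_se=0.0,
            interaction_t=math.copysign(math.inf, coef) if coef != 0 else 0.0,
            interaction_p=0.0 if coef != 0 else 1.0,
            df_residual=n - 4, n_used=n,
            zero_residual=True, reason="zero_residual",
        )
    return InteractionFit(
        direction=direction,
        intercept=float(res.params[0]),
        slope_control=float(res.params[1]),
        condition_offset=float(res.params[2]),
        interaction_coefficient=float(res.params[3]),
        interaction_se=float(res.bse[3]),
        interaction_t=float(res.tvalues[3]),
        interaction_p=float(res.pvalues[3]),
        df_residual=int(res.df_resid),
        n_used=n,
    )


@dataclass(frozen=True)
class ForkModelResult:
    triplet: TripletSpec
    fit_forward: InteractionFit
    fit_reverse: InteractionFit
    alpha: float
    is_fork: bool
    reason: str | None = None


def _dual_rule(
    fit_forward: InteractionFit, fit_reverse: InteractionFit, cfg: ModelConfig
) -> tuple[bool, str | None]:
    """Both directions must have interaction p strictly below alpha."""
    for fit in (fit_forward, fit_reverse):
        if fit.degenerate:
            return False, f"{fit.direction}: degenerate ({fit.reason})"
        if fit.zero_residual and not cfg.zero_residual_is_fork:
            return False, f"{fit.direction}: zero_residual"
    ok = fit_forward.interaction_p < cfg.alpha and fit_reverse.interaction_p < cfg.alpha
    return ok, None


def evaluate_fork(
    t: ScreenedTriplet,
    m: OmicsMatrix,
    d: SampleDesign,
    cfg: ModelConfig | None = None,
) -> ForkModelResult:
    """Fit both directional interaction models for one screened candidate.

    Uses exactly the samples the screen used (per-condition non-missing
    intersection, design order).
    """
    cfg = cfg or ModelConfig()
    if not t.passed:
        raise ValueError(f"{t.triplet} did not pass screening")
    if not m.log_scale:
        raise ValueError("model fitting requires a log-transformed matrix")
    control, treatment = triplet_samples(m, d, t.triplet)
    samples = control + treatment
    a_vals = m.values.loc[t.triplet.a, samples].to_numpy(dtype=float)
    ratio = ratio_series(m, t.triplet.b, t.triplet.c, samples)
    g = np.array([0] * len(control) + [1] * len(treatment))
    fwd = fit_interaction(a_vals, ratio, g, direction=FORWARD)
    rev = fit_interaction(ratio, a_vals, g, direction=REVERSE)
    is_fork, reason = _dual_rule(fwd, rev, cfg)
    return ForkModelResult(
        triplet=t.triplet, fit_forward=fwd, fit_reverse=rev,
        alpha=cfg.alpha, is_fork=is_fork, reason=reason,
    )


def batch_evaluate(
    candidates: Iterable[ScreenedTriplet],
    m: OmicsMatrix,
    d: SampleDesign,
    cfg: ModelConfig | None = None,
) -> list[ForkModelResult]:
    """Evaluate all screened candidates in deterministic triplet order."""
    cfg = cfg or ModelConfig()
    ordered = sorted(candidates, key=lambda s: s.triplet)
    results = [evaluate_fork(s, m, d, cfg) for s in ordered]
    logger.info(
        "model funnel: %d candidates -> %d validated forks",
        len(results), sum(r.is_fork for r in results),
    )
    return results


def results_to_frame(
    results: Sequence[ForkModelResult], fdr_adjust: bool = False
) -> pd.DataFrame:
    """Flatten fork results into a table; optional BH-adjusted q columns."""
    rows = []
    for r in results:
        row: dict = {"a": r.triplet.a, "b": r.triplet.b, "c": r.triplet.c}
        for tag, fit in (("forward", r.fit_forward), ("reverse", r.fit_reverse)):
            row.update(
                {
                    f"{tag}_intercept": fit.intercept,
                    f"{tag}_slope_control": fit.slope_control,
                    f"{tag}_condition_offset": fit.condition_offset,
                    f"{tag}_interaction_coef": fit.interaction_coefficient,
                    f"{tag}_interaction_se": fit.interaction_se,
                    f"{tag}_interaction_t": fit.interaction_t,
                    f"{tag}_interaction_p": fit.interaction_p,
                    f"{tag}_df_residual": fit.df_residual,
                    f"{tag}_zero_residual": fit.zero_residual,
                    f"{tag}_degenerate": fit.degenerate,
                }
            )
        row["n_used"] = r.fit_forward.n_used
        row["alpha"] = r.alpha
        row["is_fork"] = r.is_fork
        row["reason"] = r.reason or ""
        rows.append(row)
    df = pd.DataFrame(rows)
    if fdr_adjust and len(df):
        for tag in ("forward", "reverse"):
            p = df[f"{tag}_interaction_p"].to_numpy(dtype=float)
            finite = np.isfinite(p)
            q = np.full_like(p, np.nan)
            if finite.any():
                q[finite] = multipletests(p[finite], method="fdr_bh")[1]
            df[f"{tag}_interaction_q"] = q
    return df
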