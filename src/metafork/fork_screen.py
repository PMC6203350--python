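"""Differential-correlation screen for candidate metabolic forks.

A candidate triplet is a focal feature A paired with an unordered ratio pair
{B, C}. On log-transformed data the ratio B/C is the difference
log B − log C, so swapping B and C only flips the sign of the ratio series;
one orientation per pair is enumerated. A triplet passes the screen when the
Pearson correlation of A with the log-ratio differs between conditions by at
least ``delta_threshold`` in absolute value:

    |cor_treatment(A, log B/C) − cor_control(A, log B/C)| >= delta

The screen is deliberately ad hoc — it only proposes candidates for the
interaction linear models that provide the actual inferential control.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .io_formats import CONTROL, TREATMENT, OmicsMatrix, SampleDesign

logger = logging.getLogger("metafork.screen")


class ZeroVarianceError(ValueError):
    """A correlation input has no variance; the correlation is undefined."""


class TripletSkipped(Exception):
    """Raised when a triplet cannot be screened (too few samples, no variance)."""

    def __init__(self, triplet: "TripletSpec", reason: str):
        super().__init__(f"{triplet}: {reason}")
        self.triplet = triplet
        self.reason = reason


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation, clipped to [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


@dataclass(frozen=True, order=True)
class TripletSpec:
    """Focal feature ``a`` and ratio pair ``b``/``c`` (numerator/denominator)."""

    a: str
    b: str
    c: str

    def __post_init__(self) -> None:
        if len({self.a, self.b, self.c}) != 3:
            raise ValueError(f"triplet members must be pairwise distinct: {self}")

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.a, self.b, self.c)

    def swapped(self) -> "TripletSpec":
        return TripletSpec(self.a, self.c, self.b)

    def __str__(self) -> str:
        return f"{self.a}~{self.b}/{self.c}"


@dataclass(frozen=True)
class ScreenConfig:
    delta_threshold: float = 1.2
    min_samples_per_condition: int = 3
    allow_cross_omic: bool = True

    def __post_init__(self) -> None:
        # delta itself lives in [0, 2]; a threshold above 2 is allowed and
        # simply screens out everything
        if self.delta_threshold < 0:
            raise ValueError("delta_threshold must be non-negative")
        if self.min_samples_per_condition < 3:
            raise ValueError("min_samples_per_condition must be >= 3")


@dataclass(frozen=True)
class ScreenedTriplet:
    triplet: TripletSpec
    cor_control: float
    cor_treatment: float
    delta: float
    n_control: int
    n_treatment: int
    passed: bool


def enumerate_triplets(
    features: Sequence[str], cfg: ScreenConfig | None = None
) -> Iterator[TripletSpec]:
    """Yield every (A, {B, C}) triplet in deterministic lexicographic order.

    One orientation per unordered ratio pair (B < C); for m features the
    count is m * (m-1) * (m-2) / 2.
    """
    feats = sorted(set(features))
    if len(feats) < 3:
        raise ValueError("need at least 3 features to enumerate triplets")
    for a in feats:
        others = [f for f in feats if f != a]
        for b, c in itertools.combinations(others, 2):
            yield TripletSpec(a, b, c)


def triplet_samples(
    m: OmicsMatrix, d: SampleDesign, t: TripletSpec
) -> tuple[list[str], list[str]]:
    """Samples usable for a triplet, split by condition, in design order.

    A sample is usable when all three members have a value there — for
    cross-omic triplets this is the intersection of the samples measured in
    both omics.
    """
    cols = [s for s in d.sample_ids if s in m.values.columns]
    sub = m.values.loc[list(t.members), cols]
    ok = sub.notna().all(axis=0)
    usable = [s for s in cols if ok[s]]
    cond = d.condition_of
    return (
        [s for s in usable if cond[s] == CONTROL],
        [s for s in usable if cond[s] == TREATMENT],
    )


def ratio_series(m: OmicsMatrix, b: str, c: str, samples: Sequence[str]) -> np.ndarray:
    """log(B/C) per sample, i.e. log B − log C on a log-scale matrix."""
    return (
        m.values.loc[b, list(samples)].to_numpy(dtype=float)
        - m.values.loc[c, list(samples)].to_numpy(dtype=float)
    )


def screen_triplet(
    t: TripletSpec, m: OmicsMatrix, d: SampleDesign, cfg: ScreenConfig | None = None
) -> ScreenedTriplet:
    """Screen one triplet; raises TripletSkipped when undefined."""
    cfg = cfg or ScreenConfig()
    if not m.log_scale:
        raise ValueError("screening requires a log-transformed matrix")
    control, treatment = triplet_samples(m, d, t)
    if len(control) < cfg.min_samples_per_condition or len(treatment) < cfg.min_samples_per_condition:
        raise TripletSkipped(
            t, f"insufficient samples (control={len(control)}, treatment={len(treatment)})"
        )
    cors = {}
    for label, samples in ((CONTROL, control), (TREATMENT, treatment)):
        a_vals = m.values.loc[t.a, samples].to_numpy(dtype=float)
        ratio = ratio_series(m, t.b, t.c, samples)
        try:
            cors[label] = pearson(a_vals, ratio)
        except ZeroVarianceError:
            raise TripletSkipped(t, f"zero variance in {label} condition") from None
    delta = abs(cors[TREATMENT] - cors[CONTROL])
    return ScreenedTriplet(
        triplet=t,
        cor_control=cors[CONTROL],
        cor_treatment=cors[TREATMENT],
        delta=delta,
        n_control=len(control),
        n_treatment=len(treatment),
        passed=delta >= cfg.delta_threshold,
    )


def screen_all(
    m: OmicsMatrix, d: SampleDesign, cfg: ScreenConfig | None = None
) -> tuple[list[ScreenedTriplet], int]:
    """Screen every enumerable triplet; returns (results, n_skipped).

    Cross-omic triplets (members from both omics) are skipped when
    ``allow_cross_omic`` is false. Skips are logged with their reason.
    """
    cfg = cfg or ScreenConfig()
    if not m.log_scale:
        raise ValueError("screening requires a log-transformed matrix")
    results: list[ScreenedTriplet] = []
    n_skipped = 0
    omic = m.feature_meta["omic_type"].to_dict()

    # flat numpy views, columns in design order, for the hot loop
    cols = [s for s in d.sample_ids if s in m.values.columns]
    vals = m.values[cols].to_numpy(dtype=float)
    notna = ~np.isnan(vals)
    row = {f: i for i, f in enumerate(m.feature_ids)}
    cond = d.condition_of
    is_control = np.array([cond[s] == CONTROL for s in cols])
    min_n = cfg.min_samples_per_condition

    for t in enumerate_triplets(m.feature_ids, cfg):
        if not cfg.allow_cross_omic and len({omic[f] for f in t.members}) > 1:
            n_skipped += 1
            continue
        ia, ib, ic = row[t.a], row[t.b], row[t.c]
        ok = notna[ia] & notna[ib] & notna[ic]
        masks = (ok & is_control, ok & ~is_control)
        ns = (int(masks[0].sum()), int(masks[1].sum()))
        if ns[0] < min_n or ns[1] < min_n:
            logger.debug("skipped %s: insufficient samples %s", t, ns)
            n_skipped += 1
            continue
        cors = []
        for mask in masks:
            a_vals = vals[ia, mask]
            ratio = vals[ib, mask] - vals[ic, mask]
            try:
                cors.append(pearson(a_vals, ratio))
            except ZeroVarianceError:
                break
        if len(cors) < 2:
            logger.debug("skipped %s: zero variance", t)
            n_skipped += 1
            continue
        delta = abs(cors[1] - cors[0])
        results.append(
            ScreenedTriplet(
                triplet=t,
                cor_control=cors[0],
                cor_treatment=cors[1],
                delta=delta,
                n_control=ns[0],
                n_treatment=ns[1],
                passed=delta >= cfg.delta_threshold,
            )
        )
    return results, n_skipped


def screened_to_frame(results: Iterable[ScreenedTriplet]) -> pd.DataFrame:
    rows = [
        {
            "a": r.triplet.a,
            "b": r.triplet.b,
            "c": r.triplet.c,
            "cor_control": r.cor_control,
            "cor_treatment": r.cor_treatment,
            "delta": r.delta,
            "n_control": r.n_control,
            "n_treatment": r.n_treatment,
            "passed": r.passed,
        }
        for r in results
    ]
    columns = [
        "a", "b", "c", "cor_control", "cor_treatment", "delta",
        "n_control", "n_treatment", "passed",
    ]
    return pd.DataFrame(rows, columns=columns)
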