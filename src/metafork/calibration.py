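"""Replicate studies: type-I error, screening null rate, recovery and power.

These run the real pipeline primitives (generator -> impute -> log ->
screen_triplet -> fit_interaction) over many seeded replicates. They back
both the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fork_models import FORWARD, REVERSE, ModelConfig, evaluate_fork, fit_interaction
from .fork_screen import ScreenConfig, screen_triplet
from .io_formats import OmicsMatrix, SampleDesign
from .preprocess import PreprocessConfig, impute_min, log_transform
from .synthetic_data import (
    GeneratorConfig,
    PlantedFork,
    derive_seeds,
    generate,
)


def _prepared(cfg: GeneratorConfig) -> tuple[OmicsMatrix, SampleDesign, object]:
    metabolites, transcripts, design, truth = generate(cfg)
    m = log_transform(impute_min(metabolites), PreprocessConfig(keep_all=True))
    if len(transcripts.feature_ids):
        t = log_transform(transcripts, PreprocessConfig(keep_all=True))
        m = OmicsMatrix.concat([m, t])
    return m, design, truth


@dataclass(frozen=True)
class TypeIStudy:
    replicates: int
    rate_forward: float
    rate_reverse: float
    rate_dual: float
    screen_pass_rate: float


def type_i_study(
    replicates: int,
    seed: int,
    slope: float = 1.0,
    noise_sd: float = 0.5,
    alpha: float = 0.05,
    delta_threshold: float = 1.2,
    n_control: int = 12,
    n_treatment: int = 11,
) -> TypeIStudy:
    """Null-triplet calibration: equal slopes in both conditions.

    Per replicate the planted triplet is fit in both directions (rejection
    counted at ``alpha``) and screened at ``delta_threshold``. Under the
    Gaussian null each direction's rejection rate should sit at alpha and
    the screen's pass rate should be a rare-tail event.
    """
    base = GeneratorConfig(
        n_control=n_control,
        n_treatment=n_treatment,
        n_null_features=0,
        n_null_transcripts=0,
        planted_forks=(PlantedFork(slope, slope, noise_sd),),
        missing_rate=0.0,
        seed=seed,
    )
    screen_cfg = ScreenConfig(delta_threshold=delta_threshold)
    rej_f = rej_r = rej_dual = screened = 0
    for child in derive_seeds(seed, replicates):
        m, design, truth = _prepared(replace(base, seed=child))
        t = truth.planted[0].triplet
        st = screen_triplet(t, m, design, screen_cfg)
        screened += st.passed
        samples = list(design.sample_ids)
        a = m.values.loc[t.a, samples].to_numpy(dtype=float)
        ratio = (
            m.values.loc[t.b, samples].to_numpy(dtype=float)
            - m.values.loc[t.c, samples].to_numpy(dtype=float)
        )
        g = np.array([0 if c == "control" else 1 for c in design.conditions])
        fwd = fit_interaction(a, ratio, g, FORWARD)
        rev = fit_interaction(ratio, a, g, REVERSE)
        f_sig = fwd.interaction_p < alpha
        r_sig = rev.interaction_p < alpha
        rej_f += f_sig
        rej_r += r_sig
        rej_dual += f_sig and r_sig
    return TypeIStudy(
        replicates=replicates,
        rate_forward=rej_f / replicates,
        rate_reverse=rej_r / replicates,
        rate_dual=rej_dual / replicates,
        screen_pass_rate=screened / replicates,
    )


@dataclass(frozen=True)
class RecoveryStudy:
    replicates: int
    screen_rate: float
    recovery_rate: float  # screened AND validated by the dual rule


def recovery_study(
    replicates: int,
    seed: int,
    slope_control: float = 1.0,
    slope_treatment: float = -1.0,
    noise_sd: float = 0.1,
    generator: GeneratorConfig | None = None,
    screen_cfg: ScreenConfig | None = None,
    model_cfg: ModelConfig | None = None,
) -> RecoveryStudy:
    """How often the planted fork survives screen + dual-model validation."""
    base = generator or GeneratorConfig()
    base = replace(
        base, planted_forks=(PlantedFork(slope_control, slope_treatment, noise_sd),)
    )
    screen_cfg = screen_cfg or ScreenConfig()
    model_cfg = model_cfg or ModelConfig()
    screened = recovered = 0
    for child in derive_seeds(seed, replicates):
        m, design, truth = _prepared(replace(base, seed=child))
        t = truth.planted[0].triplet
        st = screen_triplet(t, m, design, screen_cfg)
        if not st.passed:
            continue
        screened += 1
        res = evaluate_fork(st, m, design, model_cfg)
        recovered += res.is_fork
    return RecoveryStudy(
        replicates=replicates,
        screen_rate=screened / replicates,
        recovery_rate=recovered / replicates,
    )


def power_curve(
    slope_differences: list[float],
    replicates: int,
    seed: int,
    noise_sd: float = 0.5,
    alpha: float = 0.05,
) -> dict[float, float]:
    """Dual-rule rejection rate vs slope difference (symmetric +-d/2 slopes).

    Power of the validation step itself, so no screening gate is applied.
    """
    out: dict[float, float] = {}
    cfg = ModelConfig(alpha=alpha)
    for k, d_slope in enumerate(slope_differences):
        base = GeneratorConfig(
            n_null_features=0,
            n_null_transcripts=0,
            planted_forks=(PlantedFork(d_slope / 2, -d_slope / 2, noise_sd),),
            missing_rate=0.0,
            seed=seed + k,
        )
        hits = 0
        for child in derive_seeds(seed + k, replicates):
            m, design, truth = _prepared(replace(base, seed=child))
            t = truth.planted[0].triplet
            samples = list(design.sample_ids)
            a = m.values.loc[t.a, samples].to_numpy(dtype=float)
            ratio = (
                m.values.loc[t.b, samples].to_numpy(dtype=float)
                - m.values.loc[t.c, samples].to_numpy(dtype=float)
            )
            g = np.array([0 if c == "control" else 1 for c in design.conditions])
            fwd = fit_interaction(a, ratio, g, FORWARD)
            rev = fit_interaction(ratio, a, g, REVERSE)
            hits += (fwd.interaction_p < alpha) and (rev.interaction_p < alpha)
        out[d_slope] = hits / replicates
    return out
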