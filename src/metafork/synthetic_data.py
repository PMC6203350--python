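"""Two-condition multi-omics simulator with planted forks and known truth.

The generator emulates the structure the pipeline assumes: log-normal
metabolite abundances over 12 control + 11 treatment samples, an FPKM-like
transcript table over a nested 8 + 8 subset of those samples, and planted
fork triplets in which the focal compound A tracks the log-ratio of B to C
with a condition-dependent slope:

    R_s ~ Normal(ratio_log_mean, log_sd)                  (log B/C, per sample)
    log A_s = base + slope_{cond(s)} * R_s + Normal(0, noise_sd)
    log C_s ~ Normal(base, log_sd),  log B_s = R_s + log C_s

Everything is exponentiated back to abundances, so the pipeline's own
imputation and log transform are exercised. Null features are independent
log-normals. Missing cells are masked in the metabolite table only
(non-detects), never removing all values of a feature.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .fork_screen import TripletSpec
from .io_formats import (
    CONTROL,
    METABOLITE,
    TRANSCRIPT,
    TREATMENT,
    OmicsMatrix,
    SampleDesign,
)


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedFork:
    """Ground-truth triplet: slope of log A on log(B/C) per condition."""

    slope_control: float = 1.0
    slope_treatment: float = -1.0
    noise_sd: float = 0.1
    #: plant B as a transcript (measured only on the transcriptome subset)
    cross_omic: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise GeneratorError("noise_sd must be > 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_control: int = 12
    n_treatment: int = 11
    n_transcriptome_per_group: int = 8  # nested subset of the metabolome samples
    n_null_features: int = 20
    n_null_transcripts: int = 10
    planted_forks: tuple[PlantedFork, ...] = (PlantedFork(),)
    base_abundance_log_mean: float = 10.0
    log_sd: float = 0.5
    ratio_log_mean: float = 0.0
    missing_rate: float = 0.02
    transcript_log_mean: float = 2.0
    transcript_log_sd: float = 1.0
    transcript_zero_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 3 or self.n_treatment < 3:
            raise GeneratorError("need >= 3 samples per condition")
        if not (3 <= self.n_transcriptome_per_group <= min(self.n_control, self.n_treatment)):
            raise GeneratorError(
                "transcriptome samples must be a nested subset (3 <= n <= group size)"
            )
        if not 0 <= self.missing_rate < 1:
            raise GeneratorError("missing_rate must lie in [0, 1)")
        if self.log_sd <= 0:
            raise GeneratorError("log_sd must be > 0")
        if self.n_null_features < 0 or self.n_null_transcripts < 0:
            raise GeneratorError("feature counts must be non-negative")


@dataclass(frozen=True)
class PlantedTriplet:
    triplet: TripletSpec
    slope_control: float
    slope_treatment: float
    noise_sd: float


@dataclass(frozen=True)
class SyntheticTruth:
    planted: tuple[PlantedTriplet, ...]
    null_features: tuple[str, ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [
                {
                    "a": p.triplet.a, "b": p.triplet.b, "c": p.triplet.c,
                    "slope_control": p.slope_control,
                    "slope_treatment": p.slope_treatment,
                    "noise_sd": p.noise_sd,
                }
                for p in self.planted
            ],
            "null_features": list(self.null_features),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        planted = tuple(
            PlantedTriplet(
                TripletSpec(p["a"], p["b"], p["c"]),
                p["slope_control"], p["slope_treatment"], p["noise_sd"],
            )
            for p in payload["planted"]
        )
        return cls(planted=planted, null_features=tuple(payload["null_features"]))


def generate(
    cfg: GeneratorConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, SampleDesign, SyntheticTruth]:
    """Draw one dataset: (metabolites, transcripts, design, truth).

    Fully reproducible from ``cfg.seed``; two calls with the same config are
    bit-identical.
    """
    rng = np.random.default_rng(cfg.seed)
    control = [f"C{i + 1:02d}" for i in range(cfg.n_control)]
    treatment = [f"H{i + 1:02d}" for i in range(cfg.n_treatment)]
    samples = control + treatment
    design = SampleDesign(
        tuple(samples),
        tuple([CONTROL] * cfg.n_control + [TREATMENT] * cfg.n_treatment),
    )
    tx_samples = control[: cfg.n_transcriptome_per_group] + treatment[: cfg.n_transcriptome_per_group]
    is_treatment = np.array([0] * cfg.n_control + [1] * cfg.n_treatment)
    n = len(samples)
    base = cfg.base_abundance_log_mean

    metab_log: dict[str, np.ndarray] = {}
    tx_log: dict[str, np.ndarray] = {}  # on the full sample axis; subset later
    planted: list[PlantedTriplet] = []
    for i, fork in enumerate(cfg.planted_forks, start=1):
        ratio = rng.normal(cfg.ratio_log_mean, cfg.log_sd, size=n)
        slopes = np.where(is_treatment == 1, fork.slope_treatment, fork.slope_control)
        noise = rng.normal(0.0, fork.noise_sd, size=n)
        log_a = base + slopes * ratio + noise
        log_c = rng.normal(base, cfg.log_sd, size=n)
        log_b = ratio + log_c
        a_name, c_name = f"met_fork{i}_A", f"met_fork{i}_C"
        metab_log[a_name] = log_a
        metab_log[c_name] = log_c
        if fork.cross_omic:
            b_name = f"tx_fork{i}_B"
            tx_log[b_name] = log_b
        else:
            b_name = f"met_fork{i}_B"
            metab_log[b_name] = log_b
        planted.append(
            PlantedTriplet(
                TripletSpec(a_name, b_name, c_name),
                fork.slope_control, fork.slope_treatment, fork.noise_sd,
            )
        )

    null_features = []
    for i in range(1, cfg.n_null_features + 1):
        name = f"met_null{i:03d}"
        metab_log[name] = rng.normal(base, cfg.log_sd, size=n)
        null_features.append(name)
    for i in range(1, cfg.n_null_transcripts + 1):
        name = f"tx_null{i:03d}"
        tx_log[name] = rng.normal(cfg.transcript_log_mean, cfg.transcript_log_sd, size=n)
        null_features.append(name)

    metab_values = pd.DataFrame(
        {s: [np.exp(metab_log[f][j]) for f in metab_log] for j, s in enumerate(samples)},
        index=list(metab_log),
    )
    # non-detect masking, null metabolites only; planted members stay intact
    # (min-value imputation of a fork member would corrupt the ground truth
    # the dataset exists to certify), and masking never removes all values
    if cfg.missing_rate > 0 and len(metab_values):
        mask = rng.random(metab_values.shape) < cfg.missing_rate
        planted_members = {m_ for p in planted for m_ in p.triplet.members}
        for r, name in enumerate(metab_values.index):
            if name in planted_members:
                mask[r, :] = False
            elif mask[r].all():
                keep = rng.integers(0, mask.shape[1])
                mask[r, keep] = False
        metab_values = metab_values.mask(mask)

    pathway_cycle = ("sulfur", "lipid", "sugar")
    classes = {}
    for p in planted:
        for k, member in enumerate(p.triplet.members):
            classes[member] = pathway_cycle[k % 3]
    pathway = pd.Series(
        [classes.get(f, "other") for f in metab_values.index], index=metab_values.index
    )
    metabolites = OmicsMatrix.build(metab_values, METABOLITE, pathway_class=pathway)

    tx_index = sorted(tx_log)
    sample_pos = {s: j for j, s in enumerate(samples)}
    tx_values = pd.DataFrame(
        {s: [np.exp(tx_log[f][sample_pos[s]]) for f in tx_index] for s in tx_samples},
        index=tx_index,
    )
    if cfg.transcript_zero_rate > 0 and len(tx_values):
        zero_mask = rng.random(tx_values.shape) < cfg.transcript_zero_rate
        # keep planted transcript members intact: zero-inflation models dropout
        # of weakly expressed genes, not of a fork member under study
        planted_tx = {p.triplet.b for p in planted if p.triplet.b.startswith("tx_")}
        for r, name in enumerate(tx_index):
            if name in planted_tx:
                zero_mask[r, :] = False
        tx_values = tx_values.mask(zero_mask, 0.0)
    transcripts = OmicsMatrix.build(tx_values, TRANSCRIPT)

    truth = SyntheticTruth(planted=tuple(planted), null_features=tuple(null_features))
    return metabolites, transcripts, design, truth


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) for replicate studies."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def generate_null_battery(
    cfg: GeneratorConfig, replicates: int
) -> Iterator[tuple[OmicsMatrix, OmicsMatrix, SampleDesign, SyntheticTruth]]:
    """Independent datasets with distinct derived seeds, for calibration runs."""
    if replicates < 1:
        raise GeneratorError("replicates must be >= 1")
    for child in derive_seeds(cfg.seed, replicates):
        yield generate(replace(cfg, seed=child))
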