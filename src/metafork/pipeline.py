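"""End-to-end orchestration: preprocess -> screen -> model -> DE -> circuit.

Each stage writes a plain-text artifact so any stage can be rerun standalone
from the previous stage's files, and identical inputs plus config produce
byte-identical outputs. The filtering funnel (features -> enumerated
triplets -> screened candidates -> validated forks -> circuit components) is
logged and written to funnel.log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import circuit_assembly as ca
from .diffexpr import de_table
from .fork_models import ModelConfig, batch_evaluate, results_to_frame
from .fork_screen import ScreenConfig, screen_all, screened_to_frame
from .io_formats import (
    METABOLITE,
    TRANSCRIPT,
    OmicsMatrix,
    SampleDesign,
    read_design,
    read_omics_table,
    write_circuit,
    write_matrix,
    write_table,
)
from .preprocess import PreprocessConfig, impute_min, log_transform, subset_features

logger = logging.getLogger("metafork.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    metabolites: Path | None = None
    expression: Path | None = None
    design: Path | None = None
    regulators: Path | None = None
    out_dir: Path = Path("metafork_out")
    condition_map: dict[str, str] | None = None
    pathway_class_column: str | None = None
    preprocess: PreprocessConfig = field(default_factory=lambda: PreprocessConfig(keep_all=True))
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    de_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("metabolites", "expression", "design", "regulators", "out_dir"):
            if raw.get(key) is not None:
                setattr(cfg, key, Path(raw[key]))
        for key in ("condition_map", "pathway_class_column", "de_alpha"):
            if raw.get(key) is not None:
                setattr(cfg, key, raw[key])
        if "preprocess" in raw:
            cfg.preprocess = PreprocessConfig(
                pathway_classes=tuple(raw["preprocess"].get("pathway_classes", ())),
                keep_all=raw["preprocess"].get("keep_all", False),
                log_base=raw["preprocess"].get("log_base", cfg.preprocess.log_base),
                transcript_pseudocount=raw["preprocess"].get(
                    "transcript_pseudocount", cfg.preprocess.transcript_pseudocount
                ),
            )
        if "screen" in raw:
            cfg.screen = ScreenConfig(**raw["screen"])
        if "model" in raw:
            cfg.model = ModelConfig(**raw["model"])
        return cfg


def prepare_matrix(cfg: PipelineConfig) -> tuple[OmicsMatrix, SampleDesign]:
    """Read, subset, impute and log-transform into one combined log matrix."""
    design = read_design(cfg.design, condition_map=cfg.condition_map)
    parts = []
    if cfg.metabolites is not None:
        metab = read_omics_table(
            cfg.metabolites, METABOLITE, sep=",",
            pathway_class_column=cfg.pathway_class_column,
        )
        metab = subset_features(
            metab, cfg.preprocess.pathway_classes, keep_all=cfg.preprocess.keep_all
        )
        parts.append(log_transform(impute_min(metab), cfg.preprocess))
    if cfg.expression is not None:
        tx = read_omics_table(cfg.expression, TRANSCRIPT, sep="\t")
        parts.append(log_transform(tx, cfg.preprocess))
    if not parts:
        raise ValueError("no input tables configured")
    m = OmicsMatrix.concat(parts)
    unknown = set(m.sample_ids) - set(design.sample_ids)
    if unknown:
        raise ValueError(f"samples missing from design: {sorted(unknown)}")
    return m, design


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage in order, writing all artifacts to out_dir.

    Returns the funnel summary. Any stage error is wrapped in PipelineError
    carrying the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    funnel: dict = {}

    try:
        m, design = prepare_matrix(cfg)
        write_matrix(m, out / "processed_matrix.tsv")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("preprocess", exc) from exc
    funnel["n_features"] = len(m.feature_ids)
    n_feat = len(m.feature_ids)
    funnel["n_triplets"] = n_feat * (n_feat - 1) * (n_feat - 2) // 2

    try:
        screened, n_skipped = screen_all(m, design, cfg.screen)
        write_table(screened_to_frame(screened), out / "screened.tsv")
    except Exception as exc:
        raise PipelineError("screen", exc) from exc
    candidates = [s for s in screened if s.passed]
    funnel["n_screened"] = len(screened)
    funnel["n_skipped"] = n_skipped
    funnel["n_candidates"] = len(candidates)

    try:
        results = batch_evaluate(candidates, m, design, cfg.model)
        write_table(results_to_frame(results, fdr_adjust=cfg.model.fdr_adjust), out / "forks.tsv")
    except Exception as exc:
        raise PipelineError("model", exc) from exc
    funnel["n_forks"] = sum(r.is_fork for r in results)

    try:
        de = de_table(m, design, alpha=cfg.de_alpha)
        write_table(de, out / "de.tsv")
    except Exception as exc:
        raise PipelineError("de", exc) from exc
    funnel["n_de_significant"] = int((de["direction"] != "unchanged").sum()) if len(de) else 0

    try:
        by_triplet = {s.triplet: s for s in candidates}
        forks = [
            ca.Fork(screen=by_triplet[r.triplet], model=r) for r in results if r.is_fork
        ]
        circuit = ca.merge_forks(forks)
        ca.annotate_pairwise(circuit, m, design)
        ca.annotate_de(circuit, de)
        if cfg.regulators is not None:
            reg = pd.read_csv(cfg.regulators, sep="\t", dtype=str)
            ca.attach_regulators(circuit, reg, de)
        export = ca.to_export(circuit)
        write_circuit(export, out / "circuit.graphml", "graphml")
        write_circuit(export, out / "circuit.json", "json")
        write_table(ca.component_summary(circuit), out / "components.tsv")
    except Exception as exc:
        raise PipelineError("circuit", exc) from exc
    funnel["n_components"] = len(circuit.components)

    lines = [f"{k}\t{v}" for k, v in funnel.items()]
    (out / "funnel.log").write_text("\n".join(lines) + "\n")
    logger.info("funnel: %s", funnel)
    return funnel
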