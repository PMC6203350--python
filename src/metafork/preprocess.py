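"""Data conditioning ahead of the fork screen.

Three steps, in the order a metabolomics vendor workflow applies them:
pathway-class subsetting (e.g. 600 measured compounds down to the ~60 in
sulfur/lipid/sugar metabolism), minimum-observed-value imputation of
non-detects on the raw scale, then log transformation. Transcript tables get
a pseudocount before the log because FPKM values can be exactly zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import METABOLITE, TRANSCRIPT, OmicsMatrix

logger = logging.getLogger("metafork.funnel")


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the conditioning stage.

    pathway_classes: tags to retain (case-insensitive exact match); empty
        with keep_all=True means no subsetting.
    log_base: base of the log transform. Screening correlations and
        interaction p-values are invariant to this choice (the transform is
        affine in the log values); it only rescales reported coefficients.
    transcript_pseudocount: added to FPKM before the log so zeros survive.
    """

    pathway_classes: tuple[str, ...] = ()
    keep_all: bool = False
    log_base: float = math.e
    transcript_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (self.log_base > 0 and self.log_base != 1):
            raise PreprocessError("log_base must be positive and != 1")
        if self.transcript_pseudocount < 0:
            raise PreprocessError("transcript_pseudocount must be >= 0")


def subset_features(
    m: OmicsMatrix, classes: tuple[str, ...] | list[str], keep_all: bool = False
) -> OmicsMatrix:
    """Retain features whose pathway_class matches any requested tag.

    Matching is a case-insensitive exact tag comparison. With keep_all the
    matrix passes through untouched (identity).
    """
    if keep_all:
        logger.info("feature funnel: %d -> %d (keep_all)", len(m.feature_ids), len(m.feature_ids))
        return m
    wanted = {c.strip().lower() for c in classes}
    if not wanted:
        raise PreprocessError("no pathway classes requested (use keep_all for identity)")
    tags = m.feature_meta["pathway_class"].astype(str).str.strip().str.lower()
    keep = [f for f, t in zip(m.feature_ids, tags) if t in wanted]
    logger.info("feature funnel: %d -> %d (classes=%s)", len(m.feature_ids), len(keep), sorted(wanted))
    if len(keep) < 3:
        raise PreprocessError(
            f"subsetting left {len(keep)} features; need >= 3 to form any triplet"
        )
    return m.subset_features(keep)


def impute_min(m: OmicsMatrix) -> OmicsMatrix:
    """Replace each missing cell with the feature's minimum observed value.

    The minimum is taken over all samples pooled (both conditions), on the
    raw abundance scale. Idempotent; observed cells are untouched.
    """
    if m.log_scale:
        raise PreprocessError("impute_min applies to raw-scale matrices")
    values = m.values.copy()
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        feat = values.index[all_missing][0]
        raise PreprocessError(f"feature {feat!r} has no observed values; cannot impute")
    mins = values.min(axis=1, skipna=True)
    values = values.apply(lambda row: row.fillna(mins[row.name]), axis=1)
    return OmicsMatrix(values, m.feature_meta.copy(), log_scale=False)


def log_transform(m: OmicsMatrix, cfg: PreprocessConfig | None = None) -> OmicsMatrix:
    """Log-transform abundances, per feature omic type.

    Metabolites must be strictly positive (impute first); transcripts get
    ``log(FPKM + pseudocount)``.
    """
    cfg = cfg or PreprocessConfig(keep_all=True)
    if m.log_scale:
        raise PreprocessError("matrix is already on the log scale")
    values = m.values.copy()
    is_metab = m.feature_meta["omic_type"] == METABOLITE
    metab = values.loc[is_metab]
    if metab.isna().any().any():
        feat = metab.index[metab.isna().any(axis=1)][0]
        raise PreprocessError(f"metabolite {feat!r} still has missing values; impute first")
    if (metab <= 0).any().any():
        feat = metab.index[(metab <= 0).any(axis=1)][0]
        raise PreprocessError(f"metabolite {feat!r} has non-positive values; cannot log")
    trans = values.loc[~is_metab]
    if (trans < 0).any().any():
        feat = trans.index[(trans < 0).any(axis=1)][0]
        raise PreprocessError(f"transcript {feat!r} has negative values")
    scale = np.log(cfg.log_base)
    values.loc[is_metab] = np.log(metab) / scale
    values.loc[~is_metab] = np.log(trans + cfg.transcript_pseudocount) / scale
    return OmicsMatrix(values, m.feature_meta.copy(), log_scale=True)
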