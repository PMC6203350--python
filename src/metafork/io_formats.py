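"""Tables, containers and serializers for the fork-discovery pipeline.

This module owns every external representation the pipeline touches:

* wide metabolite abundance tables (CSV, features x samples, blanks/"NA" are
  non-detects, zeros are measured zeros),
* FPKM expression tables (TSV, same orientation),
* the sample design (sample -> control/treatment),
* processed-matrix checkpoints, and
* the merged circuit (GraphML / JSON / sectioned TSV, all round-trip safe).

No statistics live here.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

CONTROL = "control"
TREATMENT = "treatment"
CONDITIONS = (CONTROL, TREATMENT)

METABOLITE = "metabolite"
TRANSCRIPT = "transcript"
OMIC_TYPES = (METABOLITE, TRANSCRIPT)

#: cell contents treated as missing (non-detects) in abundance tables
DEFAULT_NA_VALUES = ("", "NA", "NaN", "nan")


class FormatError(ValueError):
    """An input file or in-memory table violates the expected layout."""


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Maps each sample to one of two condition levels.

    Both levels must be present with at least 3 samples each — per-condition
    Pearson correlations and interaction fits need the degrees of freedom.
    """

    sample_ids: tuple[str, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.conditions):
            raise FormatError("sample_ids and conditions differ in length")
        seen: set[str] = set()
        dups = sorted({s for s in self.sample_ids if s in seen or seen.add(s)})
        if dups:
            raise FormatError(f"duplicate sample ids: {dups}")
        levels = set(self.conditions)
        if levels != set(CONDITIONS):
            raise FormatError(
                f"design must contain exactly the levels {CONDITIONS}, got {sorted(levels)}"
            )
        for level in CONDITIONS:
            n = self.conditions.count(level)
            if n < 3:
                raise FormatError(f"condition {level!r} has {n} samples; need >= 3")

    @property
    def n_control(self) -> int:
        return self.conditions.count(CONTROL)

    @property
    def n_treatment(self) -> int:
        return self.conditions.count(TREATMENT)

    @property
    def condition_of(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.conditions))

    def samples_for(self, condition: str) -> tuple[str, ...]:
        return tuple(s for s, c in zip(self.sample_ids, self.conditions) if c == condition)

    def subset(self, samples: Sequence[str]) -> "SampleDesign":
        """Restrict to ``samples``, preserving this design's order."""
        keep = set(samples)
        unknown = keep - set(self.sample_ids)
        if unknown:
            raise FormatError(f"samples not in design: {sorted(unknown)}")
        pairs = [(s, c) for s, c in zip(self.sample_ids, self.conditions) if s in keep]
        return SampleDesign(tuple(s for s, _ in pairs), tuple(c for _, c in pairs))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "condition": self.conditions})


def read_design(
    path: str | Path,
    condition_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> SampleDesign:
    """Read a two-column (sample_id, condition) design table.

    ``condition_map`` translates study-specific labels (e.g. "TN"/"HS") to the
    canonical control/treatment levels; identity if omitted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty design file") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: design needs two columns (sample_id, condition)")
    if df.empty:
        raise FormatError(f"{path}: design has no rows")
    sample_col, cond_col = df.columns[:2]
    samples = [str(s).strip() for s in df[sample_col]]
    raw = [str(c).strip() for c in df[cond_col]]
    if condition_map is not None:
        unknown = sorted({c for c in raw if c not in condition_map})
        if unknown:
            raise FormatError(
                f"{path}: condition labels {unknown} missing from condition_map"
            )
        conditions = [condition_map[c] for c in raw]
    else:
        conditions = raw
    bad = sorted({c for c in conditions if c not in CONDITIONS})
    if bad:
        raise FormatError(
            f"{path}: unmapped condition labels {bad}; expected {CONDITIONS} "
            "(supply condition_map)"
        )
    return SampleDesign(tuple(samples), tuple(conditions))


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.as_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# omics matrices
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """Features x samples abundance matrix with per-feature metadata.

    ``values`` holds floats with NaN for missing cells. Before log transform,
    missing means non-detect (metabolites); after per-omic transform and
    cross-omic concatenation, NaN marks samples a feature was not measured in
    (transcripts outside the transcriptome subset).

    ``feature_meta`` is indexed identically to ``values`` with columns
    ``omic_type`` (metabolite/transcript) and ``pathway_class`` (free tag,
    may be empty).
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise FormatError(f"duplicate feature ids: {dups}")
        if not self.values.index.equals(self.feature_meta.index):
            raise FormatError("feature_meta index does not match values index")
        for col in ("omic_type", "pathway_class"):
            if col not in self.feature_meta.columns:
                raise FormatError(f"feature_meta missing column {col!r}")
        bad = set(self.feature_meta["omic_type"]) - set(OMIC_TYPES)
        if bad:
            raise FormatError(f"unknown omic types: {sorted(bad)}")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.rename(None)
        self.values.columns = self.values.columns.rename(None)
        self.feature_meta = self.feature_meta.copy()
        self.feature_meta.index = self.feature_meta.index.rename(None)
        if not self.log_scale:
            neg = self.values.lt(0)
            if neg.any().any():
                feat = self.values.index[neg.any(axis=1)][0]
                raise FormatError(f"negative abundance for feature {feat!r}")

    @classmethod
    def build(
        cls,
        values: pd.DataFrame,
        omic_type: str,
        pathway_class: pd.Series | None = None,
        log_scale: bool = False,
    ) -> "OmicsMatrix":
        if omic_type not in OMIC_TYPES:
            raise FormatError(f"omic_type must be one of {OMIC_TYPES}")
        pc = (
            pathway_class.reindex(values.index).fillna("")
            if pathway_class is not None
            else pd.Series("", index=values.index)
        )
        meta = pd.DataFrame({"omic_type": omic_type, "pathway_class": pc}, index=values.index)
        return cls(values=values, feature_meta=meta, log_scale=log_scale)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def omic_type(self, feature: str) -> str:
        return str(self.feature_meta.at[feature, "omic_type"])

    def subset_features(self, features: Sequence[str]) -> "OmicsMatrix":
        missing = [f for f in features if f not in self.values.index]
        if missing:
            raise FormatError(f"unknown features: {missing}")
        return OmicsMatrix(
            self.values.loc[list(features)],
            self.feature_meta.loc[list(features)],
            self.log_scale,
        )

    def subset_samples(self, samples: Sequence[str]) -> "OmicsMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise FormatError(f"unknown samples: {missing}")
        return OmicsMatrix(self.values[list(samples)], self.feature_meta.copy(), self.log_scale)

    @staticmethod
    def concat(matrices: Sequence["OmicsMatrix"]) -> "OmicsMatrix":
        """Stack matrices over the union of samples (NaN where unmeasured)."""
        if not matrices:
            raise FormatError("nothing to concatenate")
        if len({m.log_scale for m in matrices}) != 1:
            raise FormatError("cannot mix log and raw matrices")
        columns: list[str] = []
        for m in matrices:
            columns.extend(c for c in m.sample_ids if c not in columns)
        values = pd.concat([m.values.reindex(columns=columns) for m in matrices])
        meta = pd.concat([m.feature_meta for m in matrices])
        return OmicsMatrix(values, meta, matrices[0].log_scale)


def read_omics_table(
    path: str | Path,
    omic_type: str,
    sep: str = ",",
    pathway_class_column: str | None = None,
    na_values: Sequence[str] = DEFAULT_NA_VALUES,
) -> OmicsMatrix:
    """Read a wide features-x-samples abundance table.

    First column: feature ids. Optional ``pathway_class_column`` holds the
    pathway tag; all remaining columns are samples. Blank cells and the
    strings in ``na_values`` are missing (non-detects); zeros are measured
    zeros. Parsing is locale-independent (decimal point).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty table") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a feature-id column plus >=1 sample column")
    feature_col = df.columns[0]
    features = df[feature_col].astype(str).str.strip()
    dups = sorted(features[features.duplicated()].unique())
    if dups:
        raise FormatError(f"{path}: duplicate feature ids: {dups}")
    df = df.drop(columns=[feature_col])
    df.index = pd.Index(features, name="feature_id")

    pathway = None
    if pathway_class_column is not None:
        if pathway_class_column not in df.columns:
            raise FormatError(f"{path}: pathway column {pathway_class_column!r} not found")
        pathway = df[pathway_class_column].astype(str).str.strip()
        df = df.drop(columns=[pathway_class_column])

    na_set = set(na_values)
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col].astype(str).str.strip()
        is_na = raw.isin(na_set)
        parsed = pd.to_numeric(raw.where(~is_na), errors="coerce")
        bad = parsed.isna() & ~is_na
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(
                f"{path}: non-numeric value {raw[bad].iloc[0]!r} at row {row!r}, column {col!r}"
            )
        values[col] = parsed
    return OmicsMatrix.build(values, omic_type=omic_type, pathway_class=pathway)


_MATRIX_HEADER = "#metafork-matrix"


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write a processed-matrix checkpoint (TSV, full precision)."""
    path = Path(path)
    out = m.feature_meta.copy()
    out = pd.concat([out, m.values], axis=1)
    with open(path, "w") as fh:
        fh.write(f"{_MATRIX_HEADER} log_scale={str(m.log_scale).lower()}\n")
        out.to_csv(fh, sep="\t", index=True, index_label="feature_id")


def read_matrix(path: str | Path) -> OmicsMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(_MATRIX_HEADER):
            raise FormatError(f"{path}: not a metafork matrix checkpoint")
        log_scale = header.endswith("log_scale=true")
        df = pd.read_csv(
            fh, sep="\t", index_col="feature_id", dtype={0: str},
            float_precision="round_trip",
        )
    meta = df[["omic_type", "pathway_class"]].copy()
    meta["pathway_class"] = meta["pathway_class"].fillna("").astype(str)
    values = df.drop(columns=["omic_type", "pathway_class"]).astype(float)
    return OmicsMatrix(values, meta, log_scale=log_scale)


# ---------------------------------------------------------------------------
# circuit export
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircuitNode:
    feature_id: str
    omic_type: str | None = None
    role: str = "member"  # member | regulator
    de_direction: str | None = None
    de_p: float | None = None


@dataclass(frozen=True)
class CircuitEdge:
    source: str
    target: str
    fork_ids: tuple[str, ...] = ()
    cor_control: float | None = None
    cor_treatment: float | None = None
    p_forward: float | None = None  # most significant owning fork, A~(B/C) direction
    p_reverse: float | None = None
    kind: str = "fork"  # fork | regulator
    relation: str | None = None


@dataclass(frozen=True)
class CircuitFork:
    fork_id: str
    a: str
    b: str
    c: str
    cor_control: float
    cor_treatment: float
    delta: float
    p_forward: float
    p_reverse: float


@dataclass(frozen=True)
class CircuitExport:
    nodes: tuple[CircuitNode, ...]
    edges: tuple[CircuitEdge, ...]
    forks: tuple[CircuitFork, ...]

    def validate(self) -> None:
        ids = {n.feature_id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise FormatError("duplicate circuit nodes")
        fork_ids = {f.fork_id for f in self.forks}
        for e in self.edges:
            for end in (e.source, e.target):
                if end not in ids:
                    raise FormatError(f"edge endpoint {end!r} is not a node")
            for fid in e.fork_ids:
                if fid not in fork_ids:
                    raise FormatError(f"edge references unknown fork {fid!r}")


CIRCUIT_FORMATS = ("graphml", "json", "tsv")


def _drop_none(d: dict) -> dict:
    return {k: v for k, v in d.items() if v is not None}


def write_circuit(circuit: CircuitExport, path: str | Path, format: str = "graphml") -> None:
    """Serialize a circuit; read_circuit on the result reconstructs it exactly."""
    circuit.validate()
    if format not in CIRCUIT_FORMATS:
        raise FormatError(f"unsupported circuit format {format!r}; use one of {CIRCUIT_FORMATS}")
    path = Path(path)
    if format == "json":
        payload = {
            "nodes": [asdict(n) for n in circuit.nodes],
            "edges": [dict(asdict(e), fork_ids=list(e.fork_ids)) for e in circuit.edges],
            "forks": [asdict(f) for f in circuit.forks],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    elif format == "graphml":
        g = nx.Graph()
        g.graph["forks"] = json.dumps([asdict(f) for f in circuit.forks])
        for n in circuit.nodes:
            g.add_node(n.feature_id, **_drop_none(asdict(n)))
        for e in circuit.edges:
            attrs = _drop_none(asdict(e))
            attrs.pop("source")
            attrs.pop("target")
            attrs["fork_ids"] = json.dumps(list(e.fork_ids))
            g.add_edge(e.source, e.target, **attrs)
        nx.write_graphml(g, path)
    else:  # tsv, three sections in one file
        with open(path, "w") as fh:
            fh.write("#section\tnodes\n")
            fh.write("feature_id\tomic_type\trole\tde_direction\tde_p\n")
            for n in circuit.nodes:
                fh.write(_tsv_row(n.feature_id, n.omic_type, n.role, n.de_direction, n.de_p))
            fh.write("#section\tedges\n")
            fh.write(
                "source\ttarget\tfork_ids\tcor_control\tcor_treatment"
                "\tp_forward\tp_reverse\tkind\trelation\n"
            )
            for e in circuit.edges:
                fh.write(
                    _tsv_row(
                        e.source,
                        e.target,
                        ",".join(e.fork_ids),
                        e.cor_control,
                        e.cor_treatment,
                        e.p_forward,
                        e.p_reverse,
                        e.kind,
                        e.relation,
                    )
                )
            fh.write("#section\tforks\n")
            fh.write(
                "fork_id\ta\tb\tc\tcor_control\tcor_treatment\tdelta\tp_forward\tp_reverse\n"
            )
            for f in circuit.forks:
                fh.write(
                    _tsv_row(
                        f.fork_id, f.a, f.b, f.c, f.cor_control, f.cor_treatment,
                        f.delta, f.p_forward, f.p_reverse,
                    )
                )


def _tsv_row(*cells) -> str:
    out = []
    for c in cells:
        if c is None:
            out.append("")
        elif isinstance(c, float):
            out.append(repr(c))
        else:
            out.append(str(c))
    return "\t".join(out) + "\n"


def _opt_str(s: str) -> str | None:
    return s if s != "" else None


def _opt_float(s: str) -> float | None:
    return float(s) if s != "" else None


def read_circuit(path: str | Path, format: str = "graphml") -> CircuitExport:
    if format not in CIRCUIT_FORMATS:
        raise FormatError(f"unsupported circuit format {format!r}; use one of {CIRCUIT_FORMATS}")
    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text())
        nodes = tuple(CircuitNode(**n) for n in payload["nodes"])
        edges = tuple(
            CircuitEdge(**dict(e, fork_ids=tuple(e["fork_ids"]))) for e in payload["edges"]
        )
        forks = tuple(CircuitFork(**f) for f in payload["forks"])
    elif format == "graphml":
        g = nx.read_graphml(path)
        forks = tuple(CircuitFork(**f) for f in json.loads(g.graph.get("forks", "[]")))
        nodes = tuple(
            CircuitNode(
                feature_id=str(nid),
                omic_type=attrs.get("omic_type"),
                role=attrs.get("role", "member"),
                de_direction=attrs.get("de_direction"),
                de_p=attrs.get("de_p"),
            )
            for nid, attrs in g.nodes(data=True)
        )
        edges = tuple(
            CircuitEdge(
                source=str(u),
                target=str(v),
                fork_ids=tuple(json.loads(attrs.get("fork_ids", "[]"))),
                cor_control=attrs.get("cor_control"),
                cor_treatment=attrs.get("cor_treatment"),
                p_forward=attrs.get("p_forward"),
                p_reverse=attrs.get("p_reverse"),
                kind=attrs.get("kind", "fork"),
                relation=attrs.get("relation"),
            )
            for u, v, attrs in g.edges(data=True)
        )
    else:
        nodes_l: list[CircuitNode] = []
        edges_l: list[CircuitEdge] = []
        forks_l: list[CircuitFork] = []
        section = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#section\t"):
                    section = line.split("\t", 1)[1]
                    next(fh)  # header row
                    continue
                if not line:
                    continue
                cells = line.split("\t")
                if section == "nodes":
                    nodes_l.append(
                        CircuitNode(
                            cells[0], _opt_str(cells[1]), cells[2],
                            _opt_str(cells[3]), _opt_float(cells[4]),
                        )
                    )
                elif section == "edges":
                    edges_l.append(
                        CircuitEdge(
                            cells[0], cells[1],
                            tuple(cells[2].split(",")) if cells[2] else (),
                            _opt_float(cells[3]), _opt_float(cells[4]),
                            _opt_float(cells[5]), _opt_float(cells[6]),
                            cells[7], _opt_str(cells[8]),
                        )
                    )
                elif section == "forks":
                    forks_l.append(
                        CircuitFork(
                            cells[0], cells[1], cells[2], cells[3],
                            float(cells[4]), float(cells[5]), float(cells[6]),
                            float(cells[7]), float(cells[8]),
                        )
                    )
        nodes, edges, forks = tuple(nodes_l), tuple(edges_l), tuple(forks_l)
    out = CircuitExport(nodes=nodes, edges=edges, forks=forks)
    out.validate()
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a stage result table (TSV, floats at 6 significant digits)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
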