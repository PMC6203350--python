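"""Merging validated forks into annotated regulatory circuits.

Each validated fork contributes a 3-clique over its members; forks sharing
at least one member fall into the same connected component, and the union of
these cliques is the circuit. Edges carry the per-condition pairwise Pearson
correlations of their endpoints and the interaction p-values of the fork(s)
that own them; nodes carry omic type and differential-abundance calls.
Regulator genes (curated biochemistry, supplied by the user) can be attached
to nodes or edges with their expression change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .fork_models import ForkModelResult
from .fork_screen import (
    ScreenedTriplet,
    TripletSpec,
    ZeroVarianceError,
    pearson,
)
from .io_formats import (
    CONTROL,
    TREATMENT,
    CircuitEdge,
    CircuitExport,
    CircuitFork,
    CircuitNode,
    OmicsMatrix,
    SampleDesign,
)

logger = logging.getLogger("metafork.circuit")


class CircuitError(ValueError):
    pass


@dataclass(frozen=True)
class Fork:
    """A triplet that survived both screening and the dual-model rule."""

    screen: ScreenedTriplet
    model: ForkModelResult

    def __post_init__(self) -> None:
        if not self.model.is_fork:
            raise CircuitError(f"{self.model.triplet} is not a validated fork")
        if self.screen.triplet != self.model.triplet:
            raise CircuitError("screen and model refer to different triplets")

    @property
    def triplet(self) -> TripletSpec:
        return self.model.triplet

    @property
    def fork_id(self) -> str:
        return str(self.triplet)


@dataclass
class CircuitGraph:
    """Undirected circuit over fork members; wraps a networkx graph."""

    graph: nx.Graph
    forks: dict[str, Fork]

    @property
    def components(self) -> list[tuple[str, ...]]:
        comps = [tuple(sorted(c)) for c in nx.connected_components(self.graph)]
        return sorted(comps)

    def member_nodes(self) -> list[str]:
        return sorted(
            n for n, a in self.graph.nodes(data=True) if a.get("role", "member") == "member"
        )


def merge_forks(forks: Sequence[Fork]) -> CircuitGraph:
    """Union the 3-cliques of all forks into one graph.

    Duplicate identical triplets are dropped with a warning. Output is
    independent of input order: nodes, edges and fork ids are added in
    canonical sorted order.
    """
    unique: dict[str, Fork] = {}
    for f in sorted(forks, key=lambda f: f.triplet):
        if f.fork_id in unique:
            warnings.warn(f"duplicate fork {f.fork_id} dropped", stacklevel=2)
            continue
        unique[f.fork_id] = f
    g = nx.Graph()
    for fid, f in unique.items():
        members = sorted(f.triplet.members)
        for m_ in members:
            if m_ not in g:
                g.add_node(m_, role="member")
        for i in range(3):
            for j in range(i + 1, 3):
                u, v = members[i], members[j]
                if g.has_edge(u, v):
                    g.edges[u, v]["fork_ids"].append(fid)
                else:
                    g.add_edge(u, v, fork_ids=[fid], kind="fork")
    logger.info(
        "merge: %d forks -> %d nodes, %d edges, %d components",
        len(unique), g.number_of_nodes(), g.number_of_edges(),
        nx.number_connected_components(g),
    )
    return CircuitGraph(graph=g, forks=unique)


def annotate_pairwise(c: CircuitGraph, m: OmicsMatrix, d: SampleDesign) -> CircuitGraph:
    """Attach per-condition Pearson correlations to every fork edge.

    Cross-omic edges use the intersection of samples measured for both
    endpoints; an undefined correlation (zero variance, too few samples)
    becomes an explicit None.
    """
    cond = d.condition_of
    for node in c.graph.nodes:
        if node in m.values.index:
            c.graph.nodes[node]["omic_type"] = m.omic_type(node)
    for u, v, attrs in c.graph.edges(data=True):
        if attrs.get("kind") != "fork":
            continue
        if u not in m.values.index or v not in m.values.index:
            raise CircuitError(f"edge endpoint missing from matrix: {u}--{v}")
        cols = [s for s in d.sample_ids if s in m.values.columns]
        sub = m.values.loc[[u, v], cols]
        ok = sub.notna().all(axis=0)
        for label, key in ((CONTROL, "cor_control"), (TREATMENT, "cor_treatment")):
            samples = [s for s in cols if ok[s] and cond[s] == label]
            try:
                attrs[key] = (
                    pearson(
                        m.values.loc[u, samples].to_numpy(dtype=float),
                        m.values.loc[v, samples].to_numpy(dtype=float),
                    )
                    if len(samples) >= 3
                    else None
                )
            except ZeroVarianceError:
                attrs[key] = None
    return c


def annotate_de(c: CircuitGraph, de: pd.DataFrame) -> CircuitGraph:
    """Copy differential-test direction and p-value onto matching nodes."""
    indexed = de.set_index("feature_id")
    for node in c.graph.nodes:
        if node in indexed.index:
            c.graph.nodes[node]["de_direction"] = str(indexed.at[node, "direction"])
            c.graph.nodes[node]["de_p"] = float(indexed.at[node, "p_value"])
    return c


def attach_regulators(
    c: CircuitGraph, regulators: pd.DataFrame, de: pd.DataFrame
) -> CircuitGraph:
    """Add user-curated regulator genes to the circuit.

    ``regulators`` rows: gene_id, target, relation — target is a node id or
    an edge written "u--v". Every gene must appear in the DE table and every
    target in the circuit; offending rows are reported together.
    """
    if regulators.empty:
        return c
    required = {"gene_id", "target", "relation"}
    if not required <= set(regulators.columns):
        raise CircuitError(f"regulator map needs columns {sorted(required)}")
    indexed = de.set_index("feature_id")
    bad_rows = []
    for i, row in regulators.iterrows():
        gene, target = str(row["gene_id"]), str(row["target"])
        if gene not in indexed.index:
            bad_rows.append(f"row {i}: gene {gene!r} not in DE table")
            continue
        if "--" in target:
            u, v = target.split("--", 1)
            if not c.graph.has_edge(u, v):
                bad_rows.append(f"row {i}: edge {target!r} not in circuit")
        elif target not in c.graph:
            bad_rows.append(f"row {i}: node {target!r} not in circuit")
    if bad_rows:
        raise CircuitError("invalid regulator map: " + "; ".join(bad_rows))
    for _, row in regulators.iterrows():
        gene, target, relation = str(row["gene_id"]), str(row["target"]), str(row["relation"])
        c.graph.add_node(
            gene,
            role="regulator",
            omic_type=str(indexed.at[gene, "omic_type"]) if "omic_type" in indexed else None,
            de_direction=str(indexed.at[gene, "direction"]),
            de_p=float(indexed.at[gene, "p_value"]),
        )
        endpoints = target.split("--", 1) if "--" in target else [target]
        for end in endpoints:
            c.graph.add_edge(gene, end, kind="regulator", relation=relation, fork_ids=[])
    return c


def component_summary(c: CircuitGraph) -> pd.DataFrame:
    rows = []
    fork_members = {fid: set(f.triplet.members) for fid, f in c.forks.items()}
    for i, comp in enumerate(c.components):
        members = set(comp)
        owning = sorted(fid for fid, mem in fork_members.items() if mem <= members)
        rows.append(
            {
                "component": i,
                "n_nodes": len(comp),
                "n_forks": len(owning),
                "members": ",".join(comp),
                "fork_ids": ",".join(owning),
            }
        )
    return pd.DataFrame(rows, columns=["component", "n_nodes", "n_forks", "members", "fork_ids"])


def to_export(c: CircuitGraph) -> CircuitExport:
    """Freeze the graph into the serializable circuit record."""
    nodes = tuple(
        CircuitNode(
            feature_id=n,
            omic_type=attrs.get("omic_type"),
            role=attrs.get("role", "member"),
            de_direction=attrs.get("de_direction"),
            de_p=attrs.get("de_p"),
        )
        for n, attrs in sorted(c.graph.nodes(data=True))
    )
    fork_records = tuple(
        CircuitFork(
            fork_id=fid,
            a=f.triplet.a, b=f.triplet.b, c=f.triplet.c,
            cor_control=f.screen.cor_control,
            cor_treatment=f.screen.cor_treatment,
            delta=f.screen.delta,
            p_forward=f.model.fit_forward.interaction_p,
            p_reverse=f.model.fit_reverse.interaction_p,
        )
        for fid, f in sorted(c.forks.items())
    )
    by_id = {fr.fork_id: fr for fr in fork_records}
    edges = []
    canonical = [(*sorted((u, v)), attrs) for u, v, attrs in c.graph.edges(data=True)]
    for u, v, attrs in sorted(canonical, key=lambda e: (e[0], e[1])):
        fork_ids = tuple(sorted(attrs.get("fork_ids", [])))
        owning = [by_id[fid] for fid in fork_ids]
        edges.append(
            CircuitEdge(
                source=u, target=v,
                fork_ids=fork_ids,
                cor_control=attrs.get("cor_control"),
                cor_treatment=attrs.get("cor_treatment"),
                p_forward=min((fr.p_forward for fr in owning), default=None),
                p_reverse=min((fr.p_reverse for fr in owning), default=None),
                kind=attrs.get("kind", "fork"),
                relation=attrs.get("relation"),
            )
        )
    export = CircuitExport(nodes=nodes, edges=tuple(edges), forks=fork_records)
    export.validate()
    return export
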