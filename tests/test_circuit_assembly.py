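import numpy as np
import pandas as pd
import pytest

from metafork import circuit_assembly as ca
from metafork.fork_models import FORWARD, REVERSE, InteractionFit, ForkModelResult
from metafork.fork_screen import ScreenedTriplet, TripletSpec
from metafork.io_formats import read_circuit, write_circuit

from conftest import make_design, make_matrix


def make_fork(a, b, c, p_forward=0.01, p_reverse=0.02, delta=1.5):
    """A validated fork with synthetic screen/model records."""
    t = TripletSpec(a, b, c)
    screen = ScreenedTriplet(
        triplet=t, cor_control=0.7, cor_treatment=-0.8, delta=delta,
        n_control=12, n_treatment=11, passed=True,
    )

    def fit(direction, p):
        return InteractionFit(
            direction=direction, intercept=0.0, slope_control=1.0,
            condition_offset=0.0, interaction_coefficient=-2.0,
            interaction_se=0.2, interaction_t=-10.0, interaction_p=p,
            df_residual=19, n_used=23,
        )

    model = ForkModelResult(
        triplet=t, fit_forward=fit(FORWARD, p_forward),
        fit_reverse=fit(REVERSE, p_reverse), alpha=0.05, is_fork=True,
    )
    return ca.Fork(screen=screen, model=model)


def union_find_components(fork_member_sets):
    """Brute-force disjoint-set oracle over fork member sets."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for members in fork_member_sets:
        m = list(members)
        for other in m[1:]:
            union(m[0], other)
    groups = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestMergeForks:
    def test_disjoint_forks_stay_separate(self):
        c = ca.merge_forks([make_fork("A", "B", "C"), make_fork("D", "E", "F")])
        assert len(c.components) == 2
        assert c.graph.number_of_nodes() == 6
        assert c.graph.number_of_edges() == 6

    def test_shared_member_joins_components(self):
        c = ca.merge_forks([make_fork("A", "B", "C"), make_fork("C", "D", "E")])
        assert len(c.components) == 1
        assert c.graph.number_of_nodes() == 5
        assert c.graph.number_of_edges() == 6

    def test_duplicate_triplets_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            c = ca.merge_forks([make_fork("A", "B", "C"), make_fork("A", "B", "C")])
        assert len(c.forks) == 1

    def test_components_match_union_find_oracle(self, rng):
        features = [f"n{i}" for i in range(20)]
        for _ in range(50):
            n_forks = int(rng.integers(1, 12))
            forks = []
            seen = set()
            for _ in range(n_forks):
                a, b, c = rng.choice(features, size=3, replace=False)
                t = (a, *sorted([b, c]))
                if t in seen:
                    continue
                seen.add(t)
                forks.append(make_fork(*t))
            circuit = ca.merge_forks(forks)
            oracle = union_find_components(
                [f.triplet.members for f in forks]
            )
            assert circuit.components == oracle

    def test_order_invariance(self, rng):
        forks = [make_fork("A", "B", "C"), make_fork("C", "D", "E"), make_fork("F", "G", "H")]
        a = ca.merge_forks(forks)
        b = ca.merge_forks(forks[::-1])
        assert list(a.graph.nodes) == list(b.graph.nodes)
        assert list(a.graph.edges) == list(b.graph.edges)
        assert a.components == b.components

    def test_component_count_monotone_as_forks_added(self):
        forks = [
            make_fork("A", "B", "C"),
            make_fork("D", "E", "F"),
            make_fork("C", "D", "X"),
            make_fork("P", "Q", "R"),
        ]
        prev = None
        seen = []
        for f in forks:
            seen.append(f)
            n = len(ca.merge_forks(seen).components)
            if prev is not None:
                assert n <= prev + 1  # adding a fork adds at most one component
            prev = n


class TestAnnotations:
    def test_duplicated_rows_correlate_perfectly(self):
        row = np.linspace(1, 4, 12)
        m = make_matrix(np.vstack([row, row, row + 1]), features=["A", "B", "C"],
                        log_scale=True)
        d = make_design(6, 6)
        c = ca.merge_forks([make_fork("A", "B", "C")])
        ca.annotate_pairwise(c, m, d)
        assert c.graph.edges["A", "B"]["cor_control"] == pytest.approx(1.0)
        assert c.graph.edges["A", "B"]["cor_treatment"] == pytest.approx(1.0)

    def test_planted_fork_edge_signs_match_generator(self, log_dataset):
        m, d, truth = log_dataset
        p = truth.planted[0]
        # slope +1 in control: A rises with log(B/C); B carries the ratio, so
        # A-B correlate positively under control and negatively under treatment
        c = ca.merge_forks([make_fork(*p.triplet.members)])
        ca.annotate_pairwise(c, m, d)
        edge = c.graph.edges[p.triplet.a, p.triplet.b]
        assert edge["cor_control"] > 0
        assert edge["cor_treatment"] < 0

    def test_zero_variance_edge_marked_unavailable(self):
        m = make_matrix(
            np.vstack([[1.0] * 12, np.linspace(0, 1, 12), np.linspace(2, 3, 12)]),
            features=["A", "B", "C"], log_scale=True,
        )
        c = ca.merge_forks([make_fork("A", "B", "C")])
        ca.annotate_pairwise(c, m, make_design(6, 6))
        assert c.graph.edges["A", "B"]["cor_control"] is None
        export = ca.to_export(c)
        ab = next(e for e in export.edges if (e.source, e.target) == ("A", "B"))
        assert ab.cor_control is None  # propagated as explicit null


def _de_frame(rows):
    return pd.DataFrame(
        rows, columns=["feature_id", "omic_type", "mean_control", "mean_treatment",
                       "t_stat", "df", "p_value", "direction", "degenerate"],
    )


class TestRegulators:
    def setup_method(self):
        self.circuit = ca.merge_forks([make_fork("A", "B", "C")])
        self.de = _de_frame([
            ["geneX", "transcript", 1.0, 0.5, 3.0, 10.0, 0.01, "down", False],
        ])

    def test_regulator_attached_with_de_call(self):
        reg = pd.DataFrame([{"gene_id": "geneX", "target": "A--B", "relation": "catalyzes"}])
        c = ca.attach_regulators(self.circuit, reg, self.de)
        assert c.graph.nodes["geneX"]["de_direction"] == "down"
        assert c.graph.has_edge("geneX", "A") and c.graph.has_edge("geneX", "B")
        assert c.graph.edges["geneX", "A"]["relation"] == "catalyzes"

    def test_empty_map_is_identity(self):
        before = set(self.circuit.graph.nodes)
        ca.attach_regulators(self.circuit, pd.DataFrame(), self.de)
        assert set(self.circuit.graph.nodes) == before

    def test_unknown_target_listed_in_error(self):
        reg = pd.DataFrame([{"gene_id": "geneX", "target": "ghost", "relation": "r"}])
        with pytest.raises(ca.CircuitError, match="ghost"):
            ca.attach_regulators(self.circuit, reg, self.de)

    def test_gene_missing_from_de_table_rejected(self):
        reg = pd.DataFrame([{"gene_id": "mystery", "target": "A", "relation": "r"}])
        with pytest.raises(ca.CircuitError, match="mystery"):
            ca.attach_regulators(self.circuit, reg, self.de)


class TestExportRoundTrip:
    @pytest.mark.parametrize("fmt", ["graphml", "json", "tsv"])
    def test_full_annotation_survives_serialization(self, tmp_path, log_dataset, fmt):
        m, d, truth = log_dataset
        p = truth.planted[0]
        c = ca.merge_forks([make_fork(*p.triplet.members)])
        ca.annotate_pairwise(c, m, d)
        de = _de_frame([[p.triplet.a, "metabolite", 1.0, 2.0, -3.0, 15.0, 0.01, "up", False]])
        ca.annotate_de(c, de)
        export = ca.to_export(c)
        path = tmp_path / f"circuit.{fmt}"
        write_circuit(export, path, fmt)
        assert read_circuit(path, fmt) == export
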