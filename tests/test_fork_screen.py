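import math

import numpy as np
import pytest

from metafork.fork_screen import (
    ScreenConfig,
    TripletSpec,
    ZeroVarianceError,
    enumerate_triplets,
    pearson,
    screen_all,
    screen_triplet,
)

from conftest import make_design, make_matrix


def pearson_oracle(x, y):
    """Direct sum-formula evaluation, independent of numpy.corrcoef."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


class TestPearson:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            assert pearson(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_zero_variance_signalled(self):
        with pytest.raises(ZeroVarianceError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [2.0, 1.0])


class TestEnumerateTriplets:
    @pytest.mark.parametrize("m,expected", [(3, 3), (4, 12), (60, 102_660)])
    def test_count_matches_m_choose_formula(self, m, expected):
        feats = [f"f{i:02d}" for i in range(m)]
        count = sum(1 for _ in enumerate_triplets(feats))
        assert count == expected == m * (m - 1) * (m - 2) // 2

    def test_one_orientation_per_ratio_pair(self):
        triplets = list(enumerate_triplets(["a", "b", "c", "d"]))
        assert all(t.b < t.c for t in triplets)
        assert len(set(triplets)) == len(triplets)

    def test_members_distinct_enforced(self):
        with pytest.raises(ValueError):
            TripletSpec("a", "a", "b")


def _planted_matrix(rng, slope_control, slope_treatment, noise_sd=0.1,
                    n_control=12, n_treatment=11):
    """Log-scale matrix with A tracking log(B/C) at condition slopes."""
    n = n_control + n_treatment
    ratio = rng.normal(0, 0.5, size=n)
    log_c = rng.normal(10, 0.5, size=n)
    slopes = np.array([slope_control] * n_control + [slope_treatment] * n_treatment)
    log_a = 10 + slopes * ratio + rng.normal(0, noise_sd, size=n)
    m = make_matrix(
        np.vstack([log_a, ratio + log_c, log_c]),
        features=["A", "B", "C"],
        log_scale=True,
    )
    return m, make_design(n_control, n_treatment)


class TestScreenTriplet:
    def test_planted_fork_passes_at_default_threshold(self, rng):
        m, d = _planted_matrix(rng, +1.0, -1.0, noise_sd=0.1)
        st = screen_triplet(TripletSpec("A", "B", "C"), m, d)
        assert st.passed and st.delta >= 1.2
        assert st.cor_control > 0.8 and st.cor_treatment < -0.8
        assert (st.n_control, st.n_treatment) == (12, 11)

    def test_identical_conditions_give_zero_delta(self, rng):
        half = rng.normal(size=(3, 6))
        m = make_matrix(np.hstack([half, half]), features=["A", "B", "C"], log_scale=True)
        d = make_design(6, 6)
        st = screen_triplet(TripletSpec("A", "B", "C"), m, d)
        assert st.delta == pytest.approx(0.0, abs=1e-12)
        assert not st.passed

    def test_threshold_is_inclusive(self, rng):
        m, d = _planted_matrix(rng, +0.5, -0.5, noise_sd=0.3)
        t = TripletSpec("A", "B", "C")
        st = screen_triplet(t, m, d)
        at_boundary = screen_triplet(t, m, d, ScreenConfig(delta_threshold=st.delta))
        assert at_boundary.passed  # "delta or greater" includes equality
        above = screen_triplet(
            t, m, d, ScreenConfig(delta_threshold=np.nextafter(st.delta, 2.0))
        )
        assert not above.passed

    def test_swapping_ratio_members_flips_correlations_only(self, rng):
        for _ in range(50):
            m, d = _planted_matrix(
                rng,
                float(rng.uniform(-1.5, 1.5)),
                float(rng.uniform(-1.5, 1.5)),
                noise_sd=float(rng.uniform(0.05, 1.0)),
            )
            t = TripletSpec("A", "B", "C")
            fwd = screen_triplet(t, m, d)
            rev = screen_triplet(t.swapped(), m, d)
            assert rev.cor_control == pytest.approx(-fwd.cor_control, abs=1e-12)
            assert rev.cor_treatment == pytest.approx(-fwd.cor_treatment, abs=1e-12)
            assert rev.delta == pytest.approx(fwd.delta, abs=1e-12)
            assert rev.passed == fwd.passed
            assert 0 <= fwd.delta <= 2

    def test_invariant_to_affine_rescaling(self, rng):
        m, d = _planted_matrix(rng, 1.0, -1.0)
        t = TripletSpec("A", "B", "C")
        before = screen_triplet(t, m, d)
        m.values.loc["A"] = 3.5 * m.values.loc["A"] + 7.0
        after = screen_triplet(t, m, d)
        assert after.cor_control == pytest.approx(before.cor_control, abs=1e-12)
        assert after.delta == pytest.approx(before.delta, abs=1e-12)

    def test_zero_variance_triplet_skipped_with_reason(self):
        from metafork.fork_screen import TripletSkipped

        m = make_matrix(
            [[1.0] * 12, list(range(12)), list(range(12, 24))],
            features=["A", "B", "C"],
            log_scale=True,
        )
        d = make_design(6, 6)
        with pytest.raises(TripletSkipped, match="zero variance"):
            screen_triplet(TripletSpec("A", "B", "C"), m, d)

    def test_requires_log_scale(self, rng):
        m = make_matrix(rng.lognormal(0, 1, size=(3, 12)), features=["A", "B", "C"])
        with pytest.raises(ValueError, match="log"):
            screen_triplet(TripletSpec("A", "B", "C"), m, make_design(6, 6))


class TestScreenAll:
    def test_matches_per_triplet_reference_path(self, log_dataset):
        m, d, _ = log_dataset
        small = m.subset_features(m.feature_ids[:8])
        results, n_skipped = screen_all(small, d)
        assert n_skipped == 0
        by_triplet = {r.triplet: r for r in results}
        for t, r in by_triplet.items():
            ref = screen_triplet(t, small, d)
            assert r.cor_control == pytest.approx(ref.cor_control, abs=1e-12)
            assert r.cor_treatment == pytest.approx(ref.cor_treatment, abs=1e-12)
            assert r.passed == ref.passed
            assert (r.n_control, r.n_treatment) == (ref.n_control, ref.n_treatment)

    def test_cross_omic_triplets_use_sample_intersection(self, log_dataset):
        m, d, truth = log_dataset
        tx = next(f for f in m.feature_ids if f.startswith("tx_"))
        met = [f for f in m.feature_ids if f.startswith("met_")][:2]
        t = TripletSpec(met[0], *sorted([tx, met[1]]))
        st = screen_triplet(t, m, d)
        assert (st.n_control, st.n_treatment) == (8, 8)

    def test_cross_omic_can_be_disabled(self, log_dataset):
        m, d, _ = log_dataset
        sub = m.subset_features(
            [f for f in m.feature_ids if f.startswith("met_")][:4]
            + [f for f in m.feature_ids if f.startswith("tx_")][:2]
        )
        mixed_allowed, _ = screen_all(sub, d, ScreenConfig(allow_cross_omic=True))
        pure_only, n_skipped = screen_all(sub, d, ScreenConfig(allow_cross_omic=False))
        omic = sub.feature_meta["omic_type"].to_dict()
        assert all(len({omic[f] for f in r.triplet.members}) == 1 for r in pure_only)
        assert len(mixed_allowed) > len(pure_only)
        assert n_skipped > 0
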