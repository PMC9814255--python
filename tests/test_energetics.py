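import numpy as np
import pytest

from bpopen.energetics import (
    EnergyLevels,
    ReactionPath,
    asynchronicity,
    barrier_summary,
    barrier_trend,
    published_levels_eq,
    read_energy_levels,
    survival_threshold,
    write_energy_levels,
)
from bpopen.synthetic import gen_reaction_path


def oracle_alpha(path, label_a, label_b):
    """Brute-force finite-difference asynchronicity, independent of the library."""
    q = path.q_irc
    pos = {}
    for label in (label_a, label_b):
        i = path.labels.index(label)
        best_val, best_mid = -1.0, None
        for k in range(len(q) - 1):
            dq = q[k + 1] - q[k]
            if dq <= 0:
                continue
            d = (path.coords[k + 1, i] - path.coords[k, i]) / dq
            v = float(d @ d)
            if v > best_val:
                best_val, best_mid = v, (q[k] + q[k + 1]) / 2.0
        pos[label] = best_mid
    return abs(pos[label_a] - pos[label_b]) / q[-1]


def random_path(rng, n_images=12, n_atoms=5):
    coords = np.cumsum(rng.normal(0, 0.3, size=(n_images, n_atoms, 3)), axis=0)
    labels = [f"A{i}" for i in range(n_atoms)]
    return ReactionPath(labels=labels, coords=coords)


class TestAsynchronicity:
    def test_synchronous_path_alpha_zero(self):
        path = gen_reaction_path(n_images=15, transfer_q_b1=0.5, transfer_q_b2=0.5)
        res = asynchronicity(path, "H41", "H1")
        assert res.alpha == pytest.approx(0.0, abs=1e-12)

    def test_29_image_stepwise_path_hand_computed(self):
        # protons hop in segments 4 and 23 (0-based) of 28 uniform segments
        path = gen_reaction_path(n_images=29, transfer_q_b1=23 / 28 + 1e-9,
                                 transfer_q_b2=4 / 28 + 1e-9)
        res = asynchronicity(path, "H41", "H1")
        assert res.alpha == pytest.approx(19 / 28, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 9, 29])
    def test_endpoint_transfers_approach_unity(self, n):
        path = gen_reaction_path(n_images=n, transfer_q_b1=1.0, transfer_q_b2=0.0)
        res = asynchronicity(path, "H41", "H1")
        assert res.alpha == pytest.approx((n - 2) / (n - 1), abs=1e-12)

    def test_matches_brute_force_oracle_on_random_paths(self, rng):
        for _ in range(30):
            path = random_path(rng)
            got = asynchronicity(path, "A0", "A3").alpha
            assert got == pytest.approx(oracle_alpha(path, "A0", "A3"), abs=1e-12)
            assert 0.0 <= got <= 1.0

    def test_invariant_under_rigid_translation_and_q_rescaling(self, rng):
        path = random_path(rng)
        base = asynchronicity(path, "A1", "A2").alpha
        shifted = ReactionPath(
            labels=path.labels, coords=path.coords + np.array([5.0, -3.0, 1.0]),
            q_irc=path.q_irc,
        )
        rescaled = ReactionPath(
            labels=path.labels, coords=path.coords, q_irc=path.q_irc * 7.5
        )
        assert asynchronicity(shifted, "A1", "A2").alpha == pytest.approx(base, abs=1e-12)
        assert asynchronicity(rescaled, "A1", "A2").alpha == pytest.approx(base, abs=1e-12)

    def test_unknown_proton_label_raises(self):
        path = gen_reaction_path()
        with pytest.raises(KeyError, match="H99"):
            asynchronicity(path, "H99", "H1")

    def test_b2_transfers_before_b1_in_generated_path(self):
        path = gen_reaction_path(transfer_q_b1=0.8, transfer_q_b2=0.2)
        res = asynchronicity(path, "H41", "H1")
        assert res.alpha_b2 < res.alpha_b1  # middle proton moves first


class TestReactionPathIO:
    def test_xyz_roundtrip_lossless(self, tmp_path, rng):
        path = random_path(rng, n_images=5, n_atoms=3)
        path.energies = rng.normal(size=5)
        f = tmp_path / "path.xyz"
        path.to_xyz(f)
        back = ReactionPath.from_xyz(f)
        assert back.labels == path.labels
        np.testing.assert_array_equal(back.coords, path.coords)
        np.testing.assert_array_equal(back.energies, path.energies)

    def test_default_q_is_cumulative_arc_length(self):
        coords = np.zeros((3, 2, 3))
        coords[1:, 0, 0] = 3.0  # atom 0 moves 3 A on segment 1, then rests
        coords[2, 1, 1] = 4.0  # atom 1 moves 4 A on segment 2
        path = ReactionPath(labels=["a", "b"], coords=coords)
        np.testing.assert_allclose(path.q_irc, [0.0, 3.0, 7.0])

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError, match="3 images"):
            ReactionPath(labels=["a"], coords=np.zeros((2, 1, 3)))


class TestBarriers:
    def test_published_fixture_barriers(self):
        s = barrier_summary(published_levels_eq())
        assert s.forward_1 == pytest.approx(0.574, abs=1e-12)
        assert s.asymmetry == pytest.approx(0.507, abs=1e-12)
        assert s.reverse_2 == pytest.approx(0.058, abs=1e-12)

    def test_algebraic_identities_on_random_levels(self, rng):
        for _ in range(50):
            e = rng.normal(0, 1, 4)
            lv = EnergyLevels(separation=0.0, e_ts1=e[0], e_intermediate=e[1],
                              e_ts2=e[2], e_tautomer=e[3])
            s = barrier_summary(lv)
            assert s.forward_1 == e[0]
            assert s.forward_2 == e[2] - e[1]
            assert s.reverse_1 == e[0] - e[1]
            assert s.reverse_2 == e[2] - e[3]
            assert s.asymmetry == e[3]
            assert s.reverse_2 + s.asymmetry == pytest.approx(e[2], abs=1e-15)

    def test_all_zero_levels(self):
        s = barrier_summary(EnergyLevels(0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
        assert (s.forward_1, s.forward_2, s.reverse_1, s.reverse_2, s.asymmetry) == (
            0.0, 0.0, 0.0, 0.0, 0.0,
        )

    def test_missing_level_flagged(self):
        lv = EnergyLevels(separation=0.0, e_ts1=0.5)
        with pytest.warns(UserWarning, match="missing"):
            s = barrier_summary(lv)
        assert "e_tautomer" in s.missing
        assert np.isnan(s.asymmetry)

    def test_canonical_reference_shift(self):
        lv = EnergyLevels(separation=0.0, e_canonical=1.0, e_ts1=1.574,
                          e_intermediate=1.399, e_ts2=1.565, e_tautomer=1.507)
        s = barrier_summary(lv)
        assert s.forward_1 == pytest.approx(0.574)
        assert s.asymmetry == pytest.approx(0.507)


class TestBarrierTrend:
    def test_exact_linear_levels_recovered(self):
        levels = [
            EnergyLevels(separation=s, e_ts1=0.5 + 1.3 * s, e_intermediate=0.3,
                         e_ts2=0.6, e_tautomer=0.5)
            for s in (0.0, 0.5, 1.0, 2.0)
        ]
        t = barrier_trend(levels)
        assert t.slope == pytest.approx(1.3, abs=1e-12)
        assert t.r_squared == pytest.approx(1.0, abs=1e-12)
        assert t.monotonic

    def test_printed_endpoint_barriers(self):
        levels = [
            EnergyLevels(separation=0.0, e_ts1=0.57, e_intermediate=0.0,
                         e_ts2=0.0, e_tautomer=0.0),
            EnergyLevels(separation=3.0, e_ts1=4.80, e_intermediate=0.0,
                         e_ts2=0.0, e_tautomer=0.0),
        ]
        t = barrier_trend(levels)
        assert t.slope == pytest.approx(4.23 / 3.0, abs=1e-12)
        assert t.monotonic

    def test_constant_barriers_zero_slope(self):
        levels = [
            EnergyLevels(separation=s, e_ts1=0.5, e_intermediate=0.3,
                         e_ts2=0.6, e_tautomer=0.5)
            for s in (0.0, 1.0, 2.0)
        ]
        t = barrier_trend(levels)
        assert t.slope == pytest.approx(0.0, abs=1e-12)
        assert t.r_squared == pytest.approx(1.0)

    def test_duplicate_separations_averaged(self):
        levels = [
            EnergyLevels(separation=0.0, e_ts1=0.4, e_intermediate=0, e_ts2=0, e_tautomer=0),
            EnergyLevels(separation=0.0, e_ts1=0.6, e_intermediate=0, e_ts2=0, e_tautomer=0),
            EnergyLevels(separation=1.0, e_ts1=1.5, e_intermediate=0, e_ts2=0, e_tautomer=0),
        ]
        t = barrier_trend(levels)
        assert t.slope == pytest.approx(1.0, abs=1e-12)


class TestSurvivalThreshold:
    def test_characteristic_speed_gives_1p7_ps(self):
        t = survival_threshold(2.0, 1.2)
        assert t == pytest.approx(5 / 3, abs=1e-12)
        assert round(t, 1) == 1.7

    @pytest.mark.parametrize("dist,speed,expected", [(2.0, 2.0, 1.0), (0.0, 1.2, 0.0)])
    def test_simple_ratios(self, dist, speed, expected):
        assert survival_threshold(dist, speed) == pytest.approx(expected)

    def test_homogeneous_in_distance(self):
        assert survival_threshold(4.0, 1.2) == pytest.approx(2 * survival_threshold(2.0, 1.2))

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            survival_threshold(2.0, 0.0)


class TestLevelTables:
    def test_roundtrip_and_reference_shift(self, tmp_path):
        levels = [
            EnergyLevels(separation=0.0, e_ts1=0.574, e_intermediate=0.399,
                         e_ts2=0.565, e_tautomer=0.507),
            EnergyLevels(separation=1.0, e_ts1=1.2, e_intermediate=0.8,
                         e_ts2=1.1, e_tautomer=0.9),
        ]
        f = tmp_path / "levels.csv"
        write_energy_levels(levels, f)
        back = read_energy_levels(f)
        assert len(back) == 2
        assert back[0].e_ts1 == pytest.approx(0.574)
        assert back[0].e_canonical == 0.0

    def test_missing_column_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("separation_A,E_can\n0.0,0.0\n")
        with pytest.raises(ValueError, match="E_ts1"):
            read_energy_levels(f)
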