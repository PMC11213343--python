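import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pbpsensor import (
    AnalysisConfig,
    HingeSpec,
    build_pearson_matrix,
    generate_hinge_trajectory,
    hysteresis_contact_series,
    mean_pearson_matrix,
    pair_min_distance_series,
    pearson_vs_time,
    two_structure_matrix,
)
from pbpsensor.contacts import PearsonMatrix

from conftest import make_structure, make_trajectory, matrix_from_pixels
from oracles import hysteresis_oracle, pearson_oracle


class TestPairMinDistance:
    def test_constant_single_atom_residues(self):
        frames = np.array(
            [[[0.0, 0, 0], [4.0, 0, 0]], [[0.0, 0, 0], [4.0, 0, 0]]]
        )
        traj = make_trajectory(frames)
        series = pair_min_distance_series(traj, 1, 2, "all")
        np.testing.assert_allclose(series.distances, 4.0)

    def test_multi_atom_min_matches_exhaustive_enumeration(self, rng):
        coords = rng.uniform(0, 15, size=(3, 4, 3))  # frames x (2 res x 2 atoms)
        traj = make_trajectory(
            coords,
            residue_ids=[1, 1, 2, 2],
            atom_names=["CA", "CB"] * 2,
        )
        series = pair_min_distance_series(traj, 1, 2, "all")
        for f in range(3):
            brute = min(
                np.linalg.norm(coords[f, a] - coords[f, b])
                for a, b in itertools.product([0, 1], [2, 3])
            )
            assert series.distances[f] == pytest.approx(brute, abs=1e-12)

    def test_same_residue_errors(self, rng):
        traj = make_trajectory(rng.uniform(0, 5, size=(2, 3, 3)))
        with pytest.raises(ValueError, match="distinct"):
            pair_min_distance_series(traj, 2, 2)


class TestHysteresis:
    @pytest.mark.parametrize(
        "distances, expected",
        [
            ([9.0, 8.5, 10.0], [False, False, False]),  # never forms
            ([4.0, 6.0, 7.9, 8.1, 6.0], [True, True, True, False, False]),
            ([6.0, 4.9, 7.0, 9.0, 4.5], [False, True, True, False, True]),
        ],
    )
    def test_hand_traced_state_machine(self, distances, expected):
        series = hysteresis_contact_series(np.array(distances))
        assert list(series.in_contact) == expected

    def test_matches_transition_table_oracle_on_random_series(self, rng):
        cfg = AnalysisConfig()
        for _ in range(1000):
            d = rng.uniform(3.0, 10.0, size=rng.integers(2, 40))
            got = hysteresis_contact_series(d, cfg).in_contact
            want = hysteresis_oracle(d, cfg.r_start, cfg.r_end)
            assert np.array_equal(got, want)

    def test_ever_in_contact_is_or_of_flags(self, rng):
        d = rng.uniform(3.0, 10.0, size=20)
        series = hysteresis_contact_series(d)
        assert series.ever_in_contact == bool(np.any(series.in_contact))


class TestPearsonVsTime:
    def test_monotone_series_give_exact_unit_correlation(self):
        t = np.arange(5.0)
        assert pearson_vs_time(np.array([1.0, 2, 3, 4, 5]), t) == 1.0
        assert pearson_vs_time(np.array([5.0, 4, 3, 2, 1]), t) == -1.0

    def test_constant_series_gives_zero_by_convention(self):
        assert pearson_vs_time(np.full(6, 4.2), np.arange(6.0)) == 0.0

    def test_matches_textbook_formula_on_random_series(self, rng):
        cfg = AnalysisConfig()
        for _ in range(1000):
            n = rng.integers(2, 30)
            d = rng.uniform(1.0, 7.5, size=n)  # below r_end: no truncation
            t = np.sort(rng.uniform(0, 10, size=n))
            while len(np.unique(t)) < n:
                t = np.sort(rng.uniform(0, 10, size=n))
            assert pearson_vs_time(d, t, cfg) == pytest.approx(
                pearson_oracle(d, t), abs=1e-12
            )

    def test_truncation_at_r_end(self):
        # far excursions are clipped: series constant after clipping -> 0
        d = np.array([9.0, 10.0, 11.0, 12.0])
        assert pearson_vs_time(d, np.arange(4.0)) == 0.0

    def test_indicator_mode_sign_convention(self):
        # contact early, lost late -> positive (closed-state contact)
        d = np.array([4.0, 4.0, 9.0, 9.0])
        assert pearson_vs_time(d, np.arange(4.0), mode="indicator") > 0

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            pearson_vs_time(np.array([1.0]), np.array([0.0]))


class TestBuildMatrix:
    def test_static_trajectory_gives_zero_matrix(self, rng):
        frame = rng.uniform(0, 20, size=(6, 3))
        traj = make_trajectory([frame] * 5)
        M = build_pearson_matrix(traj, selection_mode="all")
        np.testing.assert_array_equal(M.values, 0.0)

    def test_designed_hinge_pair_is_plus_one_with_mirror(self, hinge):
        traj, truth = hinge
        M = build_pearson_matrix(traj)
        i, j, sign = truth.designed_pairs[0]
        assert M.pixel(i, j) == pytest.approx(1.0 * sign, abs=1e-12)
        assert M.pixel(j, i) == M.pixel(i, j)

    def test_matrix_equals_transpose_exactly(self, hinge):
        M = build_pearson_matrix(hinge[0])
        np.testing.assert_array_equal(M.values, M.values.T)

    def test_neighbor_band_and_diagonal_are_zero(self, hinge):
        M = build_pearson_matrix(hinge[0])
        n = M.n
        for a in range(n):
            for b in range(n):
                if abs(a - b) <= 2:
                    assert M.values[a, b] == 0.0

    def test_invariant_to_rigid_body_motion_of_frames(self, hinge, rng):
        traj, _ = hinge
        M0 = build_pearson_matrix(traj)
        frames = []
        for f in traj.frames:
            R = Rotation.random(random_state=int(rng.integers(1 << 16))).as_matrix()
            frames.append(f @ R.T + rng.normal(size=3) * 25)
        moved = make_trajectory(frames, frame_times=traj.frame_times)
        M1 = build_pearson_matrix(moved)
        np.testing.assert_allclose(M1.values, M0.values, atol=1e-9)


class TestMeanMatrix:
    def test_single_matrix_is_identity(self):
        M = matrix_from_pixels(6, {(1, 4): 0.5})
        out = mean_pearson_matrix([M])
        np.testing.assert_array_equal(out.values, M.values)

    def test_opposite_pixels_cancel(self):
        a = matrix_from_pixels(6, {(1, 4): 1.0})
        b = matrix_from_pixels(6, {(1, 4): -1.0})
        assert mean_pearson_matrix([a, b]).pixel(1, 4) == 0.0

    def test_three_way_mean(self):
        ms = [matrix_from_pixels(6, {(2, 5): v}) for v in (0.2, 0.4, 0.9)]
        assert mean_pearson_matrix(ms).pixel(2, 5) == pytest.approx(0.5)

    def test_shape_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_pearson_matrix([])
        with pytest.raises(ValueError):
            mean_pearson_matrix(
                [matrix_from_pixels(5, {}), matrix_from_pixels(6, {})]
            )


class TestTwoStructureMatrix:
    @staticmethod
    def _line(spacing, y_last=0.0):
        coords = np.zeros((5, 3))
        coords[:, 0] = np.arange(5) * spacing
        coords[4, 1] = y_last
        return make_structure(coords)

    def test_identical_structures_give_zeros(self):
        s = self._line(6.0)
        M = two_structure_matrix(s, s, selection_mode="all")
        np.testing.assert_array_equal(M.values, 0.0)

    def test_contact_lost_in_second_structure_is_plus_one(self):
        a = make_structure([[0.0, 0, 0], [20, 0, 0], [40, 0, 0], [4.0, 0, 0.5]])
        b = make_structure([[0.0, 0, 0], [20, 0, 0], [40, 0, 0], [10.0, 0, 0.5]])
        M = two_structure_matrix(a, b, selection_mode="all")
        assert M.pixel(1, 4) == 1.0

    def test_values_restricted_to_sign_set(self, rng):
        a = make_structure(rng.uniform(0, 12, size=(6, 3)))
        b = make_structure(rng.uniform(0, 12, size=(6, 3)))
        M = two_structure_matrix(a, b, selection_mode="all")
        assert set(np.unique(M.values)) <= {-1.0, 0.0, 1.0}

    def test_numbering_mismatch_errors(self):
        a = self._line(6.0)
        b = make_structure(a.coords, residue_ids=np.arange(2, 7))
        with pytest.raises(ValueError, match="numbering"):
            two_structure_matrix(a, b)


class TestMatrixIO:
    def test_dense_tsv_round_trip(self, tmp_path, rng):
        M = matrix_from_pixels(7, {(3, 7): 0.25, (4, 8): -0.75}, offset=3)
        path = tmp_path / "m.tsv"
        M.write_tsv(path)
        back = PearsonMatrix.read_tsv(path)
        np.testing.assert_allclose(back.values, M.values, atol=1e-6)
        assert np.array_equal(back.residue_ids, M.residue_ids)

    def test_long_tsv_lists_nonzero_upper_pixels(self, tmp_path):
        M = matrix_from_pixels(5, {(1, 4): 0.5, (2, 5): -0.5})
        path = tmp_path / "long.tsv"
        M.write_long_tsv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "res_i\tres_j\tvalue"
        assert len(lines) == 3
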