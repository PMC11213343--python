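import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pbpsensor import (
    AnalysisConfig,
    State,
    ca_pseudo_dihedral,
    classify_state,
    delta_dihe_structures,
    ensemble_delta,
    rmsd_series,
    rmsf_profile,
    superpose,
)
from pbpsensor.metrics import (
    ResidueProfile,
    RmsdSeries,
    _torsion_deg,
    circular_mean_deg,
    dihedral_profile,
    wrap_angle,
)
from pbpsensor.trajectory import AtomSelection

from conftest import make_structure, make_trajectory
from oracles import torsion_arccos_oracle


class TestSuperpose:
    def test_identity_gives_zero_rmsd(self, rng):
        pts = rng.normal(size=(10, 3))
        _, _, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(10, 3))
        _, _, rmsd = superpose(pts + [5.0, 0.0, 0.0], pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_rotation(self, rng):
        pts = rng.normal(size=(10, 3))
        true = Rotation.random(random_state=7).as_matrix()
        R, t, rmsd = superpose(pts @ true.T, pts)
        assert rmsd < 1e-8
        np.testing.assert_allclose(R, true.T, atol=1e-8)

    def test_fit_never_increases_rmsd(self, rng):
        for _ in range(20):
            a = rng.normal(size=(8, 3))
            b = rng.normal(size=(8, 3))
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            _, _, fitted = superpose(a, b)
            assert fitted <= raw + 1e-10

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            superpose(line, line)
        with pytest.raises(ValueError, match="mismatch"):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmsdSeries:
    def test_static_trajectory_is_all_zero(self, rng):
        frame = rng.normal(size=(6, 3))
        traj = make_trajectory([frame] * 4)
        series = rmsd_series(traj, traj.structure_at(0))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-6)

    def test_single_atom_displacement_without_fit(self):
        frames = np.zeros((2, 3, 3))
        frames[0] = [[0, 0, 0], [5, 0, 0], [10, 0, 0]]
        frames[1] = frames[0]
        frames[1, 1, 0] += 3.0  # displace middle atom 3 Å in frame 2
        traj = make_trajectory(frames)
        sel = AtomSelection(np.array([1]), "one")
        series = rmsd_series(traj, traj.structure_at(0), selection=sel, fit=False)
        np.testing.assert_allclose(series.values, [0.0, 3.0])

    def test_length_matches_frame_count(self, rng):
        traj = make_trajectory(rng.normal(size=(7, 5, 3)))
        series = rmsd_series(traj, traj.structure_at(0))
        assert len(series.values) == 7


class TestClassifyState:
    @staticmethod
    def _series(level):
        return RmsdSeries(
            values=np.full(101, float(level)), frame_times=np.arange(101.0)
        )

    def test_low_rmsd_is_closed_at_defaults(self):
        assert classify_state(self._series(1.0)).state is State.CLOSED

    def test_high_rmsd_is_open_at_defaults(self):
        assert classify_state(self._series(3.0)).state is State.OPEN

    def test_exact_threshold_is_open(self):
        assert classify_state(self._series(2.5)).state is State.OPEN

    def test_short_series_errors(self):
        short = RmsdSeries(values=np.ones(5), frame_times=np.arange(5.0))
        with pytest.raises(ValueError, match="shorter than window"):
            classify_state(short)

    def test_lowering_threshold_never_opens_to_closed(self, rng):
        levels = rng.uniform(0.5, 5.0, size=30)
        for lev in levels:
            hi = classify_state(self._series(lev), AnalysisConfig(rmsd_threshold=2.5))
            lo = classify_state(self._series(lev), AnalysisConfig(rmsd_threshold=1.5))
            if hi.state is State.OPEN:
                assert lo.state is State.OPEN


class TestPseudoDihedral:
    def test_planar_cis_is_zero(self):
        ang = _torsion_deg(
            np.array([0.0, 0, 0]),
            np.array([1.0, 0, 0]),
            np.array([1.0, 1, 0]),
            np.array([0.0, 1, 0]),
        )
        assert float(ang) == pytest.approx(0.0, abs=1e-10)

    def test_planar_trans_is_180(self):
        ang = _torsion_deg(
            np.array([0.0, 0, 0]),
            np.array([1.0, 0, 0]),
            np.array([1.0, 1, 0]),
            np.array([2.0, 1, 0]),
        )
        assert float(ang) == pytest.approx(180.0, abs=1e-10)

    def test_matches_arccos_oracle_on_random_quadruples(self, rng):
        for _ in range(100):
            quad = rng.normal(size=(4, 3)) * 3
            try:
                expected = torsion_arccos_oracle(*quad)
            except ZeroDivisionError:  # pragma: no cover
                continue
            got = float(_torsion_deg(*quad))
            assert got == pytest.approx(expected, abs=1e-6)

    def test_structure_level_accessor_and_errors(self):
        coords = np.array(
            [[0.0, 0, 0], [3.8, 0, 0], [5.0, 3.0, 1.0], [8.0, 3.5, -1.0]]
        )
        s = make_structure(coords)
        assert ca_pseudo_dihedral(s, 2) == pytest.approx(
            torsion_arccos_oracle(*coords), abs=1e-8
        )
        with pytest.raises(IndexError):
            ca_pseudo_dihedral(s, 1)  # first residue: no i-1
        with pytest.raises(IndexError):
            ca_pseudo_dihedral(s, 3)  # last two residues undefined

    def test_colinear_geometry_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 1, 0]])
        with pytest.raises(ValueError, match="colinear"):
            _torsion_deg(*line)


class TestDeltaDihe:
    @staticmethod
    def _zigzag(n, rng=None):
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * 3.8
        coords[1::2, 1] = 2.0
        coords[::3, 2] = 1.0
        return coords

    def test_identical_structures_give_zero_profile(self):
        s = make_structure(self._zigzag(8))
        prof = delta_dihe_structures(s, s)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-9)
        # defined for all but first residue and last two
        assert list(prof.residue_ids) == list(range(2, 7))

    def test_wraparound_difference(self):
        assert float(np.abs(wrap_angle(170.0 - (-170.0)))) == pytest.approx(20.0)
        assert float(np.abs(wrap_angle(179.0 - (-179.0)))) == pytest.approx(2.0)

    def test_invariant_to_rigid_body_motion(self, rng):
        a = make_structure(self._zigzag(8))
        R = Rotation.random(random_state=3).as_matrix()
        b = make_structure(self._zigzag(8) @ R.T + [10.0, -4.0, 2.0])
        prof = delta_dihe_structures(a, b)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-7)

    def test_numbering_mismatch_errors(self):
        a = make_structure(self._zigzag(8))
        b = make_structure(self._zigzag(8), residue_ids=np.arange(2, 10))
        with pytest.raises(ValueError, match="numbering"):
            delta_dihe_structures(a, b)


class TestRmsf:
    def test_static_trajectory_gives_zero(self, rng):
        frame = rng.normal(size=(5, 3)) * 4
        traj = make_trajectory([frame] * 6)
        prof = rmsf_profile(traj)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-9)

    def test_two_level_oscillation_without_fit(self):
        base = np.array(
            [[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0.0, 3.8, 1.0]]
        )
        frames = []
        for k in range(6):
            f = base.copy()
            f[2, 0] += 1.0 if k % 2 == 0 else -1.0  # ±1 Å about the mean
            frames.append(f)
        prof = rmsf_profile(make_trajectory(frames), fit=False)
        assert prof.values[2] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(np.delete(prof.values, 2), 0.0, atol=1e-12)

    def test_invariant_to_rigid_body_motion_of_frames(self, rng):
        frames = rng.normal(size=(8, 6, 3)) * 0.3 + np.arange(6)[:, None] * 3.0
        traj = make_trajectory(frames)
        ref_prof = rmsf_profile(traj)
        moved = []
        for f in frames:
            R = Rotation.random(random_state=int(rng.integers(1 << 16))).as_matrix()
            moved.append(f @ R.T + rng.normal(size=3) * 10)
        prof = rmsf_profile(make_trajectory(moved))
        np.testing.assert_allclose(prof.values, ref_prof.values, atol=1e-6)


class TestEnsembleDelta:
    @staticmethod
    def _prof(vals, metric="rmsf"):
        return ResidueProfile(np.arange(1, len(vals) + 1), np.array(vals), metric)

    def test_identical_ensembles_give_zero(self):
        p = self._prof([1.0, 2.0, 3.0])
        out = ensemble_delta([p], [p], "rmsf")
        np.testing.assert_allclose(out.values, 0.0)

    def test_rmsf_means_cancel(self):
        closed = [self._prof([2.0])]
        open_ = [self._prof([1.0]), self._prof([3.0])]
        out = ensemble_delta(closed, open_, "rmsf")
        assert out.values[0] == pytest.approx(0.0)

    def test_dihedral_wrapped_subtraction(self):
        out = ensemble_delta(
            [self._prof([179.0])], [self._prof([-179.0])], "dihedral"
        )
        assert out.values[0] == pytest.approx(2.0)

    def test_empty_state_group_errors(self):
        with pytest.raises(ValueError):
            ensemble_delta([], [self._prof([1.0])], "rmsf")

    def test_circular_mean_near_branch_cut(self):
        assert circular_mean_deg(np.array([179.0, -179.0])) == pytest.approx(
            180.0, abs=1e-9
        ) or circular_mean_deg(np.array([179.0, -179.0])) == pytest.approx(
            -180.0, abs=1e-9
        )
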