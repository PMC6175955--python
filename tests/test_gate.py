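"""Gate COM-distance geometry on toy trajectories."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import hdxdiff as hd
from hdxdiff.errors import ParameterError, SelectionError, ValidationError
from hdxdiff.gate import ATOMIC_MASSES

from conftest import write_pdb


def _series(coords_per_frame, resids, times_ns):
    """Cα-only FrameSeries from raw coordinate arrays."""
    n = len(resids)
    return hd.FrameSeries(
        coordinates=np.asarray(coords_per_frame, dtype=float),
        resids=np.asarray(resids),
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        times_ns=np.asarray(times_ns, dtype=float),
    )


def _two_group_frame(d):
    """Six Cα atoms: group {1,2,3} centered at origin, group {11,12,13}
    centered at (d, 0, 0)."""
    return np.array([
        [-1.0, 0, 0], [1.0, 0, 0], [0.0, 0, 0],
        [d - 1.0, 0, 0], [d + 1.0, 0, 0], [d, 0, 0],
    ])


GATE = hd.GateDefinition(group1=(1, 2, 3), group2=(11, 12, 13))
RESIDS = [1, 2, 3, 11, 12, 13]


class TestGateDefinition:
    def test_range_parsing(self):
        assert hd.parse_residue_ranges("75-80,149-154") == tuple(
            list(range(75, 81)) + list(range(149, 155))
        )
        assert hd.parse_residue_ranges("7") == (7,)

    def test_default_xyle_gate(self):
        g = hd.XYLE_INTRACELLULAR_GATE
        assert 75 in g.group1 and 165 in g.group1 and 16 not in g.group1
        assert 404 in g.group2
        assert not set(g.group1) & set(g.group2)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValidationError):
            hd.GateDefinition(group1=(1, 2), group2=(2, 3))

    def test_descending_range_rejected(self):
        with pytest.raises(ParameterError):
            hd.parse_residue_ranges("160-16")


class TestCenterOfMass:
    def test_single_atom(self):
        com = hd.center_of_mass([[1.0, 2.0, 3.0]], [12.0])
        assert np.allclose(com, [1, 2, 3])

    def test_equal_mass_midpoint(self):
        com = hd.center_of_mass([[0, 0, 0], [2, 0, 0]], [12.0, 12.0])
        assert np.allclose(com, [1, 0, 0])

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        xyz = rng.normal(size=(10, 3))
        m = rng.uniform(1, 30, size=10)
        com = hd.center_of_mass(xyz, m)
        oracle = np.zeros(3)
        for i in range(10):
            oracle += m[i] * xyz[i]
        oracle /= m.sum()
        assert np.allclose(com, oracle, atol=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(SelectionError):
            hd.center_of_mass(np.empty((0, 3)), [])


class TestGateDistance:
    def test_three_four_five(self):
        coords = np.array([
            [0, 0, 0], [0, 0, 0], [0, 0, 0],
            [3, 4, 0], [3, 4, 0], [3, 4, 0],
        ])
        s = _series([coords], RESIDS, [0.0])
        assert hd.gate_distance(s, GATE) == pytest.approx(5.0)

    def test_hand_placed_six_atoms(self):
        s = _series([_two_group_frame(7.5)], RESIDS, [0.0])
        assert hd.gate_distance(s, GATE) == pytest.approx(7.5)

    def test_symmetric_under_group_swap(self):
        s = _series([_two_group_frame(9.0)], RESIDS, [0.0])
        swapped = hd.GateDefinition(group1=GATE.group2, group2=GATE.group1)
        assert hd.gate_distance(s, GATE) == pytest.approx(
            hd.gate_distance(s, swapped)
        )

    def test_missing_residue_listed(self):
        s = _series([_two_group_frame(9.0)], RESIDS, [0.0])
        gate = hd.GateDefinition(group1=(1, 2, 3, 99), group2=(11, 12, 13))
        with pytest.raises(SelectionError, match="99"):
            hd.gate_distance(s, gate)

    @given(st.integers(0, 2**31 - 1))
    def test_rigid_body_invariance(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.normal(scale=5.0, size=(6, 3))
        s = _series([frame], RESIDS, [0.0])
        d0 = hd.gate_distance(s, GATE)
        q = rng.normal(size=4)
        rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        shift = rng.normal(scale=50.0, size=3)
        s2 = _series([frame @ rot.T + shift], RESIDS, [0.0])
        assert hd.gate_distance(s2, GATE) == pytest.approx(d0, abs=1e-9)

    def test_matches_brute_force_mass_weighted_sum(self):
        rng = np.random.default_rng(11)
        frame = rng.normal(scale=8.0, size=(6, 3))
        s = _series([frame], RESIDS, [0.0])
        m = ATOMIC_MASSES["C"]
        com1 = sum(m * frame[i] for i in range(3)) / (3 * m)
        com2 = sum(m * frame[i] for i in range(3, 6)) / (3 * m)
        oracle = float(np.sqrt(((com1 - com2) ** 2).sum()))
        assert hd.gate_distance(s, GATE) == pytest.approx(oracle, abs=1e-9)


class TestTrace:
    def test_static_trajectory_constant_trace(self):
        frame = _two_group_frame(9.0)
        s = _series([frame] * 5, RESIDS, np.arange(5.0))
        trace = hd.distance_trace(s, GATE)
        assert len(trace) == 5
        assert np.allclose(trace["distance_A"], 9.0)

    def test_translating_trajectory_constant_trace(self):
        frame = _two_group_frame(9.0)
        frames = [frame + k * np.array([1.0, -2.0, 0.5]) for k in range(8)]
        s = _series(frames, RESIDS, np.arange(8.0))
        trace = hd.distance_trace(s, GATE)
        assert np.allclose(trace["distance_A"], 9.0, atol=1e-12)

    def test_times_preserved_in_order(self):
        frame = _two_group_frame(9.0)
        times = [0.0, 0.5, 1.5, 4.0]
        s = _series([frame] * 4, RESIDS, times)
        assert list(hd.distance_trace(s, GATE)["time_ns"]) == times


class TestTrailingDistribution:
    def _two_level_trace(self, n=100, hi=13.0, lo=9.0):
        frames = [_two_group_frame(hi)] * (n // 2) + \
                 [_two_group_frame(lo)] * (n // 2)
        s = _series(frames, RESIDS, np.arange(float(n)))
        return hd.distance_trace(s, GATE)

    def test_single_valued_trace(self):
        trace = hd.distance_trace(
            _series([_two_group_frame(9.0)] * 3, RESIDS, np.arange(3.0)), GATE
        )
        hist = hd.trailing_distribution(trace, window_ns=2.0)
        widths = hist["bin_right_A"] - hist["bin_left_A"]
        assert (hist["density"] > 0).sum() == 1
        assert float((hist["density"] * widths).sum()) == pytest.approx(1.0)

    def test_window_equal_to_span_uses_all_frames(self):
        trace = self._two_level_trace()
        hist = hd.trailing_distribution(trace, window_ns=99.0, bins=10)
        # both levels present: mass near 9 and near 13
        centers = (hist["bin_left_A"] + hist["bin_right_A"]) / 2
        assert (hist["density"][centers < 10] > 0).any()
        assert (hist["density"][centers > 12] > 0).any()

    def test_two_level_trace_trailing_half_is_unimodal_low(self):
        trace = self._two_level_trace()
        hist = hd.trailing_distribution(trace, window_ns=49.0, bins=20)
        assert hd.distribution_mode(hist) == pytest.approx(9.0, abs=0.5)
        widths = hist["bin_right_A"] - hist["bin_left_A"]
        assert float((hist["density"] * widths).sum()) == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(1, 100))
    def test_density_integrates_to_one_for_any_binning(self, bins):
        trace = self._two_level_trace()
        hist = hd.trailing_distribution(trace, window_ns=99.0, bins=bins)
        widths = hist["bin_right_A"] - hist["bin_left_A"]
        assert float((hist["density"] * widths).sum()) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_oversized_window_rejected(self):
        trace = self._two_level_trace()
        with pytest.raises(ParameterError):
            hd.trailing_distribution(trace, window_ns=1000.0)


class TestReaders:
    def _write_multimodel(self, tmp_path, frames):
        residues = [
            (r, "ALA", [("CA", "C", (0.0, 0.0, 0.0))]) for r in RESIDS
        ]
        return write_pdb(tmp_path / "traj.pdb", residues, multi=frames)

    def test_multimodel_pdb_round_trip(self, tmp_path):
        frames = [_two_group_frame(13.0), _two_group_frame(9.0)]
        path = self._write_multimodel(tmp_path, frames)
        s = hd.FrameSeries.from_multimodel_pdb(path, frame_interval_ns=10.0)
        assert s.n_frames == 2
        assert list(s.times_ns) == [0.0, 10.0]
        trace = hd.distance_trace(s, GATE)
        assert list(trace["distance_A"]) == pytest.approx([13.0, 9.0], abs=1e-3)

    def test_times_are_never_guessed(self, tmp_path):
        path = self._write_multimodel(tmp_path, [_two_group_frame(9.0)])
        with pytest.raises(ParameterError, match="never guessed"):
            hd.FrameSeries.from_multimodel_pdb(path)
        with pytest.raises(ParameterError):
            hd.FrameSeries.from_multimodel_pdb(
                path, frame_interval_ns=1.0, times_ns=[0.0]
            )

    def test_frames_table_round_trip(self, tmp_path):
        frames = [_two_group_frame(13.0), _two_group_frame(9.0)]
        s = _series(frames, RESIDS, [0.0, 5.0])
        path = tmp_path / "frames.tsv"
        s.to_frames_table(path)
        back = hd.FrameSeries.from_frames_table(path)
        assert back.n_frames == 2
        assert np.allclose(back.coordinates, s.coordinates, atol=1e-6)
        assert list(back.times_ns) == [0.0, 5.0]

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValidationError):
            _series([_two_group_frame(9.0)] * 2, RESIDS, [1.0, 0.0])
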