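"""Distance series, binned frequency tables, occupancy, rings, RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pocket_eda.synthetic_data import (HBondSpec, ToyTrajectory,
                                       make_hbond_trajectory, mixture_cdf)
from pocket_eda.trajectory_stats import (HBondSeries, RingPair,
                                         TrajectoryInputError,
                                         bin_hbond_series,
                                         binding_power_fractions,
                                         fraction_below, hbond_series,
                                         histogram_frame, occupancy,
                                         ring_centroid_series, rmsd_series)


def toy(frames, labels=None):
    frames = np.asarray(frames, dtype=float)
    labels = labels or ["X"] * frames.shape[1]
    return ToyTrajectory(frames, labels)


class TestHBondSeries:
    def test_single_frame_distance(self):
        t = toy([[[0, 0, 0], [2.0, 0, 0]]])
        s = hbond_series(t, (0, 1))
        assert s.distances.tolist() == [2.0]

    def test_multi_frame_hand_computed(self):
        frames = [[[0, 0, 0], [1.8, 0, 0]],
                  [[0, 0, 0], [2.2, 0, 0]],
                  [[0, 0, 0], [3.0, 0, 0]]]
        s = hbond_series(toy(frames), (0, 1))
        assert np.allclose(s.distances, [1.8, 2.2, 3.0])

    def test_zero_variance_synthetic_series(self):
        traj = make_hbond_trajectory(
            [HBondSpec("c", ((1.0, 2.0, 0.0),), 10)], seed=1)
        s = hbond_series(traj, traj.monitored_pairs["c"], bond_id="c")
        assert np.all(s.distances == 2.0)

    def test_index_out_of_range(self):
        t = toy([[[0, 0, 0], [2.0, 0, 0]]])
        with pytest.raises(TrajectoryInputError):
            hbond_series(t, (0, 5))


class TestBinning:
    def test_three_value_example(self):
        s = HBondSeries("b", [1.625, 1.626, 1.874])
        h = bin_hbond_series(s)
        assert h.frequencies[0] == pytest.approx(200 / 3, abs=1e-9)
        assert h.frequencies[1] == pytest.approx(100 / 3, abs=1e-9)
        assert h.frequencies[2:].sum() == 0

    def test_out_of_range_counts_in_denominator(self):
        s = HBondSeries("b", [5.0] * 100)
        h = bin_hbond_series(s)
        assert np.all(h.frequencies == 0)
        assert h.n_frames_total == 100
        assert h.out_of_range == 100

    def test_constant_series_single_bin(self):
        s = HBondSeries("b", [2.125] * 50)
        h = bin_hbond_series(s)
        k = int(np.argmax(h.frequencies))
        assert h.bin_centers[k] == pytest.approx(2.125)
        assert h.frequencies[k] == 100.0

    def test_edge_value_goes_to_upper_bin(self):
        h = bin_hbond_series(HBondSeries("b", [1.75]))
        assert h.frequencies[1] == 100.0     # bin centered 1.875
        assert h.frequencies[0] == 0.0

    def test_default_bin_centers(self):
        h = bin_hbond_series(HBondSeries("b", [2.0]))
        assert np.allclose(h.bin_centers,
                           [1.625, 1.875, 2.125, 2.375,
                            2.625, 2.875, 3.125, 3.375])

    def test_empty_series_rejected(self):
        with pytest.raises(TrajectoryInputError):
            HBondSeries("b", [])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.5, max_value=6.0,
                              allow_nan=False), min_size=1, max_size=200))
    def test_histogram_conservation(self, values):
        h = bin_hbond_series(HBondSeries("b", values))
        assert h.counts.sum() + h.out_of_range == len(values)

    def test_frequencies_converge_to_mixture_probabilities(
            self, bimodal_trajectory):
        specs, traj = bimodal_trajectory
        for spec in specs:
            s = hbond_series(traj, traj.monitored_pairs[spec.bond_id],
                             bond_id=spec.bond_id)
            h = bin_hbond_series(s)
            for k in range(len(h.bin_centers)):
                lo, hi = h.bin_interval(k)
                p = 100 * (mixture_cdf(spec.mixture, hi)
                           - mixture_cdf(spec.mixture, lo))
                assert abs(h.frequencies[k] - p) < 2.0


class TestOccupancy:
    def test_hand_counted(self):
        s = HBondSeries("b", [1.8, 2.2, 4.0])
        assert occupancy(s, 3.5) == pytest.approx(200 / 3)

    def test_limits(self):
        s = HBondSeries("b", [1.8, 2.2, 4.0])
        assert occupancy(s, np.inf) == 100.0
        assert occupancy(s, 1.0) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.5, max_value=6.0,
                              allow_nan=False), min_size=1, max_size=100),
           st.floats(min_value=0.5, max_value=6.0),
           st.floats(min_value=0.0, max_value=2.0))
    def test_monotone_in_cutoff(self, values, cutoff, delta):
        s = HBondSeries("b", values)
        assert occupancy(s, cutoff + delta) >= occupancy(s, cutoff)

    def test_binding_power_fractions_sum_to_100(self):
        s = HBondSeries("b", [1.8, 2.1, 2.7, 3.2])
        f = binding_power_fractions(s)
        assert f["strong"] + f["medium"] + f["weak"] == pytest.approx(100.0)
        assert f["strong"] == pytest.approx(25.0)


class TestRings:
    def triangle(self, center):
        c = np.asarray(center, dtype=float)
        return [c + [0, 1, 0], c + [0, -0.5, 0.87], c + [0, -0.5, -0.87]]

    def test_centroid_distance(self):
        frame = self.triangle([0, 0, 0]) + self.triangle([4.0, 0, 0])
        t = toy([frame])
        d = ring_centroid_series(t, RingPair((0, 1, 2), (3, 4, 5)))
        assert d[0] == pytest.approx(4.0, abs=1e-12)

    def test_identical_rings_zero(self):
        tri = self.triangle([1, 2, 3])
        t = toy([tri + tri])
        d = ring_centroid_series(t, RingPair((0, 1, 2), (3, 4, 5)))
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_min_method_below_centroid(self):
        frame = self.triangle([0, 0, 0]) + self.triangle([4.0, 0, 0])
        t = toy([frame])
        pair = RingPair((0, 1, 2), (3, 4, 5))
        assert (ring_centroid_series(t, pair, method="min")[0]
                <= ring_centroid_series(t, pair)[0])

    def test_fraction_below(self):
        assert fraction_below([4.9, 5.1], 5.0) == 0.5

    def test_small_or_overlapping_rings_rejected(self):
        with pytest.raises(TrajectoryInputError):
            RingPair((0, 1), (2, 3, 4))
        with pytest.raises(TrajectoryInputError):
            RingPair((0, 1, 2), (2, 3, 4))


class TestRMSD:
    def random_frames(self, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(6, 3))
        frames = [base]
        for _ in range(4):
            frames.append(base + rng.normal(scale=0.3, size=(6, 3)))
        return toy(np.array(frames))

    def test_identical_frames_zero(self):
        base = np.random.default_rng(1).normal(size=(5, 3))
        t = toy(np.array([base, base, base]))
        assert np.allclose(rmsd_series(t), 0.0, atol=1e-12)

    def test_pure_translation(self):
        base = np.random.default_rng(2).normal(size=(5, 3))
        t = toy(np.array([base, base + [1.0, 0, 0]]))
        assert rmsd_series(t, superpose=True)[1] == pytest.approx(0.0,
                                                                  abs=1e-9)
        assert rmsd_series(t, superpose=False)[1] == pytest.approx(1.0)

    def test_superposed_never_larger(self):
        t = self.random_frames()
        r_sup = rmsd_series(t, superpose=True)
        r_raw = rmsd_series(t, superpose=False)
        assert np.all(r_sup <= r_raw + 1e-12)

    def test_rotation_removed_by_superposition(self):
        from scipy.spatial.transform import Rotation
        base = np.random.default_rng(3).normal(size=(7, 3))
        R = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        t = toy(np.array([base, base @ R.as_matrix().T + [0.5, -1, 2]]))
        assert rmsd_series(t, superpose=True)[1] == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_too_few_atoms_for_superposition(self):
        t = toy([[[0, 0, 0], [1, 0, 0]]])
        with pytest.raises(TrajectoryInputError):
            rmsd_series(t, atom_selection=[0, 1], superpose=True)


def test_histogram_frame_layout():
    tables = [bin_hbond_series(HBondSeries("b1", [2.0, 2.1, 4.0])),
              bin_hbond_series(HBondSeries("b2", [1.7] * 4))]
    df = histogram_frame(tables)
    assert list(df.index) == ["b1", "b2"]
    assert "out_of_range" in df.columns
    assert df.loc["b1", "out_of_range"] == pytest.approx(33.3)
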