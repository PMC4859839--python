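"""Synthetic trajectory and dimer-scan generation."""

import numpy as np
import pytest
from scipy.stats import kstest

from pocket_eda import templates
from pocket_eda.fragments import FragmentError
from pocket_eda.synthetic_data import (DimerScanSpec, HBondSpec, RingSpec,
                                       SyntheticConfigError, ToyTrajectory,
                                       load_hbond_specs, make_dimer_scan,
                                       make_hbond_trajectory, mixture_cdf,
                                       write_pdb_trajectory,
                                       write_xyz_trajectory)
from pocket_eda.trajectory_stats import hbond_series, read_trajectory


def monitored_distances(traj, bond_id):
    h, a = traj.monitored_pairs[bond_id]
    return np.linalg.norm(traj.frames[:, h] - traj.frames[:, a], axis=1)


class TestHBondSpecValidation:
    def test_nonnormalized_weights_rejected(self):
        with pytest.raises(SyntheticConfigError, match="weights"):
            HBondSpec("b", ((0.5, 2.0, 0.1), (0.4, 2.5, 0.1)), 10)

    def test_mean_outside_histogram_domain_rejected(self):
        with pytest.raises(SyntheticConfigError, match="outside"):
            HBondSpec("b", ((1.0, 4.2, 0.1),), 10)

    def test_negative_sd_and_zero_frames_rejected(self):
        with pytest.raises(SyntheticConfigError):
            HBondSpec("b", ((1.0, 2.0, -0.1),), 10)
        with pytest.raises(SyntheticConfigError):
            HBondSpec("b", ((1.0, 2.0, 0.1),), 0)

    def test_inconsistent_frame_counts_rejected(self):
        specs = [HBondSpec("a", ((1.0, 2.0, 0.1),), 10),
                 HBondSpec("b", ((1.0, 2.0, 0.1),), 20)]
        with pytest.raises(SyntheticConfigError, match="n_frames"):
            make_hbond_trajectory(specs, seed=1)


class TestHBondTrajectory:
    def test_zero_variance_is_exactly_constant(self):
        spec = HBondSpec("const", ((1.0, 2.0, 0.0),), 10)
        traj = make_hbond_trajectory([spec], seed=3)
        d = monitored_distances(traj, "const")
        assert np.all(d == 2.0)

    def test_sample_moments_recover_mixture(self):
        # single Gaussian far from the truncation bounds: sample mean/sd
        # must match the component parameters
        spec = HBondSpec("g", ((1.0, 2.0, 0.1),), 10000)
        traj = make_hbond_trajectory([spec], seed=7)
        d = monitored_distances(traj, "g")
        assert abs(d.mean() - 2.0) < 0.01
        assert abs(d.std(ddof=1) - 0.1) < 0.01

    def test_bimodal_component_fractions(self):
        # 2.4 Å separates the two well-resolved modes: the mass below it
        # equals the first component's weight (closed-form mixture CDF)
        spec = HBondSpec("bi", ((0.6, 1.9, 0.05), (0.4, 2.9, 0.05)), 20000)
        traj = make_hbond_trajectory([spec], seed=11)
        d = monitored_distances(traj, "bi")
        assert abs(np.mean(d < 2.4) - 0.6) < 0.02
        assert abs(mixture_cdf(spec.mixture, 2.4) - 0.6) < 1e-9

    def test_kolmogorov_smirnov_against_mixture_cdf(self, bimodal_trajectory):
        specs, traj = bimodal_trajectory
        for spec in specs:
            d = monitored_distances(traj, spec.bond_id)
            stat = kstest(d, lambda x, m=spec.mixture:
                          mixture_cdf(m, x)).statistic
            assert stat < 0.02

    def test_seed_reproducibility_and_sensitivity(self):
        specs = [HBondSpec("a", ((1.0, 2.2, 0.2),), 500),
                 HBondSpec("b", ((0.5, 1.8, 0.1), (0.5, 2.8, 0.1)), 500)]
        t1 = make_hbond_trajectory(specs, seed=42)
        t2 = make_hbond_trajectory(specs, seed=42)
        t3 = make_hbond_trajectory(specs, seed=43)
        assert np.array_equal(t1.frames, t2.frames)
        assert not np.array_equal(t1.frames, t3.frames)

    def test_geometry_realizes_distances_along_axis(self):
        # acceptor moves along +x only; the monitored distance equals the
        # x-offset exactly, i.e. the drawn value is realized exactly
        spec = HBondSpec("g", ((1.0, 2.1, 0.15),), 200)
        traj = make_hbond_trajectory([spec], seed=5)
        h, a = traj.monitored_pairs["g"]
        d = monitored_distances(traj, "g")
        x_offset = traj.frames[:, a, 0] - traj.frames[:, h, 0]
        assert np.max(np.abs(d - x_offset)) < 1e-9

    def test_ring_series_realized(self):
        spec = HBondSpec("hb", ((1.0, 2.0, 0.1),), 300)
        ring = RingSpec("ring", ((1.0, 4.8, 0.4),), 300)
        traj = make_hbond_trajectory([spec], seed=9, ring_specs=[ring])
        ra, rb = traj.ring_pairs["ring"]
        ca = traj.frames[:, list(ra)].mean(axis=1)
        cb = traj.frames[:, list(rb)].mean(axis=1)
        d = np.linalg.norm(ca - cb, axis=1)
        assert d.min() > 2.0 and abs(d.mean() - 4.8) < 0.1


class TestDimerScan:
    def test_water_water_oo_distances_exact(self):
        spec = DimerScanSpec(templates.water("donor"),
                             templates.water("acceptor"),
                             separations=(3.0, 5.0, 10.0))
        dimers = make_dimer_scan(spec)
        assert len(dimers) == 3
        for dim, s in zip(dimers, (3.0, 5.0, 10.0)):
            oo = np.linalg.norm(dim.fragment_a.coords[0]
                                - dim.fragment_b.coords[0])
            assert oo == pytest.approx(s, abs=1e-12)

    def test_overlapping_atoms_refused(self):
        spec = DimerScanSpec(templates.helium(), templates.helium(),
                             separations=(0.3,))
        with pytest.raises(FragmentError, match="overlap"):
            make_dimer_scan(spec)

    def test_formamide_nh_o_fixture(self):
        # N-H...O=C contact: donor anti N-H along +x, acceptor O on the axis
        spec = DimerScanSpec(templates.formamide_donor(),
                             templates.formamide_acceptor(),
                             separations=(1.9,),
                             ref_atom_a=templates.FORMAMIDE_H_ANTI,
                             ref_atom_b=templates.FORMAMIDE_O)
        dim = make_dimer_scan(spec)[0]
        h = dim.fragment_a.coords[templates.FORMAMIDE_H_ANTI]
        o = dim.fragment_b.coords[templates.FORMAMIDE_O]
        assert np.linalg.norm(h - o) == pytest.approx(1.9, abs=1e-9)

    def test_separations_must_increase(self):
        with pytest.raises(SyntheticConfigError):
            DimerScanSpec(templates.helium(), templates.helium(),
                          separations=(3.0, 2.0))

    def test_charges_carried_through(self):
        spec = DimerScanSpec(templates.methylguanidinium(),
                             templates.acetate(), separations=(6.0,))
        dim = make_dimer_scan(spec)[0]
        assert dim.fragment_a.net_charge == 1
        assert dim.fragment_b.net_charge == -1
        assert dim.total_charge == 0


class TestIO:
    def test_xyz_round_trip(self, tmp_path):
        spec = HBondSpec("a", ((1.0, 2.2, 0.2),), 20)
        traj = make_hbond_trajectory([spec], seed=1)
        path = tmp_path / "t.xyz"
        write_xyz_trajectory(traj, path)
        back = read_trajectory(path, traj.monitored_pairs)
        assert back.frames.shape == traj.frames.shape
        assert np.max(np.abs(back.frames - traj.frames)) < 1e-6
        d0 = hbond_series(traj, traj.monitored_pairs["a"]).distances
        d1 = hbond_series(back, back.monitored_pairs["a"]).distances
        assert np.max(np.abs(d0 - d1)) < 1e-5

    def test_pdb_round_trip(self, tmp_path):
        spec = HBondSpec("a", ((1.0, 2.2, 0.2),), 5)
        traj = make_hbond_trajectory([spec], seed=1)
        path = tmp_path / "t.pdb"
        write_pdb_trajectory(traj, path)
        back = read_trajectory(path)
        assert back.frames.shape == traj.frames.shape
        # PDB stores 3 decimals
        assert np.max(np.abs(back.frames - traj.frames)) < 2e-3

    def test_yaml_spec_loading(self, tmp_path):
        cfg = tmp_path / "specs.yaml"
        cfg.write_text(
            "n_frames: 50\n"
            "hbonds:\n"
            "  - bond_id: b1\n"
            "    mixture: [[0.7, 1.9, 0.1], [0.3, 2.9, 0.2]]\n"
            "rings:\n"
            "  - ring_id: r1\n"
            "    mixture: [[1.0, 4.8, 0.5]]\n")
        hb, rg = load_hbond_specs(cfg)
        assert hb[0].bond_id == "b1" and hb[0].n_frames == 50
        assert rg[0].ring_id == "r1"
        traj = make_hbond_trajectory(hb, seed=2, ring_specs=rg)
        assert isinstance(traj, ToyTrajectory)
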