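"""Interaction-energy decomposition: limits, oracles, invariances."""

import numpy as np
import pytest

from oracles import grid_ee_coulomb, nonorthogonal_determinant_energy
from pocket_eda import templates
from pocket_eda.eda import (EDAError, _nuclear_ops, build_context, decompose,
                            electrostatic_first_order, heitler_london,
                            scf_monomer_in_dcbs, supermolecular_hf)
from pocket_eda.fragments import DimerSystem
from pocket_eda.qchem.scf import (AOSystem, BOHR_PER_ANGSTROM, Center,
                                  HARTREE_TO_KCALMOL, coulomb, restricted_hf)
from pocket_eda.synthetic_data import DimerScanSpec, make_dimer_scan


def he_dimer(sep):
    return make_dimer_scan(DimerScanSpec(templates.helium(),
                                         templates.helium(),
                                         separations=(sep,)))[0]


def hl_oracle(ctx, wfn_a, wfn_b):
    """Heitler–London energy by the nonorthogonal-determinant cofactor
    formula (independent of the Löwdin + Fock-build route)."""
    C = np.hstack([wfn_a.occ_coeff, wfn_b.occ_coeff])
    V_a, V_b, _ = _nuclear_ops(ctx)
    h = ctx.ints.T + V_a + V_b
    e_det = nonorthogonal_determinant_energy(C, ctx.ints, h) \
        + ctx.sys_ab.nuclear_repulsion()
    return e_det - wfn_a.energy - wfn_b.energy


class TestMonomerInDCBS:
    def test_far_ghost_equals_isolated_monomer(self):
        ctx = build_context(he_dimer(100.0))
        wfn = scf_monomer_in_dcbs(ctx, "A")
        iso = restricted_hf(AOSystem([Center("He", np.zeros(3))]))
        assert abs(wfn.energy - iso.energy) < 1e-8

    def test_dcbs_is_variational_improvement(self, water_dimer):
        ctx = build_context(water_dimer)
        wfn = scf_monomer_in_dcbs(ctx, "A")
        iso = restricted_hf(AOSystem(
            [Center(s, c) for s, c in zip(water_dimer.fragment_a.symbols,
                                          water_dimer.fragment_a.coords)]))
        assert wfn.energy <= iso.energy + 1e-12

    def test_anion_electrons_stay_on_monomer(self):
        # F-'s HOMO is positive in a minimal basis; without care its
        # electrons leak onto the distant Li+ ghost functions
        dim = make_dimer_scan(DimerScanSpec(templates.lithium_cation(),
                                            templates.fluoride_anion(),
                                            separations=(20.0,)))[0]
        ctx = build_context(dim)
        wfn_b = scf_monomer_in_dcbs(ctx, "B")
        iso = restricted_hf(AOSystem([Center("F", np.zeros(3))], charge=-1))
        assert wfn_b.energy == pytest.approx(iso.energy, abs=1e-6)


class TestElectrostatics:
    def test_neutral_far_limit(self):
        ctx = build_context(he_dimer(100.0))
        wa = scf_monomer_in_dcbs(ctx, "A")
        wb = scf_monomer_in_dcbs(ctx, "B")
        assert abs(electrostatic_first_order(ctx, wa, wb)) < 1e-6

    def test_ion_pair_point_charge_law(self):
        dim = make_dimer_scan(DimerScanSpec(templates.lithium_cation(),
                                            templates.fluoride_anion(),
                                            separations=(20.0,)))[0]
        ctx = build_context(dim)
        wa = scf_monomer_in_dcbs(ctx, "A")
        wb = scf_monomer_in_dcbs(ctx, "B")
        e_el = electrostatic_first_order(ctx, wa, wb)
        R = 20.0 * BOHR_PER_ANGSTROM
        assert e_el == pytest.approx(-1.0 / R, rel=0.01)

    def test_electron_coulomb_against_grid_quadrature(self):
        dim = make_dimer_scan(DimerScanSpec(templates.h2(), templates.h2(),
                                            separations=(5.0,)))[0]
        ctx = build_context(dim)
        wa = scf_monomer_in_dcbs(ctx, "A")
        wb = scf_monomer_in_dcbs(ctx, "B")
        ee_impl = float(np.sum(wa.density * coulomb(ctx.ints.eri,
                                                    wb.density)))
        ee_grid = grid_ee_coulomb(wa.density, wb.density, ctx.ints.shells,
                                  extent=6.0, npts=64)
        assert abs(ee_impl - ee_grid) < 1e-4

    def test_dipole_dipole_decay(self):
        # two collinear water dipoles: eps_el ~ -2 mu^2 / R^3
        w = templates.water("axial")
        Rs = [8.0, 10.0, 13.0, 16.0, 20.0]
        els = []
        for s in Rs:
            ctx = build_context(make_dimer_scan(
                DimerScanSpec(w, w, separations=(s,)))[0])
            wa = scf_monomer_in_dcbs(ctx, "A")
            wb = scf_monomer_in_dcbs(ctx, "B")
            els.append(electrostatic_first_order(ctx, wa, wb))
        slope = np.polyfit(np.log(Rs), np.log(np.abs(els)), 1)[0]
        assert slope == pytest.approx(-3.0, rel=0.05)
        assert all(e < 0 for e in els)     # head-to-tail: attractive


class TestHeitlerLondon:
    def test_zero_overlap_limit(self):
        ctx = build_context(he_dimer(100.0))
        wa = scf_monomer_in_dcbs(ctx, "A")
        wb = scf_monomer_in_dcbs(ctx, "B")
        _, e_ex = heitler_london(ctx, wa, wb)
        assert abs(e_ex) < 1e-8

    def test_exchange_positive_monotone_and_superpolynomial(self):
        seps = [2.5, 3.0, 3.5, 4.0]
        exs = []
        for s in seps:
            ctx = build_context(he_dimer(s))
            wa = scf_monomer_in_dcbs(ctx, "A")
            wb = scf_monomer_in_dcbs(ctx, "B")
            exs.append(heitler_london(ctx, wa, wb)[1])
        assert all(e > 0 for e in exs)
        assert all(a > b for a, b in zip(exs, exs[1:]))
        # decays faster than R^-15 over 3.0 -> 4.0 Å
        assert exs[3] < exs[1] * (3.0 / 4.0) ** 15

    @pytest.mark.parametrize("builder,sep", [
        (lambda: templates.helium(), 2.5),
        (lambda: templates.helium(), 3.5),
        (lambda: templates.h2(), 3.0),
        (lambda: templates.h2(), 5.0),
    ])
    def test_matches_nonorthogonal_determinant_oracle(self, builder, sep):
        dim = make_dimer_scan(DimerScanSpec(builder(), builder(),
                                            separations=(sep,)))[0]
        ctx = build_context(dim)
        wa = scf_monomer_in_dcbs(ctx, "A")
        wb = scf_monomer_in_dcbs(ctx, "B")
        e_hl, _ = heitler_london(ctx, wa, wb)
        assert abs(e_hl - hl_oracle(ctx, wa, wb)) < 1e-8

    def test_singular_overlap_refused(self):
        ctx = build_context(he_dimer(0.55))
        wa = scf_monomer_in_dcbs(ctx, "A")
        wb = scf_monomer_in_dcbs(ctx, "B")
        with pytest.raises(EDAError, match="singular"):
            heitler_london(ctx, wa, wb, singular_tol=0.5)


class TestDecompose:
    def test_noninteracting_limit_all_components_vanish(self):
        res = decompose(he_dimer(100.0))
        for v in (res.e_el_10, res.e_ex_hl, res.e_del_hf, res.e_hl,
                  res.e_hf):
            assert abs(v) < 1e-4

    def test_additivity_exact(self, water_dimer_eda):
        r = water_dimer_eda
        assert r.e_hf == pytest.approx(r.e_el_10 + r.e_ex_hl + r.e_del_hf,
                                       abs=1e-8)
        assert r.e_hl == pytest.approx(r.e_el_10 + r.e_ex_hl, abs=1e-8)

    def test_hydrogen_bond_sign_pattern(self, water_dimer_eda):
        r = water_dimer_eda
        assert r.e_el_10 < 0 and r.e_ex_hl > 0
        assert r.e_del_hf < 0 and r.e_hf < 0

    def test_supermolecular_counterpoise_oracle(self, water_dimer):
        # dE(HF) recomputed from three independent total-energy SCF runs
        # (dimer, monomer A with ghost B, monomer B with ghost A)
        res = decompose(water_dimer)
        centers = ([Center(s, c) for s, c in
                    zip(water_dimer.fragment_a.symbols,
                        water_dimer.fragment_a.coords)]
                   + [Center(s, c) for s, c in
                      zip(water_dimer.fragment_b.symbols,
                          water_dimer.fragment_b.coords)])
        e_ab = restricted_hf(AOSystem(centers)).energy
        ghosts_b = [Center(c.symbol, c.coord_ang, ghost=(i >= 3))
                    for i, c in enumerate(centers)]
        ghosts_a = [Center(c.symbol, c.coord_ang, ghost=(i < 3))
                    for i, c in enumerate(centers)]
        e_a = restricted_hf(AOSystem(ghosts_b)).energy
        e_b = restricted_hf(AOSystem(ghosts_a)).energy
        e_hf = (e_ab - e_a - e_b) * HARTREE_TO_KCALMOL
        assert res.e_hf == pytest.approx(e_hf, abs=1e-6)

    def test_rigid_body_invariance(self, water_dimer, water_dimer_eda):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zyx", [31, -57, 13], degrees=True)
        M = R.as_matrix()
        shift = np.array([1.7, -2.3, 0.9])
        moved = DimerSystem(
            water_dimer.fragment_a.rotated(M).translated(shift),
            water_dimer.fragment_b.rotated(M).translated(shift))
        r0, r1 = water_dimer_eda, decompose(moved)
        for a, b in [(r0.e_el_10, r1.e_el_10), (r0.e_ex_hl, r1.e_ex_hl),
                     (r0.e_del_hf, r1.e_del_hf), (r0.e_hf, r1.e_hf)]:
            assert abs(a - b) < 1e-7

    def test_fragment_swap_symmetry(self):
        dim = he_dimer(3.0)
        r1, r2 = decompose(dim), decompose(dim.swapped())
        assert abs(r1.e_el_10 - r2.e_el_10) < 1e-10
        assert abs(r1.e_ex_hl - r2.e_ex_hl) < 1e-10
        assert abs(r1.e_hf - r2.e_hf) < 1e-10

    def test_result_serialization(self, water_dimer_eda, tmp_path):
        p = tmp_path / "r.json"
        water_dimer_eda.to_json(p)
        import json
        d = json.loads(p.read_text())
        assert d["hartree_to_kcalmol"] == 627.509474
        row = water_dimer_eda.as_table_row()
        assert set(row) == {"label", "DE_HL", "e_el_10", "DE_ex_HL",
                            "DE_del_HF", "DE_HF"}
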