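"""Variational–perturbational decomposition of the Hartree–Fock
interaction energy of a dimer.

The supermolecular HF interaction energy is split as

    dE(HF) = eps_el(10) + dE_ex(HL) + dE_del(HF)

* eps_el(10): first-order electrostatics — the Coulomb interaction of the
  two unperturbed monomer charge distributions (no antisymmetrization
  between fragments);
* dE_ex(HL): Heitler–London exchange — the Pauli-repulsion remainder after
  subtracting eps_el(10) from the antisymmetrized-product interaction
  energy E(HL);
* dE_del(HF): delocalization (deformation) — the SCF relaxation remainder
  dE(HF) − E(HL), containing polarization/induction and charge transfer.

Every quantity is evaluated in the dimer-centered basis set (DCBS): each
monomer SCF uses the full dimer basis with the partner's nuclei as ghost
centers, which makes the total interaction energy and all of its
components free of basis-set superposition error by construction.

E(HL) is evaluated as the closed-shell single-determinant energy of the
combined occupied monomer orbitals after Löwdin symmetric orthogonalization
of their mutual overlap — for closed shells this equals the energy of the
antisymmetrized product of the monomer determinants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .fragments import DimerSystem
from .qchem import integrals
from .qchem.scf import (AOIntegrals, AOSystem, Center, HARTREE_TO_KCALMOL,
                        SCFResult, coulomb, density_energy, restricted_hf)

ADDITIVITY_TOL_KCAL = 1e-8


class EDAError(RuntimeError):
    pass


@dataclass
class EDAResult:
    """The five interaction-energy quantities for one dimer, kcal/mol."""

    e_el_10: float
    e_ex_hl: float
    e_del_hf: float
    e_hl: float
    e_hf: float
    basis_name: str
    monomer_energies: tuple[float, float]   # Hartree, DCBS
    dimer_energy: float = 0.0               # Hartree
    label: str = ""
    hartree_to_kcalmol: float = HARTREE_TO_KCALMOL

    def __post_init__(self):
        if abs(self.e_hl - (self.e_el_10 + self.e_ex_hl)) > ADDITIVITY_TOL_KCAL:
            raise EDAError("E(HL) != eps_el + dE_ex beyond tolerance")
        if abs(self.e_hf - (self.e_el_10 + self.e_ex_hl + self.e_del_hf)) \
                > ADDITIVITY_TOL_KCAL:
            raise EDAError("dE(HF) != component sum beyond tolerance")

    def to_dict(self) -> dict:
        return {"label": self.label, "basis": self.basis_name,
                "e_el_10": self.e_el_10, "e_ex_hl": self.e_ex_hl,
                "e_del_hf": self.e_del_hf, "e_hl": self.e_hl,
                "e_hf": self.e_hf,
                "monomer_energies_hartree": list(self.monomer_energies),
                "dimer_energy_hartree": self.dimer_energy,
                "hartree_to_kcalmol": self.hartree_to_kcalmol}

    def to_json(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def as_table_row(self) -> dict:
        """Row in the reference-table column order (2-dp display rounding)."""
        return {"label": self.label,
                "DE_HL": round(self.e_hl, 2),
                "e_el_10": round(self.e_el_10, 2),
                "DE_ex_HL": round(self.e_ex_hl, 2),
                "DE_del_HF": round(self.e_del_hf, 2),
                "DE_HF": round(self.e_hf, 2)}


@dataclass
class _DimerContext:
    """Shared AO data for one dimer geometry (one integral build)."""

    dimer: DimerSystem
    ints: AOIntegrals
    sys_ab: AOSystem
    sys_a: AOSystem
    sys_b: AOSystem
    mask_a: np.ndarray      # True for centers belonging to fragment A
    lindep: float = 1e-6


def build_context(dimer: DimerSystem, lindep: float = 1e-6) -> _DimerContext:
    """Build the dimer-centered basis and cache its AO integrals."""
    centers_real = (
        [Center(s, c) for s, c in zip(dimer.fragment_a.symbols,
                                      dimer.fragment_a.coords)]
        + [Center(s, c) for s, c in zip(dimer.fragment_b.symbols,
                                        dimer.fragment_b.coords)])
    na = dimer.fragment_a.n_atoms
    mask_a = np.zeros(len(centers_real), dtype=bool)
    mask_a[:na] = True

    def with_ghosts(keep_mask, charge):
        cs = [Center(c.symbol, c.coord_ang, ghost=not keep)
              for c, keep in zip(centers_real, keep_mask)]
        return AOSystem(cs, charge=charge, basis_name=dimer.basis_name)

    sys_ab = AOSystem([Center(c.symbol, c.coord_ang) for c in centers_real],
                      charge=dimer.total_charge, basis_name=dimer.basis_name)
    sys_a = with_ghosts(mask_a, dimer.fragment_a.net_charge)
    sys_b = with_ghosts(~mask_a, dimer.fragment_b.net_charge)
    ints = AOIntegrals.build(sys_ab.shells())
    return _DimerContext(dimer, ints, sys_ab, sys_a, sys_b, mask_a, lindep)


def scf_monomer_in_dcbs(ctx: _DimerContext, which: str,
                        **scf_kw) -> SCFResult:
    """Converged RHF of one monomer in the full dimer basis (partner nuclei
    as zero-charge ghost centers).

    The isolated monomer (own basis only) is solved first and its occupied
    orbitals, embedded in the dimer basis, seed a maximum-overlap SCF.
    This pins the monomer's electrons to the monomer even when the partner
    ghost functions offer spurious lower-eigenvalue levels (weakly bound
    anionic HOMOs); for ordinary closed-shell monomers it coincides with
    the aufbau solution.
    """
    if which not in ("A", "B"):
        raise ValueError("which must be 'A' or 'B'")
    system = ctx.sys_a if which == "A" else ctx.sys_b
    frag = ctx.dimer.fragment_a if which == "A" else ctx.dimer.fragment_b
    try:
        iso_sys = AOSystem([Center(s, c) for s, c in
                            zip(frag.symbols, frag.coords)],
                           charge=frag.net_charge,
                           basis_name=ctx.dimer.basis_name)
        iso = restricted_hf(iso_sys, lindep=ctx.lindep, **scf_kw)
        nbf_total = ctx.ints.S.shape[0]
        nbf_own = iso.mo_coeff.shape[0]
        guess = np.zeros((nbf_total, iso.n_occ))
        off = 0 if which == "A" else nbf_total - nbf_own
        guess[off: off + nbf_own, :] = iso.occ_coeff
        return restricted_hf(system, ctx.ints, lindep=ctx.lindep,
                             guess_occ=guess, occupation="mom", **scf_kw)
    except EDAError:
        raise
    except Exception as exc:
        raise EDAError(f"monomer {which} SCF failed: {exc}") from exc


def _nuclear_ops(ctx: _DimerContext):
    coords = ctx.sys_ab.coords_bohr
    q = ctx.sys_ab.nuclear_charges
    a, b = ctx.mask_a, ~ctx.mask_a
    V_a = integrals.point_charge_matrix(ctx.ints.shells, coords[a], q[a])
    V_b = integrals.point_charge_matrix(ctx.ints.shells, coords[b], q[b])
    e_nn_inter = 0.0
    for i in np.flatnonzero(a):
        for j in np.flatnonzero(b):
            e_nn_inter += q[i] * q[j] / np.linalg.norm(coords[i] - coords[j])
    return V_a, V_b, float(e_nn_inter)


def electrostatic_first_order(ctx: _DimerContext, wfn_a: SCFResult,
                              wfn_b: SCFResult) -> float:
    """eps_el(10) in Hartree: Coulomb interaction of the frozen monomer
    charge distributions (electrons A – electrons B, electrons – partner
    nuclei, nuclei A – nuclei B)."""
    V_a, V_b, e_nn = _nuclear_ops(ctx)
    D_a, D_b = wfn_a.density, wfn_b.density
    e_ee = float(np.sum(D_a * coulomb(ctx.ints.eri, D_b)))
    e_en = float(np.sum(D_a * V_b) + np.sum(D_b * V_a))
    return e_ee + e_en + e_nn


def heitler_london(ctx: _DimerContext, wfn_a: SCFResult, wfn_b: SCFResult,
                   singular_tol: float = 1e-8) -> tuple[float, float]:
    """(E(HL), dE_ex(HL)) in Hartree.

    The antisymmetrized-product energy is the single-determinant energy of
    the combined occupied monomer orbitals after Löwdin orthogonalization;
    a near-singular inter-monomer occupied overlap (fragments too close or
    a degenerate basis) is refused.
    """
    S = ctx.ints.S
    C = np.hstack([wfn_a.occ_coeff, wfn_b.occ_coeff])
    M = C.T @ S @ C
    w, U = np.linalg.eigh(M)
    if w.min() < singular_tol:
        raise EDAError(
            f"combined occupied-orbital overlap is singular "
            f"(min eigenvalue {w.min():.2e}); fragments too close or basis "
            f"degenerate")
    M_invsqrt = U @ np.diag(1.0 / np.sqrt(w)) @ U.T
    C_orth = C @ M_invsqrt
    D_hl = 2.0 * C_orth @ C_orth.T
    V_a, V_b, e_nn_inter = _nuclear_ops(ctx)
    h = ctx.ints.T + V_a + V_b
    e_det = density_energy(h, ctx.ints.eri, D_hl) \
        + ctx.sys_ab.nuclear_repulsion()
    e_hl = e_det - wfn_a.energy - wfn_b.energy
    e_el = electrostatic_first_order(ctx, wfn_a, wfn_b)
    return e_hl, e_hl - e_el


def supermolecular_hf(ctx: _DimerContext, **scf_kw) -> SCFResult:
    """Full-dimer RHF in the same basis/integral context."""
    try:
        return restricted_hf(ctx.sys_ab, ctx.ints, lindep=ctx.lindep,
                             **scf_kw)
    except Exception as exc:
        raise EDAError(f"dimer SCF failed: {exc}") from exc


def decompose(dimer: DimerSystem, label: str = "", lindep: float = 1e-6,
              **scf_kw) -> EDAResult:
    """Full decomposition of one dimer; all components in kcal/mol."""
    ctx = build_context(dimer, lindep=lindep)
    wfn_a = scf_monomer_in_dcbs(ctx, "A", **scf_kw)
    wfn_b = scf_monomer_in_dcbs(ctx, "B", **scf_kw)
    e_el = electrostatic_first_order(ctx, wfn_a, wfn_b)
    e_hl, e_ex = heitler_london(ctx, wfn_a, wfn_b)
    wfn_ab = supermolecular_hf(ctx, **scf_kw)
    e_hf = wfn_ab.energy - wfn_a.energy - wfn_b.energy
    e_del = e_hf - e_hl
    k = HARTREE_TO_KCALMOL
    return EDAResult(
        e_el_10=e_el * k, e_ex_hl=e_ex * k, e_del_hf=e_del * k,
        e_hl=(e_el + e_ex) * k, e_hf=(e_el + e_ex + e_del) * k,
        basis_name=dimer.basis_name,
        monomer_energies=(wfn_a.energy, wfn_b.energy),
        dimer_energy=wfn_ab.energy,
        label=label or f"{dimer.fragment_a.label}--{dimer.fragment_b.label}")
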