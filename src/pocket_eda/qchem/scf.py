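"""Restricted Hartree–Fock in a fixed AO basis, with ghost-center support.

The :class:`AOSystem` couples a set of basis centers (real nuclei or ghost
centers carrying only basis functions) with an electron count, so the same
dimer-spanning basis can host the full dimer, either monomer with the
partner's functions as ghosts, or an antisymmetrized product state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import integrals
from .basis import Shell, atomic_number, shells_for_atom

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
HARTREE_TO_KCALMOL = 627.509474


class SCFConvergenceError(RuntimeError):
    """Raised when the SCF iteration fails to reach the requested thresholds."""


@dataclass
class Center:
    symbol: str                 # element symbol of the basis functions
    coord_ang: np.ndarray       # Å
    ghost: bool = False

    @property
    def nuclear_charge(self) -> float:
        return 0.0 if self.ghost else float(atomic_number(self.symbol))


@dataclass
class AOSystem:
    """Basis centers + electron count defining one SCF problem."""

    centers: list[Center]
    charge: int = 0
    basis_name: str = "STO-3G"

    def __post_init__(self):
        nel = self.n_electrons
        if nel <= 0:
            raise ValueError("system has no electrons")
        if nel % 2 != 0:
            raise ValueError(
                "open-shell fragment (odd electron count) is not supported; "
                "all systems handled here are closed-shell")

    @property
    def n_electrons(self) -> int:
        z = sum(int(c.nuclear_charge) for c in self.centers)
        return z - self.charge

    @property
    def coords_bohr(self) -> np.ndarray:
        return np.array([c.coord_ang for c in self.centers]) * BOHR_PER_ANGSTROM

    @property
    def nuclear_charges(self) -> np.ndarray:
        return np.array([c.nuclear_charge for c in self.centers])

    def shells(self) -> list[Shell]:
        out: list[Shell] = []
        coords = self.coords_bohr
        for i, c in enumerate(self.centers):
            out.extend(shells_for_atom(c.symbol, self.basis_name, coords[i], i))
        return out

    def nuclear_repulsion(self) -> float:
        coords = self.coords_bohr
        q = self.nuclear_charges
        e = 0.0
        for i in range(len(q)):
            for j in range(i):
                if q[i] == 0.0 or q[j] == 0.0:
                    continue
                e += q[i] * q[j] / np.linalg.norm(coords[i] - coords[j])
        return e


@dataclass
class AOIntegrals:
    """Cached AO integrals over a fixed set of shells (geometry-only data)."""

    S: np.ndarray
    T: np.ndarray
    eri: np.ndarray
    shells: list[Shell] = field(repr=False, default_factory=list)

    @classmethod
    def build(cls, shells: list[Shell]) -> "AOIntegrals":
        return cls(S=integrals.overlap_matrix(shells),
                   T=integrals.kinetic_matrix(shells),
                   eri=integrals.electron_repulsion_tensor(shells),
                   shells=shells)


def orthogonalizer(S: np.ndarray, lindep: float = 1e-6) -> np.ndarray:
    """Canonical orthogonalization X with X^T S X = 1.

    Eigenvectors of S with eigenvalue below `lindep` are projected out,
    which keeps near-linearly-dependent (e.g. diffuse dimer-centered) bases
    numerically stable.
    """
    w, U = np.linalg.eigh(S)
    keep = w > lindep
    return U[:, keep] / np.sqrt(w[keep])


def coulomb(eri: np.ndarray, D: np.ndarray) -> np.ndarray:
    return np.einsum("pqrs,rs->pq", eri, D, optimize=True)


def exchange(eri: np.ndarray, D: np.ndarray) -> np.ndarray:
    return np.einsum("prqs,rs->pq", eri, D, optimize=True)


def density_energy(h: np.ndarray, eri: np.ndarray, D: np.ndarray) -> float:
    """Closed-shell single-determinant electronic energy of density D.

    D is the total (spin-summed) AO density; E = tr(Dh) + 1/2 tr(D J)
    - 1/4 tr(D K).
    """
    J = coulomb(eri, D)
    K = exchange(eri, D)
    return float(np.sum(D * h) + 0.5 * np.sum(D * J) - 0.25 * np.sum(D * K))


@dataclass
class SCFResult:
    energy: float               # total energy incl. nuclear repulsion (Ha)
    energy_elec: float
    mo_coeff: np.ndarray        # (nbf, nmo) over the full AO basis
    mo_energy: np.ndarray
    density: np.ndarray         # spin-summed AO density, D = 2 C_occ C_occ^T
    n_occ: int
    converged: bool
    n_iter: int

    @property
    def occ_coeff(self) -> np.ndarray:
        return self.mo_coeff[:, : self.n_occ]


def restricted_hf(system: AOSystem, ints: AOIntegrals | None = None,
                  conv_energy: float = 1e-9, conv_density: float = 1e-7,
                  max_cycles: int = 200, lindep: float = 1e-6,
                  diis_size: int = 8, guess_occ: np.ndarray | None = None,
                  occupation: str = "aufbau") -> SCFResult:
    """Solve restricted HF for `system`; DIIS-accelerated, core-guess start.

    `ints` may carry pre-built integrals for the same shells (they depend on
    geometry and basis only, not on electron count or which centers are
    ghosts), which is how the dimer-centered-basis monomer and dimer
    calculations share one integral build.

    `occupation='mom'` selects, each cycle, the `n_occ` eigenvectors with
    maximum overlap onto the previous cycle's occupied space instead of the
    lowest eigenvalues (seeded by `guess_occ`, occupied MO coefficients over
    this AO basis).  This keeps a monomer's electrons on the monomer when
    ghost-center orbitals would otherwise fall below a weakly bound (e.g.
    anionic) HOMO in a dimer-centered basis.
    """
    shells = system.shells()
    if ints is None:
        ints = AOIntegrals.build(shells)
    S, T, eri = ints.S, ints.T, ints.eri
    coords = system.coords_bohr
    q = system.nuclear_charges
    real = q != 0.0
    if real.any():
        V = integrals.point_charge_matrix(ints.shells, coords[real], q[real])
    else:
        V = np.zeros_like(S)
    h = T + V
    e_nuc = system.nuclear_repulsion()
    n_occ = system.n_electrons // 2
    X = orthogonalizer(S, lindep)
    if occupation not in ("aufbau", "mom"):
        raise ValueError(f"unknown occupation mode {occupation!r}")
    if occupation == "mom" and guess_occ is None:
        raise ValueError("occupation='mom' needs guess_occ")

    def solve(F):
        Fp = X.T @ F @ X
        w, Cp = np.linalg.eigh(Fp)
        return w, X @ Cp

    def pick_occ(w, C, ref_occ):
        if occupation == "aufbau" or ref_occ is None:
            return np.arange(n_occ)
        proj = ref_occ.T @ S @ C             # (n_occ_ref, nmo)
        weight = np.sum(proj * proj, axis=0)
        sel = np.sort(np.argsort(weight)[::-1][:n_occ])
        return sel

    ref_occ = guess_occ
    if guess_occ is not None:
        C_occ = guess_occ
        mo_e, C = None, None
    else:
        mo_e, C = solve(h)
        C_occ = C[:, pick_occ(mo_e, C, ref_occ)]
    D = 2.0 * C_occ @ C_occ.T
    e_old = 0.0
    err_list: list[np.ndarray] = []
    f_list: list[np.ndarray] = []
    converged = False
    for it in range(1, max_cycles + 1):
        J = coulomb(eri, D)
        K = exchange(eri, D)
        F = h + J - 0.5 * K
        e_elec = float(np.sum(D * h) + 0.5 * np.sum(D * (J - 0.5 * K)))
        # DIIS on the orthonormal-basis gradient
        err = X.T @ (F @ D @ S - S @ D @ F) @ X
        err_list.append(err)
        f_list.append(F)
        if len(err_list) > diis_size:
            err_list.pop(0)
            f_list.pop(0)
        if len(err_list) >= 2:
            m = len(err_list)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for a in range(m):
                for b in range(m):
                    B[a, b] = np.sum(err_list[a] * err_list[b])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:m]
                F = sum(ci * Fi for ci, Fi in zip(c, f_list))
            except np.linalg.LinAlgError:
                pass
        mo_e, C = solve(F)
        occ_idx = pick_occ(mo_e, C, ref_occ)
        C_occ = C[:, occ_idx]
        if occupation == "mom":
            ref_occ = C_occ
        D_new = 2.0 * C_occ @ C_occ.T
        d_rms = np.sqrt(np.mean((D_new - D) ** 2))
        d_e = abs(e_elec - e_old)
        D, e_old = D_new, e_elec
        if it > 1 and d_e < conv_energy and d_rms < conv_density:
            converged = True
            break
    if not converged:
        raise SCFConvergenceError(
            f"SCF not converged in {max_cycles} cycles "
            f"(dE={d_e:.3e}, dD={d_rms:.3e})")
    # final energy with the converged density
    J = coulomb(eri, D)
    K = exchange(eri, D)
    e_elec = float(np.sum(D * h) + 0.5 * np.sum(D * (J - 0.5 * K)))
    # occupied columns first (MOM may occupy out of eigenvalue order)
    order = np.concatenate([occ_idx,
                            np.setdiff1d(np.arange(C.shape[1]), occ_idx)])
    return SCFResult(energy=e_elec + e_nuc, energy_elec=e_elec,
                     mo_coeff=C[:, order], mo_energy=mo_e[order], density=D,
                     n_occ=n_occ, converged=True, n_iter=it)
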