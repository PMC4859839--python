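"""Small rigid monomer geometries used to build test dimers.

Geometries are idealized (experimental or standard internal coordinates),
adequate for interaction-energy scans and fixtures; none of them claims to
be an ab-initio-optimized structure.  Coordinates in Å.
"""

from __future__ import annotations

import numpy as np

from .fragments import MolecularFragment


def _rotation_between(u, v) -> np.ndarray:
    """Rotation matrix sending unit vector u onto unit vector v (Rodrigues)."""
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any perpendicular axis
        a = np.array([1.0, 0, 0]) if abs(u[0]) < 0.9 else np.array([0, 1.0, 0])
        k = np.cross(u, a)
        k /= np.linalg.norm(k)
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        return np.eye(3) + 2 * K @ K
    k = np.cross(u, v)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + K + K @ K / (1 + c)


def helium() -> MolecularFragment:
    return MolecularFragment(["He"], np.zeros((1, 3)), label="He")


def h2(bond: float = 0.7414) -> MolecularFragment:
    """Hydrogen molecule along z, centered at the origin."""
    z = bond / 2
    return MolecularFragment(["H", "H"], [[0, 0, -z], [0, 0, z]], label="H2")


def lithium_cation() -> MolecularFragment:
    return MolecularFragment(["Li"], np.zeros((1, 3)), net_charge=1,
                             label="Li+")


def fluoride_anion() -> MolecularFragment:
    return MolecularFragment(["F"], np.zeros((1, 3)), net_charge=-1,
                             label="F-")


def water(role: str = "plain") -> MolecularFragment:
    """Water monomer (r_OH 0.9572 Å, angle 104.52°), O at the origin.

    role='donor'    one O-H bond along +x (H-bond donor toward +x)
    role='acceptor' both O-H bonds pointing into +x half-space, so the
                    oxygen lone pairs face -x
    role='axial'    C2v axis (dipole) along +x
    role='plain'    C2v axis along -z (textbook orientation)
    """
    r, half = 0.9572, np.deg2rad(104.52) / 2
    if role == "plain":
        coords = [[0, 0, 0],
                  [0, r * np.sin(half), -r * np.cos(half)],
                  [0, -r * np.sin(half), -r * np.cos(half)]]
    elif role == "donor":
        ang = np.deg2rad(104.52)
        coords = [[0, 0, 0], [r, 0, 0],
                  [r * np.cos(ang), r * np.sin(ang), 0]]
    elif role == "acceptor":
        coords = [[0, 0, 0],
                  [r * np.cos(half), 0, r * np.sin(half)],
                  [r * np.cos(half), 0, -r * np.sin(half)]]
    elif role == "axial":
        coords = [[0, 0, 0],
                  [r * np.cos(half), r * np.sin(half), 0],
                  [r * np.cos(half), -r * np.sin(half), 0]]
    else:
        raise ValueError(f"unknown water role {role!r}")
    return MolecularFragment(["O", "H", "H"], coords, label=f"H2O({role})")


WATER_DONOR_H = 1          # atom index of the donating hydrogen
WATER_O = 0


def formamide() -> MolecularFragment:
    """Planar formamide HC(=O)NH2 in the xy plane; C at the origin.

    Atom order: C, O, N, H(C), H(N, anti to C=O), H(N, syn to C=O).
    """
    C = np.zeros(3)
    O = np.array([1.212, 0.0, 0.0])
    N = 1.368 * np.array([np.cos(np.deg2rad(125)), np.sin(np.deg2rad(125)), 0])
    HC = 1.102 * np.array([np.cos(np.deg2rad(-123)),
                           np.sin(np.deg2rad(-123)), 0])
    u = (C - N) / np.linalg.norm(C - N)

    def rot2(vec, deg):
        t = np.deg2rad(deg)
        return np.array([vec[0] * np.cos(t) - vec[1] * np.sin(t),
                         vec[0] * np.sin(t) + vec[1] * np.cos(t), 0.0])

    HN_anti = N + 1.002 * rot2(u, 119)
    HN_syn = N + 1.002 * rot2(u, -119)
    return MolecularFragment(["C", "O", "N", "H", "H", "H"],
                             [C, O, N, HC, HN_anti, HN_syn],
                             label="formamide")


FORMAMIDE_O = 1
FORMAMIDE_N = 2
FORMAMIDE_H_ANTI = 4


def formamide_donor() -> MolecularFragment:
    """Formamide oriented with the anti N-H bond along +x, H at the origin."""
    f = formamide()
    n, h = f.coords[FORMAMIDE_N], f.coords[FORMAMIDE_H_ANTI]
    R = _rotation_between(h - n, [1.0, 0, 0])
    return MolecularFragment(f.symbols, (f.coords - h) @ R.T, f.net_charge,
                             1, "formamide(donor)")


def formamide_acceptor() -> MolecularFragment:
    """Formamide oriented with the C=O bond along -x, O at the origin."""
    f = formamide()
    c, o = f.coords[0], f.coords[FORMAMIDE_O]
    R = _rotation_between(o - c, [-1.0, 0, 0])
    return MolecularFragment(f.symbols, (f.coords - o) @ R.T, f.net_charge,
                             1, "formamide(acceptor)")


def _methyl_hydrogens(c_methyl, attach, bond=1.09):
    """Three tetrahedral H positions on a methyl carbon."""
    u = (c_methyl - attach)
    u = u / np.linalg.norm(u)
    a = np.array([0, 0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0, 0])
    v = np.cross(u, a)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    t = np.deg2rad(109.47)      # H-C-attach tetrahedral angle
    out = []
    for phi in (0, 2 * np.pi / 3, 4 * np.pi / 3):
        d = np.cos(t) * (-u) + np.sin(t) * (np.cos(phi) * v + np.sin(phi) * w)
        out.append(c_methyl + bond * d / np.linalg.norm(d))
    return out


def methylguanidinium() -> MolecularFragment:
    """Planar methylguanidinium cation (arginine side-chain analogue), +1."""
    C0 = np.zeros(3)
    N1 = np.array([1.33, 0, 0])
    N2 = 1.33 * np.array([np.cos(np.deg2rad(120)), np.sin(np.deg2rad(120)), 0])
    N3 = 1.33 * np.array([np.cos(np.deg2rad(240)), np.sin(np.deg2rad(240)), 0])
    Cm = N1 + 1.46 * np.array([np.cos(np.deg2rad(60)),
                               np.sin(np.deg2rad(60)), 0])
    HN1 = N1 + 1.01 * np.array([np.cos(np.deg2rad(-60)),
                                np.sin(np.deg2rad(-60)), 0])
    H2a = N2 + 1.01 * np.array([np.cos(np.deg2rad(60)),
                                np.sin(np.deg2rad(60)), 0])
    H2b = N2 + 1.01 * np.array([-1.0, 0, 0])
    H3a = N3 + 1.01 * np.array([np.cos(np.deg2rad(-60)),
                                np.sin(np.deg2rad(-60)), 0])
    H3b = N3 + 1.01 * np.array([-1.0, 0, 0])
    Hm = _methyl_hydrogens(Cm, N1)
    syms = ["C", "N", "N", "N", "C", "H", "H", "H", "H", "H", "H", "H", "H"]
    coords = [C0, N1, N2, N3, Cm, HN1, H2a, H2b, H3a, H3b, *Hm]
    return MolecularFragment(syms, coords, net_charge=1,
                             label="methylguanidinium")


def acetate() -> MolecularFragment:
    """Acetate anion CH3COO-, carboxyl carbon at the origin, -1."""
    C1 = np.zeros(3)
    O1 = 1.25 * np.array([np.cos(np.deg2rad(65)), np.sin(np.deg2rad(65)), 0])
    O2 = 1.25 * np.array([np.cos(np.deg2rad(-65)), np.sin(np.deg2rad(-65)), 0])
    C2 = np.array([-1.52, 0, 0])
    Hm = _methyl_hydrogens(C2, C1)
    return MolecularFragment(["C", "O", "O", "C", "H", "H", "H"],
                             [C1, O1, O2, C2, *Hm], net_charge=-1,
                             label="acetate")
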