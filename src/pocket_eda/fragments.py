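"""Molecular fragments, residue–ligand dimers, and their file dialects.

A :class:`MolecularFragment` is a rigid set of atoms with an integral net
charge; a :class:`DimerSystem` pairs two fragments as the unit of
interaction-energy work.  Residue–ligand dimers can be excised from a PDB
complex with hydrogen caps closing the broken peptide bonds.

Coordinates are Cartesian Å throughout this module.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .qchem.basis import atomic_number

# standard cap bond lengths, Å
CAP_NH = 1.01
CAP_CH = 1.09

MIN_INTERFRAGMENT_DISTANCE = 0.5   # Å; closer contacts are unphysical here

BACKBONE_ATOMS = {"N", "CA", "C", "O", "H", "HA", "OXT", "H1", "H2", "H3",
                  "HA2", "HA3"}


class FragmentError(ValueError):
    """Invalid fragment or dimer construction."""


@dataclass
class MolecularFragment:
    """A rigid molecular fragment: elements, coordinates (Å), net charge."""

    symbols: list[str]
    coords: np.ndarray
    net_charge: int = 0
    multiplicity: int = 1
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) != len(self.coords):
            raise FragmentError("symbols and coordinates differ in length")
        if not np.all(np.isfinite(self.coords)):
            raise FragmentError("non-finite coordinates")
        for s in self.symbols:
            atomic_number(s)      # raises on unknown elements
        if self.multiplicity != 1:
            raise FragmentError(
                "only closed-shell (multiplicity 1) fragments are supported")
        if int(self.net_charge) != self.net_charge:
            raise FragmentError("net charge must be integral")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def n_electrons(self) -> int:
        return sum(atomic_number(s) for s in self.symbols) - self.net_charge

    def translated(self, shift) -> "MolecularFragment":
        return replace(self, coords=self.coords + np.asarray(shift, float))

    def rotated(self, R: np.ndarray, about=None) -> "MolecularFragment":
        about = np.zeros(3) if about is None else np.asarray(about, float)
        return replace(self, coords=(self.coords - about) @ np.asarray(R).T
                       + about)


@dataclass
class DimerSystem:
    """Two fragments sharing one (dimer-centered) basis."""

    fragment_a: MolecularFragment
    fragment_b: MolecularFragment
    basis_name: str = "STO-3G"

    def __post_init__(self):
        d = self.min_interfragment_distance()
        if d < MIN_INTERFRAGMENT_DISTANCE:
            raise FragmentError(
                f"inter-fragment atoms only {d:.3f} Å apart "
                f"(< {MIN_INTERFRAGMENT_DISTANCE} Å): fragments overlap")

    def min_interfragment_distance(self) -> float:
        diff = (self.fragment_a.coords[:, None, :]
                - self.fragment_b.coords[None, :, :])
        return float(np.sqrt((diff ** 2).sum(-1)).min())

    @property
    def total_charge(self) -> int:
        return self.fragment_a.net_charge + self.fragment_b.net_charge

    def swapped(self) -> "DimerSystem":
        return DimerSystem(self.fragment_b, self.fragment_a, self.basis_name)


# ---------------------------------------------------------------------------
# fragment-annotated XYZ dialect
# ---------------------------------------------------------------------------

_FRAG_RE = re.compile(
    r"FRAG_A=1\.\.(\d+)\s+FRAG_B=(\d+)\.\.(\d+)\s+"
    r"CHARGE_A=(-?\d+)\s+CHARGE_B=(-?\d+)")


def write_dimer_xyz(dimer: DimerSystem, path) -> None:
    """Write a dimer as XYZ with fragment/charge annotation on line 2."""
    a, b = dimer.fragment_a, dimer.fragment_b
    n = a.n_atoms + b.n_atoms
    lines = [str(n),
             f"FRAG_A=1..{a.n_atoms} FRAG_B={a.n_atoms + 1}..{n} "
             f"CHARGE_A={a.net_charge} CHARGE_B={b.net_charge}"]
    for frag in (a, b):
        for s, (x, y, z) in zip(frag.symbols, frag.coords):
            lines.append(f"{s:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dimer_xyz(path, basis_name: str = "STO-3G") -> DimerSystem:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    m = _FRAG_RE.search(lines[1])
    if m is None:
        raise FragmentError(
            f"{path}: missing FRAG_A/FRAG_B/CHARGE annotation on comment line")
    ka, kb0, kb1, qa, qb = (int(g) for g in m.groups())
    if kb0 != ka + 1 or kb1 != n:
        raise FragmentError(f"{path}: inconsistent fragment ranges")
    symbols, coords = [], []
    for ln in lines[2: 2 + n]:
        parts = ln.split()
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    coords = np.array(coords)
    fa = MolecularFragment(symbols[:ka], coords[:ka], qa, label="A")
    fb = MolecularFragment(symbols[ka:], coords[ka:], qb, label="B")
    return DimerSystem(fa, fb, basis_name)


# ---------------------------------------------------------------------------
# residue excision from a PDB complex
# ---------------------------------------------------------------------------

def load_residue_charges(path=None) -> dict[str, int]:
    """Formal net charges per residue name (packaged table by default)."""
    if path is None:
        ref = importlib.resources.files("pocket_eda") / "data" / \
            "residue_charges.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    return {k.upper(): int(v) for k, v in yaml.safe_load(text).items()}


def _resolve(structure, selector):
    """Resolve a '(chain, seqid)' tuple or 'CHAIN/SEQID' / 'RESNAME' string
    against a gemmi structure; returns (chain, residue)."""
    model = structure[0]
    if isinstance(selector, str) and "/" in selector:
        chain_name, seq = selector.split("/")
        selector = (chain_name, int(seq))
    if isinstance(selector, tuple):
        chain_name, seq = selector
        for chain in model:
            if chain.name == chain_name:
                for res in chain:
                    if res.seqid.num == seq:
                        return chain, res
        raise FragmentError(f"residue {selector!r} not found")
    # by residue name (first match) — convenient for a unique ligand
    for chain in model:
        for res in chain:
            if res.name == selector:
                return chain, res
    raise FragmentError(f"residue named {selector!r} not found")


def _residue_atoms(res):
    syms, coords, names = [], [], []
    for atom in res:
        syms.append(atom.element.name)
        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        names.append(atom.name)
    return syms, np.array(coords), names


def _cap_positions(chain, res, cap_scheme):
    """Hydrogen cap positions for broken bonds, as (element, xyz) pairs.

    Backbone scheme: the peptide bonds C(i-1)–N(i) and C(i)–N(i+1) are cut;
    caps are placed along the broken-bond vectors at N–H 1.01 Å / C–H 1.09 Å.
    Caps are only added where a bonded neighbour actually exists, so an
    already-excised fragment passes through unchanged.
    """
    caps = []
    residues = list(chain)
    i = next(k for k, r in enumerate(residues) if r is res)

    def atom_pos(r, name):
        for a in r:
            if a.name == name:
                return np.array([a.pos.x, a.pos.y, a.pos.z])
        return None

    if cap_scheme not in ("backbone", "sidechain"):
        raise FragmentError(f"unknown cap scheme {cap_scheme!r}")
    if cap_scheme == "sidechain":
        ca = atom_pos(res, "CA")
        cb = atom_pos(res, "CB")
        if ca is not None and cb is not None:
            u = (ca - cb) / np.linalg.norm(ca - cb)
            caps.append(("H", cb + CAP_CH * u))
        return caps
    n_pos = atom_pos(res, "N")
    c_pos = atom_pos(res, "C")
    if i > 0 and n_pos is not None:
        prev_c = atom_pos(residues[i - 1], "C")
        if prev_c is not None and np.linalg.norm(prev_c - n_pos) < 2.0:
            u = (prev_c - n_pos) / np.linalg.norm(prev_c - n_pos)
            caps.append(("H", n_pos + CAP_NH * u))
    if i < len(residues) - 1 and c_pos is not None:
        next_n = atom_pos(residues[i + 1], "N")
        if next_n is not None and np.linalg.norm(next_n - c_pos) < 2.0:
            u = (next_n - c_pos) / np.linalg.norm(next_n - c_pos)
            caps.append(("H", c_pos + CAP_CH * u))
    return caps


def extract_residue_dimer(structure, residue_selector, ligand_selector,
                          cap_scheme: str = "backbone",
                          ligand_charge: int | None = None,
                          residue_charge: int | None = None,
                          charge_table: dict[str, int] | None = None,
                          basis_name: str = "STO-3G") -> DimerSystem:
    """Excise one residue and one ligand from a complex as a capped dimer.

    `structure` is a gemmi.Structure or a PDB path.  The residue's broken
    peptide bonds are closed with hydrogen caps; its net charge comes from
    the residue-charge table unless `residue_charge` overrides it.  The
    ligand's formal charge is never guessed: `ligand_charge` is required.
    """
    import gemmi
    if not isinstance(structure, gemmi.Structure):
        structure = gemmi.read_structure(str(structure))
    chain_r, res = _resolve(structure, residue_selector)
    chain_l, lig = _resolve(structure, ligand_selector)
    if res is lig:
        raise FragmentError("residue and ligand selectors share atoms")
    if ligand_charge is None:
        raise FragmentError(
            "ligand net charge must be given explicitly (never guessed)")

    syms, coords, names = _residue_atoms(res)
    if cap_scheme == "sidechain":
        keep = [k for k, nm in enumerate(names) if nm not in BACKBONE_ATOMS
                or nm == "CB"]
        if not keep:
            raise FragmentError(f"{res.name} has no side chain to excise")
        syms = [syms[k] for k in keep]
        coords = coords[keep]
    caps = _cap_positions(chain_r, res, cap_scheme)
    for el, pos in caps:
        syms.append(el)
        coords = np.vstack([coords, pos])

    if residue_charge is None:
        table = charge_table if charge_table is not None \
            else load_residue_charges()
        if res.name.upper() not in table:
            raise FragmentError(
                f"no net charge known for residue {res.name!r}; pass "
                f"residue_charge explicitly")
        residue_charge = table[res.name.upper()]
        if cap_scheme == "sidechain" and res.name.upper() not in (
                "ARG", "LYS", "ASP", "GLU", "HIS"):
            residue_charge = 0

    lsyms, lcoords, _ = _residue_atoms(lig)
    frag_a = MolecularFragment(syms, coords, residue_charge,
                               label=f"{res.name}{res.seqid.num}")
    frag_b = MolecularFragment(lsyms, lcoords, ligand_charge, label=lig.name)
    return DimerSystem(frag_a, frag_b, basis_name)
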