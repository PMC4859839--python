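"""Excise a capped residue-ligand dimer from a (toy) PDB complex.

A three-glycine chain plus a water 'ligand' stands in for a real pocket;
the middle residue is cut out of the chain, the two broken peptide bonds
are closed with hydrogen caps, and the result is written in the
fragment-annotated XYZ dialect ready for decomposition.
"""

from pathlib import Path
import tempfile

from pocket_eda import extract_residue_dimer, write_dimer_xyz


def gly(i, seqid):
    x0 = 4.32 * i
    rows = [("N", "N", x0, 0.0, 0.0), ("CA", "C", x0 + 1.46, 0.0, 0.0),
            ("C", "C", x0 + 2.99, 0.0, 0.0), ("O", "O", x0 + 2.99, 1.23, 0.0)]
    return [("GLY", "A", seqid, *r) for r in rows]


rows = gly(0, 1) + gly(1, 2) + gly(2, 3) + [
    ("HOH", "B", 1, "O", "O", 2.0, 8.0, 0.0),
    ("HOH", "B", 1, "H1", "H", 2.76, 8.59, 0.0),
    ("HOH", "B", 1, "H2", "H", 1.24, 8.59, 0.0)]
pdb_text = "".join(
    f"ATOM  {i + 1:5d}  {name:<3s} {res:>3s} {ch}{seq:4d}    "
    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n"
    for i, (res, ch, seq, name, el, x, y, z) in enumerate(rows)) + "END\n"

with tempfile.TemporaryDirectory() as td:
    pdb = Path(td) / "toy_complex.pdb"
    pdb.write_text(pdb_text)
    dimer = extract_residue_dimer(pdb, ("A", 2), "HOH", ligand_charge=0)
    out = Path(td) / "gly2_water.xyz"
    write_dimer_xyz(dimer, out)
    print(f"residue fragment: {dimer.fragment_a.label}, "
          f"{dimer.fragment_a.n_atoms} atoms "
          f"(4 backbone + 2 hydrogen caps), "
          f"charge {dimer.fragment_a.net_charge:+d}")
    print(f"ligand fragment:  {dimer.fragment_b.label}, "
          f"{dimer.fragment_b.n_atoms} atoms, "
          f"charge {dimer.fragment_b.net_charge:+d}")
    print("XYZ annotation line:", out.read_text().splitlines()[1])
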