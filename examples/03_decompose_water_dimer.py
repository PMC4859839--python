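"""Decompose the HF interaction energy of a hydrogen-bonded water dimer.

The donor O-H points at the acceptor oxygen (O...O = 3.0 Å).  Expected
hydrogen-bond signature: attractive electrostatics, repulsive exchange,
attractive delocalization, net attraction — and the components must sum to
the supermolecular interaction energy exactly.
"""

from pocket_eda import DimerScanSpec, decompose, make_dimer_scan
from pocket_eda import templates

dimer = make_dimer_scan(DimerScanSpec(
    templates.water("donor"), templates.water("acceptor"),
    separations=(3.0,), basis_name="STO-3G"))[0]

r = decompose(dimer, label="water-dimer")
print(f"basis: {r.basis_name}; energies in kcal/mol")
print(f"  eps_el(10)  = {r.e_el_10:8.3f}   (electrostatics, frozen monomers)")
print(f"  dE_ex(HL)   = {r.e_ex_hl:8.3f}   (Pauli repulsion)")
print(f"  E(HL)       = {r.e_hl:8.3f}   (= el + ex)")
print(f"  dE_del(HF)  = {r.e_del_hf:8.3f}   (induction + charge transfer)")
print(f"  dE(HF)      = {r.e_hf:8.3f}   (= el + ex + del)")
resid = abs(r.e_hf - (r.e_el_10 + r.e_ex_hl + r.e_del_hf))
print(f"additivity residual: {resid:.1e} kcal/mol")
print(f"covalency ratio dE_del/eps_el = {r.e_del_hf / r.e_el_10:.2f}")
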