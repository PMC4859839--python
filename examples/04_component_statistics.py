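"""Rank correlations and covalency classification of the packaged
per-residue interaction-energy table (deacetylase pocket vs ADP-HPD).

The table holds one row per pocket residue (plus the ADP/NICO ligand
sub-fragments) with the five decomposition quantities in kcal/mol.
"""

from pocket_eda import (correlation_table, covalency_report,
                        load_reference_components, spearman_rho)
from pocket_eda.interaction_stats import AMINO_ACID_EXCLUDE

table = load_reference_components()
residues = table.select(exclude=AMINO_ACID_EXCLUDE)
print(f"{len(residues)} amino-acid rows (ligand sub-fragments excluded)")

rho = spearman_rho(residues.frame["e_el_10"], residues.frame["e_del_hf"])
print(f"Spearman rho(eps_el, dE_del) = {rho:.2f}  "
      "(strong monotone association: the residues with the most negative "
      "electrostatics also polarize the ligand most)")

corr = correlation_table(table, exclude=AMINO_ACID_EXCLUDE)
print("\nfull rank-correlation matrix:")
print(corr.matrix.round(2))

print("\ncovalency classification (ratio > 0.45 -> partially covalent):")
rep = covalency_report(table)
print(rep.frame.round(2).to_string(index=False))
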