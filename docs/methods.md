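# Methods

`pocket_eda` reimplements, at desk scale, the analysis chain commonly
applied to a protein–ligand binding pocket after docking and molecular
dynamics: per-contact hydrogen-bond statistics over a trajectory, selection
of a representative snapshot, excision of residue–ligand dimers, a
Hartree–Fock variational–perturbational interaction-energy decomposition of
those dimers, and rank-correlation / covalency post-processing of the
resulting component tables.  The reference system the packaged data
describes is the active site of the yeast sirtuin Hst2 (an NAD⁺-dependent
deacetylase of the Sir2 family) in complex with the inhibitor ADP-HPD, a
carba-NAD⁺ analogue.

## Interaction-energy decomposition

For a dimer A–B the supermolecular restricted-HF interaction energy is
partitioned as

```
ΔE^HF = ε_el^(10) + ΔE_ex^HL + ΔE_del^HF
```

* **ε_el^(10)** — first-order electrostatics: the Coulomb interaction of
  the two *unperturbed* monomer charge distributions,
  `Tr(D_A J[D_B]) + Tr(D_A V_B) + Tr(D_B V_A) + E_nn(A,B)`, with no
  antisymmetrization between the fragments.
* **ΔE_ex^HL** — Heitler–London exchange: the Pauli-repulsion remainder
  `E^HL − ε_el^(10)`, where `E^HL` is the interaction energy of the
  antisymmetrized product of the frozen monomer determinants.
* **ΔE_del^HF** — delocalization (deformation): the SCF relaxation
  remainder `ΔE^HF − E^HL`, containing mutual polarization (induction) and
  charge transfer.  Its ratio to ε_el^(10) is used downstream as a
  covalency indicator.

Correlation-level contributions (dispersion, exchange–dispersion, the
correlation correction to electrostatics) are out of scope by design; the
partition is purely at the HF level.

**Dimer-centered basis set (DCBS).**  Every quantity — both monomer SCF
solutions, `E^HL` and the supermolecular energy — is evaluated in the full
dimer basis, with the partner's nuclei present as zero-charge ghost
centers.  Because monomers and dimer share one basis, the interaction
energy and each component are free of basis-set superposition error by
construction; "adding" further ghost functions at the partner's positions
changes nothing because they are already there.  One integral build is
shared by all three SCF problems of a dimer.

**Evaluation of E^HL.**  The occupied monomer orbitals (each set expressed
over the full dimer basis) are concatenated and Löwdin-orthogonalized
through the inverse square root of their mutual overlap; the closed-shell
single-determinant energy of the result equals the energy of the
antisymmetrized product of the two monomer determinants.  The test suite
cross-checks this route against an independent evaluation through the
spin-orbital inverse-overlap (generalized Slater–Condon) formula for
nonorthogonal determinants, to 1e-8 hartree.  A combined occupied overlap
with an eigenvalue below `singular_tol` (default 1e-8) is refused: the
fragments are unphysically close or the basis is degenerate.

**Monomer SCF occupation.**  Monomer orbitals in the DCBS are obtained by a
maximum-overlap (MOM) SCF seeded with the isolated-monomer solution: at
each cycle the occupied set is the eigenvectors with the largest projection
onto the previous occupied space rather than the lowest-eigenvalue set.
For ordinary neutral closed-shell monomers this coincides with the aufbau
solution; for weakly bound anions (a minimal-basis F⁻ has a positive HOMO)
it prevents the monomer's electrons from spuriously collapsing onto the
partner's ghost functions, which would otherwise contaminate every
component.  The supermolecular dimer SCF remains a plain aufbau ground
state.

**The HF engine.**  Integrals (overlap, kinetic, nuclear attraction /
point-charge, two-electron repulsion) are evaluated by the
McMurchie–Davidson Hermite-expansion scheme over contracted Cartesian
Gaussians, with the Boys function computed from the regularized incomplete
gamma function.  The SCF is closed-shell restricted HF with DIIS, a
core-Hamiltonian guess, canonical orthogonalization (eigenvalue cutoff
`lindep`, default 1e-6) for near-linearly-dependent bases, and convergence
thresholds of 1e-9 hartree on the energy and 1e-7 RMS on the density.
Open-shell fragments are rejected; every system this package targets is
closed shell.  The engine reproduces standard anchors: H₂/STO-3G at
R = 1.4 a₀ gives −1.11671 Ha, He/STO-3G −2.807784 Ha, H₂O/6-31G
−75.98397 Ha, CH₄/6-31G −40.18053 Ha.

**Basis sets.**  STO-3G is shipped for H–Ne and 6-31G for H, C, O; both
contain only s and p shells, for which Cartesian and spherical Gaussians
coincide.  These desk-scale bases are the package default for tests and
examples; production-quality decompositions of real pocket dimers would use
a correlation-consistent basis (e.g. aug-cc-pVDZ) at cluster scale, which
changes absolute component values but none of the identities or qualitative
properties verified here.  Energies are reported in kcal/mol using
1 hartree = 627.509474 kcal/mol (recorded in every result's metadata);
coordinates are Å externally and bohr internally
(1 bohr = 0.529177210903 Å).

## Synthetic trajectories

The generator is a statistical stand-in for MD output, not an MD engine.
Each monitored hydrogen bond is prescribed as a Gaussian mixture of
length components (weights summing to 1; means confined to the 1.5–3.5 Å
histogram domain; a zero standard deviation yields an exactly constant
bond).  Samples are truncated to 1.0–5.0 Å by rejection; each bond draws
from its own RNG substream derived deterministically from the global seed
and the bond label (CRC-32), so trajectories are bit-reproducible and
insensitive to spec ordering.  Geometrically, each bond occupies an
isolated donor–H–acceptor "lane" and the acceptor moves along a fixed axis
so the drawn distance is realized exactly (to 1e-9 Å); ring-distance series
are realized the same way by translating one carbon triangle relative to
another.  What the generator deliberately lacks: force-field energetics,
solvent, coupling between contacts, autocorrelation in time, and angular
H-bond structure.  Passing statistics-recovery tests therefore demonstrates
the correctness of the estimators, not MD realism.

The demo mixtures in the pipeline configuration mimic the qualitative
shapes seen in deacetylase-pocket data — a bimodal carboxylate contact
(strong mode near 1.9 Å plus a long tail, as when two rotatable carboxyl
oxygens alternate), unimodal medium-strength amide contacts near 2.1–2.2 Å,
and a ring–ring distance straddling the 5 Å stacking criterion — with 2000
frames by default (10⁴ in the statistics-recovery checks, where ±2 % bin
accuracy is the verified level).

## Trajectory statistics

Hydrogen bonds are monitored as user-declared hydrogen/acceptor atom pairs
and measured by the plain H⋯acceptor Euclidean distance — no angular
criterion, since occupancy and the frequency tables are defined on
distances alone.  Frequency tables use eight half-open 0.25-Å bins with
centers 1.625 … 3.375 Å; a value exactly on an edge belongs to the upper
bin; frames outside the window count in the denominator but in no bin, so
row sums may be below 100 %.  Occupancy is the percentage of frames at or
below a cutoff (default 3.5 Å, the end of the binned window).  The
strong/medium/weak "binding power" labels (< 2.0 Å / 2.0–2.6 Å / ≥ 2.6 Å)
are conventions of this package, configurable and marked as such.
Ring–ring proximity uses unweighted centroid–centroid distance by default
(a per-atom-pair minimum is available), with a 5 Å contact threshold.
RMSD uses optional Kabsch superposition; with superposition the RMSD can
never exceed the unsuperposed value, and rigid motions give exactly zero.

## Representative-frame selection

Two criteria define the representative snapshot: (i) every monitored
distance lies in the most-populated ("modal") bin of its own distribution,
and (ii) among such frames the summed hydrogen-bond length is minimal.
The criteria do not by themselves give a total order, so the package makes
the combination explicit: *strict* mode demands (i) and minimizes (ii),
erroring if no frame qualifies; *lexicographic* mode maximizes the count of
modal memberships and then minimizes the total; *auto* falls back from
strict to lexicographic.  Modal-bin ties break toward the shorter distance,
and all remaining ties break toward the lowest frame index, making
selection deterministic and order-invariant.  Ring-distance series
participate in modal membership only — the minimized total runs over
hydrogen bonds alone, since total *bond length* is the affinity proxy.
Frame indices are 0-based throughout the API and reports.  The selector is
verified against exhaustive enumeration on every instance up to 100 frames.

## Fragment excision

A pocket residue is excised with its backbone: the two peptide bonds
C(i−1)–N(i) and C(i)–N(i+1) are cut and closed with hydrogen caps placed
exactly on the broken-bond vectors at standard lengths (N–H 1.01 Å,
C–H 1.09 Å).  Caps are added only where a bonded neighbour actually exists,
so re-extracting an already-excised fragment is a no-op.  A side-chain-only
scheme (cut Cα–Cβ, cap Cβ) is available by flag; the choice of chemical
boundary is deliberately explicit and configurable rather than hard-coded.
Residue formal charges come from a packaged table (ARG/LYS +1, ASP/GLU −1,
others including acetyllysine 0); an unknown residue name without an
explicit charge is a hard error, and the ligand's formal charge must always
be given by the caller — it is never guessed.

## Component statistics

Spearman's ρ is computed by the plain rank-difference formula
`ρ = 1 − 6Σd²/(n(n²−1))` with no tie correction; energy components are
continuous, so ties are pathological and only raise a warning.  The default
row set for pocket-level correlations is the 15 amino-acid rows of the
packaged reference table (the ADP and NICO ligand-fragment rows excluded),
which reproduces ρ(ε_el, ΔE_del) = 0.76.  Hydrogen bonds with
ΔE_del^HF/ε_el^(10) strictly above 0.45 are classified partially covalent
— delocalization at that relative weight signals charge-transfer character
— otherwise electrostatic.  Ratios and energies are displayed at 2 dp;
full precision is kept in JSON.  On ingestion of externally rounded tables
the per-row additivity |ε_el + ΔE_ex + ΔE_del − ΔE^HF| is checked against a
0.05 kcal/mol tolerance (warning, not error: the packaged reference table
itself carries one row with a 0.03 kcal/mol printing inconsistency);
internally computed rows satisfy the identity to 1e-8 kcal/mol by
construction.

## Numerical and design notes

* Problem sizes: tests and the acceptance script use minimal-basis dimers
  of 2–26 basis functions (He₂, H₂–H₂, Li⁺F⁻, the water dimer), 10⁴-frame
  synthetic trajectories, and ≤100-frame selection instances; these sizes
  make every check exact or statistically tight while keeping a full run in
  well under a minute.
* The ERI build screens shell quartets by Gaussian-product weight, so
  widely separated dimers (the 100 Å non-interacting limit) cost nothing
  and the far-limit components vanish to < 1e-4 kcal/mol.
* Degenerate inputs: zero-variance mixtures, all-out-of-range histograms
  (no modal bin → selection error), empty series, overlapping fragments
  (< 0.5 Å inter-fragment contact), odd electron counts and singular
  occupied overlaps are all explicit errors rather than silent surprises.
* Known limitations: no MP2-level partition; no open shells; no angular
  H-bond criterion; shipped bases stop at s/p shells (no d functions, so
  second-row elements end at Ne and the basis menu is intentionally
  small); the synthetic generator's independence across contacts means
  joint statistics between bonds carry no information.
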