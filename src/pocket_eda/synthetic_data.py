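"""Synthetic trajectories and dimer scans for exercising the pipeline.

This module is a statistical stand-in for docking + molecular-dynamics
output, not an MD engine: hydrogen-bond lengths and ring-centroid distances
are drawn from prescribed Gaussian mixtures (truncated to a physical range
by rejection sampling) and realized exactly in toy Cartesian geometries, so
every downstream statistic has a known generating distribution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fragments import DimerSystem, MolecularFragment

TRUNCATION_RANGE = (1.0, 5.0)   # Å, for H-bond mixtures
RING_TRUNCATION_RANGE = (2.0, 12.0)

__all__ = [
    "HBondSpec", "RingSpec", "ToyTrajectory", "DimerScanSpec",
    "make_hbond_trajectory", "make_dimer_scan", "sample_mixture",
    "mixture_cdf", "load_hbond_specs", "write_xyz_trajectory",
    "write_pdb_trajectory",
]


class SyntheticConfigError(ValueError):
    """Inconsistent synthetic-trajectory configuration."""


@dataclass(frozen=True)
class HBondSpec:
    """Prescription for one monitored hydrogen bond's length distribution.

    `mixture` is a list of (weight, mean Å, sd Å) Gaussian components;
    weights must sum to one, means must lie in the histogram domain
    [1.5, 3.5] Å, and sd may be zero (degenerate, exactly-constant bond).
    """

    bond_id: str
    mixture: tuple[tuple[float, float, float], ...]
    n_frames: int
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mixture",
                           tuple((float(w), float(m), float(s))
                                 for w, m, s in self.mixture))
        w = sum(c[0] for c in self.mixture)
        if abs(w - 1.0) > 1e-12:
            raise SyntheticConfigError(
                f"{self.bond_id}: mixture weights sum to {w}, not 1")
        for _, m, s in self.mixture:
            if not 1.5 <= m <= 3.5:
                raise SyntheticConfigError(
                    f"{self.bond_id}: component mean {m} outside [1.5, 3.5] Å")
            if s < 0:
                raise SyntheticConfigError(f"{self.bond_id}: negative sd")
        if self.n_frames < 1:
            raise SyntheticConfigError(f"{self.bond_id}: n_frames < 1")


@dataclass(frozen=True)
class RingSpec:
    """Prescription for a ring-centroid distance series (π-stacking proxy)."""

    ring_id: str
    mixture: tuple[tuple[float, float, float], ...]
    n_frames: int
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mixture",
                           tuple((float(w), float(m), float(s))
                                 for w, m, s in self.mixture))
        w = sum(c[0] for c in self.mixture)
        if abs(w - 1.0) > 1e-12:
            raise SyntheticConfigError(
                f"{self.ring_id}: mixture weights sum to {w}, not 1")
        if self.n_frames < 1:
            raise SyntheticConfigError(f"{self.ring_id}: n_frames < 1")


@dataclass
class ToyTrajectory:
    """Multi-frame toy geometry with declared monitored atom pairs.

    frames: (n_frames, n_atoms, 3) Å.  monitored_pairs maps a bond id to a
    (hydrogen index, acceptor index) tuple; ring_pairs maps a ring id to a
    pair of atom-index tuples.
    """

    frames: np.ndarray
    atom_labels: list[str]
    monitored_pairs: dict[str, tuple[int, int]] = field(default_factory=dict)
    ring_pairs: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = \
        field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise SyntheticConfigError("frames must have shape (n, atoms, 3)")
        if self.frames.shape[1] != len(self.atom_labels):
            raise SyntheticConfigError("atom_labels/frames length mismatch")
        if not np.all(np.isfinite(self.frames)):
            raise SyntheticConfigError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


def _substream(seed: int, label: str, spec_seed: int) -> np.random.Generator:
    """Deterministic per-series RNG derived from (seed, label)."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode()), int(spec_seed)])


def sample_mixture(mixture, n: int, rng: np.random.Generator,
                   lo: float, hi: float) -> np.ndarray:
    """Draw n values from a Gaussian mixture truncated to [lo, hi]
    by rejection sampling (degenerate sd=0 components pass through)."""
    w = np.array([c[0] for c in mixture])
    mu = np.array([c[1] for c in mixture])
    sd = np.array([c[2] for c in mixture])
    comp = rng.choice(len(w), size=n, p=w)
    x = rng.normal(mu[comp], sd[comp])
    bad = (x < lo) | (x > hi)
    while bad.any():
        comp_b = rng.choice(len(w), size=int(bad.sum()), p=w)
        x[bad] = rng.normal(mu[comp_b], sd[comp_b])
        bad = (x < lo) | (x > hi)
    return x


def mixture_cdf(mixture, x) -> np.ndarray:
    """CDF of the truncated mixture at x (same truncation as the sampler)."""
    from scipy.stats import norm
    lo, hi = TRUNCATION_RANGE
    x = np.asarray(x, dtype=float)
    num = np.zeros_like(x)
    den = 0.0
    for w, m, s in mixture:
        if s == 0.0:
            num = num + w * (x >= m)
            den += w
        else:
            num = num + w * (norm.cdf(np.clip(x, lo, hi), m, s)
                             - norm.cdf(lo, m, s))
            den += w * (norm.cdf(hi, m, s) - norm.cdf(lo, m, s))
    return num / den


# toy geometry layout constants
_DH_BOND = 1.0         # donor-H distance, Å
_LANE_SPACING = 10.0   # Å between bond lanes, prevents cross-talk
_RING_RADIUS = 1.2


def make_hbond_trajectory(specs, seed: int,
                          ring_specs=()) -> ToyTrajectory:
    """Realize H-bond (and optional ring-distance) mixtures as a trajectory.

    Each bond occupies its own 'lane': donor N at (0, 10k, 0), H displaced
    1 Å along +x, acceptor O placed so the H...O distance equals the drawn
    value exactly.  Ring specs add two carbon triangles whose centroid
    separation realizes the drawn series.  Identical (specs, seed) input
    reproduces the trajectory bit for bit.
    """
    specs = list(specs)
    if not specs:
        raise SyntheticConfigError("no H-bond specs given")
    n_frames = {s.n_frames for s in specs} | {r.n_frames for r in ring_specs}
    if len(n_frames) != 1:
        raise SyntheticConfigError(
            f"inconsistent n_frames across specs: {sorted(n_frames)}")
    n = n_frames.pop()

    labels: list[str] = []
    monitored: dict[str, tuple[int, int]] = {}
    rings: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {}
    cols: list[np.ndarray] = []       # static per-atom base positions
    moving: list[tuple[int, np.ndarray, np.ndarray]] = []

    for k, spec in enumerate(specs):
        y = k * _LANE_SPACING
        base = len(labels)
        labels += ["N", "H", "O"]
        cols += [np.array([0.0, y, 0.0]), np.array([_DH_BOND, y, 0.0]),
                 np.array([_DH_BOND, y, 0.0])]
        monitored[spec.bond_id] = (base + 1, base + 2)
        d = sample_mixture(spec.mixture, n,
                           _substream(seed, spec.bond_id, spec.seed),
                           *TRUNCATION_RANGE)
        moving.append((base + 2, np.array([1.0, 0.0, 0.0]), d))

    for k, rspec in enumerate(ring_specs):
        y = -(k + 1) * _LANE_SPACING
        base = len(labels)
        tri = _RING_RADIUS * np.array(
            [[0.0, np.cos(a), np.sin(a)]
             for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)])
        for v in tri:
            labels.append("C")
            cols.append(v + np.array([0.0, y, 0.0]))
        for v in tri:
            labels.append("C")
            cols.append(v + np.array([0.0, y, 0.0]))
        rings[rspec.ring_id] = (tuple(range(base, base + 3)),
                                tuple(range(base + 3, base + 6)))
        d = sample_mixture(rspec.mixture, n,
                           _substream(seed, rspec.ring_id, rspec.seed),
                           *RING_TRUNCATION_RANGE)
        for j in range(3):
            moving.append((base + 3 + j, np.array([1.0, 0.0, 0.0]), d))

    frames = np.tile(np.array(cols)[None, :, :], (n, 1, 1))
    for idx, axis, series in moving:
        frames[:, idx, :] += series[:, None] * axis[None, :]
    return ToyTrajectory(frames, labels, monitored, rings)


@dataclass(frozen=True)
class DimerScanSpec:
    """Rigid scan of monomer B along an axis relative to fixed monomer A.

    `separations` are the exact distances between `ref_atom_a` of A and
    `ref_atom_b` of B, strictly positive and strictly increasing.
    """

    monomer_a: MolecularFragment
    monomer_b: MolecularFragment
    separations: tuple[float, ...]
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    ref_atom_a: int = 0
    ref_atom_b: int = 0
    basis_name: str = "STO-3G"

    def __post_init__(self):
        sep = tuple(float(s) for s in self.separations)
        object.__setattr__(self, "separations", sep)
        if any(s <= 0 for s in sep):
            raise SyntheticConfigError("separations must be positive")
        if any(b <= a for a, b in zip(sep, sep[1:])):
            raise SyntheticConfigError("separations must strictly increase")
        ax = np.asarray(self.axis, dtype=float)
        nrm = np.linalg.norm(ax)
        if nrm == 0:
            raise SyntheticConfigError("axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(ax / nrm))


def make_dimer_scan(spec: DimerScanSpec) -> list[DimerSystem]:
    """One rigid dimer per separation (A fixed, B translated along axis)."""
    out = []
    axis = np.asarray(spec.axis)
    ra = spec.monomer_a.coords[spec.ref_atom_a]
    for s in spec.separations:
        target = ra + s * axis
        shift = target - spec.monomer_b.coords[spec.ref_atom_b]
        b = spec.monomer_b.translated(shift)
        out.append(DimerSystem(spec.monomer_a, b, spec.basis_name))
    return out


# ---------------------------------------------------------------------------
# configuration and file output
# ---------------------------------------------------------------------------

def load_hbond_specs(source) -> tuple[list[HBondSpec], list[RingSpec]]:
    """Read H-bond/ring mixture specs from a YAML mapping or file.

    Schema::

        n_frames: 2000
        hbonds:
          - bond_id: ASP118_O1
            mixture: [[0.7, 1.9, 0.12], [0.3, 2.9, 0.2]]
        rings:
          - ring_id: PHE44
            mixture: [[1.0, 4.8, 0.5]]
    """
    if not isinstance(source, dict):
        source = yaml.safe_load(Path(source).read_text())
    n = int(source["n_frames"])
    hb = [HBondSpec(bond_id=e["bond_id"],
                    mixture=tuple(tuple(c) for c in e["mixture"]),
                    n_frames=e.get("n_frames", n), seed=e.get("seed", 0))
          for e in source.get("hbonds", [])]
    rg = [RingSpec(ring_id=e["ring_id"],
                   mixture=tuple(tuple(c) for c in e["mixture"]),
                   n_frames=e.get("n_frames", n), seed=e.get("seed", 0))
          for e in source.get("rings", [])]
    return hb, rg


def write_xyz_trajectory(traj: ToyTrajectory, path) -> None:
    """Concatenated-XYZ frames (frame index on the comment line)."""
    lines = []
    for f in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        lines.append(f"frame {f}")
        for s, (x, y, z) in zip(traj.atom_labels, traj.frames[f]):
            lines.append(f"{s:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pdb_trajectory(traj: ToyTrajectory, path) -> None:
    """Multi-model PDB (MODEL/ATOM/ENDMDL records, one residue per frame)."""
    lines = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i, (s, (x, y, z)) in enumerate(
                zip(traj.atom_labels, traj.frames[f]), start=1):
            name = f"{s}{i}"[:4]
            lines.append(
                f"ATOM  {i:5d} {name:<4s} TOY A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {s:>2s}")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
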