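"""Per-bond distance series, binned frequency tables, occupancies,
ring-centroid distances and RMSD over a trajectory.

The frequency tables follow the convention of reporting bin centers spaced
0.25 Å apart (1.625, 1.875, ..., 3.375 by default); frames falling outside
the binned window still count in the denominator, so row sums are <= 100 %.
Bins are half-open [low, high): a value exactly on an edge belongs to the
upper bin.

'Strong/medium/weak' binding-power labels are a convention of this package
(configurable thresholds), not a universal definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import ToyTrajectory

DEFAULT_BIN_WIDTH = 0.25
DEFAULT_FIRST_CENTER = 1.625
DEFAULT_N_BINS = 8
DEFAULT_OCCUPANCY_CUTOFF = 3.5   # Å; end of the binned window
DEFAULT_RING_THRESHOLD = 5.0     # Å; stacking-contact criterion

# package-convention binding-power thresholds (Å)
STRONG_MAX = 2.0
MEDIUM_MAX = 2.6


class TrajectoryInputError(ValueError):
    pass


@dataclass
class HBondSeries:
    """Hydrogen...acceptor distance per frame for one monitored contact."""

    bond_id: str
    distances: np.ndarray
    donor_atom: int | None = None
    hydrogen_atom: int | None = None
    acceptor_atom: int | None = None

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        if self.distances.size == 0:
            raise TrajectoryInputError(f"{self.bond_id}: empty series")
        if not np.all(self.distances > 0):
            raise TrajectoryInputError(f"{self.bond_id}: nonpositive distance")

    @property
    def n_frames(self) -> int:
        return self.distances.size


@dataclass
class HistogramTable:
    """Binned frequency-of-occurrence table for one bond."""

    bond_id: str
    bin_centers: np.ndarray
    frequencies: np.ndarray        # percent of all frames
    n_frames_total: int
    counts: np.ndarray = field(default=None, repr=False)
    out_of_range: int = 0

    @property
    def bin_width(self) -> float:
        if len(self.bin_centers) > 1:
            return float(self.bin_centers[1] - self.bin_centers[0])
        return DEFAULT_BIN_WIDTH

    def bin_interval(self, k: int) -> tuple[float, float]:
        w = self.bin_width
        c = self.bin_centers[k]
        return (c - w / 2, c + w / 2)


@dataclass(frozen=True)
class RingPair:
    """Two disjoint atom-index sets defining ring centroids."""

    ring_a_atoms: tuple[int, ...]
    ring_b_atoms: tuple[int, ...]

    def __post_init__(self):
        a, b = tuple(self.ring_a_atoms), tuple(self.ring_b_atoms)
        object.__setattr__(self, "ring_a_atoms", a)
        object.__setattr__(self, "ring_b_atoms", b)
        if len(a) < 3 or len(b) < 3:
            raise TrajectoryInputError("a ring needs at least 3 atoms")
        if set(a) & set(b):
            raise TrajectoryInputError("ring atom sets overlap")


def hbond_series(trajectory: ToyTrajectory, pair: tuple[int, int],
                 bond_id: str | None = None,
                 donor_atom: int | None = None) -> HBondSeries:
    """Euclidean hydrogen...acceptor distance in every frame."""
    h, a = pair
    n_atoms = trajectory.n_atoms
    if not (0 <= h < n_atoms and 0 <= a < n_atoms):
        raise TrajectoryInputError(
            f"atom pair {pair} out of range for {n_atoms} atoms")
    d = np.linalg.norm(trajectory.frames[:, h, :] - trajectory.frames[:, a, :],
                       axis=1)
    return HBondSeries(bond_id or f"pair_{h}_{a}", d,
                       donor_atom=donor_atom, hydrogen_atom=h, acceptor_atom=a)


def bin_hbond_series(series: HBondSeries,
                     bin_width: float = DEFAULT_BIN_WIDTH,
                     first_center: float = DEFAULT_FIRST_CENTER,
                     n_bins: int = DEFAULT_N_BINS) -> HistogramTable:
    """Frequency (percent of all frames) per half-open 0.25-Å bin."""
    if bin_width <= 0 or n_bins < 1:
        raise TrajectoryInputError("bin_width must be > 0 and n_bins >= 1")
    d = series.distances
    low0 = first_center - bin_width / 2
    idx = np.floor((d - low0) / bin_width).astype(int)
    in_range = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[in_range], minlength=n_bins)[:n_bins]
    n = series.n_frames
    centers = first_center + bin_width * np.arange(n_bins)
    return HistogramTable(series.bond_id, centers, 100.0 * counts / n, n,
                          counts=counts, out_of_range=int(n - counts.sum()))


def occupancy(series: HBondSeries,
              cutoff: float = DEFAULT_OCCUPANCY_CUTOFF) -> float:
    """Percent of frames with distance <= cutoff."""
    if cutoff <= 0:
        raise TrajectoryInputError("cutoff must be positive")
    return float(100.0 * np.mean(series.distances <= cutoff))


def binding_power_fractions(series: HBondSeries,
                            strong_max: float = STRONG_MAX,
                            medium_max: float = MEDIUM_MAX) -> dict[str, float]:
    """Percent of frames with strong (< strong_max), medium
    ([strong_max, medium_max)) and weak (>= medium_max) contact distance."""
    d = series.distances
    return {"strong": float(100.0 * np.mean(d < strong_max)),
            "medium": float(100.0 * np.mean((d >= strong_max)
                                            & (d < medium_max))),
            "weak": float(100.0 * np.mean(d >= medium_max))}


def ring_centroid_series(trajectory: ToyTrajectory, pair: RingPair,
                         method: str = "centroid") -> np.ndarray:
    """Per-frame ring-ring distance: centroid-centroid (default) or the
    minimum over inter-ring atom pairs (method='min')."""
    fa = trajectory.frames[:, list(pair.ring_a_atoms), :]
    fb = trajectory.frames[:, list(pair.ring_b_atoms), :]
    if method == "centroid":
        return np.linalg.norm(fa.mean(axis=1) - fb.mean(axis=1), axis=1)
    if method == "min":
        diff = fa[:, :, None, :] - fb[:, None, :, :]
        return np.sqrt((diff ** 2).sum(-1)).min(axis=(1, 2))
    raise TrajectoryInputError(f"unknown ring-distance method {method!r}")


def fraction_below(series, threshold: float = DEFAULT_RING_THRESHOLD) -> float:
    """Fraction of frames with value <= threshold."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise TrajectoryInputError("empty series")
    return float(np.mean(series <= threshold))


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    return Vt.T @ D @ U.T


def rmsd_series(trajectory: ToyTrajectory, reference_frame: int = 0,
                atom_selection=None, superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD (Å) of the selection to a reference frame.

    With superpose=True the optimal rigid-body (Kabsch) superposition is
    removed first, which requires at least 3 selected atoms.
    """
    n = trajectory.n_frames
    if not 0 <= reference_frame < n:
        raise TrajectoryInputError("reference frame out of range")
    sel = (list(range(trajectory.n_atoms)) if atom_selection is None
           else list(atom_selection))
    if len(sel) == 0:
        raise TrajectoryInputError("empty atom selection")
    if superpose and len(sel) < 3:
        raise TrajectoryInputError("superposition needs >= 3 atoms")
    ref = trajectory.frames[reference_frame, sel, :]
    out = np.empty(n)
    ref_c = ref - ref.mean(axis=0)
    for f in range(n):
        cur = trajectory.frames[f, sel, :]
        if superpose:
            cur_c = cur - cur.mean(axis=0)
            R = _kabsch(cur_c, ref_c)
            diff = cur_c @ R.T - ref_c
        else:
            diff = cur - ref
        out[f] = np.sqrt(np.mean((diff ** 2).sum(axis=1)))
    return out


# ---------------------------------------------------------------------------
# trajectory file reading and table output
# ---------------------------------------------------------------------------

def read_trajectory(path, monitored_pairs=None, ring_pairs=None) -> ToyTrajectory:
    """Read a multi-model PDB or concatenated-XYZ trajectory.

    Atom ordering must be identical in every frame; monitored pairs / ring
    definitions (0-based indices) may be attached for downstream stages.
    """
    path = Path(path)
    if path.suffix.lower() in (".xyz",):
        frames, labels = _read_xyz_frames(path)
    else:
        frames, labels = _read_pdb_frames(path)
    return ToyTrajectory(frames, labels, dict(monitored_pairs or {}),
                         dict(ring_pairs or {}))


def _read_xyz_frames(path):
    lines = Path(path).read_text().splitlines()
    frames, labels = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        block = lines[i + 2: i + 2 + n]
        syms = [ln.split()[0] for ln in block]
        coords = [[float(v) for v in ln.split()[1:4]] for ln in block]
        if labels is None:
            labels = syms
        elif syms != labels:
            raise TrajectoryInputError(
                f"{path}: atom ordering changes between frames")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise TrajectoryInputError(f"{path}: no frames found")
    return np.array(frames), labels


def _read_pdb_frames(path):
    import gemmi
    st = gemmi.read_structure(str(path))
    frames, labels = [], None
    for model in st:
        syms, coords = [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    syms.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if labels is None:
            labels = syms
        elif len(syms) != len(labels):
            raise TrajectoryInputError(
                f"{path}: atom count changes between models")
        frames.append(coords)
    if not frames:
        raise TrajectoryInputError(f"{path}: no models found")
    return np.array(frames), labels


def load_pairs_config(source):
    """Monitored pairs and ring definitions from YAML (0-based indices).

    Schema::

        pairs:
          - bond_id: ASP118_O1
            hydrogen: 4
            acceptor: 11
        rings:
          - ring_id: PHE44
            ring_a: [0, 1, 2, 3, 4, 5]
            ring_b: [12, 13, 14]

    Returns (monitored_pairs, ring_pairs) dicts in the ToyTrajectory layout.
    """
    import yaml
    if not isinstance(source, dict):
        source = yaml.safe_load(Path(source).read_text())
    pairs = {e["bond_id"]: (int(e["hydrogen"]), int(e["acceptor"]))
             for e in source.get("pairs", [])}
    rings = {e["ring_id"]: (tuple(int(i) for i in e["ring_a"]),
                            tuple(int(i) for i in e["ring_b"]))
             for e in source.get("rings", [])}
    return pairs, rings


def histogram_frame(tables: list[HistogramTable],
                    decimals: int = 1) -> pd.DataFrame:
    """Frequency tables as one DataFrame (rows = bonds, columns = bin
    centers + out-of-range percent), rounded for display."""
    if not tables:
        raise TrajectoryInputError("no histogram tables")
    cols = [f"{c:.3f}" for c in tables[0].bin_centers]
    rows = {}
    for t in tables:
        vals = list(np.round(t.frequencies, decimals))
        vals.append(round(100.0 * t.out_of_range / t.n_frames_total, decimals))
        rows[t.bond_id] = vals
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=cols + ["out_of_range"])


def write_histogram_csv(tables: list[HistogramTable], path,
                        decimals: int = 1) -> None:
    histogram_frame(tables, decimals).to_csv(path, index_label="bond_id")
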