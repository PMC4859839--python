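"""Gaussian basis-set data and shell construction.

Shipped sets:

* ``STO-3G`` for H through Ne (Hehre–Stewart–Pople least-squares fits of
  three Gaussians per Slater orbital).
* ``6-31G`` for a subset of elements sufficient for the small hydrogen-bonded
  test systems used throughout the package.

Coordinates entering :class:`Shell` are in bohr; basis functions are
contracted Cartesian Gaussians (for the s/p shells shipped here the
Cartesian and spherical representations coincide).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]

ATOMIC_NUMBER = {sym: z for z, sym in enumerate(ELEMENTS)}


def atomic_number(symbol: str) -> int:
    """Nuclear charge for an element symbol (case-insensitive)."""
    sym = symbol.strip().capitalize()
    try:
        z = ATOMIC_NUMBER[sym]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None
    if z == 0:
        raise ValueError("'X' is reserved for ghost centers")
    return z


# ---------------------------------------------------------------------------
# STO-3G
#
# Each entry: list of (angular momenta string, exponents, {l: coefficients}).
# "SP" shells share exponents between the s and p contraction.
# ---------------------------------------------------------------------------

_S3G_1S_C = [0.15432897, 0.53532814, 0.44463454]
_S3G_2S_C = [-0.09996723, 0.39951283, 0.70011547]
_S3G_2P_C = [0.15591627, 0.60768372, 0.39195739]

_STO3G: dict[str, list] = {
    "H": [("S", [3.42525091, 0.62391373, 0.16885540], {"S": _S3G_1S_C})],
    "He": [("S", [6.36242139, 1.15892300, 0.31364979], {"S": _S3G_1S_C})],
    "Li": [
        ("S", [16.11957475, 2.93620066, 0.79465050], {"S": _S3G_1S_C}),
        ("SP", [0.63628970, 0.14786010, 0.04808870],
         {"S": _S3G_2S_C, "P": _S3G_2P_C}),
    ],
    "Be": [
        ("S", [30.16787069, 5.49511818, 1.48719276], {"S": _S3G_1S_C}),
        ("SP", [1.31483311, 0.30553890, 0.09937074],
         {"S": _S3G_2S_C, "P": _S3G_2P_C}),
    ],
    "B": [
        ("S", [48.79111318, 8.88738342, 2.40526704], {"S": _S3G_1S_C}),
        ("SP", [2.23695610, 0.51982050, 0.16906180],
         {"S": _S3G_2S_C, "P": _S3G_2P_C}),
    ],
    "C": [
        ("S", [71.61683735, 13.04509632, 3.53051216], {"S": _S3G_1S_C}),
        ("SP", [2.94124940, 0.68348310, 0.22228990],
         {"S": _S3G_2S_C, "P": _S3G_2P_C}),
    ],
    "N": [
        ("S", [99.10616896, 18.05231239, 4.88566024], {"S": _S3G_1S_C}),
        ("SP", [3.78045590, 0.87849660, 0.28571440],
         {"S": _S3G_2S_C, "P": _S3G_2P_C}),
    ],
    "O": [
        ("S", [130.70932140, 23.80886605, 6.44360831], {"S": _S3G_1S_C}),
        ("SP", [5.03315132, 1.16959612, 0.38038900],
         {"S": _S3G_2S_C, "P": _S3G_2P_C}),
    ],
    "F": [
        ("S", [166.67913400, 30.36081230, 8.21682070], {"S": _S3G_1S_C}),
        ("SP", [6.46480320, 1.50228120, 0.48858850],
         {"S": _S3G_2S_C, "P": _S3G_2P_C}),
    ],
    "Ne": [
        ("S", [207.01561000, 37.70815100, 10.20529700], {"S": _S3G_1S_C}),
        ("SP", [8.24631512, 1.91626625, 0.62322929],
         {"S": _S3G_2S_C, "P": _S3G_2P_C}),
    ],
}

# ---------------------------------------------------------------------------
# 6-31G (split valence); element coverage limited to what the shipped test
# systems need.
# ---------------------------------------------------------------------------

_631G: dict[str, list] = {
    "H": [
        ("S", [18.73113696, 2.82539437, 0.64012169],
         {"S": [0.03349460, 0.23472695, 0.81375733]}),
        ("S", [0.16127776], {"S": [1.0]}),
    ],
    "O": [
        ("S", [5484.67166, 825.234946, 188.046958, 52.9645000,
               16.8975704, 5.79963534],
         {"S": [0.00183107443, 0.0139501722, 0.0684450781,
                0.232714336, 0.470192898, 0.358520853]}),
        ("SP", [15.53961625, 3.599933586, 1.013761750],
         {"S": [-0.110777549525, -0.148026262701, 1.130767015354],
          "P": [0.070874268231, 0.339752839147, 0.727158577316]}),
        ("SP", [0.270005823], {"S": [1.0], "P": [1.0]}),
    ],
    "C": [
        ("S", [3047.52488, 457.369518, 103.948685, 29.2101553,
               9.28666296, 3.16392696],
         {"S": [0.0018347, 0.0140373, 0.0688426,
                0.2321844, 0.4679413, 0.3623120]}),
        ("SP", [7.86827235, 1.88128854, 0.544249258],
         {"S": [-0.1193324, -0.1608542, 1.1434564],
          "P": [0.0689991, 0.3164240, 0.7443083]}),
        ("SP", [0.1687144782], {"S": [1.0], "P": [1.0]}),
    ],
}

_BASIS_LIBRARY = {"STO-3G": _STO3G, "6-31G": _631G}

_ANGMOM = {"S": 0, "P": 1, "D": 2}

# double factorial (2n-1)!! for n = 0..
_DFACT = [1, 1, 3, 15, 105, 945]


@dataclass
class Shell:
    """One contracted Cartesian Gaussian shell on a center."""

    l: int
    center: np.ndarray          # bohr, shape (3,)
    exps: np.ndarray
    coefs: np.ndarray           # normalized contraction coefficients
    atom_index: int = -1

    @property
    def ncart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2

    def cart_components(self) -> list[tuple[int, int, int]]:
        return cart_components(self.l)


def cart_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian (lx, ly, lz) triples in canonical order (x first)."""
    return [(l - a, a - b, b) for a in range(l + 1) for b in range(a + 1)]


def _primitive_norm(alpha: float, l: int) -> float:
    # norm of x^l exp(-a r^2) style primitive, (l,0,0) component
    return ((2 * alpha / np.pi) ** 0.75
            * (4 * alpha) ** (l / 2.0)
            / np.sqrt(_DFACT[l]))


def make_shell(l: int, center, exps, coefs, atom_index: int = -1) -> Shell:
    """Build a shell with normalized contraction coefficients."""
    exps = np.asarray(exps, dtype=float)
    coefs = np.asarray(coefs, dtype=float)
    c = coefs * np.array([_primitive_norm(a, l) for a in exps])
    # normalize the contracted (l,0,0) function
    ee = exps[:, None] + exps[None, :]
    s = np.sum(c[:, None] * c[None, :]
               * (np.pi / ee) ** 1.5 * _DFACT[l] / (2 * ee) ** l)
    c /= np.sqrt(s)
    return Shell(l=l, center=np.asarray(center, dtype=float),
                 exps=exps, coefs=c, atom_index=atom_index)


def available_basis_sets() -> list[str]:
    return sorted(_BASIS_LIBRARY)


def shells_for_atom(symbol: str, basis_name: str, center,
                    atom_index: int = -1) -> list[Shell]:
    """Contracted shells of `basis_name` placed at `center` (bohr)."""
    key = basis_name.strip().upper().replace(" ", "")
    lib = None
    for name, table in _BASIS_LIBRARY.items():
        if name.replace("-", "").upper() == key.replace("-", ""):
            lib = table
            break
    if lib is None:
        raise ValueError(
            f"basis set {basis_name!r} not shipped; "
            f"available: {available_basis_sets()}")
    sym = symbol.strip().capitalize()
    if sym not in lib:
        raise ValueError(
            f"basis {basis_name!r} has no data for element {sym!r}")
    shells = []
    for block, exps, coef_map in lib[sym]:
        for lsym in block:          # "SP" expands to S then P
            shells.append(make_shell(_ANGMOM[lsym], center, exps,
                                     coef_map[lsym], atom_index))
    return shells
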