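"""McMurchie–Davidson evaluation of Gaussian one- and two-electron integrals.

All quantities are in atomic units.  Contracted Cartesian shells come from
:mod:`pocket_eda.qchem.basis`; the public entry points operate on a list of
shells and return matrices/tensors over the full (Cartesian) AO basis.

The implementation vectorizes over primitive pairs within a shell pair and
over primitive-pair products within a shell quartet, which keeps pure-Python
overhead acceptable for the few-tens-of-functions systems this package
targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc, gammaln

from .basis import Shell

__all__ = [
    "boys", "overlap_matrix", "kinetic_matrix", "nuclear_attraction_matrix",
    "point_charge_matrix", "electron_repulsion_tensor", "nbf",
]


def boys(nmax: int, x: np.ndarray) -> np.ndarray:
    """Boys functions F_n(x) for n = 0..nmax; returns shape (nmax+1,) + x.shape.

    Uses the regularized lower incomplete gamma function; a two-term Taylor
    expansion guards the x -> 0 limit.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty((nmax + 1,) + x.shape)
    small = x < 1e-13
    xs = np.where(small, 1.0, x)
    for n in range(nmax + 1):
        a = n + 0.5
        # F_n(x) = gamma(a) P(a, x) / (2 x^a)
        val = np.exp(gammaln(a)) * gammainc(a, xs) / (2.0 * xs ** a)
        out[n] = np.where(small, 1.0 / (2 * n + 1) - x / (2 * n + 3), val)
    return out


def _hermite_E(l1: int, l2: int, a: np.ndarray, b: np.ndarray,
               AB: np.ndarray) -> np.ndarray:
    """Hermite expansion coefficients E_t^{ij} for one Cartesian direction.

    `a`, `b` are primitive exponent arrays broadcast to the primitive-pair
    axis; `AB` is the scalar A-B separation along this direction.
    Returns array of shape (npp, l1+1, l2+1, l1+l2+1).
    """
    npp = a.shape[0]
    p = a + b
    mu = a * b / p
    E = np.zeros((npp, l1 + 1, l2 + 1, l1 + l2 + 2))
    E[:, 0, 0, 0] = np.exp(-mu * AB * AB)
    PA = -b * AB / p
    PB = a * AB / p
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                # build from (i-1, 0)
                src = E[:, i - 1, 0, :]
                X = PA
            else:
                src = E[:, i, j - 1, :]
                X = PB
            tmax = i + j
            dst = E[:, i, j, :]
            for t in range(tmax + 1):
                val = X * src[:, t]
                if t > 0:
                    val = val + src[:, t - 1] / (2 * p)
                val = val + (t + 1) * src[:, t + 1]
                dst[:, t] = val
    return E[:, :, :, : l1 + l2 + 1]


@dataclass
class _ShellPair:
    """Precomputed data for a pair of shells."""

    la: int
    lb: int
    p: np.ndarray           # (npp,) combined exponents
    cc: np.ndarray          # (npp,) contraction coefficient products
    P: np.ndarray           # (npp, 3) Gaussian product centers
    E3: np.ndarray          # (npp, ncA, ncB, Lt+1, Lu+1, Lv+1)
    A: np.ndarray
    B: np.ndarray


def _shell_pair(sa: Shell, sb: Shell) -> _ShellPair:
    a = np.repeat(sa.exps, len(sb.exps))
    b = np.tile(sb.exps, len(sa.exps))
    cc = np.repeat(sa.coefs, len(sb.coefs)) * np.tile(sb.coefs, len(sa.coefs))
    p = a + b
    P = (a[:, None] * sa.center[None, :] + b[:, None] * sb.center[None, :]) \
        / p[:, None]
    AB = sa.center - sb.center
    Ex = _hermite_E(sa.l, sb.l, a, b, AB[0])
    Ey = _hermite_E(sa.l, sb.l, a, b, AB[1])
    Ez = _hermite_E(sa.l, sb.l, a, b, AB[2])
    compA = sa.cart_components()
    compB = sb.cart_components()
    L = sa.l + sb.l
    E3 = np.zeros((len(p), len(compA), len(compB), L + 1, L + 1, L + 1))
    for ia, (ix, iy, iz) in enumerate(compA):
        for ib, (jx, jy, jz) in enumerate(compB):
            ex = Ex[:, ix, jx, : ix + jx + 1]
            ey = Ey[:, iy, jy, : iy + jy + 1]
            ez = Ez[:, iz, jz, : iz + jz + 1]
            E3[:, ia, ib, : ix + jx + 1, : iy + jy + 1, : iz + jz + 1] = (
                ex[:, :, None, None] * ey[:, None, :, None]
                * ez[:, None, None, :])
    return _ShellPair(sa.l, sb.l, p, cc, P, E3, sa.center, sb.center)


def _hermite_R(L: int, p: np.ndarray, PC: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R^0_{tuv} for t+u+v <= L.

    `p` has shape (n,), `PC` shape (n, 3).  Returns (n, L+1, L+1, L+1)
    (entries with t+u+v > L are garbage-free zeros of the recursion but
    unused by callers).
    """
    n = p.shape[0]
    r2 = np.einsum("ni,ni->n", PC, PC)
    F = boys(L, p * r2)
    # R^n_{000} = (-2p)^n F_n
    base = np.empty((L + 1, n))
    mul = np.ones(n)
    for order in range(L + 1):
        base[order] = mul * F[order]
        mul = mul * (-2.0 * p)

    cache: dict[tuple[int, int, int, int], np.ndarray] = {}

    def R(t: int, u: int, v: int, order: int) -> np.ndarray:
        key = (t, u, v, order)
        if key in cache:
            return cache[key]
        if t == u == v == 0:
            val = base[order]
        elif t > 0:
            val = PC[:, 0] * R(t - 1, u, v, order + 1)
            if t > 1:
                val = val + (t - 1) * R(t - 2, u, v, order + 1)
        elif u > 0:
            val = PC[:, 1] * R(t, u - 1, v, order + 1)
            if u > 1:
                val = val + (u - 1) * R(t, u - 2, v, order + 1)
        else:
            val = PC[:, 2] * R(t, u, v - 1, order + 1)
            if v > 1:
                val = val + (v - 1) * R(t, u, v - 2, order + 1)
        cache[key] = val
        return val

    out = np.zeros((n, L + 1, L + 1, L + 1))
    for t in range(L + 1):
        for u in range(L + 1 - t):
            for v in range(L + 1 - t - u):
                out[:, t, u, v] = R(t, u, v, 0)
    return out


def nbf(shells: list[Shell]) -> int:
    return sum(s.ncart for s in shells)


def _offsets(shells: list[Shell]) -> list[int]:
    off, tot = [], 0
    for s in shells:
        off.append(tot)
        tot += s.ncart
    return off


def overlap_matrix(shells: list[Shell]) -> np.ndarray:
    n = nbf(shells)
    off = _offsets(shells)
    S = np.zeros((n, n))
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells):
            if j > i:
                continue
            sp = _shell_pair(sa, sb)
            pref = sp.cc * (np.pi / sp.p) ** 1.5
            blk = np.einsum("n,nab->ab", pref, sp.E3[:, :, :, 0, 0, 0])
            S[off[i]: off[i] + sa.ncart, off[j]: off[j] + sb.ncart] = blk
            S[off[j]: off[j] + sb.ncart, off[i]: off[i] + sa.ncart] = blk.T
    return S


def _kinetic_block(sa: Shell, sb: Shell) -> np.ndarray:
    a = np.repeat(sa.exps, len(sb.exps))
    b = np.tile(sb.exps, len(sa.exps))
    cc = np.repeat(sa.coefs, len(sb.coefs)) * np.tile(sb.coefs, len(sa.coefs))
    p = a + b
    AB = sa.center - sb.center
    # 1D overlap factors up to lb+2 in j
    Es = [_hermite_E(sa.l, sb.l + 2, a, b, AB[d]) for d in range(3)]
    sq = np.sqrt(np.pi / p)

    def S1(d, i, j):
        if j < 0 or i < 0:
            return np.zeros_like(p)
        return Es[d][:, i, j, 0] * sq

    def T1(d, i, j):
        val = -2.0 * b * b * S1(d, i, j + 2) + b * (2 * j + 1) * S1(d, i, j)
        if j >= 2:
            val = val - 0.5 * j * (j - 1) * S1(d, i, j - 2)
        return val

    compA = sa.cart_components()
    compB = sb.cart_components()
    blk = np.zeros((sa.ncart, sb.ncart))
    for ia, ca in enumerate(compA):
        for ib, cb in enumerate(compB):
            term = (T1(0, ca[0], cb[0]) * S1(1, ca[1], cb[1]) * S1(2, ca[2], cb[2])
                    + S1(0, ca[0], cb[0]) * T1(1, ca[1], cb[1]) * S1(2, ca[2], cb[2])
                    + S1(0, ca[0], cb[0]) * S1(1, ca[1], cb[1]) * T1(2, ca[2], cb[2]))
            blk[ia, ib] = np.sum(cc * term)
    return blk


def kinetic_matrix(shells: list[Shell]) -> np.ndarray:
    n = nbf(shells)
    off = _offsets(shells)
    T = np.zeros((n, n))
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells):
            if j > i:
                continue
            blk = _kinetic_block(sa, sb)
            T[off[i]: off[i] + sa.ncart, off[j]: off[j] + sb.ncart] = blk
            T[off[j]: off[j] + sb.ncart, off[i]: off[i] + sa.ncart] = blk.T
    return T


def point_charge_matrix(shells: list[Shell], positions: np.ndarray,
                        charges: np.ndarray) -> np.ndarray:
    """Interaction of the AO charge distribution with point charges.

    Returns V with V_{mu nu} = -sum_C q_C <mu| 1/|r-R_C| |nu>, i.e. the
    potential-energy matrix of electrons in the field of `charges` at
    `positions` (bohr).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    charges = np.atleast_1d(np.asarray(charges, dtype=float))
    n = nbf(shells)
    off = _offsets(shells)
    V = np.zeros((n, n))
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells):
            if j > i:
                continue
            sp = _shell_pair(sa, sb)
            L = sa.l + sb.l
            npp = len(sp.p)
            nc = len(charges)
            # batch over (primitive pair, charge center)
            pp = np.repeat(sp.p, nc)
            PC = (sp.P[:, None, :] - positions[None, :, :]).reshape(-1, 3)
            R = _hermite_R(L, pp, PC).reshape(npp, nc, L + 1, L + 1, L + 1)
            Rq = np.einsum("c,ncTUV->nTUV", charges, R)
            pref = 2.0 * np.pi / sp.p * sp.cc
            blk = -np.einsum("n,nabtuv,ntuv->ab", pref, sp.E3, Rq)
            V[off[i]: off[i] + sa.ncart, off[j]: off[j] + sb.ncart] = blk
            V[off[j]: off[j] + sb.ncart, off[i]: off[i] + sa.ncart] = blk.T
    return V


def nuclear_attraction_matrix(shells: list[Shell], coords: np.ndarray,
                              charges: np.ndarray) -> np.ndarray:
    """Alias of :func:`point_charge_matrix` for nuclear centers."""
    return point_charge_matrix(shells, coords, charges)


def electron_repulsion_tensor(shells: list[Shell],
                              screen: float = 1e-14) -> np.ndarray:
    """Full (mu nu | la si) chemists'-notation ERI tensor.

    Permutational symmetry is exploited over shell quartets; primitive and
    Hermite sums are vectorized per quartet.  Quartets whose bra or ket pair
    carries negligible Gaussian-product weight are screened out, which makes
    widely separated dimers essentially free.
    """
    n = nbf(shells)
    off = _offsets(shells)
    nsh = len(shells)
    pairs = [(i, j) for i in range(nsh) for j in range(i + 1)]
    spd = {}
    pair_w = {}
    for (i, j) in pairs:
        sp = _shell_pair(shells[i], shells[j])
        spd[i, j] = sp
        pair_w[i, j] = float(np.max(np.abs(sp.E3)) * np.max(np.abs(sp.cc)))
    eri = np.zeros((n, n, n, n))
    for pi, (i, j) in enumerate(pairs):
        sp1 = spd[i, j]
        if pair_w[i, j] < screen:
            continue
        L1 = sp1.la + sp1.lb
        for (k, l) in pairs[: pi + 1]:
            if pair_w[k, l] < screen or pair_w[i, j] * pair_w[k, l] < screen:
                continue
            sp2 = spd[k, l]
            L2 = sp2.la + sp2.lb
            L = L1 + L2
            n1, n2 = len(sp1.p), len(sp2.p)
            pq = sp1.p[:, None] * sp2.p[None, :]
            psum = sp1.p[:, None] + sp2.p[None, :]
            alpha = (pq / psum).reshape(-1)
            PQ = (sp1.P[:, None, :] - sp2.P[None, :, :]).reshape(-1, 3)
            R = _hermite_R(L, alpha, PQ).reshape(n1, n2, L + 1, L + 1, L + 1)
            # gather combined Hermite indices: R6[..., t,u,v,T,U,V] = R[..., t+T, u+U, v+V]
            t1 = np.arange(L1 + 1)
            t2 = np.arange(L2 + 1)
            tt, uu, vv, TT, UU, VV = np.ix_(t1, t1, t1, t2, t2, t2)
            R6 = R[:, :, tt + TT, uu + UU, vv + VV]
            # R6 shape: (n1, n2, L1+1, L1+1, L1+1, L2+1, L2+1, L2+1)
            sign = np.zeros((L2 + 1, L2 + 1, L2 + 1))
            for T in range(L2 + 1):
                for U in range(L2 + 1):
                    for Vv in range(L2 + 1):
                        sign[T, U, Vv] = (-1.0) ** (T + U + Vv)
            pref = (2.0 * np.pi ** 2.5
                    / (pq * np.sqrt(psum))).reshape(n1, n2) \
                * sp1.cc[:, None] * sp2.cc[None, :]
            E2s = sp2.E3 * sign[None, None, None, :, :, :]
            blk = np.einsum("natuv,mbTUV,nm,nmtuvTUV->ab",
                            sp1.E3.reshape(n1, -1, L1 + 1, L1 + 1, L1 + 1),
                            E2s.reshape(n2, -1, L2 + 1, L2 + 1, L2 + 1),
                            pref, R6, optimize=True)
            na, nb_ = shells[i].ncart, shells[j].ncart
            nc, nd = shells[k].ncart, shells[l].ncart
            blk = blk.reshape(na, nb_, nc, nd)
            si = slice(off[i], off[i] + na)
            sj = slice(off[j], off[j] + nb_)
            sk = slice(off[k], off[k] + nc)
            sl = slice(off[l], off[l] + nd)
            eri[si, sj, sk, sl] = blk
            eri[sj, si, sk, sl] = blk.transpose(1, 0, 2, 3)
            eri[si, sj, sl, sk] = blk.transpose(0, 1, 3, 2)
            eri[sj, si, sl, sk] = blk.transpose(1, 0, 3, 2)
            eri[sk, sl, si, sj] = blk.transpose(2, 3, 0, 1)
            eri[sl, sk, si, sj] = blk.transpose(3, 2, 0, 1)
            eri[sk, sl, sj, si] = blk.transpose(2, 3, 1, 0)
            eri[sl, sk, sj, si] = blk.transpose(3, 2, 1, 0)
    return eri
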