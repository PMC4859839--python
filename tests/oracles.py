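"""Independent oracles used by the test suite.

These deliberately take different routes from the package implementation:

* `nonorthogonal_determinant_energy` evaluates the energy of a single
  closed-shell Slater determinant of nonorthogonal spatial orbitals through
  the spin-orbital inverse-overlap (generalized Slater–Condon) formula,
  never touching the Löwdin-orthogonalization + Fock-build path.
* `grid_ee_coulomb` integrates the electron–electron Coulomb interaction of
  two densities on a real-space quadrature grid (s-function bases only),
  using point-charge potentials rather than the ERI tensor for one factor.
* `brute_force_select` enumerates every frame against the selection
  criteria with plain Python loops.
* `spearman_bruteforce` ranks by explicit sorting and applies the rank-
  difference formula directly.
"""

from __future__ import annotations

import numpy as np

from pocket_eda.qchem import integrals
from pocket_eda.qchem.scf import AOIntegrals


# ---------------------------------------------------------------------------
# nonorthogonal-determinant energy (spin-orbital cofactor route)
# ---------------------------------------------------------------------------

def nonorthogonal_determinant_energy(C_occ: np.ndarray,
                                     ints: AOIntegrals,
                                     h: np.ndarray) -> float:
    """Electronic energy of the closed-shell determinant built from the
    (possibly nonorthogonal) spatial orbitals in the columns of C_occ.

    Spin orbitals are formed explicitly (each spatial orbital doubly
    occupied); with M the spin-orbital overlap and W = M^{-1},

        E = sum_ij h_ij W_ji + 1/2 sum_ijkl (<ij|kl> - <ij|lk>) W_ki W_lj
    """
    S, eri = ints.S, ints.eri
    n = C_occ.shape[1]
    # spatial-orbital matrices
    M_sp = C_occ.T @ S @ C_occ
    W_sp = np.linalg.inv(M_sp)
    h_mo = C_occ.T @ h @ C_occ
    # (ij|kl) in MO basis, chemists' notation
    eri_mo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", eri,
                       C_occ, C_occ, C_occ, C_occ, optimize=True)
    nso = 2 * n

    def spat(p):           # spin orbital index -> (spatial, spin)
        return p % n, p // n

    W = np.zeros((nso, nso))
    hso = np.zeros((nso, nso))
    for p in range(nso):
        ip, sp_ = spat(p)
        for q in range(nso):
            iq, sq = spat(q)
            if sp_ == sq:
                W[p, q] = W_sp[ip, iq]
                hso[p, q] = h_mo[ip, iq]
    e1 = np.sum(hso * W.T)
    e2 = 0.0
    for i in range(nso):
        ii, si = spat(i)
        for j in range(nso):
            ij, sj = spat(j)
            for k in range(nso):
                ik, sk = spat(k)
                if si != sk:
                    coul = 0.0
                else:
                    coul = None
                for l in range(nso):
                    il, sl = spat(l)
                    # <ij|kl> = (ik|jl) spatial, requires spin(i)==spin(k),
                    # spin(j)==spin(l)
                    v1 = eri_mo[ii, ik, ij, il] if (si == sk and sj == sl) \
                        else 0.0
                    v2 = eri_mo[ii, il, ij, ik] if (si == sl and sj == sk) \
                        else 0.0
                    e2 += 0.5 * (v1 - v2) * W[k, i] * W[l, j]
    return float(e1 + e2)


# ---------------------------------------------------------------------------
# grid quadrature for the electron-electron Coulomb interaction (s bases)
# ---------------------------------------------------------------------------

def _s_shell_data(shells):
    """Flatten s-only shells to primitive lists (exp, coef, center)."""
    prims = []
    for ish, sh in enumerate(shells):
        if sh.l != 0:
            raise ValueError("grid oracle supports s functions only")
        prims.append((sh.exps, sh.coefs, sh.center))
    return prims


def grid_ee_coulomb(D_a: np.ndarray, D_b: np.ndarray, shells,
                    extent: float = 8.0, npts: int = 48) -> float:
    """∬ rho_A(r) rho_B(r') / |r-r'| via rho_A on a Gauss–Legendre grid and
    the analytic point-charge potential of rho_B at each grid point.

    `extent` (bohr) is the half-width of the cubic grid around the centroid
    of the A density's basis centers; adequate for compact s-only systems.
    """
    prims = _s_shell_data(shells)
    # grid
    x, wx = np.polynomial.legendre.leggauss(npts)
    centers = np.array([p[2] for p in prims])
    lo = centers.min(axis=0) - extent
    hi = centers.max(axis=0) + extent
    axes, wts = [], []
    for d in range(3):
        axes.append(0.5 * (hi[d] - lo[d]) * x + 0.5 * (hi[d] + lo[d]))
        wts.append(0.5 * (hi[d] - lo[d]) * wx)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    W = (wts[0][:, None, None] * wts[1][None, :, None]
         * wts[2][None, None, :])
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    w = W.reshape(-1)

    # AO values on grid (contracted s functions)
    nbf = len(prims)
    ao = np.empty((pts.shape[0], nbf))
    for k, (exps, coefs, cen) in enumerate(prims):
        r2 = np.sum((pts - cen) ** 2, axis=1)
        ao[:, k] = np.einsum("p,gp->g", coefs,
                             np.exp(-np.outer(r2, exps)))
    rho_a = np.einsum("gi,ij,gj->g", ao, D_a, ao, optimize=True)

    # potential of rho_B at each grid point: contract point-charge
    # integrals; for s-primitives V(r_g) = sum 2*pi/p * c_i c_j
    #   exp(-mu R_ij^2) F0(p |P - r_g|^2)
    from pocket_eda.qchem.integrals import boys
    pot = np.zeros(pts.shape[0])
    for i, (ei, ci, A) in enumerate(prims):
        for j, (ej, cj, B) in enumerate(prims):
            for a, ca in zip(ei, ci):
                for b, cb in zip(ej, cj):
                    p = a + b
                    mu = a * b / p
                    K = np.exp(-mu * np.sum((A - B) ** 2))
                    if K < 1e-16:
                        continue
                    P = (a * A + b * B) / p
                    r2 = np.sum((pts - P) ** 2, axis=1)
                    F0 = boys(0, p * r2)[0]
                    pot += (D_b[i, j] * ca * cb * 2.0 * np.pi / p) * K * F0
    return float(np.sum(w * rho_a * pot))


# ---------------------------------------------------------------------------
# brute-force representative-frame selection
# ---------------------------------------------------------------------------

def brute_force_select(hbond_series, ring_series, mode,
                       hb_bins=(1.5, 0.25, 8), ring_bins=(2.0, 0.25, 24)):
    """Enumerate all frames with plain loops; returns the chosen 0-based
    frame index or None if strict mode finds no qualifying frame."""

    def modal(vals, lo0, width, nbins):
        counts = [0] * nbins
        for v in vals:
            k = int(np.floor((v - lo0) / width))
            if 0 <= k < nbins:
                counts[k] += 1
        best, arg = -1, None
        for k, c in enumerate(counts):
            if c > best:
                best, arg = c, k
        if best <= 0:
            raise ValueError("all-zero histogram")
        return (lo0 + arg * width, lo0 + (arg + 1) * width)

    n_frames = len(hbond_series[0])
    hb_iv = [modal(s, *hb_bins) for s in hbond_series]
    rg_iv = [modal(s, *ring_bins) for s in ring_series]
    best = None
    for f in range(n_frames):
        count = 0
        total = 0.0
        for s, (lo, hi) in zip(hbond_series, hb_iv):
            total += s[f]
            if lo <= s[f] < hi:
                count += 1
        for s, (lo, hi) in zip(ring_series, rg_iv):
            if lo <= s[f] < hi:
                count += 1
        rec = (count, total, f)
        if best is None:
            best = rec
        else:
            bc, bt, bf = best
            if count > bc or (count == bc and total < bt):
                best = rec
    count, total, frame = best
    if mode == "strict" and count < len(hbond_series) + len(ring_series):
        return None
    if mode == "strict":
        # among fully-modal frames, minimal total, lowest index
        cand = None
        for f in range(n_frames):
            c = 0
            t = 0.0
            for s, (lo, hi) in zip(hbond_series, hb_iv):
                t += s[f]
                if lo <= s[f] < hi:
                    c += 1
            for s, (lo, hi) in zip(ring_series, rg_iv):
                if lo <= s[f] < hi:
                    c += 1
            if c == len(hbond_series) + len(ring_series):
                if cand is None or t < cand[0]:
                    cand = (t, f)
        return cand[1]
    return frame


def spearman_bruteforce(x, y):
    """Spearman rho with ranks assigned by explicit sorting (no ties)."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0] * len(v)
        for pos, i in enumerate(order, start=1):
            r[i] = pos
        return r
    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1 - 6 * d2 / (n * (n * n - 1))
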