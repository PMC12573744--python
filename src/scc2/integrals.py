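"""AO integrals over contracted Cartesian Gaussians (McMurchie-Davidson).

The one- and two-electron integrals are assembled from Hermite Gaussian
expansions; the Boys function is evaluated through the regularized lower
incomplete gamma function. Everything is exact (no screening), which is
appropriate at the minimal-basis desk scale this package targets.

`compute_ao_integrals` is the pluggable backend contract: alternative
backends (e.g. an external integrals program) can be registered under a
name and selected per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import gamma, gammainc

from .basis import Shell, cartesian_components, shells_for_molecule
from .geometry import Geometry


@dataclass(frozen=True)
class AOIntegralSet:
    """AO-basis operator matrices in Hartree atomic units.

    eri is the rank-4 electron-repulsion tensor in chemist's notation
    (pq|rs) with the full 8-fold permutational symmetry.
    """

    n_ao: int
    overlap: np.ndarray
    core_hamiltonian: np.ndarray
    eri: np.ndarray
    nuclear_repulsion: float

    def validate(self, tol: float = 1e-10) -> None:
        s = self.overlap
        if not np.allclose(s, s.T, atol=tol):
            raise ValueError("overlap not symmetric")
        if np.linalg.eigvalsh(s).min() <= 0:
            raise ValueError("overlap not positive definite")
        h = self.core_hamiltonian
        if not np.allclose(h, h.T, atol=tol):
            raise ValueError("core Hamiltonian not symmetric")
        g = self.eri
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            if not np.allclose(g, g.transpose(perm), atol=tol):
                raise ValueError(f"eri lacks permutational symmetry {perm}")


def boys(n_max: int, t: np.ndarray) -> np.ndarray:
    """Boys functions F_0..F_n_max for an array of arguments; shape (n+1, len(t))."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty((n_max + 1, t.size))
    small = t < 1e-12
    ts = np.where(small, 1.0, t)  # avoid 0^negative; small branch overwritten
    for n in range(n_max + 1):
        a = n + 0.5
        out[n] = 0.5 * gamma(a) * gammainc(a, ts) / ts**a
        if np.any(small):
            # Taylor at t -> 0: F_n = 1/(2n+1) - t/(2n+3) + t^2/(2(2n+5))
            tt = t[small]
            out[n, small] = (1.0 / (2 * n + 1) - tt / (2 * n + 3)
                             + tt**2 / (2 * (2 * n + 5)))
    return out


def _hermite_e(l1: int, l2: int, ab: float, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hermite expansion coefficients E_t^{ij} for one Cartesian direction.

    Returns array of shape (l1+1, l2+1, l1+l2+1, nprim_pairs); ab = A - B.
    """
    p = a + b
    mu = a * b / p
    e = np.zeros((l1 + 1, l2 + 1, l1 + l2 + 2, a.size))
    e[0, 0, 0] = np.exp(-mu * ab * ab)
    pa = -b * ab / p
    pb = a * ab / p
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                src, fac = e[i - 1, 0], pa
            else:
                src, fac = e[i, j - 1], pb
            for t in range(i + j + 1):
                val = fac * src[t] + (t + 1) * src[t + 1]
                if t >= 1:
                    val = val + src[t - 1] / (2 * p)
                e[i, j, t] = val
    return e[:, :, : l1 + l2 + 1]


def _hermite_coulomb(lmax: int, alpha: np.ndarray, pq: np.ndarray) -> dict:
    """Hermite Coulomb integrals R_{tuv} (auxiliary order 0), vectorized.

    alpha: effective exponents, shape (n,); pq: P-Q vectors, shape (n, 3).
    Returns dict (t,u,v) -> array (n,) for t+u+v <= lmax.
    """
    t_arg = alpha * np.einsum("ni,ni->n", pq, pq)
    f = boys(lmax, t_arg)
    base = {n: {(0, 0, 0): (-2.0 * alpha) ** n * f[n]} for n in range(lmax + 1)}
    for total in range(1, lmax + 1):
        for n in range(lmax - total + 1):
            for t in range(total + 1):
                for u in range(total - t + 1):
                    v = total - t - u
                    if t > 0:
                        val = pq[:, 0] * base[n + 1][(t - 1, u, v)]
                        if t > 1:
                            val = val + (t - 1) * base[n + 1][(t - 2, u, v)]
                    elif u > 0:
                        val = pq[:, 1] * base[n + 1][(t, u - 1, v)]
                        if u > 1:
                            val = val + (u - 1) * base[n + 1][(t, u - 2, v)]
                    else:
                        val = pq[:, 2] * base[n + 1][(t, u, v - 1)]
                        if v > 1:
                            val = val + (v - 1) * base[n + 1][(t, u, v - 2)]
                    base[n][(t, u, v)] = val
    return base[0]


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


class _BasisFunction:
    """One contracted Cartesian Gaussian with normalized primitives."""

    __slots__ = ("center", "powers", "exps", "coefs")

    def __init__(self, center, powers, exps, coefs):
        self.center = np.asarray(center, dtype=float)
        self.powers = powers
        self.exps = np.asarray(exps, dtype=float)
        lx, ly, lz = powers
        l = lx + ly + lz
        norms = ((2 * self.exps / np.pi) ** 0.75
                 * (4 * self.exps) ** (l / 2.0)
                 / np.sqrt(_double_factorial(2 * lx - 1)
                           * _double_factorial(2 * ly - 1)
                           * _double_factorial(2 * lz - 1)))
        self.coefs = np.asarray(coefs, dtype=float) * norms


class _Pair:
    """Precomputed primitive-pair data for a pair of basis functions."""

    __slots__ = ("p", "pxyz", "ex", "ey", "ez", "cc", "la", "lb")

    def __init__(self, f1: _BasisFunction, f2: _BasisFunction):
        a = np.repeat(f1.exps, f2.exps.size)
        b = np.tile(f2.exps, f1.exps.size)
        self.p = a + b
        self.pxyz = (a[:, None] * f1.center + b[:, None] * f2.center) / self.p[:, None]
        ab = f1.center - f2.center
        self.ex = _hermite_e(f1.powers[0], f2.powers[0], ab[0], a, b)
        self.ey = _hermite_e(f1.powers[1], f2.powers[1], ab[1], a, b)
        self.ez = _hermite_e(f1.powers[2], f2.powers[2], ab[2], a, b)
        self.cc = np.repeat(f1.coefs, f2.coefs.size) * np.tile(f2.coefs, f1.coefs.size)
        self.la = f1.powers
        self.lb = f2.powers

    def hermite_density(self) -> np.ndarray:
        """E^x_t E^y_u E^z_v c_a c_b, shape (tmax, umax, vmax, npp)."""
        i, k, m = self.la
        j, l, n = self.lb
        return np.einsum("t...,u...,v...,...->tuv...",
                         self.ex[i, j], self.ey[k, l], self.ez[m, n], self.cc)


def _expand_functions(shells: list[Shell]) -> list[_BasisFunction]:
    funcs = []
    for sh in shells:
        for powers in cartesian_components(sh.l):
            funcs.append(_BasisFunction(sh.center, powers, sh.exponents, sh.coefficients))
    return funcs


def _overlap_kinetic(funcs: list[_BasisFunction]) -> tuple[np.ndarray, np.ndarray]:
    n = len(funcs)
    s_mat = np.zeros((n, n))
    t_mat = np.zeros((n, n))

    def s1d(e, i, j, p):
        return e[i, j, 0] * np.sqrt(np.pi / p)

    for mu in range(n):
        for nu in range(mu + 1):
            f1, f2 = funcs[mu], funcs[nu]
            a = np.repeat(f1.exps, f2.exps.size)
            b = np.tile(f2.exps, f1.exps.size)
            p = a + b
            cc = np.repeat(f1.coefs, f2.coefs.size) * np.tile(f2.coefs, f1.coefs.size)
            ab = f1.center - f2.center
            dims = []
            for d in range(3):
                l1, l2 = f1.powers[d], f2.powers[d]
                e = _hermite_e(l1, l2 + 2, ab[d], a, b)
                sij = s1d(e, l1, l2, p)
                tij = (-2.0 * b**2 * s1d(e, l1, l2 + 2, p)
                       + b * (2 * l2 + 1) * sij)
                if l2 >= 2:
                    tij = tij - 0.5 * l2 * (l2 - 1) * s1d(e, l1, l2 - 2, p)
                dims.append((sij, tij))
            (sx, tx), (sy, ty), (sz, tz) = dims
            s_mat[mu, nu] = s_mat[nu, mu] = np.sum(cc * sx * sy * sz)
            t_mat[mu, nu] = t_mat[nu, mu] = np.sum(
                cc * (tx * sy * sz + sx * ty * sz + sx * sy * tz))
    return s_mat, t_mat


def _nuclear(funcs: list[_BasisFunction], charges, centers) -> np.ndarray:
    n = len(funcs)
    v_mat = np.zeros((n, n))
    for mu in range(n):
        for nu in range(mu + 1):
            pair = _Pair(funcs[mu], funcs[nu])
            dens = pair.hermite_density()
            lmax = sum(pair.la) + sum(pair.lb)
            val = 0.0
            for z, c in zip(charges, centers):
                pq = pair.pxyz - np.asarray(c)
                r = _hermite_coulomb(lmax, pair.p, pq)
                acc = np.zeros(pair.p.size)
                for t in range(dens.shape[0]):
                    for u in range(dens.shape[1]):
                        for v in range(dens.shape[2]):
                            acc += dens[t, u, v] * r[(t, u, v)]
                val -= z * np.sum(2.0 * np.pi / pair.p * acc)
            v_mat[mu, nu] = v_mat[nu, mu] = val
    return v_mat


def _eri(funcs: list[_BasisFunction]) -> np.ndarray:
    n = len(funcs)
    pairs = {}
    for mu in range(n):
        for nu in range(mu + 1):
            pairs[(mu, nu)] = _Pair(funcs[mu], funcs[nu])
    dens = {k: p.hermite_density() for k, p in pairs.items()}

    g = np.zeros((n, n, n, n))
    pair_list = sorted(pairs)
    for ij_idx, (i, j) in enumerate(pair_list):
        p1 = pairs[(i, j)]
        d1 = dens[(i, j)]
        l1 = sum(p1.la) + sum(p1.lb)
        n1 = p1.p.size
        for (k, l) in pair_list[: ij_idx + 1]:
            p2 = pairs[(k, l)]
            d2 = dens[(k, l)]
            l2 = sum(p2.la) + sum(p2.lb)
            n2 = p2.p.size
            pp = np.repeat(p1.p, n2)
            qq = np.tile(p2.p, n1)
            alpha = pp * qq / (pp + qq)
            pq = np.repeat(p1.pxyz, n2, axis=0) - np.tile(p2.pxyz, (n1, 1))
            r = _hermite_coulomb(l1 + l2, alpha, pq)
            pref = 2.0 * np.pi**2.5 / (pp * qq * np.sqrt(pp + qq))
            acc = np.zeros(n1 * n2)
            for t1 in range(d1.shape[0]):
                for u1 in range(d1.shape[1]):
                    for v1 in range(d1.shape[2]):
                        d1v = d1[t1, u1, v1]
                        if not np.any(d1v):
                            continue
                        d1r = np.repeat(d1v, n2)
                        for t2 in range(d2.shape[0]):
                            for u2 in range(d2.shape[1]):
                                for v2 in range(d2.shape[2]):
                                    sign = (-1.0) ** (t2 + u2 + v2)
                                    d2t = np.tile(d2[t2, u2, v2], n1)
                                    acc += (sign * d1r * d2t
                                            * r[(t1 + t2, u1 + u2, v1 + v2)])
            val = np.sum(pref * acc)
            for a, b in ((i, j), (j, i)):
                for c, d in ((k, l), (l, k)):
                    g[a, b, c, d] = g[c, d, a, b] = val
    return g


_BACKENDS: dict[str, Callable[[Geometry, str], AOIntegralSet]] = {}


def register_backend(name: str, fn: Callable[[Geometry, str], AOIntegralSet]) -> None:
    _BACKENDS[name] = fn


def bundled_backend(geometry: Geometry, basis_name: str) -> AOIntegralSet:
    shells = shells_for_molecule(geometry.elements, geometry.coordinates_bohr(),
                                 basis_name)
    funcs = _expand_functions(shells)
    s, t = _overlap_kinetic(funcs)
    # normalize contracted functions
    scale = 1.0 / np.sqrt(np.diag(s))
    for f, c in zip(funcs, scale):
        f.coefs = f.coefs * c
    s = s * np.outer(scale, scale)
    t = t * np.outer(scale, scale)
    v = _nuclear(funcs, geometry.atomic_numbers, geometry.coordinates_bohr())
    g = _eri(funcs)
    return AOIntegralSet(
        n_ao=len(funcs),
        overlap=s,
        core_hamiltonian=t + v,
        eri=g,
        nuclear_repulsion=geometry.nuclear_repulsion(),
    )


register_backend("bundled", bundled_backend)


def compute_ao_integrals(geometry: Geometry, basis_name: str = "sto-3g",
                         backend: str = "bundled") -> AOIntegralSet:
    """AO integral acquisition through the backend registry."""
    if backend not in _BACKENDS:
        raise KeyError(f"unknown integral backend {backend!r}; registered: {sorted(_BACKENDS)}")
    return _BACKENDS[backend](geometry, basis_name)
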