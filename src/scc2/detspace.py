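"""Brute-force determinant-space algebra: the independent oracle.

Everything the working equations compute in factorized form is recomputed
here as explicit matrices over a full configuration basis at fixed Sz:
the Hamiltonian by Slater-Condon rules, cluster operators as nilpotent
matrices, similarity transforms as terminating exponential series, and
Jacobians by explicit commutators. Dense storage only; feasible for a few
hundred determinants, which covers H2, H4 and minimal-basis H2O.

The truncated-model projections (CC2 doubles with the dressed-Fock
commutator, the block-wise CC2 Jacobian) replicate the production
truncations symbolically, so the oracle validates the implemented
equations rather than full coupled cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .labels import LabelSpace
from .moints import SpinMOIntegrals

_MAX_DETS = 20_000


class BasisSizeError(ValueError):
    pass


@dataclass(frozen=True)
class DeterminantBasis:
    """Full CI determinant basis at fixed Sz over interleaved spin orbitals."""

    n_so: int
    n_alpha: int
    n_beta: int
    dets: tuple[int, ...]  # occupation bitmasks, reference first
    index: dict  # bitmask -> position

    @property
    def n_det(self) -> int:
        return len(self.dets)

    @property
    def reference(self) -> int:
        return self.dets[0]

    @property
    def n_occ(self) -> int:
        return self.n_alpha + self.n_beta


def enumerate_basis(n_spatial: int, n_alpha: int, n_beta: int) -> DeterminantBasis:
    """All determinants with the given spin occupations, ordered by
    excitation level relative to the aufbau reference, then lexicographically."""
    n_so = 2 * n_spatial
    alpha_orbs = list(range(0, n_so, 2))
    beta_orbs = list(range(1, n_so, 2))
    if n_alpha > len(alpha_orbs) or n_beta > len(beta_orbs):
        raise ValueError("electron count exceeds orbital count")
    ref = 0
    for p in alpha_orbs[:n_alpha] + beta_orbs[:n_beta]:
        ref |= 1 << p
    dets = []
    for occ_a in combinations(alpha_orbs, n_alpha):
        for occ_b in combinations(beta_orbs, n_beta):
            d = 0
            for p in occ_a + occ_b:
                d |= 1 << p
            dets.append(d)
    if len(dets) > _MAX_DETS:
        raise BasisSizeError(f"{len(dets)} determinants exceeds the cap {_MAX_DETS}")
    dets.sort(key=lambda d: (bin(d & ~ref).count("1"), d))
    assert dets[0] == ref
    return DeterminantBasis(n_so=n_so, n_alpha=n_alpha, n_beta=n_beta,
                            dets=tuple(dets), index={d: k for k, d in enumerate(dets)})


# --- elementary fermion algebra on bitmasks ---------------------------

def _phase_below(det: int, p: int) -> int:
    return -1 if bin(det & ((1 << p) - 1)).count("1") % 2 else 1


def annihilate(det: int, p: int):
    if not det & (1 << p):
        return None
    return det ^ (1 << p), _phase_below(det, p)


def create(det: int, p: int):
    if det & (1 << p):
        return None
    return det | (1 << p), _phase_below(det, p)


def apply_excitation(det: int, i: int, a: int):
    """tau_{ai} = a^+_a a_i applied to a determinant; returns (det', phase) or None."""
    res = annihilate(det, i)
    if res is None:
        return None
    d1, s1 = res
    res = create(d1, a)
    if res is None:
        return None
    d2, s2 = res
    return d2, s1 * s2


def excitation_matrix(basis: DeterminantBasis, i: int, a: int) -> np.ndarray:
    """Matrix of tau_{ai} (spin-orbital indices, a absolute) over the basis."""
    m = np.zeros((basis.n_det, basis.n_det))
    for col, det in enumerate(basis.dets):
        res = apply_excitation(det, i, a)
        if res is None:
            continue
        d2, ph = res
        row = basis.index.get(d2)
        if row is not None:
            m[row, col] = ph
    return m


def pair_excitation_matrix(basis: DeterminantBasis, i: int, a: int,
                           j: int, b: int) -> np.ndarray:
    """Matrix of tau_{ai} tau_{bj} applied on raw bitmasks.

    The operator product must be evaluated per determinant: for cross-spin
    pairings the intermediate determinant falls outside the fixed-Sz basis
    even though the product conserves Sz.
    """
    m = np.zeros((basis.n_det, basis.n_det))
    for col, det in enumerate(basis.dets):
        res = apply_excitation(det, j, b)
        if res is None:
            continue
        d1, p1 = res
        res = apply_excitation(d1, i, a)
        if res is None:
            continue
        d2, p2 = res
        row = basis.index.get(d2)
        if row is not None:
            m[row, col] = p1 * p2
    return m


# --- Slater-Condon Hamiltonian ----------------------------------------

def _occ_list(det: int, n_so: int) -> list[int]:
    return [p for p in range(n_so) if det & (1 << p)]


def _excitation_connection(d1: int, d2: int):
    """(holes, particles, phase) taking d1 -> d2, or None beyond doubles."""
    diff = d1 ^ d2
    holes = [p for p in range(diff.bit_length()) if (diff >> p) & 1 and (d1 >> p) & 1]
    parts = [p for p in range(diff.bit_length()) if (diff >> p) & 1 and (d2 >> p) & 1]
    if len(holes) > 2:
        return None
    # phase: annihilate holes (ascending), create particles (ascending)
    ph = 1
    d = d1
    for p in holes:
        d, s = annihilate(d, p)
        ph *= s
    for p in parts:
        d, s = create(d, p)
        ph *= s
    assert d == d2
    return holes, parts, ph


def hamiltonian_matrix(ints: SpinMOIntegrals, basis: DeterminantBasis) -> np.ndarray:
    """Dense Hamiltonian (Hermitian) including the scalar shift."""
    h = ints.h
    w = ints.antisymmetrized()
    n = basis.n_det
    mat = np.zeros((n, n))
    occs = [_occ_list(d, basis.n_so) for d in basis.dets]
    for col in range(n):
        dc = basis.dets[col]
        oc = occs[col]
        e = sum(h[p, p] for p in oc) + 0.5 * sum(w[p, q, p, q] for p in oc for q in oc)
        mat[col, col] = e + ints.scalar_shift
        for row in range(col + 1, n):
            dr = basis.dets[row]
            conn = _excitation_connection(dc, dr)
            if conn is None:
                continue
            holes, parts, ph = conn
            if len(holes) == 1:
                i, a = holes[0], parts[0]
                common = [p for p in oc if p != i]
                val = ph * (h[a, i] + sum(w[a, p, i, p] for p in common))
            else:
                # ph corresponds to the sequence (ann i, ann j, cre a, cre b),
                # i.e. the operator a^+_b a^+_a a_j a_i = -a^+_a a^+_b a_j a_i
                (i, j), (a, b) = holes, parts
                val = -ph * w[a, b, i, j]
            mat[row, col] = val
            mat[col, row] = val  # real symmetric
    return mat


def cluster_matrix(basis: DeterminantBasis, space: LabelSpace,
                   t1: np.ndarray | None = None, t2: np.ndarray | None = None,
                   zeta: float = 0.0, x3=None) -> np.ndarray:
    """Matrix of S = T1 + T2 + zeta*X3 over the determinant basis.

    x3, if given, is a pair of right-state tuples ((r1A, r2A), (r1B, r2B));
    its matrix is built from the bilinear products of state matrices.
    """
    no = space.no
    n = basis.n_det
    mat = np.zeros((n, n))
    if t1 is not None:
        for (i, a) in space.singles:
            if t1[i, a] != 0.0:
                mat += t1[i, a] * excitation_matrix(basis, i, no + a)
    if t2 is not None:
        for (i, j, a, b) in space.doubles:
            if t2[i, j, a, b] != 0.0:
                mat += t2[i, j, a, b] * pair_excitation_matrix(
                    basis, i, no + a, j, no + b)
    if x3 is not None and zeta != 0.0:
        (r1a, r2a), (r1b, r2b) = x3
        ma1 = cluster_matrix(basis, space, t1=r1a)
        ma2 = cluster_matrix(basis, space, t2=r2a)
        mb1 = cluster_matrix(basis, space, t1=r1b)
        mb2 = cluster_matrix(basis, space, t2=r2b)
        mat += zeta * (ma1 @ mb2 - mb1 @ ma2)
    return mat


def expm_nilpotent(m: np.ndarray) -> np.ndarray:
    """exp of a strictly excitation-raising (nilpotent) matrix, exact."""
    out = np.eye(m.shape[0])
    term = np.eye(m.shape[0])
    k = 1
    while True:
        term = term @ m / k
        if not np.any(term):
            break
        out += term
        k += 1
        if k > m.shape[0]:
            raise RuntimeError("matrix is not nilpotent")
    return out


def similarity_transform(h: np.ndarray, s: np.ndarray) -> np.ndarray:
    """exp(-S) H exp(S), exact for nilpotent S."""
    return expm_nilpotent(-s) @ h @ expm_nilpotent(s)


# --- label <-> determinant correspondence ------------------------------

def label_projections(basis: DeterminantBasis, space: LabelSpace):
    """(det index, phase) for each singles and doubles label.

    tau_mu |HF> = phase * |det>; projections <mu| pick the same phase.
    """
    no = space.no
    ref = basis.reference
    singles = []
    for (i, a) in space.singles:
        d, ph = apply_excitation(ref, i, no + a)
        singles.append((basis.index[d], ph))
    doubles = []
    for (i, j, a, b) in space.doubles:
        d1, p1 = apply_excitation(ref, j, no + b)
        d2, p2 = apply_excitation(d1, i, no + a)
        doubles.append((basis.index[d2], p1 * p2))
    return singles, doubles


def project_on_labels(column: np.ndarray, basis: DeterminantBasis,
                      space: LabelSpace) -> np.ndarray:
    """Project a determinant-space column onto the singles+doubles labels."""
    s_proj, d_proj = label_projections(basis, space)
    return np.array([ph * column[k] for (k, ph) in s_proj]
                    + [ph * column[k] for (k, ph) in d_proj])


def level_mask(basis: DeterminantBasis, max_level: int) -> np.ndarray:
    ref = basis.reference
    return np.array([bin(d & ~ref).count("1") <= max_level for d in basis.dets])


class DetSpaceOracle:
    """Convenience wrapper bundling the integrals, basis and label space."""

    def __init__(self, ints: SpinMOIntegrals, n_alpha: int | None = None,
                 n_beta: int | None = None):
        self.ints = ints
        n_spatial = ints.n_so // 2
        na = ints.n_occ // 2 if n_alpha is None else n_alpha
        nb = ints.n_occ // 2 if n_beta is None else n_beta
        self.basis = enumerate_basis(n_spatial, na, nb)
        self.space = LabelSpace(no=ints.n_occ, nv=ints.n_virt)
        self.h = hamiltonian_matrix(ints, self.basis)

    # -- similarity transforms ------------------------------------
    def hbar(self, t1=None, t2=None, zeta: float = 0.0, x3=None) -> np.ndarray:
        s = cluster_matrix(self.basis, self.space, t1=t1, t2=t2, zeta=zeta, x3=x3)
        return similarity_transform(self.h, s)

    def fock_matrix_detspace(self) -> np.ndarray:
        """Determinant-space matrix of the bare Fock operator."""
        eps = self.ints.eps
        n = self.basis.n_det
        f = np.zeros((n, n))
        for col, det in enumerate(self.basis.dets):
            f[col, col] = sum(eps[p] for p in _occ_list(det, self.basis.n_so))
        return f

    # -- projections ------------------------------------------------
    def residual(self, hbar: np.ndarray) -> np.ndarray:
        """Omega_mu = <mu|M|HF> for all singles+doubles labels."""
        return project_on_labels(hbar[:, 0], self.basis, self.space)

    def energy(self, hbar: np.ndarray) -> float:
        return float(hbar[0, 0])

    def eta(self, hbar: np.ndarray) -> np.ndarray:
        """eta_nu = <HF|[M, tau_nu]|HF> over all labels."""
        no = self.space.no
        vals = []
        for (i, a) in self.space.singles:
            tau = excitation_matrix(self.basis, i, no + a)
            vals.append((hbar @ tau)[0, 0] - (tau @ hbar)[0, 0])
        for (i, j, a, b) in self.space.doubles:
            tau = pair_excitation_matrix(self.basis, i, no + a, j, no + b)
            vals.append((hbar @ tau)[0, 0] - (tau @ hbar)[0, 0])
        return np.array(vals)

    def jacobian_column(self, m: np.ndarray, label, is_double: bool) -> np.ndarray:
        no = self.space.no
        if is_double:
            i, j, a, b = label
            tau = pair_excitation_matrix(self.basis, i, no + a, j, no + b)
        else:
            i, a = label
            tau = excitation_matrix(self.basis, i, no + a)
        comm = m @ tau - tau @ m
        return project_on_labels(comm[:, 0], self.basis, self.space)

    def cc2_jacobian(self, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
        """Block-truncated CC2 Jacobian: singles rows from the full
        T1+T2 transform, doubles rows from the T1-only transform (two-electron
        part) plus the diagonal orbital-energy differences."""
        hbar_full = self.hbar(t1=t1, t2=t2)
        hbar_t1 = self.hbar(t1=t1)
        ns = self.space.n_singles
        dim = self.space.dim
        a = np.zeros((dim, dim))
        for col, lab in enumerate(self.space.singles):
            full_col = self.jacobian_column(hbar_full, lab, is_double=False)
            t1_col = self.jacobian_column(hbar_t1, lab, is_double=False)
            a[:ns, col] = full_col[:ns]
            a[ns:, col] = t1_col[ns:]
        eps = self.ints.eps
        no = self.space.no
        for col, lab in enumerate(self.space.doubles):
            full_col = self.jacobian_column(hbar_full, lab, is_double=True)
            a[:ns, ns + col] = full_col[:ns]
            i, j, ai, bi = lab
            a[ns + col, ns + col] = (eps[no + ai] + eps[no + bi] - eps[i] - eps[j])
        return a

    def cc2_doubles_residual(self, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
        """<mu2|Htilde|HF> + eps_mu2 * t_mu2 (the truncated doubles equations)."""
        hbar_t1 = self.hbar(t1=t1)
        ns = self.space.n_singles
        om = self.residual(hbar_t1)[ns:]
        eps = self.ints.eps
        no = self.space.no
        for k, (i, j, a, b) in enumerate(self.space.doubles):
            om[k] += (eps[no + a] + eps[no + b] - eps[i] - eps[j]) * t2[i, j, a, b]
        return om

    # -- overlap machinery -----------------------------------------
    def exp_s_matrix(self, t1=None, t2=None, zeta: float = 0.0, x3=None) -> np.ndarray:
        s = cluster_matrix(self.basis, self.space, t1=t1, t2=t2, zeta=zeta, x3=x3)
        return expm_nilpotent(s)

    def full_state(self, exp_s: np.ndarray, r0: float, r1: np.ndarray,
                   r2: np.ndarray) -> np.ndarray:
        """|R> = sum_{mu>=0} exp(S)|mu> r_mu as a determinant-space vector."""
        vec = np.zeros(self.basis.n_det)
        vec[0] = r0
        s_proj, d_proj = label_projections(self.basis, self.space)
        for (k, ph), (i, a) in zip(s_proj, self.space.singles):
            vec[k] += ph * r1[i, a]
        for (k, ph), (i, j, a, b) in zip(d_proj, self.space.doubles):
            vec[k] += ph * r2[i, j, a, b]
        return exp_s @ vec

    def natural_projection_overlap(self, exp_s: np.ndarray,
                                   state_a: tuple, state_b: tuple) -> float:
        """<R^A| P |R^B> with P the projector onto levels <= 2."""
        va = self.full_state(exp_s, *state_a)
        vb = self.full_state(exp_s, *state_b)
        mask = level_mask(self.basis, 2)
        return float(np.sum(va[mask] * vb[mask]))
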