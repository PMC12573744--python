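"""Similarity-constrained CC2.

Standard CC2 has a non-Hermitian Jacobian whose defects at same-symmetry
excited-state crossings produce complex eigenvalue pairs and an unphysical
intersection tube. The similarity-constrained model augments the cluster
operator,

    S = T1 + T2 + zeta * X3,
    X3 = sum_{mu1 mu2} (r^A_mu1 r^B_mu2 - r^B_mu1 r^A_mu2) tau_mu1 tau_mu2,

and determines the extra parameter zeta from the orthogonality condition
O(A,B) = <R^A|P|R^B> = 0 with P the natural projection onto the
reference+singles+doubles space. The only change to the CC2 equations is
the term zeta * <mu1|[Htilde, X3]|HF> in the singles residual; the doubles
equations and the Jacobian used for the excited states keep their CC2 form,
evaluated at the SCC2 ground-state amplitudes.

X3 is never materialized as a triples tensor: the singles correction and
all overlap quantities are evaluated through factorized contractions of the
two constrained states' (r1, r2) amplitudes at O(N^5) cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cc2 import (CC2GroundState, DIIS, DressedIntegrals, compute_t2,
                  dress_integrals, eta_vector, ground_energy, singles_residual,
                  solve_cc2_ground)
from .eom import (ExcitedStateVector, JacobianModel, ground_contribution,
                  spin_signature)
from .labels import LabelSpace, dot_full
from .moints import SpinMOIntegrals


class SCC2ConvergenceError(RuntimeError):
    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


class StateTrackingError(RuntimeError):
    pass


@dataclass(frozen=True)
class X3Operator:
    """The antisymmetrized bilinear triples constraint operator, factorized.

    Implicit amplitudes x_{mu1 mu2} = r^A_mu1 r^B_mu2 - r^B_mu1 r^A_mu2;
    storage is only the four state tensors. Antisymmetric under A <-> B and
    zero whenever the two states are proportional.
    """

    r1a: np.ndarray
    r2a: np.ndarray
    r1b: np.ndarray
    r2b: np.ndarray

    def explicit_amplitudes(self, space: LabelSpace) -> np.ndarray:
        """x_{mu1 mu2} as a dense (n_singles, n_doubles) matrix (tests only)."""
        va, wa = space.t1_to_vec(self.r1a), space.t2_to_vec(self.r2a)
        vb, wb = space.t1_to_vec(self.r1b), space.t2_to_vec(self.r2b)
        return np.outer(va, wb) - np.outer(vb, wa)

    def swapped(self) -> "X3Operator":
        return X3Operator(self.r1b, self.r2b, self.r1a, self.r2a)


def build_x3(state_a: ExcitedStateVector, state_b: ExcitedStateVector) -> X3Operator:
    if state_a.r1.shape != state_b.r1.shape:
        raise ValueError("constrained states have mismatching dimensions")
    return X3Operator(np.real(state_a.r1), np.real(state_a.r2),
                      np.real(state_b.r1), np.real(state_b.r2))


def _x3_half_contraction(w_oovv: np.ndarray, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """<mu1| U~ tau_mu1' tau_mu2' |HF> contracted with r1 (singles factor)
    and r2 (doubles factor); the four Wick topologies of the double
    de-excitation block against the three particle-hole pairs of X3."""
    out = 0.25 * r1 * np.einsum("klcd,klcd->", w_oovv, r2, optimize=True)
    out += np.einsum("klcd,kc,lida->ia", w_oovv, r1, r2, optimize=True)
    out += 0.5 * np.einsum("klcd,ka,licd->ia", w_oovv, r1, r2, optimize=True)
    out += 0.5 * np.einsum("klcd,ic,klda->ia", w_oovv, r1, r2, optimize=True)
    return out


def scc_singles_correction(dressed: DressedIntegrals, x3: X3Operator,
                           zeta: float) -> np.ndarray:
    """Delta Omega_mu1 = zeta * <mu1|[Htilde, X3]|HF> as an (o,v) tensor."""
    if zeta == 0.0:
        return np.zeros((dressed.n_occ, dressed.n_virt))
    o, v = dressed.o, dressed.v
    w = dressed.w_tilde[o, o, v, v]
    g = _x3_half_contraction(w, x3.r1a, x3.r2b)
    g -= _x3_half_contraction(w, x3.r1b, x3.r2a)
    return zeta * g


# ----------------------------------------------------------------------
# natural-projection overlap machinery
# ----------------------------------------------------------------------

def _wedge(t1: np.ndarray, v1: np.ndarray) -> np.ndarray:
    """Bilinear antisymmetrized product: doubles-space coefficients of the
    operator product T1' V1' (both orders of the label sum included)."""
    b = np.einsum("ia,jb->ijab", t1, v1) + np.einsum("ia,jb->ijab", v1, t1)
    b = b - b.transpose(1, 0, 2, 3)
    return b


def overlap_q(t1: np.ndarray, t2: np.ndarray, zeta: float = 0.0,
              x3: X3Operator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """q_mu = <mu|exp(S)|HF> over singles and doubles labels.

    exp(S) terminates in the projection space: singles get t1, doubles get
    t2 plus the T1^2/2 disconnected product; the triples-rank zeta*X3 cannot
    reach the doubles space.
    """
    return t1.copy(), t2 + 0.5 * _wedge(t1, t1)


def overlap_q_apply(t1: np.ndarray, t2: np.ndarray, zeta: float,
                    x3: X3Operator | None, v1: np.ndarray, v2: np.ndarray):
    """(Q v)_mu = sum_nu <mu|exp(S)|nu> v_nu without materializing Q.

    Q is unit lower-triangular in excitation level: singles rows are the
    identity; doubles rows add the T1 (x) v1 product. zeta*X3 raises by
    three levels and therefore never lands back in the projection space.
    """
    return v1.copy(), v2 + _wedge(t1, v1)


def configuration_overlap_matrix(space: LabelSpace) -> np.ndarray:
    """Gram matrix <mu|nu> of the projection-space configurations.

    In the spin-orbital determinant basis used throughout this package the
    configurations are orthonormal and S is the identity; see
    `spin_adapted_doubles_gram` for the nontrivial spin-adapted case.
    """
    return np.eye(space.dim)


def spin_adapted_doubles_gram(n_spatial_occ: int, n_spatial_virt: int,
                              pairs: list[tuple[int, int, int, int]]) -> np.ndarray:
    """Gram matrix of spin-summed doubles configurations E_AI E_BJ |HF>.

    ``pairs`` lists spatial labels (I, J, A, B); the configurations are
    expanded into determinants (interleaved spin convention) and the exact
    inner products returned. Demonstrates the overlap matrix S of the
    natural-projection formula in a non-orthonormal excitation basis.
    """
    from .detspace import enumerate_basis, pair_excitation_matrix

    basis = enumerate_basis(n_spatial_occ + n_spatial_virt,
                            n_spatial_occ, n_spatial_occ)
    no = 2 * n_spatial_occ
    vecs = []
    for (i_s, j_s, a_s, b_s) in pairs:
        vec = np.zeros(basis.n_det)
        for si in (0, 1):
            for sj in (0, 1):
                i, j = 2 * i_s + si, 2 * j_s + sj
                a, b = no + 2 * a_s + si, no + 2 * b_s + sj
                m = pair_excitation_matrix(basis, i, a, j, b)
                vec += m[:, 0]
        vecs.append(vec)
    v = np.stack(vecs, axis=1)
    return v.T @ v


def orthogonality_value(t1: np.ndarray, t2: np.ndarray, zeta: float,
                        x3: X3Operator | None,
                        state_a: ExcitedStateVector,
                        state_b: ExcitedStateVector) -> float:
    """O(A,B) = <R^A|P|R^B> via the q/Q factorization.

    With the orthonormal determinant basis the configuration overlap S is
    the identity and the general four-term expression collapses to ordinary
    label-space dot products of q and the Q-transformed state vectors.
    """
    q1, q2 = overlap_q(t1, t2, zeta, x3)
    qa1, qa2 = overlap_q_apply(t1, t2, zeta, x3, np.real(state_a.r1), np.real(state_a.r2))
    qb1, qb2 = overlap_q_apply(t1, t2, zeta, x3, np.real(state_b.r1), np.real(state_b.r2))
    r0a, r0b = np.real(state_a.r0), np.real(state_b.r0)
    qq = dot_full((q1, q2), (q1, q2))
    val = r0a * r0b * (1.0 + qq)
    val += r0a * dot_full((q1, q2), (qb1, qb2))
    val += r0b * dot_full((qa1, qa2), (q1, q2))
    val += dot_full((qa1, qa2), (qb1, qb2))
    return float(val)


# ----------------------------------------------------------------------
# the coupled solver
# ----------------------------------------------------------------------

@dataclass
class SCC2Solution:
    """Converged simultaneous solution of the SCC2 equations."""

    t1: np.ndarray
    t2: np.ndarray
    zeta: float
    state_a: ExcitedStateVector
    state_b: ExcitedStateVector
    energy: float
    orthogonality_residual: float
    singles_residual_norm: float
    iterations: int
    converged: bool
    eta: tuple[np.ndarray, np.ndarray]
    history: list = field(default_factory=list)

    @property
    def omega_a(self) -> complex:
        return self.state_a.omega

    @property
    def omega_b(self) -> complex:
        return self.state_b.omega


def _real_pair_from_roots(vals, vecs, idx_a, idx_b, space: LabelSpace):
    """Two real representative vectors for the tracked pair of roots.

    For a complex-conjugate pair the orthonormalized real and imaginary
    parts span the real invariant subspace; for real roots the eigenvectors
    themselves are used.
    """
    wa, wb = vals[idx_a], vals[idx_b]
    if abs(wa.imag) > 1e-10 and abs(wa - np.conj(wb)) < 1e-8:
        x, y = vecs[:, idx_a].real, vecs[:, idx_a].imag
        qmat, _ = np.linalg.qr(np.stack([x, y], axis=1))
        va, vb = qmat[:, 0], qmat[:, 1]
        return va, vb, wa, wb, True
    va = vecs[:, idx_a]
    vb = vecs[:, idx_b]
    va = va.real if abs(wa.imag) < 1e-10 else va.real
    vb = vb.real if abs(wb.imag) < 1e-10 else vb.real
    return (va / np.linalg.norm(va), vb / np.linalg.norm(vb),
            wa.real, wb.real, False)


def _track_pair(vals, vecs, ref_a, ref_b):
    """Indices of the two roots with maximal overlap against references."""
    n = vals.size
    ovl_a = np.abs(ref_a @ vecs.real) + np.abs(ref_a @ vecs.imag)
    ovl_b = np.abs(ref_b @ vecs.real) + np.abs(ref_b @ vecs.imag)
    idx_a = int(np.argmax(ovl_a))
    ovl_b2 = ovl_b.copy()
    ovl_b2[idx_a] = -np.inf
    idx_b = int(np.argmax(ovl_b2))
    if ovl_a[idx_a] < 0.25 or ovl_b2[idx_b] < 0.25:
        raise StateTrackingError(
            "lost track of the constrained states (max overlaps "
            f"{ovl_a[idx_a]:.2f}, {ovl_b2[idx_b]:.2f})")
    return idx_a, idx_b


def _select_initial(model: JacobianModel, select: tuple[int, int],
                    singlet_only: bool = True):
    """Dense-solve at the initial point and pick two roots by index among
    the (optionally singlet-filtered) roots ordered by real part."""
    import scipy.linalg as sla

    a = model.dense()
    vals, vecs = sla.eig(a)
    order = np.argsort(vals.real)
    sp = model.space
    chosen = []
    seen_conj = set()
    for k in order:
        if k in seen_conj:
            continue
        v = vecs[:, k]
        r1, r2 = sp.unpack(v.real if abs(vals[k].imag) < 1e-10 else v.real)
        if singlet_only and spin_signature(r1, r2) < 0.0:
            continue
        chosen.append(k)
        if abs(vals[k].imag) > 1e-10:
            # mark the conjugate partner as used
            for k2 in order:
                if k2 != k and abs(vals[k2] - np.conj(vals[k])) < 1e-10:
                    seen_conj.add(k2)
                    chosen.append(k2)
                    break
    idx = [chosen[select[0]], chosen[select[1]]]
    return a, vals, vecs, idx




class _PairState:
    """Internal iterate: amplitudes, tracked pair, derived quantities."""

    __slots__ = ("t1", "t2", "dressed", "model", "va", "vb", "omega_a",
                 "omega_b", "is_complex", "near_parallel", "parallelism",
                 "st_a", "st_b", "x3", "om1", "o_val", "eta")


def _refine_pair(amat: np.ndarray, va: np.ndarray, vb: np.ndarray,
                 sigma: float, sweeps: int = 2):
    """Shift-invert subspace refinement of a two-root invariant subspace.

    Individual eigenvectors of a nearly defective non-symmetric matrix are
    ill-conditioned, but the two-dimensional invariant subspace of a pair
    well separated from the rest of the spectrum is not. Two inverse
    iterations on the orthonormalized pair give the subspace to near
    machine precision; the 2x2 projected problem then yields accurate
    eigenvalues and in-subspace eigenvectors.
    """
    import scipy.linalg as sla

    q, _ = np.linalg.qr(np.stack([va, vb], axis=1))
    shifted = amat - sigma * np.eye(amat.shape[0])
    try:
        lu = sla.lu_factor(shifted)
        for _ in range(sweeps):
            y = sla.lu_solve(lu, q)
            q, _ = np.linalg.qr(y)
    except (sla.LinAlgError, ValueError):
        pass  # keep the unrefined subspace
    b = q.T @ amat @ q
    mu, s = np.linalg.eig(b)
    if abs(mu[0].imag) > 1e-12:
        # complex pair: return the real subspace basis and complex values
        return q[:, 0], q[:, 1], mu[0], np.conj(mu[0]), True
    order = np.argsort(mu.real)
    v1 = q @ s[:, order[0]].real
    v2 = q @ s[:, order[1]].real
    return (v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2),
            float(mu[order[0]].real), float(mu[order[1]].real), False)


def _diagonalize_and_track(ints, t1, zeta, anchor_a, anchor_b, orient_a,
                           orient_b, space, defect_mode=False):
    """Dress, fold, diagonalize the CC2-form Jacobian, track the pair."""
    import scipy.linalg as sla

    ps = _PairState()
    ps.t1 = t1
    ps.dressed = dress_integrals(ints, t1)
    ps.t2 = compute_t2(ps.dressed)
    ps.model = JacobianModel(ps.dressed, ps.t2)
    amat = ps.model.dense()
    vals, vecs = sla.eig(amat)
    ia, ib = _track_pair(vals, vecs, anchor_a, anchor_b)
    va, vb, wa, wb, is_complex = _real_pair_from_roots(vals, vecs, ia, ib, space)
    sigma = float(0.5 * np.real(wa + wb)) + 1.3e-5  # off-eigenvalue shift
    va, vb, wa, wb, is_complex = _refine_pair(amat, va, vb, sigma)
    near_parallel = False
    parallelism = 0.0
    if is_complex:
        # smooth real basis of the invariant subspace (Procrustes onto the
        # previous orientation)
        vmat = np.stack([va, vb], axis=1)
        m = vmat.T @ np.stack([orient_a, orient_b], axis=1)
        u, _, wt = np.linalg.svd(m)
        vmat = vmat @ (u @ wt)
        va, vb = vmat[:, 0], vmat[:, 1]
    else:
        # assign A/B identity by overlap, not by energy order: the roots
        # swap order freely near the degeneracy
        if abs(va @ orient_a) + abs(vb @ orient_b) < \
                abs(vb @ orient_a) + abs(va @ orient_b):
            va, vb = vb, va
            wa, wb = wb, wa
        parallelism = abs(va @ vb)
        if defect_mode and parallelism > 0.5:
            # nearly defective real pair: the eigenvectors are almost
            # parallel, which annihilates X3 and removes all leverage of
            # zeta. Work in the orthonormalized invariant subspace; the
            # basis is rotated below so that the natural-projection overlap
            # vanishes, and zeta instead drives the off-diagonal of the
            # projected Jacobian (the defect itself) to zero.
            near_parallel = True
            vmat, _ = np.linalg.qr(np.stack([va, vb], axis=1))
            m = vmat.T @ np.stack([orient_a, orient_b], axis=1)
            u, _, wt = np.linalg.svd(m)
            vmat = vmat @ (u @ wt)
            va, vb = vmat[:, 0], vmat[:, 1]
    if va @ orient_a < 0:
        va = -va
    if vb @ orient_b < 0:
        vb = -vb
    ps.va, ps.vb = va, vb
    ps.omega_a = wa if is_complex else float(np.real(wa))
    ps.omega_b = wb if is_complex else float(np.real(wb))
    ps.is_complex = is_complex
    r1a, r2a = space.unpack(va)
    r1b, r2b = space.unpack(vb)
    ps.eta = eta_vector(ps.dressed, ps.t2)
    ps.st_a = ExcitedStateVector("right", r1a, r2a, ps.omega_a)
    ps.st_b = ExcitedStateVector("right", r1b, r2b, ps.omega_b)
    ps.st_a.r0 = float(np.real(ground_contribution(ps.eta, r1a, r2a, np.real(wa))))
    ps.st_b.r0 = float(np.real(ground_contribution(ps.eta, r1b, r2b, np.real(wb))))
    ps.near_parallel = near_parallel
    ps.parallelism = parallelism
    ps.x3 = build_x3(ps.st_a, ps.st_b)
    ps.om1 = singles_residual(ps.dressed, ps.t2) + scc_singles_correction(
        ps.dressed, ps.x3, zeta)
    ps.o_val = orthogonality_value(t1, ps.t2, zeta, ps.x3, ps.st_a, ps.st_b)
    if near_parallel:
        _rotate_to_p_orthogonal(ps, ints, zeta, orient_a, orient_b, space)
    return ps


def _rotate_to_p_orthogonal(ps, ints, zeta, orient_a, orient_b, space):
    """Near a defect, fix the subspace basis by the orthogonality condition.

    The 2x2 Gram matrix of the pair under the natural projection is
    symmetric and can always be diagonalized: in that rotated basis
    O(A,B) = 0 identically, and the remaining SCC2 condition is that the
    basis is also an eigenbasis of the Jacobian -- its projected 2x2
    representation must be diagonal. The symmetrized off-diagonal therefore
    replaces O(A,B) as the scalar residual paired with zeta."""
    oaa = orthogonality_value(ps.t1, ps.t2, zeta, None, ps.st_a, ps.st_a)
    obb = orthogonality_value(ps.t1, ps.t2, zeta, None, ps.st_b, ps.st_b)
    oab = ps.o_val
    gram = np.array([[oaa, oab], [oab, obb]])
    _, rot = np.linalg.eigh(gram)
    if np.linalg.det(rot) < 0:
        rot[:, 1] = -rot[:, 1]
    vmat = np.stack([ps.va, ps.vb], axis=1) @ rot
    va, vb = vmat[:, 0], vmat[:, 1]
    if va @ orient_a < 0:
        va = -va
    if vb @ orient_b < 0:
        vb = -vb
    ps.va, ps.vb = va, vb
    r1a, r2a = space.unpack(va)
    r1b, r2b = space.unpack(vb)
    # projected Jacobian in the rotated basis
    ra = ps.model.apply(r1a, r2a)
    rb = ps.model.apply(r1b, r2b)
    pack = lambda t: np.concatenate([space.t1_to_vec(t[0]),  # noqa: E731
                                     space.t2_to_vec(t[1])])
    ara, arb = pack(ra), pack(rb)
    b2 = np.array([[va @ ara, va @ arb], [vb @ ara, vb @ arb]])
    ps.omega_a, ps.omega_b = float(b2[0, 0]), float(b2[1, 1])
    ps.st_a = ExcitedStateVector("right", r1a, r2a, ps.omega_a)
    ps.st_b = ExcitedStateVector("right", r1b, r2b, ps.omega_b)
    ps.st_a.r0 = float(np.real(ground_contribution(ps.eta, r1a, r2a, ps.omega_a)))
    ps.st_b.r0 = float(np.real(ground_contribution(ps.eta, r1b, r2b, ps.omega_b)))
    ps.x3 = build_x3(ps.st_a, ps.st_b)
    ps.om1 = singles_residual(ps.dressed, ps.t2) + scc_singles_correction(
        ps.dressed, ps.x3, zeta)
    # the defect residual: symmetrized coupling between the P-orthogonal
    # basis vectors under the Jacobian
    ps.o_val = float(b2[0, 1] + b2[1, 0])


def _inner_relax(ints, ps, zeta, anchor_a, anchor_b, space, d1, threshold,
                 max_sweeps=8, t1_iters=25, defect_mode=False):
    """Self-consistency at fixed zeta: alternate cheap t1-DIIS relaxation
    (X3 frozen) with re-diagonalization/tracking, until the corrected
    singles residual is converged at the current states."""
    t1 = ps.t1
    diis = DIIS(size=10)
    for _ in range(max_sweeps):
        x3 = ps.x3
        om1 = ps.om1
        for _ in range(t1_iters):
            if np.linalg.norm(om1) <= 0.5 * threshold:
                break
            t1 = diis.extrapolate((t1 + om1 / d1).ravel(), (om1 / d1).ravel()
                                  ).reshape(t1.shape)
            dressed = dress_integrals(ints, t1)
            t2 = compute_t2(dressed)
            om1 = singles_residual(dressed, t2) + scc_singles_correction(
                dressed, x3, zeta)
        ps = _diagonalize_and_track(ints, t1, zeta, anchor_a, anchor_b,
                                    ps.va, ps.vb, space,
                                    defect_mode=defect_mode)
        t1 = ps.t1
        if np.linalg.norm(ps.om1) <= threshold:
            break
    return ps


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    k = int(np.argmax(np.abs(v)))
    return v if v[k] >= 0 else -v


def solve_scc2(ints: SpinMOIntegrals, select: tuple[int, int] = (0, 1), *,
               threshold: float = 1e-8, max_iter: int = 60,
               enforce_orthogonality: bool = True,
               singlet_only: bool = True,
               init: "SCC2Solution | CC2GroundState | None" = None,
               zeta_init: float = 0.0,
               max_zeta_step: float = 0.3,
               history_out: list | None = None) -> SCC2Solution:
    """Simultaneous solution of the coupled SCC2 equations.

    Thin robustness wrapper over the core iteration: the orientation of the
    constrained pair fixes the sign convention of zeta, and the two
    orientations can have different convergence basins, so a failed solve
    is retried once with state B mirrored.
    """
    try:
        return _solve_scc2_core(
            ints, select, threshold=threshold, max_iter=max_iter,
            enforce_orthogonality=enforce_orthogonality,
            singlet_only=singlet_only, init=init, zeta_init=zeta_init,
            max_zeta_step=max_zeta_step, history_out=history_out)
    except (SCC2ConvergenceError, StateTrackingError):
        if not enforce_orthogonality:
            raise
        return _solve_scc2_core(
            ints, select, threshold=threshold, max_iter=max_iter,
            enforce_orthogonality=enforce_orthogonality,
            singlet_only=singlet_only, init=init, zeta_init=zeta_init,
            max_zeta_step=max_zeta_step, history_out=history_out,
            mirror=True)


def _solve_scc2_core(ints: SpinMOIntegrals, select: tuple[int, int] = (0, 1), *,
               threshold: float = 1e-8, max_iter: int = 60,
               enforce_orthogonality: bool = True,
               singlet_only: bool = True,
               init: "SCC2Solution | CC2GroundState | None" = None,
               zeta_init: float = 0.0,
               max_zeta_step: float = 0.3,
               history_out: list | None = None,
               mirror: bool = False) -> SCC2Solution:
    """Simultaneous solution of the coupled SCC2 equations.

    The ground-state singles (with folded doubles), the two constrained
    right states and zeta are brought to joint self-consistency. Each outer
    cycle relaxes t1 at fixed zeta (DIIS over quasi-Newton steps, with the
    constrained pair re-tracked by overlap against the initial anchors) and
    then takes one scalar step in zeta:

    * while the tracked pair is complex (inside a CC2 defect region), zeta
      follows a continuation that drives Im(omega)^2 to zero through a
      finite-difference tangent -- the orthogonality value is flat there
      and carries no useful gradient;
    * once the pair is real, zeta is updated by a damped secant/Newton
      iteration on O(A,B).

    Starting from a CC2 solution zeta is initialized to 0; starting from a
    neighboring SCC2 solution (scans) everything is warm-started. With the
    orthogonality condition disabled the solver reproduces CC2 exactly.
    """
    no, nv = ints.n_occ, ints.n_virt
    space = LabelSpace(no=no, nv=nv)
    eps = ints.eps
    d1 = eps[:no, None] - eps[None, no:]

    if isinstance(init, SCC2Solution):
        t1 = init.t1.copy()
        zeta = init.zeta if enforce_orthogonality else zeta_init
        ref_a = np.concatenate([space.t1_to_vec(np.real(init.state_a.r1)),
                                space.t2_to_vec(np.real(init.state_a.r2))])
        ref_b = np.concatenate([space.t1_to_vec(np.real(init.state_b.r1)),
                                space.t2_to_vec(np.real(init.state_b.r2))])
        ref_a /= np.linalg.norm(ref_a)
        ref_b /= np.linalg.norm(ref_b)
    else:
        gs = init if isinstance(init, CC2GroundState) else solve_cc2_ground(
            ints, threshold=min(threshold, 1e-9))
        t1, zeta = gs.t1.copy(), zeta_init
        model0 = JacobianModel(gs.dressed, gs.t2)
        _, vals0, vecs0, idx0 = _select_initial(model0, select, singlet_only)
        ref_a, ref_b, *_ = _real_pair_from_roots(vals0, vecs0, idx0[0], idx0[1], space)
        ref_a = _canonical_sign(ref_a)
        ref_b = _canonical_sign(ref_b)
    if mirror:
        ref_b = -ref_b
    anchor_a, anchor_b = ref_a.copy(), ref_b.copy()

    ps = _diagonalize_and_track(ints, t1, zeta, anchor_a, anchor_b,
                                ref_a, ref_b, space)
    history = history_out if history_out is not None else []
    secant_prev = None  # (zeta, O) from the previous real-phase point
    cont_dir = 1.0  # probe direction for the realification continuation
    bracket = None  # ((zeta_lo, O_lo), (zeta_hi, O_hi)) with opposite signs
    defect_mode = False  # scalar residual = projected-Jacobian off-diagonal
    best_o = np.inf
    last_improve_it = 0

    def imag2(p):
        return float(np.imag(p.omega_a)) ** 2

    # O(A,B) is amplified relative to the t1 residual by roughly the
    # inverse angle between the two nearly parallel states, so the inner
    # relaxation must run well below the outer threshold
    tin = max(1e-12, 1e-3 * threshold)
    for it in range(1, max_iter + 1):
        ps = _inner_relax(ints, ps, zeta, anchor_a, anchor_b, space, d1, tin,
                          defect_mode=defect_mode)
        if (it == 1 and enforce_orthogonality and not defect_mode
                and not ps.is_complex and ps.parallelism > 0.5):
            # starting directly on a (near-)defective real pair? The almost
            # parallel eigenvectors annihilate X3, in which case the
            # overlap cannot respond to zeta. Probe the plain response
            # first; only when the Newton step is hopeless switch the
            # scalar residual to the projected-Jacobian off-diagonal in
            # the P-orthogonal subspace basis (the defect itself).
            probe0 = _inner_relax(ints, ps, zeta + 0.05, anchor_a, anchor_b,
                                  space, d1, tin, max_sweeps=3, t1_iters=14)
            slope0 = (probe0.o_val - ps.o_val) / 0.05 \
                if not probe0.is_complex else 0.0
            impotent = abs(slope0) < 1e-14 or \
                abs(ps.o_val / slope0) > 20 * max_zeta_step
            if impotent:
                defect_mode = True
                ps = _inner_relax(
                    ints, _diagonalize_and_track(ints, ps.t1, zeta, anchor_a,
                                                 anchor_b, ps.va, ps.vb, space,
                                                 defect_mode=True),
                    zeta, anchor_a, anchor_b, space, d1, tin, defect_mode=True)
        resid1 = float(np.linalg.norm(space.t1_to_vec(ps.om1)))
        resid_o = abs(ps.o_val) if enforce_orthogonality else 0.0
        history.append((resid1, resid_o, abs(np.imag(ps.omega_a)), zeta))
        if resid_o < 0.5 * best_o:
            best_o = resid_o
            last_improve_it = it
        if (enforce_orthogonality and not defect_mode and not ps.is_complex
                and ps.parallelism > 0.5 and it - last_improve_it >= 5
                and resid_o > threshold):
            # the overlap residual has stalled on a nearly parallel pair:
            # its evaluation noise is amplified by the inverse pair angle.
            # Switch to the defect residual, which is noise-robust.
            defect_mode = True
            secant_prev = None
            bracket = None
            best_o = np.inf
            last_improve_it = it
            ps = _inner_relax(
                ints, _diagonalize_and_track(ints, ps.t1, zeta, anchor_a,
                                             anchor_b, ps.va, ps.vb, space,
                                             defect_mode=True),
                zeta, anchor_a, anchor_b, space, d1, tin, defect_mode=True)
            continue
        if resid1 <= threshold and not ps.is_complex \
                and (not enforce_orthogonality or resid_o <= threshold):
            return SCC2Solution(
                t1=ps.t1, t2=ps.t2, zeta=zeta,
                state_a=ps.st_a.normalized(), state_b=ps.st_b.normalized(),
                energy=ground_energy(ps.dressed, ps.t2),
                orthogonality_residual=abs(ps.o_val),
                singles_residual_norm=resid1,
                iterations=it, converged=True, eta=ps.eta, history=history)
        if not enforce_orthogonality:
            continue  # plain CC2 relaxation only

        if ps.is_complex:
            # --- continuation phase: drive Im(omega)^2 -> 0 -----------
            # Newton step on Im^2 with backtracking: the step is only
            # accepted if it actually shrinks the imaginary part, so the
            # continuation is monotone and cannot oscillate across the
            # realification boundary.
            f0 = imag2(ps)
            h = cont_dir * max(0.05, 0.02 * (abs(zeta) + 1.0))
            probe = _inner_relax(ints, ps, zeta + h, anchor_a, anchor_b,
                                 space, d1, tin,
                                 max_sweeps=3, t1_iters=14,
                                 defect_mode=defect_mode)
            if not probe.is_complex:
                # the probe already left the complex region: take it
                zeta += h
                ps = probe
                secant_prev = None
                continue
            slope = (imag2(probe) - f0) / h
            if abs(slope) < 1e-16:
                raise SCC2ConvergenceError(
                    "imaginary part insensitive to zeta; cannot realify the "
                    "constrained pair", history)
            step = float(np.clip(-f0 / slope, -max_zeta_step, max_zeta_step))
            trial = None
            for _ in range(8):
                cand = _inner_relax(
                    ints, _diagonalize_and_track(ints, ps.t1, zeta + step,
                                                 anchor_a, anchor_b,
                                                 ps.va, ps.vb, space,
                                                 defect_mode=defect_mode),
                    zeta + step, anchor_a, anchor_b, space, d1,
                    tin, max_sweeps=3, t1_iters=14)
                if not cand.is_complex or imag2(cand) < 0.999 * f0:
                    trial = cand
                    break
                step *= 0.5
            if trial is None:
                raise SCC2ConvergenceError(
                    "zeta continuation failed to reduce the imaginary part",
                    history)
            cont_dir = float(np.sign(step)) or 1.0
            zeta += step
            ps = trial
            secant_prev = None
            continue
        else:
            # --- real phase: guarded secant on O(A,B) -----------------
            # Near the realification boundary the two real states are
            # almost parallel (O ~ 1) and a small probe can fall back into
            # the complex region; such probes are unusable and the update
            # keeps pushing outward (the direction the continuation was
            # traveling) until the secant becomes informative.
            slope = None
            if secant_prev is not None and abs(secant_prev[0] - zeta) > 1e-12 \
                    and abs(secant_prev[1] - ps.o_val) > 1e-15:
                slope = (ps.o_val - secant_prev[1]) / (zeta - secant_prev[0])
            else:
                # a macroscopic probe: the scalar residual responds weakly
                # to zeta near defects and a tiny step would drown in the
                # evaluation noise of the inner relaxation
                h = cont_dir * max(0.05, 0.01 * abs(zeta))
                probe = _inner_relax(ints, ps, zeta + h, anchor_a, anchor_b,
                                     space, d1, tin,
                                     max_sweeps=3, t1_iters=14,
                                     defect_mode=defect_mode)
                if not probe.is_complex:
                    slope = (probe.o_val - ps.o_val) / h
            secant_prev = (zeta, ps.o_val)
            if slope is not None and abs(slope) > 1e-14:
                step = float(np.clip(-ps.o_val / slope,
                                     -max_zeta_step, max_zeta_step))
            else:
                step = cont_dir * max_zeta_step  # exploratory outward step
            accepted = None
            fallback = None
            for _ in range(5):
                cand_zeta = zeta + step
                if bracket is not None and not (
                        bracket[0][0] <= cand_zeta <= bracket[1][0]):
                    cand_zeta = 0.5 * (bracket[0][0] + bracket[1][0])
                cand = _inner_relax(
                    ints, _diagonalize_and_track(ints, ps.t1, cand_zeta,
                                                 anchor_a, anchor_b,
                                                 ps.va, ps.vb, space,
                                                 defect_mode=defect_mode),
                    cand_zeta, anchor_a, anchor_b, space, d1, tin,
                    max_sweeps=3, t1_iters=14, defect_mode=defect_mode)
                if cand.is_complex:
                    # never step back inside the complex region
                    step *= 0.5
                    continue
                fallback = (cand_zeta, cand)
                if abs(cand.o_val) < abs(ps.o_val):
                    accepted = (cand_zeta, cand)
                    break
                # keep the sign-change information for bisection
                if np.sign(cand.o_val) != np.sign(ps.o_val):
                    lo, hi = sorted([(zeta, ps.o_val), (cand_zeta, cand.o_val)])
                    bracket = (lo, hi)
                step *= 0.5
            if accepted is None:
                if bracket is not None:
                    # plain bisection inside the bracket
                    cand_zeta = 0.5 * (bracket[0][0] + bracket[1][0])
                    cand = _inner_relax(
                        ints, _diagonalize_and_track(ints, ps.t1, cand_zeta,
                                                     anchor_a, anchor_b,
                                                     ps.va, ps.vb, space,
                                                     defect_mode=defect_mode),
                        cand_zeta, anchor_a, anchor_b, space, d1, tin,
                        max_sweeps=3, t1_iters=14, defect_mode=defect_mode)
                    accepted = (cand_zeta, cand)
                elif fallback is not None:
                    # no descent yet: accept the outward move regardless, to
                    # escape the near-parallel boundary region
                    accepted = fallback
                else:
                    # the Newton direction pointed back inside the complex
                    # region: step outward instead
                    cand_zeta = zeta + cont_dir * max_zeta_step
                    cand = _inner_relax(
                        ints, _diagonalize_and_track(ints, ps.t1, cand_zeta,
                                                     anchor_a, anchor_b,
                                                     ps.va, ps.vb, space,
                                                     defect_mode=defect_mode),
                        cand_zeta, anchor_a, anchor_b, space, d1, tin,
                        max_sweeps=3, t1_iters=14, defect_mode=defect_mode)
                    if cand.is_complex:
                        raise SCC2ConvergenceError(
                            "zeta update failed: every candidate step "
                            "re-entered the complex region", history)
                    accepted = (cand_zeta, cand)
            new_zeta, cand = accepted
            if not cand.is_complex and np.sign(cand.o_val) != np.sign(ps.o_val):
                lo, hi = sorted([(zeta, ps.o_val), (new_zeta, cand.o_val)])
                bracket = (lo, hi)
            elif bracket is not None and not cand.is_complex:
                # shrink the bracket with the new point when possible
                if np.sign(cand.o_val) == np.sign(bracket[0][1]):
                    bracket = ((new_zeta, cand.o_val), bracket[1])
                elif np.sign(cand.o_val) == np.sign(bracket[1][1]):
                    bracket = (bracket[0], (new_zeta, cand.o_val))
            if cand.near_parallel != ps.near_parallel:
                secant_prev = None  # the scalar residual changed meaning
            zeta = new_zeta
            ps = cand
            continue
        ps = _diagonalize_and_track(ints, ps.t1, zeta, anchor_a, anchor_b,
                                    ps.va, ps.vb, space,
                                    defect_mode=defect_mode)

    raise SCC2ConvergenceError(
        f"SCC2 did not converge in {max_iter} outer iterations "
        f"(|Omega1|={history[-1][0]:.2e}, |O|={history[-1][1]:.2e}, "
        f"|Im omega|={history[-1][2]:.2e}, zeta={history[-1][3]:+.4f})", history)


def save_solution(path, sol: SCC2Solution) -> None:
    """Serialize a converged solution (npz) for scan restarts."""
    np.savez_compressed(
        path, t1=sol.t1, t2=sol.t2, zeta=sol.zeta,
        r1a=np.real(sol.state_a.r1), r2a=np.real(sol.state_a.r2),
        r1b=np.real(sol.state_b.r1), r2b=np.real(sol.state_b.r2),
        r0a=np.real(sol.state_a.r0), r0b=np.real(sol.state_b.r0),
        omega_a=np.real(sol.state_a.omega), omega_b=np.real(sol.state_b.omega),
        energy=sol.energy, eta1=sol.eta[0], eta2=sol.eta[1])


def load_solution(path) -> SCC2Solution:
    with np.load(path) as data:
        st_a = ExcitedStateVector("right", data["r1a"], data["r2a"],
                                  float(data["omega_a"]), float(data["r0a"]))
        st_b = ExcitedStateVector("right", data["r1b"], data["r2b"],
                                  float(data["omega_b"]), float(data["r0b"]))
        return SCC2Solution(
            t1=data["t1"], t2=data["t2"], zeta=float(data["zeta"]),
            state_a=st_a, state_b=st_b, energy=float(data["energy"]),
            orthogonality_residual=np.nan, singles_residual_norm=np.nan,
            iterations=0, converged=True,
            eta=(data["eta1"], data["eta2"]))
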