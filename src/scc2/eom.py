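"""EOM-CC2 excited states: Jacobian actions, folding, eigensolvers.

The CC2 Jacobian over singles+doubles labels is

    A = [[ A11  A12 ],
         [ A21  eps ]]

with A11 = <mu1|[Htilde + [Htilde,T2], tau_nu1]|HF>, the doubles-doubles
block exactly diagonal in the orbital-energy differences, and the coupling
blocks linear in the dressed integrals. All actions are O(N^5) tensor
contractions; the doubles space is never iterated explicitly -- the
omega-nonlinear folded problem

    [A11 + A12 (omega - eps)^{-1} A21] r1 = omega r1

is solved self-consistently in omega (Davidson path), or the full matrix is
diagonalized dense, which is also the route that exposes complex-conjugate
eigenvalue pairs inside CC2 defect regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .cc2 import DressedIntegrals, doubles_denominators
from .labels import LabelSpace, dot_full

_DENSE_CAP = 20_000


class FoldSingularityError(ArithmeticError):
    pass


class EOMConvergenceError(RuntimeError):
    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


@dataclass
class ExcitedStateVector:
    """One EOM state: amplitudes (tensors), reference weight, energy.

    r1 has shape (no, nv); r2 is the antisymmetric doubles tensor. For left
    states the fields hold l1/l2 and r0 is identically 0. omega may be a
    complex scalar on the dense CC2 path inside a defect region.
    """

    side: str  # "right" | "left"
    r1: np.ndarray
    r2: np.ndarray
    omega: complex
    r0: float = 0.0
    norm_convention: str = "unit-2-norm"

    def norm(self) -> float:
        return float(np.sqrt(abs(dot_full((self.r1, self.r2), (np.conj(self.r1), np.conj(self.r2))))))

    def normalized(self) -> "ExcitedStateVector":
        n = self.norm()
        return ExcitedStateVector(self.side, self.r1 / n, self.r2 / n,
                                  self.omega, self.r0 / n, self.norm_convention)


def phase_fix(r1: np.ndarray, r2: np.ndarray):
    """Make the largest-|r1| element positive; ties break on lowest index."""
    flat = np.abs(r1).ravel()
    best = np.argmax(np.round(flat, 12))
    sign = np.sign(r1.ravel()[best].real) or 1.0
    return r1 * sign, r2 * sign, sign


def spin_flip(r1: np.ndarray, r2: np.ndarray | None = None):
    """Swap alpha and beta labels (interleaved convention: i <-> i^1)."""
    def flip_axis(x, axis):
        idx = np.arange(x.shape[axis])
        idx = idx ^ 1
        return np.take(x, idx, axis=axis)

    f1 = flip_axis(flip_axis(r1, 0), 1)
    if r2 is None:
        return f1
    f2 = r2
    for ax in range(4):
        f2 = flip_axis(f2, ax)
    return f1, f2


def spin_signature(r1: np.ndarray, r2: np.ndarray) -> float:
    """+1 for singlet-like states, -1 for triplet-like (real vectors)."""
    f1, f2 = spin_flip(r1.real, r2.real)
    num = dot_full((r1.real, r2.real), (f1, f2))
    den = dot_full((r1.real, r2.real), (r1.real, r2.real))
    return num / den if den > 0 else 0.0


@dataclass
class JacobianModel:
    """CC2 Jacobian defined by dressed integrals and ground-state doubles."""

    dressed: DressedIntegrals
    t2: np.ndarray
    space: LabelSpace = field(init=False)

    def __post_init__(self):
        self.space = self.dressed.space
        d = self.dressed
        o, v = d.o, d.v
        w = d.w_tilde
        self._f = d.f_tilde
        self._w_oovv = w[o, o, v, v]
        self._w_ovvv = w[o, v, v, v]
        self._w_oovo = w[o, o, v, o]
        self._w_voov = w[v, o, o, v]
        self._w_vvvo = w[v, v, v, o]
        self._w_ovoo = w[o, v, o, o]
        self._eps2 = -doubles_denominators(d)  # eps_a+eps_b-eps_i-eps_j

    @property
    def n_singles(self) -> int:
        return self.space.n_singles

    @property
    def n_doubles(self) -> int:
        return self.space.n_doubles

    @property
    def eps_doubles(self) -> np.ndarray:
        return self._eps2

    # ------------------------------------------------------------------
    def apply(self, r1: np.ndarray, r2: np.ndarray):
        """(rho1, rho2) = A (r1, r2); leading batch axes are supported."""
        d = self.dressed
        o, v = d.o, d.v
        f = self._f
        fvv, foo, fov = f[v, v], f[o, o], f[o, v]
        # A11: one-electron + two-electron + T2 coupling
        rho1 = np.einsum("ab,...ib->...ia", fvv, r1, optimize=True)
        rho1 -= np.einsum("ji,...ja->...ia", foo, r1, optimize=True)
        rho1 += np.einsum("ajib,...jb->...ia", self._w_voov, r1, optimize=True)
        rho1 += np.einsum("mnef,...me,inaf->...ia", self._w_oovv, r1, self.t2, optimize=True)
        rho1 -= 0.5 * np.einsum("mnef,...ma,inef->...ia", self._w_oovv, r1, self.t2, optimize=True)
        rho1 -= 0.5 * np.einsum("mnef,...ie,mnaf->...ia", self._w_oovv, r1, self.t2, optimize=True)
        # A12
        rho1 += np.einsum("jb,...ijab->...ia", fov, r2, optimize=True)
        rho1 += 0.5 * np.einsum("kacd,...kicd->...ia", self._w_ovvv, r2, optimize=True)
        rho1 -= 0.5 * np.einsum("klci,...klca->...ia", self._w_oovo, r2, optimize=True)
        # A21
        x = np.einsum("abej,...ie->...ijab", self._w_vvvo, r1, optimize=True)
        rho2 = x - np.swapaxes(x, -4, -3)
        y = np.einsum("mbij,...ma->...ijab", self._w_ovoo, r1, optimize=True)
        rho2 -= y - np.swapaxes(y, -2, -1)
        # A22 diagonal
        rho2 = rho2 + self._eps2 * r2
        return rho1, rho2

    def apply_transpose(self, l1: np.ndarray, l2: np.ndarray):
        """(sigma1, sigma2) = A^T (l1, l2) in the label-space inner product."""
        d = self.dressed
        o, v = d.o, d.v
        f = self._f
        fvv, foo, fov = f[v, v], f[o, o], f[o, v]
        # A11^T
        sig1 = np.einsum("ab,ia->ib", fvv, l1, optimize=True)
        sig1 -= np.einsum("ji,ia->ja", foo, l1, optimize=True)
        sig1 += np.einsum("ajib,ia->jb", self._w_voov, l1, optimize=True)
        sig1 += np.einsum("mnef,inaf,ia->me", self._w_oovv, self.t2, l1, optimize=True)
        sig1 -= 0.5 * np.einsum("mnef,inef,ia->ma", self._w_oovv, self.t2, l1, optimize=True)
        sig1 -= 0.5 * np.einsum("mnef,mnaf,ia->ie", self._w_oovv, self.t2, l1, optimize=True)
        # A21^T (doubles -> singles)
        sig1 += np.einsum("abej,ijab->ie", self._w_vvvo, l2, optimize=True)
        sig1 -= np.einsum("mbij,ijab->ma", self._w_ovoo, l2, optimize=True)
        # A12^T (singles -> doubles), fully antisymmetrized
        b = np.einsum("jb,ia->ijab", fov, l1, optimize=True)
        sig2 = _antisymmetrize(b)
        t = 0.5 * np.einsum("kacd,ia->kicd", self._w_ovvv, l1, optimize=True)
        sig2 += _antisymmetrize(t)
        t = -0.5 * np.einsum("klci,ia->klca", self._w_oovo, l1, optimize=True)
        sig2 += _antisymmetrize(t)
        # A22^T diagonal
        sig2 += self._eps2 * l2
        return sig1, sig2

    # ------------------------------------------------------------------
    def unfold_r2(self, r1: np.ndarray, omega: complex, guard: float = 1e-8):
        """r2 = (omega - eps)^{-1} A21 r1 with singularity guard."""
        x = np.einsum("abej,ie->ijab", self._w_vvvo, r1, optimize=True)
        a21 = x - x.transpose(1, 0, 2, 3)
        y = np.einsum("mbij,ma->ijab", self._w_ovoo, r1, optimize=True)
        a21 -= y - y.transpose(0, 1, 3, 2)
        den = omega - self._eps2
        if np.isrealobj(np.asarray(omega)) and np.isreal(omega):
            small = np.abs(den) < guard
            if np.any(small):
                idx = tuple(np.argwhere(small)[0])
                raise FoldSingularityError(
                    f"omega within {guard:.0e} of doubles energy at label {idx}")
        return a21 / den

    def folded_apply(self, omega: float, r1: np.ndarray) -> np.ndarray:
        """[A11 + A12 (omega - eps)^{-1} A21] r1 with r2 implicit."""
        r2 = self.unfold_r2(r1, omega)
        rho1, _ = self.apply(r1, r2)
        return rho1

    # ------------------------------------------------------------------
    def dense(self) -> np.ndarray:
        """Explicit (singles+doubles) Jacobian; columns via apply on unit vectors."""
        sp = self.space
        if sp.dim > _DENSE_CAP:
            raise ValueError(
                f"dimension {sp.dim} exceeds dense cap {_DENSE_CAP}; use the Davidson path")
        # batched application to the full unit basis
        b1 = sp.vec_to_t1(np.eye(sp.n_singles))
        rho1, rho2 = self.apply(b1, np.zeros((sp.n_singles, sp.no, sp.no,
                                              sp.nv, sp.nv)))
        cols_s = np.concatenate([sp.t1_to_vec(rho1), sp.t2_to_vec(rho2)], axis=-1)
        b2 = sp.vec_to_t2(np.eye(sp.n_doubles))
        rho1, rho2 = self.apply(np.zeros((sp.n_doubles, sp.no, sp.nv)), b2)
        cols_d = np.concatenate([sp.t1_to_vec(rho1), sp.t2_to_vec(rho2)], axis=-1)
        return np.concatenate([cols_s, cols_d], axis=0).T

    def folded_dense(self, omega: float) -> np.ndarray:
        """Dense matrix of the folded operator at fixed omega."""
        sp = self.space
        a = np.empty((sp.n_singles, sp.n_singles))
        for k in range(sp.n_singles):
            e = np.zeros(sp.n_singles)
            e[k] = 1.0
            a[:, k] = sp.t1_to_vec(self.folded_apply(omega, sp.vec_to_t1(e)))
        return a


def _antisymmetrize(x: np.ndarray) -> np.ndarray:
    x = x - x.transpose(1, 0, 2, 3)
    return x - x.transpose(0, 1, 3, 2)


def ground_contribution(eta: tuple[np.ndarray, np.ndarray],
                        r1: np.ndarray, r2: np.ndarray, omega: complex) -> complex:
    """r0 = eta^T r / omega (Eq. of the similarity-transformed H matrix)."""
    if abs(omega) < 1e-12:
        raise ZeroDivisionError("r0 undefined for omega ~ 0")
    num = dot_full((eta[0], eta[1]), (r1, r2))
    return num / omega


# ----------------------------------------------------------------------
# dense and Davidson eigensolvers
# ----------------------------------------------------------------------

def solve_right_states_dense(model: JacobianModel, n_states: int,
                             singlet_only: bool = False) -> list[ExcitedStateVector]:
    """All right eigenpairs from the dense Jacobian; lowest by real part.

    Complex-conjugate pairs (CC2 defects) are returned as genuinely complex
    states; spin filtering assumes a spin-restricted reference.
    """
    sp = model.space
    a = model.dense()
    vals, vecs = sla.eig(a)
    order = np.argsort(vals.real)
    out = []
    for k in order:
        w = vals[k]
        v = vecs[:, k]
        if abs(w.imag) < 1e-10:
            w = w.real
            v = _realize(v)
        r1, r2 = sp.unpack(v)
        st = ExcitedStateVector("right", r1, r2, w).normalized()
        if singlet_only and spin_signature(st.r1.real, st.r2.real) < 0.0:
            continue
        st.r1, st.r2, _ = phase_fix(st.r1, st.r2)
        out.append(st)
        if len(out) == n_states:
            break
    return out


def _realize(v: np.ndarray) -> np.ndarray:
    """Rotate a numerically-complex eigenvector with real eigenvalue to real."""
    k = np.argmax(np.abs(v))
    v = v * np.exp(-1j * np.angle(v[k]))
    return v.real


def solve_left_states(model: JacobianModel,
                      rights: list[ExcitedStateVector]) -> list[ExcitedStateVector]:
    """Left eigenvectors biorthonormalized against the given right states."""
    sp = model.space
    a = model.dense()
    vals, vecs = sla.eig(a.T)
    lefts = []
    for r in rights:
        # match by eigenvalue
        k = int(np.argmin(np.abs(vals - r.omega)))
        if abs(vals[k] - r.omega) > 1e-6:
            raise EOMConvergenceError(
                f"no left eigenvalue matches omega={r.omega}")
        lv = vecs[:, k]
        if abs(np.asarray(r.omega).imag) < 1e-10:
            lv = _realize(lv)
        l1, l2 = sp.unpack(lv)
        ov = dot_full((l1, l2), (r.r1, r.r2))
        if abs(ov) < 1e-10:
            raise EOMConvergenceError(
                "defective Jacobian: left/right overlap vanishes "
                f"at omega={r.omega} (expected only at an exact CC2 intersection seam)")
        lefts.append(ExcitedStateVector("left", l1 / ov, l2 / ov, vals[k], r0=0.0))
    return lefts


def _initial_guesses(model: JacobianModel, n: int) -> list[np.ndarray]:
    """Koopmans-like guesses on the smallest orbital-energy gaps.

    For a spin-restricted reference each spatial excitation appears as an
    alpha and a beta label; their symmetric/antisymmetric combinations give
    singlet- and triplet-adapted starting vectors.
    """
    sp = model.space
    d = model.dressed
    labels = {lab: k for k, lab in enumerate(sp.singles)}
    diag = np.array([d.eps[sp.no + a] - d.eps[i] for (i, a) in sp.singles])
    out, seen = [], set()
    for k in np.argsort(diag):
        i, a = sp.singles[k]
        key = (i // 2, a // 2)
        if key in seen:
            continue
        seen.add(key)
        partner = labels.get((i ^ 1, a ^ 1))
        for sign in (+1.0, -1.0):
            e = np.zeros(sp.n_singles)
            e[k] = 1.0
            if partner is not None and partner != k:
                e[partner] = sign
                e /= np.sqrt(2.0)
            out.append(e)
            if partner is None or partner == k:
                break
        if len(out) >= n:
            break
    return out[:n]


def solve_right_states_davidson(model: JacobianModel, n_states: int,
                                guesses: list[np.ndarray] | None = None,
                                threshold: float = 1e-9, max_iter: int = 100,
                                relax: float = 0.5,
                                omega_tol: float = 1e-9) -> list[ExcitedStateVector]:
    """Folded nonlinear eigenproblem by subspace iteration + omega fixed point.

    Each root is converged in the singles space with its own self-consistent
    omega; doubles are reconstructed by unfolding at the end. Detects root
    coalescence (possible CC2 defect) and raises with guidance toward the
    dense path.
    """
    sp = model.space
    d = model.dressed
    diag = np.array([d.eps[sp.no + a] - d.eps[i] for (i, a) in sp.singles])
    if guesses is None:
        guesses = _initial_guesses(model, min(3 * n_states + 2, sp.n_singles))
    states = []
    found_vecs: list[np.ndarray] = []
    guess_queue = list(guesses)
    attempts = 0
    while len(states) < n_states and guess_queue and attempts < 10 * n_states:
        attempts += 1
        x = guess_queue.pop(0)
        # bias the start away from roots already found
        for fv in found_vecs:
            x = x - fv * (fv @ x)
        if np.linalg.norm(x) < 1e-8:
            continue
        omega = float(diag[int(np.argmax(np.abs(x)))])
        x = x / np.linalg.norm(x)
        vs = [x]
        target = None
        history = []
        for it in range(max_iter):
            vmat = np.stack(vs, axis=1)
            # orthonormalize subspace
            q, _ = np.linalg.qr(vmat)
            avs = np.stack([sp.t1_to_vec(model.folded_apply(omega, sp.vec_to_t1(q[:, j])))
                            for j in range(q.shape[1])], axis=1)
            h_sub = q.T @ avs
            evals, evecs = sla.eig(h_sub)
            # pick subspace root: nearest to omega with real part, else by overlap
            if target is None:
                pick = int(np.argmin(np.abs(evals.real - omega) + 1e3 * np.abs(evals.imag)))
            else:
                ovl = np.abs((q @ evecs.real).T @ target) + np.abs((q @ evecs.imag).T @ target)
                pick = int(np.argmax(ovl))
            theta = evals[pick]
            if abs(theta.imag) > 1e-8:
                raise EOMConvergenceError(
                    "folded Davidson encountered a complex subspace root "
                    "(possible CC2 defect region); use the dense path", history)
            theta = float(theta.real)
            xfull = _realize(q @ evecs[:, pick])
            xfull /= np.linalg.norm(xfull)
            target = xfull
            resid_vec = sp.t1_to_vec(model.folded_apply(omega, sp.vec_to_t1(xfull))) - theta * xfull
            rnorm = np.linalg.norm(resid_vec)
            history.append((omega, theta, rnorm))
            if rnorm < threshold and abs(theta - omega) < omega_tol:
                break
            omega = omega + relax * (theta - omega)
            denom = theta - diag
            denom = np.where(np.abs(denom) < 1e-6, np.sign(denom + 1e-30) * 1e-6, denom)
            corr = resid_vec / denom
            # orthogonalize against subspace
            corr = corr - q @ (q.T @ corr)
            if np.linalg.norm(corr) > 1e-12:
                vs.append(corr / np.linalg.norm(corr))
            if len(vs) > min(30, sp.n_singles):
                vs = [xfull]
        else:
            raise EOMConvergenceError(
                f"Davidson: no convergence in {max_iter} iterations", history)
        # duplicate detection: same omega and same singles vector
        duplicate = any(abs(st.omega - omega) < 1e-8 and abs(fv @ xfull) > 0.9
                        for st, fv in zip(states, found_vecs))
        if duplicate:
            continue
        r1 = sp.vec_to_t1(xfull)
        r2 = model.unfold_r2(r1, omega)
        st = ExcitedStateVector("right", r1, r2, omega).normalized()
        st.r1, st.r2, _ = phase_fix(st.r1, st.r2)
        states.append(st)
        found_vecs.append(xfull)
    if len(states) < n_states:
        raise EOMConvergenceError(
            f"Davidson located only {len(states)} of {n_states} distinct roots")
    order = np.argsort([np.real(s.omega) for s in states])
    return [states[k] for k in order]


def solve_right_states(model: JacobianModel, n_states: int,
                       method: str = "dense", **kw) -> list[ExcitedStateVector]:
    if method == "dense":
        return solve_right_states_dense(model, n_states, **kw)
    if method == "davidson":
        return solve_right_states_davidson(model, n_states, **kw)
    raise ValueError(f"unknown eigensolver method {method!r}")
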