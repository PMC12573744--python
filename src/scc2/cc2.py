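"""CC2 ground state: T1-dressed integrals, folded doubles, DIIS solver.

Working equations are spin-orbital. The T1 transformation is realized
exactly as a pair of modified one-index transformations of the MO
integrals; the doubles equations then read

    <mu2| Htilde |HF> + eps_mu2 t_mu2 = 0,

because the T1-transformed Fock operator has diagonal occupied-occupied
and virtual-virtual blocks for canonical orbitals and its virtual-occupied
block commutes with T2. The closed-form doubles

    t_{ij}^{ab} = <ab||ij>~ / (eps_i + eps_j - eps_a - eps_b)

are therefore exact for this model, and only the singles are iterated
(folding). The ground-state energy and the singles residual use the CCSD
expressions with dressed integrals, which terminate exactly at terms
linear in T2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import LabelSpace
from .moints import SpinMOIntegrals


class DegeneracyError(ArithmeticError):
    """Vanishing orbital-energy denominator in a closed-form doubles update."""


class CCConvergenceError(RuntimeError):
    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class DressedIntegrals:
    """T1-transformed Hamiltonian blocks (spin-orbital).

    h_tilde / g_tilde are the similarity-transformed one- and two-electron
    integrals (g in chemist notation, no permutational symmetry in general);
    w_tilde is the antisymmetrized physicist form <pq||rs>~; f_tilde is the
    one-body (Fock-like) part of the normal-ordered dressed Hamiltonian.
    At t1 = 0 everything reduces to the undressed integrals exactly.
    """

    h_tilde: np.ndarray
    g_tilde: np.ndarray
    w_tilde: np.ndarray
    f_tilde: np.ndarray
    eps: np.ndarray  # bare canonical orbital energies
    n_occ: int
    scalar: float  # <HF| Htilde |HF> including nuclear repulsion

    @property
    def n_so(self) -> int:
        return self.h_tilde.shape[0]

    @property
    def n_virt(self) -> int:
        return self.n_so - self.n_occ

    @property
    def space(self) -> LabelSpace:
        return LabelSpace(no=self.n_occ, nv=self.n_virt)

    # convenient slices
    @property
    def o(self):
        return slice(0, self.n_occ)

    @property
    def v(self):
        return slice(self.n_occ, self.n_so)


def dress_integrals(ints: SpinMOIntegrals, t1: np.ndarray) -> DressedIntegrals:
    """exp(-T1) H exp(T1) realized by one-index transformations.

    The creation-line transform X = 1 - t1 (virtual-occupied block) and the
    annihilation-line transform Y = 1 + t1 (occupied-virtual block) carry
    the full dressing; the operator identity is exact, no truncation.
    """
    nso, no = ints.n_so, ints.n_occ
    x = np.eye(nso)
    x[no:, :no] = -t1.T
    y = np.eye(nso)
    y[:no, no:] = t1
    h_t = x @ ints.h @ y.T
    g_t = np.einsum("Pp,Qq,pqrs->PQrs", x, y, ints.g, optimize=True)
    g_t = np.einsum("Rr,Ss,PQrs->PQRS", x, y, g_t, optimize=True)
    w_t = g_t.transpose(0, 2, 1, 3) - g_t.transpose(0, 2, 3, 1)
    o = slice(0, no)
    f_t = h_t + np.einsum("piqi->pq", w_t[:, o, :, o])
    scalar = (ints.scalar_shift + np.einsum("ii->", h_t[o, o])
              + 0.5 * np.einsum("ijij->", w_t[o, o, o, o]))
    return DressedIntegrals(h_tilde=h_t, g_tilde=g_t, w_tilde=w_t, f_tilde=f_t,
                            eps=ints.eps, n_occ=no, scalar=float(scalar))


def doubles_denominators(dressed: DressedIntegrals) -> np.ndarray:
    """eps_i + eps_j - eps_a - eps_b as an (o,o,v,v) tensor."""
    eps, no = dressed.eps, dressed.n_occ
    e_o, e_v = eps[:no], eps[no:]
    return (e_o[:, None, None, None] + e_o[None, :, None, None]
            - e_v[None, None, :, None] - e_v[None, None, None, :])


def compute_t2(dressed: DressedIntegrals, guard: float = 1e-8) -> np.ndarray:
    """Closed-form folded doubles t2[i,j,a,b] = <ab||ij>~ / D_{ijab}."""
    d = doubles_denominators(dressed)
    small = np.abs(d) < guard
    if np.any(small):
        idx = np.argwhere(small)[0]
        raise DegeneracyError(
            f"occupied/virtual degeneracy in doubles denominator at (i,j,a,b)={tuple(idx)}: "
            f"|D|={abs(d[tuple(idx)]):.2e} < {guard:.0e}")
    o, v = dressed.o, dressed.v
    return dressed.w_tilde[v, v, o, o].transpose(2, 3, 0, 1) / d


def doubles_residual(dressed: DressedIntegrals, t2: np.ndarray) -> np.ndarray:
    """Omega_mu2 = <mu2|Htilde|HF> + eps_mu2 t_mu2 (vanishes for folded t2)."""
    o, v = dressed.o, dressed.v
    return dressed.w_tilde[v, v, o, o].transpose(2, 3, 0, 1) - doubles_denominators(dressed) * t2


def singles_residual(dressed: DressedIntegrals, t2: np.ndarray) -> np.ndarray:
    """Omega_mu1 = <mu1|Htilde + [Htilde, T2]|HF> as an (o,v) tensor."""
    o, v = dressed.o, dressed.v
    f, w = dressed.f_tilde, dressed.w_tilde
    om = f[v, o].T.copy()
    om += np.einsum("jb,ijab->ia", f[o, v], t2, optimize=True)
    om += 0.5 * np.einsum("kacd,kicd->ia", w[o, v, v, v], t2, optimize=True)
    om -= 0.5 * np.einsum("klci,klca->ia", w[o, o, v, o], t2, optimize=True)
    return om


def ground_energy(dressed: DressedIntegrals, t2: np.ndarray) -> float:
    """E0 = <HF|Htilde + [Htilde, T2]|HF>."""
    o, v = dressed.o, dressed.v
    return dressed.scalar + 0.25 * float(
        np.einsum("ijab,ijab->", dressed.w_tilde[o, o, v, v], t2, optimize=True))


def eta_vector(dressed: DressedIntegrals, t2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """eta_nu = <HF|[Hbar, tau_nu]|HF> as (singles, doubles) tensors.

    For the T = T1 + T2 transform the commutator terminates: the singles
    part is the occupied-virtual block of the dressed Fock-like matrix and
    the doubles part is the bare dressed <ij||ab>~; T2 cannot contribute.
    """
    o, v = dressed.o, dressed.v
    eta1 = dressed.f_tilde[o, v].copy()
    eta2 = dressed.w_tilde[o, o, v, v].copy()
    return eta1, eta2


def mp2_correlation_energy(ints: SpinMOIntegrals) -> float:
    """Closed-form MP2 correlation energy from bare integrals."""
    dressed = dress_integrals(ints, np.zeros((ints.n_occ, ints.n_virt)))
    t2 = compute_t2(dressed)
    o, v = dressed.o, dressed.v
    return 0.25 * float(np.einsum("ijab,ijab->", dressed.w_tilde[o, o, v, v], t2))


@dataclass
class CC2GroundState:
    """Converged CC2 (or SCC2 ground-state part) amplitudes and energy."""

    t1: np.ndarray
    t2: np.ndarray
    energy: float
    eta: tuple[np.ndarray, np.ndarray]
    dressed: DressedIntegrals
    iterations: int
    residual_norm: float
    history: list = field(default_factory=list)


class DIIS:
    """Direct inversion in the iterative subspace for flat parameter vectors."""

    def __init__(self, size: int = 8, cond_max: float = 1e12):
        self.size = size
        self.cond_max = cond_max
        self.params: list[np.ndarray] = []
        self.errors: list[np.ndarray] = []

    def extrapolate(self, param: np.ndarray, error: np.ndarray) -> np.ndarray:
        self.params.append(param.copy())
        self.errors.append(error.copy())
        if len(self.params) > self.size:
            self.params.pop(0)
            self.errors.pop(0)
        m = len(self.params)
        if m < 2:
            return param
        b = np.empty((m + 1, m + 1))
        b[:m, :m] = np.array([[e1 @ e2 for e2 in self.errors] for e1 in self.errors])
        b[m, :], b[:, m] = -1.0, -1.0
        b[m, m] = 0.0
        if np.linalg.cond(b) > self.cond_max:
            # restart on ill-conditioning, keep the most recent pair
            self.params, self.errors = self.params[-1:], self.errors[-1:]
            return param
        rhs = np.zeros(m + 1)
        rhs[m] = -1.0
        coef = np.linalg.solve(b, rhs)[:m]
        return sum(c * p for c, p in zip(coef, self.params))


def solve_cc2_ground(ints: SpinMOIntegrals, *, threshold: float = 1e-8,
                     max_iter: int = 100, diis_size: int = 8,
                     t1_guess: np.ndarray | None = None,
                     mode: str = "folded") -> CC2GroundState:
    """Solve the CC2 amplitude equations.

    mode='folded' iterates only t1 with t2 recomputed in closed form each
    iteration; mode='simultaneous' quasi-Newton-updates (t1, t2) together.
    Both converge to the same fixed point.
    """
    no, nv = ints.n_occ, ints.n_virt
    eps = ints.eps
    d1 = eps[:no, None] - eps[None, no:]
    t1 = np.zeros((no, nv)) if t1_guess is None else t1_guess.copy()
    diis = DIIS(size=diis_size)
    history = []
    space = LabelSpace(no=no, nv=nv)

    if mode == "folded":
        t2 = None
        for it in range(1, max_iter + 1):
            dressed = dress_integrals(ints, t1)
            t2 = compute_t2(dressed)
            om1 = singles_residual(dressed, t2)
            resid = np.linalg.norm(space.t1_to_vec(om1))
            history.append(resid)
            if resid <= threshold:
                return CC2GroundState(
                    t1=t1, t2=t2, energy=ground_energy(dressed, t2),
                    eta=eta_vector(dressed, t2), dressed=dressed,
                    iterations=it, residual_norm=resid, history=history)
            t1 = diis.extrapolate((t1 + om1 / d1).ravel(), om1.ravel()).reshape(no, nv)
        raise CCConvergenceError(
            f"CC2 folded solver: no convergence in {max_iter} iterations "
            f"(last residual {history[-1]:.3e})", history)

    if mode != "simultaneous":
        raise ValueError(f"unknown mode {mode!r}")
    d2 = None
    t2 = np.zeros((no, no, nv, nv))
    for it in range(1, max_iter + 1):
        dressed = dress_integrals(ints, t1)
        if d2 is None:
            d2 = doubles_denominators(dressed)
        om1 = singles_residual(dressed, t2)
        om2 = doubles_residual(dressed, t2)
        resid = np.linalg.norm(np.concatenate(
            [space.t1_to_vec(om1), space.t2_to_vec(om2)]))
        history.append(resid)
        if resid <= threshold:
            return CC2GroundState(
                t1=t1, t2=t2, energy=ground_energy(dressed, t2),
                eta=eta_vector(dressed, t2), dressed=dressed,
                iterations=it, residual_norm=resid, history=history)
        new1 = t1 + om1 / d1
        new2 = t2 + om2 / d2
        packed = diis.extrapolate(np.concatenate([new1.ravel(), new2.ravel()]),
                                  np.concatenate([om1.ravel(), om2.ravel()]))
        t1 = packed[: no * nv].reshape(no, nv)
        t2 = packed[no * nv:].reshape(no, no, nv, nv)
    raise CCConvergenceError(
        f"CC2 simultaneous solver: no convergence in {max_iter} iterations "
        f"(last residual {history[-1]:.3e})", history)
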