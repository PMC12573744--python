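"""Restricted Hartree-Fock reference determinant.

Canonical closed-shell RHF with DIIS acceleration; the converged orbitals
define the Fock/fluctuation partition used by all correlated models here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .integrals import AOIntegralSet


class SCFConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last DIIS residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class ReferenceDeterminant:
    """Canonical RHF solution: MO coefficients, orbital energies, HF energy."""

    mo_coefficients: np.ndarray  # (n_ao, n_mo)
    orbital_energies: np.ndarray  # ascending, Hartree
    n_occ: int  # doubly occupied spatial orbitals
    hf_energy: float  # Hartree

    @property
    def n_mo(self) -> int:
        return self.mo_coefficients.shape[1]

    @property
    def n_virt(self) -> int:
        return self.n_mo - self.n_occ


def _fock_matrix(h: np.ndarray, g: np.ndarray, d: np.ndarray) -> np.ndarray:
    j = np.einsum("pqrs,rs->pq", g, d)
    k = np.einsum("prqs,rs->pq", g, d)
    return h + j - 0.5 * k


def solve_rhf(aoints: AOIntegralSet, n_electrons: int, *,
              threshold: float = 1e-10, max_iter: int = 200,
              diis_size: int = 8) -> ReferenceDeterminant:
    """Solve the closed-shell Roothaan equations with DIIS.

    The returned orbitals are canonical (the MO Fock matrix is diagonal) and
    sorted by ascending orbital energy.
    """
    if n_electrons % 2 != 0:
        raise ValueError("closed-shell RHF needs an even electron count")
    n_occ = n_electrons // 2
    if n_occ > aoints.n_ao:
        raise ValueError("more electron pairs than basis functions")

    s, h, g = aoints.overlap, aoints.core_hamiltonian, aoints.eri
    x = sla.fractional_matrix_power(s, -0.5).real

    def density(fock):
        _, c_prime = sla.eigh(x @ fock @ x)
        c = x @ c_prime
        c_occ = c[:, :n_occ]
        return 2.0 * c_occ @ c_occ.T, c

    d, _ = density(h)
    errors: list[np.ndarray] = []
    focks: list[np.ndarray] = []
    resid = np.inf
    energy = 0.0
    for _ in range(max_iter):
        f = _fock_matrix(h, g, d)
        energy = 0.5 * np.sum(d * (h + f)) + aoints.nuclear_repulsion
        err = x @ (f @ d @ s - s @ d @ f) @ x
        resid = np.abs(err).max()
        if resid < threshold:
            break
        errors.append(err.ravel())
        focks.append(f)
        if len(errors) > diis_size:
            errors.pop(0)
            focks.pop(0)
        if len(errors) > 1:
            m = len(errors)
            b = -np.ones((m + 1, m + 1))
            b[-1, -1] = 0.0
            b[:m, :m] = np.array([[e1 @ e2 for e2 in errors] for e1 in errors])
            rhs = np.zeros(m + 1)
            rhs[-1] = -1.0
            try:
                coef = np.linalg.solve(b, rhs)[:m]
                f = sum(c * fk for c, fk in zip(coef, focks))
            except np.linalg.LinAlgError:
                errors, focks = [], []
        d, _ = density(f)
    else:
        raise SCFConvergenceError(f"SCF did not converge in {max_iter} iterations", resid)

    f = _fock_matrix(h, g, d)
    eps, c_prime = sla.eigh(x @ f @ x)
    c = x @ c_prime
    # fix orbital phases deterministically: largest-|coefficient| entry positive
    for k in range(c.shape[1]):
        idx = np.argmax(np.abs(c[:, k]))
        if c[idx, k] < 0:
            c[:, k] = -c[:, k]
    energy = 0.5 * np.sum(d * (h + f)) + aoints.nuclear_repulsion
    return ReferenceDeterminant(
        mo_coefficients=c,
        orbital_energies=eps,
        n_occ=n_occ,
        hf_energy=float(energy),
    )
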