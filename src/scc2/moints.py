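"""MO-basis integrals: spatial transformation and the spin-orbital view.

The correlated modules work in an interleaved spin-orbital basis
(p = 2P + sigma), where the restricted reference occupies the first
2*n_occ spin orbitals and all two-electron quantities carry explicit
antisymmetry. At desk scale the full rank-4 MO tensor is kept in memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals import AOIntegralSet
from .scf import ReferenceDeterminant


@dataclass(frozen=True)
class MOIntegrals:
    """Spatial-orbital MO integrals with the Fock/fluctuation partition implied.

    fock_mo is diagonal for canonical orbitals; g_mo is in chemist's
    notation (PQ|RS) and inherits the 8-fold permutational symmetry.
    """

    fock_mo: np.ndarray
    h_mo: np.ndarray
    g_mo: np.ndarray
    orbital_energies: np.ndarray
    n_occ: int
    n_frozen: int
    hf_energy: float
    nuclear_repulsion: float
    frozen_core_energy: float = 0.0

    @property
    def n_mo(self) -> int:
        return self.fock_mo.shape[0]


def transform_mo_integrals(aoints: AOIntegralSet, ref: ReferenceDeterminant,
                           frozen_core: int = 0) -> MOIntegrals:
    """Quarter-transform the AO integrals into the canonical MO basis.

    ``frozen_core`` freezes that many lowest spatial orbitals: their mean
    field is folded into the one-electron operator and their energy into
    ``frozen_core_energy``. Default is all-electron.
    """
    c = ref.mo_coefficients
    h = c.T @ aoints.core_hamiltonian @ c
    g = np.einsum("pP,pqrs->Pqrs", c, aoints.eri, optimize=True)
    g = np.einsum("qQ,Pqrs->PQrs", c, g, optimize=True)
    g = np.einsum("rR,PQrs->PQRs", c, g, optimize=True)
    g = np.einsum("sS,PQRs->PQRS", c, g, optimize=True)
    fock = h + 2.0 * np.einsum("pqii->pq", g[:, :, :ref.n_occ, :ref.n_occ]) \
        - np.einsum("piiq->pq", g[:, :ref.n_occ, :ref.n_occ, :])

    e_fc = 0.0
    if frozen_core:
        if frozen_core >= ref.n_occ:
            raise ValueError("cannot freeze all occupied orbitals")
        fz = slice(0, frozen_core)
        e_fc = 2.0 * np.trace(h[fz, fz]) \
            + 2.0 * np.einsum("iijj->", g[fz, fz, fz, fz]) \
            - np.einsum("ijji->", g[fz, fz, fz, fz])
        h_eff = h + 2.0 * np.einsum("pqii->pq", g[:, :, fz, fz]) \
            - np.einsum("piiq->pq", g[:, fz, fz, :])
        act = slice(frozen_core, None)
        return MOIntegrals(
            fock_mo=fock[act, act], h_mo=h_eff[act, act], g_mo=g[act, act, act, act],
            orbital_energies=ref.orbital_energies[act],
            n_occ=ref.n_occ - frozen_core, n_frozen=frozen_core,
            hf_energy=ref.hf_energy, nuclear_repulsion=aoints.nuclear_repulsion,
            frozen_core_energy=float(e_fc),
        )
    return MOIntegrals(
        fock_mo=fock, h_mo=h, g_mo=g,
        orbital_energies=ref.orbital_energies,
        n_occ=ref.n_occ, n_frozen=0,
        hf_energy=ref.hf_energy, nuclear_repulsion=aoints.nuclear_repulsion,
    )


@dataclass(frozen=True)
class SpinMOIntegrals:
    """Interleaved spin-orbital integrals (p = 2P + sigma).

    h and g (chemist notation) are spin-blocked expansions of the spatial
    tensors; eps are the canonical orbital energies per spin orbital.
    """

    h: np.ndarray
    g: np.ndarray  # chemist (pq|rs)
    eps: np.ndarray
    n_occ: int  # occupied *spin* orbitals
    hf_energy: float
    scalar_shift: float  # nuclear repulsion + frozen-core energy

    @property
    def n_so(self) -> int:
        return self.h.shape[0]

    @property
    def n_virt(self) -> int:
        return self.n_so - self.n_occ

    def antisymmetrized(self) -> np.ndarray:
        """Physicist-notation <pq||rs> = (pr|qs) - (ps|qr)."""
        return (self.g.transpose(0, 2, 1, 3) - self.g.transpose(0, 2, 3, 1)).copy()


def to_spin_orbital(moints: MOIntegrals) -> SpinMOIntegrals:
    spin = np.eye(2)
    n = moints.n_mo
    h_so = np.einsum("PQ,pq->PpQq", moints.h_mo, spin).reshape(2 * n, 2 * n)
    g_so = np.einsum("PQRS,pq,rs->PpQqRrSs", moints.g_mo, spin, spin,
                     optimize=True).reshape(2 * n, 2 * n, 2 * n, 2 * n)
    return SpinMOIntegrals(
        h=h_so, g=g_so,
        eps=np.repeat(moints.orbital_energies, 2),
        n_occ=2 * moints.n_occ,
        hf_energy=moints.hf_energy,
        scalar_shift=moints.nuclear_repulsion + moints.frozen_core_energy,
    )
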