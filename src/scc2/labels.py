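"""Excitation-label bookkeeping shared by working equations and the oracle.

Spin orbitals are interleaved (p = 2P + sigma). Excitation labels are
restricted to Sz-conserving singles (i, a) and doubles (i < j, a < b with
matching total spin); amplitudes are nevertheless stored as full dense
tensors -- t1 of shape (no, nv), t2 antisymmetric of shape (no, no, nv, nv)
-- whose entries outside the allowed label set vanish identically for
spin-conserving operators.

The doubles label (i, j, a, b) refers to the configuration
tau_{ai} tau_{bj} |HF> with i < j and a < b, whose vector component equals
the tensor entry t2[i, j, a, b].
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np


def spin(index: int) -> int:
    return index % 2


@lru_cache(maxsize=64)
def singles_labels(no: int, nv: int) -> tuple[tuple[int, int], ...]:
    """Sz-conserving single excitations (i, a); a indexes virtuals from 0."""
    return tuple((i, a) for i in range(no) for a in range(nv)
                 if spin(i) == spin(no + a))


@lru_cache(maxsize=64)
def doubles_labels(no: int, nv: int) -> tuple[tuple[int, int, int, int], ...]:
    """Sz-conserving double excitations with i < j, a < b."""
    out = []
    for i in range(no):
        for j in range(i + 1, no):
            for a in range(nv):
                for b in range(a + 1, nv):
                    if spin(i) + spin(j) == spin(no + a) + spin(no + b):
                        out.append((i, j, a, b))
    return tuple(out)


@lru_cache(maxsize=64)
def _singles_arrays(no: int, nv: int):
    labs = singles_labels(no, nv)
    return tuple(np.array(x) for x in zip(*labs)) if labs else (np.array([], int),) * 2


@lru_cache(maxsize=64)
def _doubles_arrays(no: int, nv: int):
    labs = doubles_labels(no, nv)
    return tuple(np.array(x) for x in zip(*labs)) if labs else (np.array([], int),) * 4


@dataclass(frozen=True)
class LabelSpace:
    """Dimensions and vec/tensor converters for one (no, nv) problem.

    The converters use precomputed index arrays and accept leading batch
    axes, which keeps dense-matrix construction vectorized.
    """

    no: int
    nv: int

    @property
    def singles(self):
        return singles_labels(self.no, self.nv)

    @property
    def doubles(self):
        return doubles_labels(self.no, self.nv)

    @property
    def n_singles(self) -> int:
        return len(self.singles)

    @property
    def n_doubles(self) -> int:
        return len(self.doubles)

    @property
    def dim(self) -> int:
        return self.n_singles + self.n_doubles

    # --- converters (batch-aware on leading axes) ---------------------
    def t1_to_vec(self, t1: np.ndarray) -> np.ndarray:
        i, a = _singles_arrays(self.no, self.nv)
        return t1[..., i, a]

    def vec_to_t1(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v)
        i, a = _singles_arrays(self.no, self.nv)
        t1 = np.zeros(v.shape[:-1] + (self.no, self.nv), dtype=v.dtype)
        t1[..., i, a] = v
        return t1

    def t2_to_vec(self, t2: np.ndarray) -> np.ndarray:
        i, j, a, b = _doubles_arrays(self.no, self.nv)
        return t2[..., i, j, a, b]

    def vec_to_t2(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v)
        i, j, a, b = _doubles_arrays(self.no, self.nv)
        t2 = np.zeros(v.shape[:-1] + (self.no, self.no, self.nv, self.nv),
                      dtype=v.dtype)
        t2[..., i, j, a, b] = v
        t2[..., j, i, a, b] = -v
        t2[..., i, j, b, a] = -v
        t2[..., j, i, b, a] = v
        return t2

    def pack(self, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
        return np.concatenate([self.t1_to_vec(t1), self.t2_to_vec(t2)], axis=-1)

    def unpack(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (self.vec_to_t1(v[..., : self.n_singles]),
                self.vec_to_t2(v[..., self.n_singles:]))


def dot_singles(x1: np.ndarray, y1: np.ndarray) -> float:
    """Label-space inner product of two singles tensors."""
    return float(np.sum(x1 * y1))


def dot_doubles(x2: np.ndarray, y2: np.ndarray) -> float:
    """Label-space inner product of two antisymmetric doubles tensors.

    Each unordered label appears 4 times in the full tensor sum.
    """
    return 0.25 * float(np.sum(x2 * y2))


def dot_full(x: tuple[np.ndarray, np.ndarray], y: tuple[np.ndarray, np.ndarray]) -> float:
    return dot_singles(x[0], y[0]) + dot_doubles(x[1], y[1])
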