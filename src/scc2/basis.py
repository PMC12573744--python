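"""Bundled Gaussian basis sets.

Only the minimal STO-3G set is shipped (exponents and contraction
coefficients are the standard published values); anything else must be
supplied through a registered integral backend. This keeps the desk-scale
test systems (H2, H4, H2O, HOF) self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class BasisError(KeyError):
    """Unknown basis-set label or element/basis combination."""


@dataclass(frozen=True)
class Shell:
    """A contracted shell of Cartesian Gaussians on one atom.

    l: angular momentum (0 = s, 1 = p); exponents/coefficients are the
    primitive parameters, coefficients for *normalized* primitives.
    """

    l: int
    exponents: tuple[float, ...]
    coefficients: tuple[float, ...]
    center: np.ndarray  # Bohr


_S = (0.15432897, 0.53532814, 0.44463454)
_SP_S = (-0.09996723, 0.39951283, 0.70115470)
_SP_P = (0.15591627, 0.60768372, 0.39195739)

# element -> list of (l-codes, exponents, coefficients-per-l)
_STO3G = {
    "H": [(("s",), (3.42525091, 0.62391373, 0.16885540), (_S,))],
    "He": [(("s",), (6.36242139, 1.15892300, 0.31364979), (_S,))],
    "C": [
        (("s",), (71.6168370, 13.0450960, 3.5305122), (_S,)),
        (("s", "p"), (2.9412494, 0.6834831, 0.2222899), (_SP_S, _SP_P)),
    ],
    "N": [
        (("s",), (99.1061690, 18.0523120, 4.8856602), (_S,)),
        (("s", "p"), (3.7804559, 0.8784966, 0.2857144), (_SP_S, _SP_P)),
    ],
    "O": [
        (("s",), (130.7093200, 23.8088610, 6.4436083), (_S,)),
        (("s", "p"), (5.0331513, 1.1695961, 0.3803890), (_SP_S, _SP_P)),
    ],
    "F": [
        (("s",), (166.6791300, 30.3608120, 8.2168207), (_S,)),
        (("s", "p"), (6.4648032, 1.5022812, 0.4885885), (_SP_S, _SP_P)),
    ],
}

_LCODE = {"s": 0, "p": 1}

BUNDLED_BASIS_SETS = ("sto-3g",)


def shells_for_molecule(elements, centers_bohr, basis_name: str) -> list[Shell]:
    """Expand a molecule into a list of contracted shells.

    Raises BasisError for labels or elements outside the bundled tables.
    """
    name = basis_name.strip().lower()
    if name != "sto-3g":
        raise BasisError(
            f"basis {basis_name!r} is not bundled (available: {BUNDLED_BASIS_SETS}); "
            "register an integral backend that provides it")
    shells: list[Shell] = []
    for sym, center in zip(elements, centers_bohr):
        if sym not in _STO3G:
            raise BasisError(f"no sto-3g data bundled for element {sym!r}")
        for lcodes, exps, coefs in _STO3G[sym]:
            for lc, cs in zip(lcodes, coefs):
                shells.append(Shell(_LCODE[lc], tuple(exps), tuple(cs),
                                    np.asarray(center, dtype=float)))
    return shells


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian powers (lx, ly, lz) for angular momentum l, fixed order."""
    return [(lx, ly, l - lx - ly)
            for lx in range(l, -1, -1)
            for ly in range(l - lx, -1, -1)]
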