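"""Shared fixtures: small molecules, their integrals, and oracles.

Everything is generated at test time from geometry builders; session scope
keeps the integral evaluations (the slowest step) to one per system.
"""

from __future__ import annotations

import numpy as np
import pytest

from scc2 import (compute_ao_integrals, make_h2_geometry, make_h2o_geometry,
                  make_h4_geometry, make_hof_geometry, solve_rhf,
                  to_spin_orbital, transform_mo_integrals)
from scc2.detspace import DetSpaceOracle

# geometry of the same-symmetry near-degeneracy located for HOF/STO-3G:
# the CC2 Jacobian has a complex eigenvalue pair here (the defect tube)
HOF_SEAM = dict(r_oh=1.106738, r_of=1.306488, theta=97.1378)


def _spin_ints(geometry):
    ao = compute_ao_integrals(geometry, "sto-3g")
    ref = solve_rhf(ao, geometry.n_electrons)
    return ao, ref, to_spin_orbital(transform_mo_integrals(ao, ref))


@pytest.fixture(scope="session")
def h2_system():
    geo = make_h2_geometry(0.74)
    ao, ref, ints = _spin_ints(geo)
    return dict(geometry=geo, ao=ao, ref=ref, ints=ints)


@pytest.fixture(scope="session")
def h4_system():
    # bent ring, away from the square degeneracy: well-behaved reference
    geo = make_h4_geometry(1.0, 80.0)
    ao, ref, ints = _spin_ints(geo)
    return dict(geometry=geo, ao=ao, ref=ref, ints=ints)


@pytest.fixture(scope="session")
def h2o_system():
    geo = make_h2o_geometry()
    ao, ref, ints = _spin_ints(geo)
    return dict(geometry=geo, ao=ao, ref=ref, ints=ints)


@pytest.fixture(scope="session")
def hof_seam_system():
    geo = make_hof_geometry(HOF_SEAM["r_oh"], HOF_SEAM["r_of"], HOF_SEAM["theta"])
    ao, ref, ints = _spin_ints(geo)
    return dict(geometry=geo, ao=ao, ref=ref, ints=ints)


@pytest.fixture(scope="session")
def h2_oracle(h2_system):
    return DetSpaceOracle(h2_system["ints"])


@pytest.fixture(scope="session")
def h4_oracle(h4_system):
    return DetSpaceOracle(h4_system["ints"])


@pytest.fixture(scope="session")
def h2o_oracle(h2o_system):
    return DetSpaceOracle(h2o_system["ints"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


def random_amplitudes(space, rng, scale=0.05):
    t1 = space.vec_to_t1(rng.normal(scale=scale, size=space.n_singles))
    t2 = space.vec_to_t2(rng.normal(scale=scale, size=space.n_doubles))
    return t1, t2
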