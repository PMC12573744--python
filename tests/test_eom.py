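"""EOM-CC2 excited states: Jacobian actions, folding, eigensolvers."""

import numpy as np
import pytest

from scc2.cc2 import dress_integrals, compute_t2, solve_cc2_ground
from scc2.eom import (ExcitedStateVector, FoldSingularityError, JacobianModel,
                      ground_contribution, solve_left_states,
                      solve_right_states, solve_right_states_davidson,
                      spin_signature)
from scc2.labels import dot_full
from scc2.moints import SpinMOIntegrals
from tests.conftest import random_amplitudes


@pytest.fixture(scope="module")
def h4_model(h4_system):
    gs = solve_cc2_ground(h4_system["ints"], threshold=1e-11)
    return JacobianModel(gs.dressed, gs.t2), gs


@pytest.fixture(scope="module")
def h2o_model(h2o_system):
    gs = solve_cc2_ground(h2o_system["ints"], threshold=1e-11)
    return JacobianModel(gs.dressed, gs.t2), gs


def _fock_only_ints(eps_occ, eps_virt):
    eps = np.concatenate([np.repeat(eps_occ, 2), np.repeat(eps_virt, 2)])
    n = eps.size
    return SpinMOIntegrals(h=np.diag(eps), g=np.zeros((n,) * 4), eps=eps,
                           n_occ=2 * len(eps_occ), hf_energy=2 * sum(eps_occ),
                           scalar_shift=0.0)


# --- Jacobian action ----------------------------------------------------

def test_dense_jacobian_matches_oracle_blocks(h4_oracle, h4_system, rng):
    """All four blocks of the block-truncated Jacobian against explicit
    determinant-space commutators, at non-stationary amplitudes."""
    ints = h4_system["ints"]
    sp = h4_oracle.space
    t1, _ = random_amplitudes(sp, rng)
    d = dress_integrals(ints, t1)
    model = JacobianModel(d, compute_t2(d))
    a = model.dense()
    a_oracle = h4_oracle.cc2_jacobian(t1, model.t2)
    assert np.abs(a - a_oracle).max() < 1e-10


def test_dense_columns_equal_apply_on_unit_vectors(h4_model, rng):
    model, _ = h4_model
    sp = model.space
    a = model.dense()
    for k in rng.integers(0, sp.dim, size=6):
        e = np.zeros(sp.dim)
        e[k] = 1.0
        rho1, rho2 = model.apply(*sp.unpack(e))
        assert np.allclose(np.concatenate([sp.t1_to_vec(rho1), sp.t2_to_vec(rho2)]),
                           a[:, k], atol=1e-12)


def test_doubles_doubles_block_is_diagonal_orbital_gaps(h4_model):
    model, _ = h4_model
    sp = model.space
    a = model.dense()
    ns = sp.n_singles
    block = a[ns:, ns:]
    off = block - np.diag(np.diag(block))
    assert np.abs(off).max() < 1e-12
    eps = model.dressed.eps
    no = sp.no
    for k, (i, j, ai, bi) in enumerate(sp.doubles):
        expected = eps[no + ai] + eps[no + bi] - eps[i] - eps[j]
        assert block[k, k] == pytest.approx(expected, abs=1e-12)


def test_transpose_action_adjoint_identity(h4_model, rng):
    model, _ = h4_model
    sp = model.space
    worst = 0.0
    for _ in range(20):
        r = sp.unpack(rng.normal(size=sp.dim))
        l = sp.unpack(rng.normal(size=sp.dim))
        ar = model.apply(*r)
        atl = model.apply_transpose(*l)
        worst = max(worst, abs(dot_full(l, ar) - dot_full(atl, r)))
    assert worst < 1e-10


def test_transpose_action_matches_dense_transpose(h2_system):
    gs = solve_cc2_ground(h2_system["ints"], threshold=1e-11)
    model = JacobianModel(gs.dressed, gs.t2)
    sp = model.space
    a = model.dense()
    at = np.empty_like(a)
    for k in range(sp.dim):
        e = np.zeros(sp.dim)
        e[k] = 1.0
        s1, s2 = model.apply_transpose(*sp.unpack(e))
        at[:, k] = np.concatenate([sp.t1_to_vec(s1), sp.t2_to_vec(s2)])
    assert np.abs(at - a.T).max() < 1e-12


def test_fock_only_limit_is_diagonal_with_orbital_differences():
    ints = _fock_only_ints([-1.0, -0.6], [0.4, 0.9])
    d = dress_integrals(ints, np.zeros((4, 4)))
    model = JacobianModel(d, compute_t2(d))
    a = model.dense()
    off = a - np.diag(np.diag(a))
    assert np.abs(off).max() < 1e-14
    # transpose equals forward in this symmetric limit
    sp = model.space
    r = sp.unpack(np.arange(1.0, sp.dim + 1.0))
    fwd = model.apply(*r)
    bwd = model.apply_transpose(*r)
    assert np.allclose(fwd[0], bwd[0]) and np.allclose(fwd[1], bwd[1])
    # eigenvalues are orbital-energy differences (Koopmans-like)
    eps = ints.eps
    diag_singles = sorted(eps[4 + a_] - eps[i] for (i, a_) in sp.singles)
    assert np.allclose(sorted(np.diag(a)[:sp.n_singles]), diag_singles)


# --- folding ------------------------------------------------------------

def test_folded_eigenpair_unfolds_to_full_eigenvector(h4_model):
    model, _ = h4_model
    sp = model.space
    states = solve_right_states_davidson(model, 2, threshold=1e-11)
    for st in states:
        vec = np.concatenate([sp.t1_to_vec(st.r1), sp.t2_to_vec(st.r2)])
        a = model.dense()
        resid = a @ vec - np.real(st.omega) * vec
        assert np.abs(resid).max() < 1e-8


def test_folded_dense_at_selfconsistent_omega_matches_full(h4_model):
    model, _ = h4_model
    states = solve_right_states(model, 3, method="dense")
    omega = float(np.real(states[0].omega))
    folded = model.folded_dense(omega)
    evals = np.linalg.eigvals(folded)
    assert np.abs(evals - omega).min() < 1e-8


def test_folded_apply_reduces_to_a11_without_coupling():
    ints = _fock_only_ints([-1.0, -0.7], [0.3, 0.8])
    d = dress_integrals(ints, np.zeros((4, 4)))
    model = JacobianModel(d, compute_t2(d))
    r1 = np.arange(16.0).reshape(4, 4)
    rho_folded = model.folded_apply(0.123, r1)
    rho_a11, _ = model.apply(r1, np.zeros((4, 4, 4, 4)))
    assert np.allclose(rho_folded, rho_a11, atol=1e-14)


def test_fold_singularity_guard(h4_model):
    model, _ = h4_model
    sp = model.space
    omega = float(model.eps_doubles[tuple(np.argwhere(
        np.isfinite(model.eps_doubles))[0])])
    with pytest.raises(FoldSingularityError):
        model.unfold_r2(np.ones((sp.no, sp.nv)), omega)


# --- eigensolvers -------------------------------------------------------

def test_davidson_agrees_with_dense(h2o_model):
    model, _ = h2o_model
    dense = solve_right_states(model, 10, method="dense")
    dav = solve_right_states_davidson(model, 3, threshold=1e-10)
    dense_vals = np.array([np.real(s.omega) for s in dense])
    for st in dav:
        assert np.abs(dense_vals - np.real(st.omega)).min() < 1e-8


def test_spectrum_closed_under_conjugation(hof_seam_system):
    """Inside the defect region the dense path returns a genuine
    complex-conjugate pair of excitation energies."""
    gs = solve_cc2_ground(hof_seam_system["ints"], threshold=1e-9)
    model = JacobianModel(gs.dressed, gs.t2)
    import scipy.linalg as sla
    vals = sla.eig(model.dense(), right=False)
    cplx = vals[np.abs(vals.imag) > 1e-8]
    assert cplx.size >= 2
    for w in cplx:
        assert np.abs(cplx - np.conj(w)).min() < 1e-9


def test_left_right_biorthonormality(h2o_model):
    model, _ = h2o_model
    rights = solve_right_states(model, 4, method="dense")
    lefts = solve_left_states(model, rights)
    m = np.array([[dot_full((l.r1, l.r2), (r.r1, r.r2)) for r in rights]
                  for l in lefts])
    assert np.abs(m - np.eye(4)).max() < 1e-8
    assert all(l.r0 == 0.0 for l in lefts)


def test_eigenvalues_invariant_under_normalization(h4_model):
    model, _ = h4_model
    sp = model.space
    st = solve_right_states(model, 1, method="dense")[0]
    # rescale the eigenvector; the Rayleigh quotient is unchanged
    vec = np.concatenate([sp.t1_to_vec(st.r1), sp.t2_to_vec(st.r2)]) * 7.3
    a = model.dense()
    rq = (vec @ a @ vec) / (vec @ vec)
    assert rq == pytest.approx(np.real(st.omega), abs=1e-9)


def test_spin_signature_classifies_singlets_and_triplets(h4_model):
    model, _ = h4_model
    states = solve_right_states(model, 8, method="dense", singlet_only=False)
    sigs = [spin_signature(np.real(s.r1), np.real(s.r2)) for s in states]
    assert any(s > 0.9 for s in sigs)
    assert any(s < -0.9 for s in sigs)


# --- ground-state contribution r0 ---------------------------------------

def test_r0_assembles_full_hbar_eigenvector(h2_system, h2_oracle):
    gs = solve_cc2_ground(h2_system["ints"], threshold=1e-11)
    model = JacobianModel(gs.dressed, gs.t2)
    sp = model.space
    st = solve_right_states(model, 1, method="dense")[0]
    r0 = ground_contribution(gs.eta, st.r1, st.r2, st.omega)
    a_or = h2_oracle.cc2_jacobian(gs.t1, gs.t2)
    eta_or = h2_oracle.eta(h2_oracle.hbar(t1=gs.t1, t2=gs.t2))
    dim = sp.dim
    hbar_matrix = np.zeros((dim + 1, dim + 1))
    hbar_matrix[0, 0] = gs.energy
    hbar_matrix[0, 1:] = eta_or
    hbar_matrix[1:, 1:] = a_or + gs.energy * np.eye(dim)
    vec = np.concatenate([[r0], sp.t1_to_vec(st.r1), sp.t2_to_vec(st.r2)])
    resid = hbar_matrix @ vec - (gs.energy + np.real(st.omega)) * vec
    assert np.abs(resid).max() < 1e-9


def test_r0_linearity_and_orthogonal_eta(h4_model, rng):
    model, gs = h4_model
    sp = model.space
    st = solve_right_states(model, 1, method="dense")[0]
    r0 = ground_contribution(gs.eta, st.r1, st.r2, st.omega)
    r0_scaled = ground_contribution(gs.eta, 3.0 * st.r1, 3.0 * st.r2, st.omega)
    assert r0_scaled == pytest.approx(3.0 * np.real(r0), abs=1e-12)
    # a vector orthogonal to eta has r0 = 0
    ev = np.concatenate([sp.t1_to_vec(gs.eta[0]), sp.t2_to_vec(gs.eta[1])])
    v = rng.normal(size=sp.dim)
    v -= ev * (ev @ v) / (ev @ ev)
    r1o, r2o = sp.unpack(v)
    assert abs(ground_contribution(gs.eta, r1o, r2o, 0.5)) < 1e-10
    with pytest.raises(ZeroDivisionError):
        ground_contribution(gs.eta, st.r1, st.r2, 0.0)
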