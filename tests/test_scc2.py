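"""The similarity-constrained layer: X3, the zeta correction, the
natural-projection overlap, and the coupled solver."""

import numpy as np
import pytest

from scc2.cc2 import dress_integrals, solve_cc2_ground
from scc2.eom import ExcitedStateVector, JacobianModel, ground_contribution
from scc2.labels import LabelSpace
from scc2.scc2 import (SCC2Solution, build_x3, configuration_overlap_matrix,
                       load_solution, orthogonality_value, overlap_q,
                       overlap_q_apply, save_solution, scc_singles_correction,
                       solve_scc2, spin_adapted_doubles_gram)
from tests.conftest import random_amplitudes


def _random_states(sp, rng):
    r1a = sp.vec_to_t1(rng.normal(size=sp.n_singles))
    r2a = sp.vec_to_t2(rng.normal(size=sp.n_doubles))
    r1b = sp.vec_to_t1(rng.normal(size=sp.n_singles))
    r2b = sp.vec_to_t2(rng.normal(size=sp.n_doubles))
    sa = ExcitedStateVector("right", r1a, r2a, 0.5)
    sb = ExcitedStateVector("right", r1b, r2b, 0.7)
    return sa, sb


# --- X3 -----------------------------------------------------------------

def test_x3_antisymmetry_and_null_for_parallel_states(h4_oracle, rng):
    sp = h4_oracle.space
    sa, sb = _random_states(sp, rng)
    x3 = build_x3(sa, sb)
    x_mat = x3.explicit_amplitudes(sp)
    x_swap = x3.swapped().explicit_amplitudes(sp)
    assert np.allclose(x_mat, -x_swap, atol=1e-14)
    # parallel states annihilate the constraint operator
    sc = ExcitedStateVector("right", 2.0 * sa.r1, 2.0 * sa.r2, 0.9)
    assert np.abs(build_x3(sa, sc).explicit_amplitudes(sp)).max() < 1e-14


def test_x3_explicit_amplitudes_match_bilinear_formula(h4_oracle, rng):
    sp = h4_oracle.space
    sa, sb = _random_states(sp, rng)
    x_mat = build_x3(sa, sb).explicit_amplitudes(sp)
    va, wa = sp.t1_to_vec(sa.r1), sp.t2_to_vec(sa.r2)
    vb, wb = sp.t1_to_vec(sb.r1), sp.t2_to_vec(sb.r2)
    for _ in range(20):
        m1 = rng.integers(sp.n_singles)
        m2 = rng.integers(sp.n_doubles)
        expected = va[m1] * wb[m2] - vb[m1] * wa[m2]
        assert x_mat[m1, m2] == pytest.approx(expected, abs=1e-13)


# --- the singles correction --------------------------------------------

def test_correction_vanishes_for_zero_zeta_and_parallel_states(h4_system, h4_oracle, rng):
    ints = h4_system["ints"]
    sp = h4_oracle.space
    t1, _ = random_amplitudes(sp, rng)
    d = dress_integrals(ints, t1)
    sa, sb = _random_states(sp, rng)
    assert np.abs(scc_singles_correction(d, build_x3(sa, sa), 0.3)).max() < 1e-14
    assert np.abs(scc_singles_correction(d, build_x3(sa, sb), 0.0)).max() == 0.0


def test_correction_matches_determinant_space(h4_system, h4_oracle, rng):
    """zeta <mu1|[Htilde, X3]|HF> equals the difference of similarity
    transforms with S = T + zeta X3 versus T, projected on singles."""
    ints = h4_system["ints"]
    sp = h4_oracle.space
    t1, t2 = random_amplitudes(sp, rng)
    sa, sb = _random_states(sp, rng)
    zeta = 0.1
    x3 = build_x3(sa, sb)
    d = dress_integrals(ints, t1)
    mine = scc_singles_correction(d, x3, zeta)
    x3spec = ((sa.r1, sa.r2), (sb.r1, sb.r2))
    hb_s = h4_oracle.hbar(t1=t1, t2=t2, zeta=zeta, x3=x3spec)
    hb_t = h4_oracle.hbar(t1=t1, t2=t2)
    delta = (h4_oracle.residual(hb_s) - h4_oracle.residual(hb_t))[:sp.n_singles]
    assert np.allclose(sp.t1_to_vec(mine), delta, atol=1e-10)


def test_correction_antisymmetric_under_state_swap(h4_system, h4_oracle, rng):
    ints = h4_system["ints"]
    sp = h4_oracle.space
    t1, _ = random_amplitudes(sp, rng)
    d = dress_integrals(ints, t1)
    sa, sb = _random_states(sp, rng)
    fwd = scc_singles_correction(d, build_x3(sa, sb), 0.2)
    bwd = scc_singles_correction(d, build_x3(sb, sa), 0.2)
    assert np.allclose(fwd, -bwd, atol=1e-13)


# --- overlap machinery --------------------------------------------------

def test_q_vector_structure_and_oracle(h4_system, h4_oracle, rng):
    sp = h4_oracle.space
    t1, t2 = random_amplitudes(sp, rng)
    q1, q2 = overlap_q(t1, t2)
    assert np.allclose(q1, t1)
    # zero amplitudes -> q = 0
    z1, z2 = overlap_q(np.zeros_like(t1), np.zeros_like(t2))
    assert np.abs(z1).max() == 0.0 and np.abs(z2).max() == 0.0
    # t2 = 0: doubles part is the pure T1^2/2 disconnected product
    q1b, q2b = overlap_q(t1, np.zeros_like(t2))
    expected = np.einsum("ia,jb->ijab", t1, t1)
    expected = expected - expected.transpose(1, 0, 2, 3)
    assert np.allclose(q2b, expected, atol=1e-13)
    # full determinant-space check
    from scc2.detspace import project_on_labels
    es = h4_oracle.exp_s_matrix(t1=t1, t2=t2)
    q_or = project_on_labels(es[:, 0], h4_oracle.basis, sp)
    assert np.allclose(np.concatenate([sp.t1_to_vec(q1), sp.t2_to_vec(q2)]),
                       q_or, atol=1e-10)


def test_q_apply_linearity_and_oracle(h4_oracle, rng):
    sp = h4_oracle.space
    t1, t2 = random_amplitudes(sp, rng)
    v1 = sp.vec_to_t1(rng.normal(size=sp.n_singles))
    v2 = sp.vec_to_t2(rng.normal(size=sp.n_doubles))
    u1 = sp.vec_to_t1(rng.normal(size=sp.n_singles))
    u2 = sp.vec_to_t2(rng.normal(size=sp.n_doubles))
    a1, a2 = overlap_q_apply(t1, t2, 0.0, None, v1, v2)
    b1, b2 = overlap_q_apply(t1, t2, 0.0, None, u1, u2)
    c1, c2 = overlap_q_apply(t1, t2, 0.0, None, 2 * v1 + u1, 2 * v2 + u2)
    assert np.allclose(c1, 2 * a1 + b1, atol=1e-12)
    assert np.allclose(c2, 2 * a2 + b2, atol=1e-12)
    # S_cluster = 0 reduces Q to the identity
    i1, i2 = overlap_q_apply(np.zeros_like(t1), np.zeros_like(t2), 0.0, None, v1, v2)
    assert np.allclose(i1, v1) and np.allclose(i2, v2)
    # determinant-space column check
    from scc2.detspace import label_projections, project_on_labels
    es = h4_oracle.exp_s_matrix(t1=t1, t2=t2)
    sl, dl = label_projections(h4_oracle.basis, sp)
    vec = np.zeros(h4_oracle.basis.n_det)
    for (k, ph), (i, a) in zip(sl, sp.singles):
        vec[k] += ph * v1[i, a]
    for (k, ph), (i, j, a, b) in zip(dl, sp.doubles):
        vec[k] += ph * v2[i, j, a, b]
    qv_or = project_on_labels(es @ vec, h4_oracle.basis, sp)
    mine = np.concatenate([sp.t1_to_vec(a1), sp.t2_to_vec(a2)])
    assert np.allclose(mine, qv_or, atol=1e-10)


def test_configuration_overlap_identity_in_determinant_basis(h4_oracle):
    s = configuration_overlap_matrix(h4_oracle.space)
    assert np.array_equal(s, np.eye(h4_oracle.space.dim))


def test_spin_adapted_gram_matches_determinant_expansion():
    """Spin-summed doubles configurations are not orthonormal; their Gram
    matrix must match the brute-force determinant inner products, including
    the exchange-paired block (aibj)/(biaj)."""
    pairs = [(0, 1, 0, 1), (0, 1, 1, 0), (0, 0, 0, 0), (0, 0, 1, 1)]
    gram = spin_adapted_doubles_gram(2, 2, pairs)
    assert np.allclose(gram, gram.T, atol=1e-12)
    assert np.linalg.eigvalsh(gram).min() > -1e-12
    # independent check by hand-expandable counting: E_AI E_BJ |HF> with all
    # labels distinct expands into 4 orthonormal determinants of unit
    # weight -> norm^2 = 4; the exchange-paired configuration shares two of
    # them (sign set by fermionic reordering) -> |off-diagonal| = 2
    assert gram[0, 0] == pytest.approx(4.0, abs=1e-12)
    assert abs(gram[0, 1]) == pytest.approx(2.0, abs=1e-12)
    # same-orbital double (I=J, A=B): one determinant of weight 2
    assert gram[2, 2] == pytest.approx(4.0, abs=1e-12)
    # configurations with disjoint determinant support are orthogonal
    assert gram[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_orthogonality_value_collapses_without_cluster(h4_oracle, rng):
    sp = h4_oracle.space
    sa, sb = _random_states(sp, rng)
    sa.r0, sb.r0 = 0.2, -0.4
    z1 = np.zeros((sp.no, sp.nv))
    z2 = np.zeros((sp.no, sp.no, sp.nv, sp.nv))
    o = orthogonality_value(z1, z2, 0.0, None, sa, sb)
    from scc2.labels import dot_full
    plain = sa.r0 * sb.r0 + dot_full((sa.r1, sa.r2), (sb.r1, sb.r2))
    assert o == pytest.approx(plain, abs=1e-12)


def test_orthogonality_self_overlap_nonnegative(h4_oracle, rng):
    sp = h4_oracle.space
    t1, t2 = random_amplitudes(sp, rng)
    sa, _ = _random_states(sp, rng)
    sa.r0 = 0.3
    o = orthogonality_value(t1, t2, 0.0, None, sa, sa)
    assert o >= 0.0


def test_orthogonality_matches_projected_inner_product(h4_system, h4_oracle, rng):
    sp = h4_oracle.space
    t1, t2 = random_amplitudes(sp, rng)
    sa, sb = _random_states(sp, rng)
    sa.r0, sb.r0 = 0.3, -0.2
    zeta = 0.15
    x3 = build_x3(sa, sb)
    mine = orthogonality_value(t1, t2, zeta, x3, sa, sb)
    es = h4_oracle.exp_s_matrix(t1=t1, t2=t2, zeta=zeta,
                                x3=((sa.r1, sa.r2), (sb.r1, sb.r2)))
    oracle = h4_oracle.natural_projection_overlap(
        es, (sa.r0, sa.r1, sa.r2), (sb.r0, sb.r1, sb.r2))
    assert mine == pytest.approx(oracle, abs=1e-10)


# --- the coupled solver -------------------------------------------------

def test_solver_without_constraint_reproduces_cc2(h4_system):
    ints = h4_system["ints"]
    gs = solve_cc2_ground(ints, threshold=1e-10)
    sol = solve_scc2(ints, select=(0, 1), threshold=1e-10,
                     enforce_orthogonality=False)
    assert sol.zeta == 0.0
    assert sol.energy == pytest.approx(gs.energy, abs=1e-10)
    assert np.abs(sol.t1 - gs.t1).max() < 1e-10
    assert np.abs(sol.t2 - gs.t2).max() < 1e-10


def test_solver_converges_on_separated_states(h4_system):
    """Away from any degeneracy the constraint is a regular root-find in
    zeta; all residual classes must be at threshold and both energies real."""
    ints = h4_system["ints"]
    sol = solve_scc2(ints, select=(0, 1), threshold=1e-8)
    assert sol.converged
    assert sol.orthogonality_residual <= 1e-8
    assert sol.singles_residual_norm <= 1e-8
    assert np.imag(sol.omega_a) == 0.0 and np.imag(sol.omega_b) == 0.0
    # the constrained states are P-orthogonal at the solution
    x3 = build_x3(sol.state_a, sol.state_b)
    o = orthogonality_value(sol.t1, sol.t2, sol.zeta, x3,
                            sol.state_a, sol.state_b)
    assert abs(o) < 1e-6  # normalized states: residual scales with norms


def test_solution_roundtrip_through_npz(tmp_path, h4_system):
    ints = h4_system["ints"]
    sol = solve_scc2(ints, select=(0, 1), threshold=1e-8)
    path = tmp_path / "sol.npz"
    save_solution(path, sol)
    back = load_solution(path)
    assert back.zeta == pytest.approx(sol.zeta, abs=1e-12)
    assert back.energy == pytest.approx(sol.energy, abs=1e-12)
    assert np.allclose(back.t1, sol.t1)
    # a warm restart from the stored solution converges immediately
    again = solve_scc2(ints, threshold=1e-8, init=back)
    assert again.iterations <= 3
    assert again.energy == pytest.approx(sol.energy, abs=1e-9)
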