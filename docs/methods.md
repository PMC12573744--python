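# Methods

## The model

The package implements the second-order approximate coupled cluster
singles-and-doubles model (CC2), its equation-of-motion (EOM) excited
states, and the similarity-constrained extension (SCC2) that repairs the
description of conical intersections between excited states of the same
symmetry.

Starting from a restricted closed-shell Hartree–Fock reference |HF⟩, the
cluster operator T = T1 + T2 defines |CC⟩ = e^T |HF⟩. All one- and
two-electron integrals are dressed by the T1 similarity transformation,
H̃ = e^(−T1) H e^(T1), realized exactly as a pair of modified one-index
transformations of the MO integrals. The CC2 amplitude equations read

    Ω_μ1 = ⟨μ1| H̃ + [H̃, T2] |HF⟩ = 0
    Ω_μ2 = ⟨μ2| H̃ + [F̃, T2] |HF⟩ = 0

with F̃ the T1-transformed Fock operator. For canonical orbitals F̃ has
diagonal occupied–occupied and virtual–virtual blocks, and its
virtual–occupied block commutes with T2; the doubles equations therefore
have the exact closed-form solution

    t_{ij}^{ab} = ⟨ab||ij⟩̃ / (ε_i + ε_j − ε_a − ε_b),

which is "folded" into the singles equations: only t1 is iterated (DIIS
over quasi-Newton steps with orbital-energy denominators), and t2 is
recomputed from the dressed integrals each iteration. A simultaneous
(t1, t2) solver is provided as a cross-check; both converge to the same
fixed point. The ground-state energy uses the CCSD energy expression with
dressed integrals, which terminates exactly at terms linear in T2.

Excited states are right eigenvectors of the non-symmetric CC2 Jacobian

    A = [[A11, A12], [A21, ε δ]],

whose doubles–doubles block is exactly diagonal in the orbital-energy
differences. The folded non-linear eigenproblem
[A11 + A12 (ω − ε)^(−1) A21] r1 = ω r1 is solved by a Davidson-type
subspace iteration with a self-consistent ω fixed point (relaxation 0.5),
or the full matrix is diagonalized densely — the route that exposes the
complex-conjugate eigenvalue pairs characteristic of CC2 defect regions.
Left states are biorthonormalized against right states; the reference
weight of a right state is r0 = η·r/ω with η_ν = ⟨HF|[H̄, τ_ν]|HF⟩.

### The similarity constraint

At a near-degeneracy of two same-symmetry excited states the non-Hermitian
Jacobian becomes defective: the two eigenvectors coalesce, the intersection
seam inflates to an (M−1)-dimensional "tube" in the M internal degrees of
freedom, and complex eigenvalue pairs appear inside it. SCC2 augments the
cluster operator,

    S = T1 + T2 + ζ X3,
    X3 = Σ (r^A_μ1 r^B_μ2 − r^B_μ1 r^A_μ2) τ_μ1 τ_μ2,

and fixes ζ by demanding orthogonality of the two constrained states under
the natural projection P onto the reference+singles+doubles space,
O(A,B) = ⟨R^A|P|R^B⟩ = 0. The only change to the CC2 equations is the term
ζ⟨μ1|[H̃, X3]|HF⟩ in the singles residual; the doubles equations and the
Jacobian keep their CC2 form, evaluated at the SCC2 amplitudes. X3 is
never materialized: the singles correction is evaluated through four Wick
contraction topologies of the double-de-excitation integrals against the
factorized (r1, r2) amplitudes of the two states, at O(N^5) cost. The
overlap O(A,B) is evaluated through the q = ⟨μ|e^S|HF⟩ vector and the
Q = ⟨μ|e^S|ν⟩ action, both of which terminate after the T1-quadratic terms
inside the projection space; ζX3 is triples-rank and cannot re-enter it.

### Representation

Working equations are spin-orbital (interleaved, p = 2P + σ) with
antisymmetrized integrals. The excitation-label space is restricted to
Sz-conserving singles and doubles; with orthonormal determinants the
configuration-overlap matrix S_μν of the general orthogonality formula is
the identity. The spin-adapted (non-orthonormal) Gram machinery is
implemented and tested separately. Singlet states are identified by a
spin-flip signature of the eigenvectors; state selection defaults to
singlet roots, matching the spin-adapted theory the model targets.

## The coupled SCC2 solver

The ground singles, the two constrained states and ζ are brought to joint
self-consistency by a nested iteration rather than one concatenated DIIS:

* an inner relaxation converges t1 by DIIS at fixed ζ, alternating cheap
  quasi-Newton sweeps (X3 frozen) with re-diagonalization of the Jacobian
  and overlap-based re-tracking of the constrained pair. The inner
  threshold sits three orders below the outer one because O(A,B) is
  amplified relative to the t1 residual by roughly the inverse angle
  between the two nearly parallel states;
* the outer iteration updates the single scalar ζ, with three regimes:
  1. while the tracked pair is a complex-conjugate pair (inside a CC2
     defect region), a continuation drives Im(ω)² to zero through a
     finite-difference tangent with monotone backtracking — the overlap is
     flat there and carries no usable gradient. The real representatives
     of the pair are the orthonormalized real/imaginary parts, smoothed
     across iterations by a Procrustes rotation;
  2. for a separated real pair, a guarded secant iteration on O(A,B) with
     sign-change bracketing and bisection fallback;
  3. when the solve starts directly on a nearly defective real pair
     (|r^A·r^B| > 0.5) whose overlap does not respond to ζ, or when the
     overlap residual stalls on such a pair, the scalar residual switches
     to the *defect* itself: the pair basis is rotated inside its invariant
     subspace to diagonalize the 2×2 P-metric Gram (making O vanish by
     construction), and ζ drives the symmetrized off-diagonal of the
     projected Jacobian in that basis to zero — i.e. makes the
     P-orthogonal basis an eigenbasis. At an exact conical point the two
     formulations coincide.

Individual eigenvectors of a nearly defective matrix are ill-conditioned,
but their two-dimensional invariant subspace is not: the tracked pair is
always refined by two shift-inverted subspace iterations before use.

The orientation of the pair fixes the sign convention of ζ (the reported ζ
is convention-dependent; energies are not), and the two orientations can
have different convergence basins: a failed solve is retried once with
state B mirrored. Warm restarts from a neighboring geometry reuse
(t1, ζ, states); scans fall back to a cold start when a warm restart lands
in the wrong basin. Consistent with the published experience with
similarity-constrained solvers, isolated cold-start failures away from the
seam remain possible (one such HOF geometry is recorded in the test
fixtures' neighborhood); scans record such points as unconverged rather
than aborting.

## Integrals and reference

AO integrals are computed by a bundled McMurchie–Davidson engine (Hermite
Gaussians, Boys function via the regularized incomplete gamma function)
for s/p shells with tabulated STO-3G parameters (H, He, C, N, O, F);
`compute_ao_integrals` is a registry so an external backend can supply
other basis sets. The RHF solver uses DIIS with a core-Hamiltonian guess;
canonical MO integrals are produced by a quarter transformation. The
engine reproduces standard literature minimal-basis SCF energies (water
−74.9631, hydrogen fluoride −98.5707 Hartree) and its tensors satisfy the
exact permutational symmetries to 1e-12.

## The determinant-space oracle

Every working equation is validated against brute-force full-configuration
algebra on systems with at most a few hundred determinants: the
Hamiltonian by Slater–Condon rules (cross-checked against raw
creation/annihilation operator application), cluster operators as
nilpotent matrices, similarity transforms as terminating exponential
series, Jacobians by explicit commutators, and the natural-projection
overlap by explicit projectors. The oracle replicates the model's
truncations symbolically (doubles rows of the Jacobian from the T1-only
transform, the diagonal Fock commutator in the doubles residual), so it
validates the implemented equations, not full coupled cluster. Doubles
excitation operators are applied per determinant on raw bitmasks because
cross-spin pairings pass through intermediates outside the fixed-Sz basis.

## Study system for the intersection topology

The demonstration system is hypofluorous acid in the bundled minimal
basis. A search over the three internal coordinates located a
same-symmetry near-degeneracy of the two lowest singlet excited states
(both of A″ reflection character) with a genuine CC2 defect: at fixed
R_OH = 1.1067 Å the plane spanned by R_OF and the bond angle cuts the
complex-eigenvalue region around (R_OF, θ) ≈ (1.3065 Å, 97.14°), with
|Im ω| up to 1.2e-4 Hartree. The region is small in the minimal basis —
roughly ±4e-4 Å × ±0.07° — so the scans use a correspondingly fine 5×5
grid (steps of 4e-4 Å and 0.05°); this is the package's scaled-down
analogue of the published full-basis surface scans, with the same
qualitative content: a finite complex region for CC2, none for SCC2, a
located SCC2 gap minimum below 1e-6 Hartree, and linear gap lifting along
rays from the conical point (per-ray R² ≥ 0.99 for SCC2 versus visibly
degraded linearity for CC2 on identical rays just outside its tube).
Ray directions pair the two axes as displacement vectors (1, 0) and
(0, 125) — 125 degrees per Å roughly equalizes the two cone apertures.

Away from the seam the constraint is a small perturbation: the SCC2
excitation energies of the tracked pair stay within a few meV of CC2 at
the test geometries, far below the intrinsic accuracy of the parent model.

## Numerical choices

* SCF threshold 1e-10 (commutator norm); CC2 residual thresholds 1e-8 for
  scans and tests; inner SCC2 relaxation at 1e-3 of the outer threshold.
* DIIS subspace 8 (10 for the SCC2 inner relaxation), restart on B-matrix
  condition number above 1e12.
* Closed-form doubles denominators below 1e-8 abort with a diagnostic
  naming the orbital quadruple rather than regularizing silently.
* Davidson: spin-adapted ± combinations of the smallest-gap Koopmans
  guesses; duplicate roots are detected by overlap and retried from the
  next guess; complex roots are the dense path's job.
* ζ continuation step cap 0.3; Newton/secant steps on O(A,B) are damped by
  backtracking; all tie-breaks (phase fixing, A/B assignment) resolve by
  maximal overlap with the previous iterate and positive largest element.
* Pattern search for the intersection: compass steps with halving,
  accelerated by a local quadratic surrogate of gap² fitted to cached
  evaluations (the squared gap is smooth at a conical point); tolerance
  1e-6 Hartree on the gap.
* Reproducibility: all solvers are deterministic; scans are bit-for-bit
  reproducible under cold restart.

## Problem sizes

The validation systems are H2 (4 determinants), H4 (36), minimal-basis
water (441) for oracle equivalence, and HOF (432 singles+doubles labels)
for the topology work. These sizes keep the dense Jacobian, its full
eigendecomposition and the determinant-space oracle exact and fast while
exercising every term of the working equations; the factorized production
code paths are the same ones that would run at larger scale.

## Known limitations

* Only the bundled STO-3G tables ship with the package; other basis sets
  require registering an integral backend.
* Two constrained states only; no analytic gradients or derivative
  couplings; no oscillator strengths; no point-group symmetry blocking.
* The natural projection is only approximately size-intensive; the
  ground-state energy additivity error for SCC2 over noninteracting
  fragments is at the 1e-6 Hartree level rather than machine precision.
* SCC2 cold starts can fail to converge at isolated geometries away from
  the seam (a known property of similarity-constrained solvers); scans
  record these as unconverged points.
* The minimal-basis defect region is tiny; demonstrating the topology
  contrast at chemically realistic scales needs larger basis sets and
  therefore an external integral backend.
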