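# scc2 — similarity-constrained CC2 at desk scale

Standard coupled cluster models cannot be trusted at conical intersections
between excited states of the same symmetry: the non-Hermitian coupled
cluster Jacobian becomes defective there, the intersection seam inflates
into a spurious tube of dimension M−1 (instead of the physical M−2), and
complex excitation-energy pairs appear inside it. This breaks excited-state
dynamics. The similarity-constrained approach cures the defect with one
extra wave-function parameter: the cluster operator is extended to

    S = T1 + T2 + ζ·X3,     X3 = Σ (r^A_μ1 r^B_μ2 − r^B_μ1 r^A_μ2) τ_μ1 τ_μ2,

and ζ is determined by the orthogonality condition O(A,B) = ⟨R^A|P|R^B⟩ = 0
between the two intersecting EOM states, with P the natural projection onto
the reference+singles+doubles space. Because X3 is built bilinearly from the
two states' own amplitudes, the correction costs no more than CC2 itself
(O(N^5)), and the amplitude equations change only by a single term
ζ⟨μ1|[H̃, X3]|HF⟩ in the singles residual.

This package is a complete, oracle-validated desk-scale implementation for
quantum chemists who want to study, test or teach this construction:

* restricted Hartree–Fock + MO integrals on a bundled McMurchie–Davidson
  integral engine (STO-3G tables for H, He, C, N, O, F; pluggable backend
  for anything else),
* CC2 ground state with T1-dressed integrals and folded closed-form doubles,
* EOM-CC2 excited states: folded Davidson and dense non-symmetric
  eigensolvers, left states, biorthonormalization, complex-pair detection,
* the SCC2 layer: factorized X3 correction, the q/Q/S natural-projection
  overlap machinery, and a robust coupled solver for the simultaneous
  (amplitudes, states, ζ) equations — including inside CC2 defect regions,
* surface-scan tooling: grid scans with warm-restart chaining,
  complex-region detection, intersection location (pattern search with a
  quadratic surrogate), and ray-linearity metrics for intersection topology,
* a brute-force determinant-space oracle that recomputes every working
  equation as explicit matrix algebra on small systems.

## Worked example

The classic demonstration system is hypofluorous acid (HOF), which has a
same-symmetry intersection between its two lowest singlet excited states.
In the bundled minimal basis the crossing sits near R_OH = 1.1067 Å,
R_OF = 1.3065 Å, θ = 97.14°:

```python
import numpy as np
from scc2 import (make_hof_geometry, compute_ao_integrals, solve_rhf,
                  transform_mo_integrals, to_spin_orbital)
from scc2.cc2 import solve_cc2_ground
from scc2.eom import JacobianModel
from scc2.scc2 import solve_scc2
import scipy.linalg as sla

geo = make_hof_geometry(r_oh=1.106738, r_of=1.306488, theta=97.1378)
ao = compute_ao_integrals(geo, "sto-3g")
ref = solve_rhf(ao, geo.n_electrons)
ints = to_spin_orbital(transform_mo_integrals(ao, ref))

gs = solve_cc2_ground(ints, threshold=1e-10)
vals = sla.eig(JacobianModel(gs.dressed, gs.t2).dense(), right=False)
pair = np.sort_complex(vals[np.abs(vals.imag) > 1e-8])
print(f"E(CC2)  = {gs.energy:.8f} Hartree")
print(f"CC2 defect pair: {pair[0]:.6f}, {pair[1]:.6f} Hartree")

sol = solve_scc2(ints, select=(0, 1), threshold=1e-8)
print(f"E(SCC2) = {sol.energy:.8f} Hartree   zeta = {sol.zeta:+.4f}")
print(f"SCC2 pair: {np.real(sol.omega_a):.6f}, {np.real(sol.omega_b):.6f} Hartree"
      f"   |O(A,B)| = {sol.orthogonality_residual:.1e}")
```

prints

```
E(CC2)  = -172.41978068 Hartree
CC2 defect pair: 0.337697-0.000122j, 0.337697+0.000122j Hartree
E(SCC2) = -172.41976549 Hartree   zeta = +1.6478
SCC2 pair: 0.337766, 0.337465 Hartree   |O(A,B)| = 5.5e-10
```

At this geometry plain CC2 yields a complex-conjugate pair of excitation
energies — the unphysical signature of the defective Jacobian inside the
intersection tube. The similarity constraint (ζ ≈ 1.65; its sign is a
convention of the state orientation) restores two real energies, split by
0.3 mHartree because this grid point lies slightly off the true conical
point, while shifting the ground-state energy by only 15 μHartree. Scanning
the surrounding plane (`scc2.scan`) shows the full contrast: CC2 has a
finite complex-eigenvalue region, SCC2 has a single point degeneracy with
the gap rising linearly in every direction.

A command-line interface covers the scan workflows:

```bash
scc2 single-point h2o.xyz --n-states 4
scc2 scan config.yaml --out surface.csv
scc2 locate config.yaml --start 1.3061 97.09
scc2 detect-region surface.csv
```

## Layout

| module | contents |
|---|---|
| `scc2.geometry` | XYZ I/O, parametric builders (HOF, H2, H2O, H4 ring) |
| `scc2.basis`, `scc2.integrals` | STO-3G tables, McMurchie–Davidson engine, backend registry |
| `scc2.scf`, `scc2.moints` | RHF (DIIS), MO transformation, spin-orbital integrals |
| `scc2.cc2` | T1 dressing, folded doubles, CC2 energy/η, DIIS ground-state solver |
| `scc2.eom` | Jacobian actions (right/transpose/folded), Davidson + dense eigensolvers, left states, r0 |
| `scc2.scc2` | X3, ζ-correction, q/Q/S overlap machinery, coupled SCC2 solver |
| `scc2.detspace` | determinant-space oracle (full CI algebra on bitstrings) |
| `scc2.scan`, `scc2.cli` | surface scans, region detection, intersection location, topology metrics, CLI |

`docs/methods.md` documents the model, the solver design and the numerical
choices in detail.
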