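"""Potential-energy-surface scans, intersection location, topology metrics.

A scan walks a two-dimensional grid of geometries (internal-coordinate
ranges for hypofluorous acid, or displacements along two branching-plane
vectors for a general molecule), solves CC2 or SCC2 at every point with
chained warm restarts, and records ground- and excited-state energies.
On top of the records sit the three topology diagnostics:

* `detect_complex_region` -- the CC2 defect region where the tracked pair
  of same-symmetry states has collapsed to a complex-conjugate pair;
* `locate_intersection` -- derivative-free minimization of the real gap
  (the SCC2 surfaces admit a true point degeneracy);
* `linearity_metric` -- least-squares linearity of the gap along rays from
  a located intersection, the signature distinguishing a conical point
  (linear lifting) from the defective CC2 topology.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .cc2 import solve_cc2_ground
from .eom import JacobianModel
from .geometry import EV_PER_HARTREE, Geometry, make_hof_geometry
from .moints import to_spin_orbital, transform_mo_integrals
from .integrals import compute_ao_integrals
from .labels import LabelSpace
from .scf import solve_rhf
from .scc2 import (SCC2ConvergenceError, SCC2Solution, StateTrackingError,
                   _real_pair_from_roots, _refine_pair, _select_initial,
                   _track_pair, solve_scc2)


def hof_plane(r_oh: float = 1.1) -> Callable[[float, float], Geometry]:
    """(r_of, theta) -> HOF geometry at fixed OH distance."""
    def build(x: float, y: float) -> Geometry:
        return make_hof_geometry(r_oh, x, y)
    return build


def gh_plane(base: Geometry, g_vec: np.ndarray, h_vec: np.ndarray
             ) -> Callable[[float, float], Geometry]:
    """(x, y) -> base displaced by x*g + y*h (Cartesian, Å)."""
    g_vec = np.asarray(g_vec, dtype=float).reshape(base.n_atoms, 3)
    h_vec = np.asarray(h_vec, dtype=float).reshape(base.n_atoms, 3)

    def build(x: float, y: float) -> Geometry:
        return base.displaced(x * g_vec + y * h_vec)
    return build


@dataclass
class ScanConfig:
    """Declarative description of a 2-D surface scan."""

    geometry_map: Callable[[float, float], Geometry]
    xs: np.ndarray
    ys: np.ndarray
    method: str = "cc2"  # "cc2" | "scc2"
    basis: str = "sto-3g"
    select: tuple[int, int] = (0, 1)
    threshold: float = 1e-8
    max_iter: int = 30
    restart: str = "chain"  # "chain" | "cold"
    singlet_only: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.xs = np.atleast_1d(np.asarray(self.xs, dtype=float))
        self.ys = np.atleast_1d(np.asarray(self.ys, dtype=float))
        if self.method not in ("cc2", "scc2"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.restart not in ("chain", "cold"):
            raise ValueError(f"unknown restart policy {self.restart!r}")

    def describe(self) -> dict:
        return dict(method=self.method, basis=self.basis,
                    select=list(self.select), threshold=self.threshold,
                    restart=self.restart,
                    xs=[float(v) for v in self.xs],
                    ys=[float(v) for v in self.ys],
                    **self.metadata)


class _PointSolver:
    """Per-geometry electronic structure with pair tracking across points."""

    def __init__(self, config: ScanConfig):
        self.cfg = config
        self.ref_pair = None  # (va, vb) label-space vectors of the pair
        self.prev_scc2: SCC2Solution | None = None

    def spin_ints(self, x: float, y: float):
        geo = self.cfg.geometry_map(x, y)
        ao = compute_ao_integrals(geo, self.cfg.basis)
        ref = solve_rhf(ao, geo.n_electrons)
        return to_spin_orbital(transform_mo_integrals(ao, ref))

    def cc2_point(self, x: float, y: float) -> dict:
        ints = self.spin_ints(x, y)
        gs = solve_cc2_ground(ints, threshold=self.cfg.threshold)
        model = JacobianModel(gs.dressed, gs.t2)
        import scipy.linalg as sla
        amat = model.dense()
        vals, vecs = sla.eig(amat)
        space = model.space
        if self.ref_pair is None:
            _, _, _, idx = _select_initial(model, self.cfg.select,
                                           self.cfg.singlet_only)
            ia, ib = idx
        else:
            ia, ib = _track_pair(vals, vecs, *self.ref_pair)
        va, vb, wa, wb, is_complex = _real_pair_from_roots(vals, vecs, ia, ib,
                                                           space)
        sigma = float(0.5 * np.real(wa + wb)) + 1.3e-5
        va, vb, wa, wb, is_complex = _refine_pair(amat, va, vb, sigma)
        if self.cfg.restart == "chain":
            self.ref_pair = (va, vb)
        return dict(e0=gs.energy, omega_a=complex(wa), omega_b=complex(wb),
                    zeta=0.0, converged=True, is_complex=is_complex)

    def scc2_point(self, x: float, y: float) -> dict:
        ints = self.spin_ints(x, y)
        init = self.prev_scc2 if self.cfg.restart == "chain" else None
        try:
            sol = solve_scc2(ints, select=self.cfg.select,
                             threshold=self.cfg.threshold, init=init,
                             max_iter=self.cfg.max_iter,
                             singlet_only=self.cfg.singlet_only)
        except (SCC2ConvergenceError, StateTrackingError):
            if init is None:
                raise
            # warm restart failed (orientation/basin mismatch): retry from
            # a clean cold start, whose continuation and defect handling
            # are the most robust path
            sol = solve_scc2(ints, select=self.cfg.select,
                             threshold=self.cfg.threshold,
                             max_iter=self.cfg.max_iter,
                             singlet_only=self.cfg.singlet_only)
        if self.cfg.restart == "chain":
            self.prev_scc2 = sol
        return dict(e0=sol.energy, omega_a=complex(sol.omega_a),
                    omega_b=complex(sol.omega_b), zeta=sol.zeta,
                    converged=sol.converged, is_complex=False)

    def point(self, x: float, y: float) -> dict:
        if self.cfg.method == "cc2":
            return self.cc2_point(x, y)
        return self.scc2_point(x, y)


def run_scan(config: ScanConfig, progress: Callable[[str], None] | None = None
             ) -> pd.DataFrame:
    """One record per grid point; serpentine order for warm-restart chaining.

    Failures at individual points are recorded (converged=False), not fatal;
    a scan where no point converges raises RuntimeError.
    """
    solver = _PointSolver(config)
    records = []
    for iy, y in enumerate(config.ys):
        xs = config.xs if iy % 2 == 0 else config.xs[::-1]
        for x in xs:
            t0 = time.time()
            try:
                rec = solver.point(float(x), float(y))
            except Exception as exc:  # noqa: BLE001 - per-point fault isolation
                rec = dict(e0=np.nan, omega_a=np.nan + 0j, omega_b=np.nan + 0j,
                           zeta=np.nan, converged=False, is_complex=False,
                           error=f"{type(exc).__name__}: {exc}")
            rec.update(x=float(x), y=float(y), seconds=time.time() - t0)
            records.append(rec)
            if progress is not None:
                progress(f"({x:.6g}, {y:.6g}) "
                         f"{'ok' if rec['converged'] else 'FAILED'} "
                         f"[{rec['seconds']:.1f}s]")
    df = pd.DataFrame.from_records(records)
    if not df["converged"].any():
        raise RuntimeError("scan failed: no grid point converged")
    df = df.sort_values(["y", "x"]).reset_index(drop=True)
    for state in ("a", "b"):
        df[f"omega_{state}_re_ev"] = np.real(df[f"omega_{state}"]) * EV_PER_HARTREE
        df[f"omega_{state}_im_ev"] = np.imag(df[f"omega_{state}"]) * EV_PER_HARTREE
    return df


def scan_table(df: pd.DataFrame) -> pd.DataFrame:
    """The fixed-schema CSV view of a scan (energies in Hartree / eV)."""
    cols = ["x", "y", "e0", "omega_a_re_ev", "omega_a_im_ev",
            "omega_b_re_ev", "omega_b_im_ev", "zeta", "converged"]
    return df[cols].copy()


def write_scan(df: pd.DataFrame, config: ScanConfig, csv_path, json_path=None):
    scan_table(df).to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(config.describe(), fh, indent=2)


def detect_complex_region(df: pd.DataFrame, threshold: float = 1e-8
                          ) -> tuple[np.ndarray, np.ndarray, int]:
    """Boolean mask of complex-pair points + 4-connected region labels.

    Returns (mask, labels, n_regions) on the (ny, nx) grid implied by the
    record coordinates; threshold is on |Im omega| in Hartree.
    """
    from scipy.ndimage import label as nd_label

    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    mask = np.zeros((ys.size, xs.size), dtype=bool)
    for _, row in df.iterrows():
        ix = int(np.argmin(np.abs(xs - row["x"])))
        iy = int(np.argmin(np.abs(ys - row["y"])))
        im = abs(np.imag(row["omega_a"]))
        mask[iy, ix] = bool(row["converged"]) and im > threshold
    labels, n_regions = nd_label(mask, structure=np.array([[0, 1, 0],
                                                           [1, 1, 1],
                                                           [0, 1, 0]]))
    return mask, labels, int(n_regions)


@dataclass
class IntersectionResult:
    point: tuple[float, float]
    gap: float
    converged: bool
    complex_collapse: bool = False
    n_evaluations: int = 0


def locate_intersection(config: ScanConfig | None, start: tuple[float, float],
                        step: tuple[float, float], *,
                        gap_tol: float = 1e-6, max_eval: int = 120,
                        bounds: tuple | None = None,
                        gap_fn: Callable[[float, float], float] | None = None,
                        progress: Callable[[str], None] | None = None
                        ) -> IntersectionResult:
    """Compass (pattern) search minimizing the tracked-state gap.

    For SCC2 the minimum is a genuine conical point (gap below gap_tol);
    for CC2 inside its defect region the pair collapses to complex values,
    which is reported via `complex_collapse` instead of a gap minimum.
    """
    solver = _PointSolver(config) if gap_fn is None else None
    cache: dict[tuple[float, float], dict] = {}
    n_eval = 0

    def gap_at(x, y):
        nonlocal n_eval
        key = (round(x, 12), round(y, 12))
        if key not in cache:
            if bounds is not None:
                (x0, x1), (y0, y1) = bounds
                if not (x0 <= x <= x1 and y0 <= y <= y1):
                    cache[key] = dict(gap=np.inf, is_complex=False)
                    return cache[key]
            n_eval += 1
            if gap_fn is not None:
                cache[key] = dict(gap=float(gap_fn(x, y)), is_complex=False)
                return cache[key]
            t0 = time.time()
            try:
                rec = solver.point(x, y)
                gap = abs(np.real(rec["omega_b"]) - np.real(rec["omega_a"]))
                cache[key] = dict(gap=float(gap),
                                  is_complex=bool(rec["is_complex"]))
            except Exception as exc:  # noqa: BLE001
                cache[key] = dict(gap=np.inf, is_complex=False,
                                  error=f"{type(exc).__name__}")
            if progress is not None:
                info = cache[key]
                progress(f"eval {n_eval} ({x:.6f},{y:.4f}) "
                         f"gap={info['gap']:.3e} [{time.time() - t0:.1f}s]"
                         + (" " + info["error"] if "error" in info else ""))
        return cache[key]

    x, y = float(start[0]), float(start[1])
    hx, hy = float(step[0]), float(step[1])
    sx, sy = hx, hy  # scaling for the local quadratic model

    def model_jump():
        """Minimizer of a local quadratic fit of gap^2 over cached points.

        Near a conical intersection the squared gap is a smooth positive
        quadratic form, so a surrogate jump reaches the minimum far faster
        than step halving alone."""
        pts = [((px - x) / sx, (py - y) / sy, info["gap"])
               for (px, py), info in cache.items()
               if np.isfinite(info["gap"]) and not info["is_complex"]
               and abs(px - x) <= 8 * hx + 1e-15 and abs(py - y) <= 8 * hy + 1e-15]
        if len(pts) < 8:
            return None
        u = np.array([p[0] for p in pts])
        v = np.array([p[1] for p in pts])
        g2 = np.array([p[2] for p in pts]) ** 2
        a = np.stack([np.ones_like(u), u, v, u * u, u * v, v * v], axis=1)
        try:
            c, *_ = np.linalg.lstsq(a, g2, rcond=None)
        except np.linalg.LinAlgError:
            return None
        hess = np.array([[2 * c[3], c[4]], [c[4], 2 * c[5]]])
        if np.linalg.eigvalsh(hess).min() <= 0:
            return None
        delta = np.linalg.solve(hess, -np.array([c[1], c[2]]))
        if np.abs(delta).max() > 6.0:  # do not trust far extrapolation
            return None
        return x + delta[0] * sx, y + delta[1] * sy

    current = gap_at(x, y)
    if current["is_complex"]:
        return IntersectionResult((x, y), np.nan, False,
                                  complex_collapse=True, n_evaluations=n_eval)
    while n_eval < max_eval:
        best = None
        for dx, dy in ((hx, 0.0), (-hx, 0.0), (0.0, hy), (0.0, -hy)):
            trial = gap_at(x + dx, y + dy)
            if trial["is_complex"]:
                return IntersectionResult((x + dx, y + dy), np.nan, False,
                                          complex_collapse=True,
                                          n_evaluations=n_eval)
            if best is None or trial["gap"] < best[0]["gap"]:
                best = (trial, x + dx, y + dy)
        if best[0]["gap"] < current["gap"]:
            current, x, y = best
        else:
            jump = model_jump()
            jumped = False
            if jump is not None:
                trial = gap_at(*jump)
                if not trial["is_complex"] and trial["gap"] < current["gap"]:
                    current, (x, y) = trial, jump
                    jumped = True
            if not jumped:
                hx *= 0.5
                hy *= 0.5
        if current["gap"] <= gap_tol:
            return IntersectionResult((x, y), current["gap"], True,
                                      n_evaluations=n_eval)
        if max(hx, hy) < 1e-9:
            break
    converged = current["gap"] <= max(gap_tol, 1e-4)
    return IntersectionResult((x, y), current["gap"], converged,
                              n_evaluations=n_eval)


@dataclass
class RayFit:
    direction: tuple[float, float]
    radii: np.ndarray
    gaps: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def linearity_metric(config: ScanConfig, center: tuple[float, float],
                     directions: list[tuple[float, float]],
                     radii: np.ndarray,
                     gap_records: Callable[[float, float], float] | None = None
                     ) -> list[RayFit]:
    """Least-squares linear fit of gap vs displacement along each ray.

    A conical intersection lifts the degeneracy linearly: R^2 of the linear
    fit approaches 1 for small radii. Radii are in the scan plane's native
    units; at least 5 per ray are required.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size < 5:
        raise ValueError("need at least 5 radii per ray for a meaningful fit")
    if gap_records is None:
        solver = _PointSolver(config)

        def gap_records(x, y):
            try:
                rec = solver.point(x, y)
            except Exception:  # noqa: BLE001 - per-point fault isolation
                return np.nan
            if rec["is_complex"]:
                return np.nan
            return abs(np.real(rec["omega_b"]) - np.real(rec["omega_a"]))

    fits = []
    for (dx, dy) in directions:
        # directions are displacement vectors per unit radius (the two scan
        # axes may carry very different units, e.g. Å versus degrees)
        ux, uy = float(dx), float(dy)
        gaps = np.array([gap_records(center[0] + r * ux, center[1] + r * uy)
                         for r in radii])
        good = np.isfinite(gaps)
        rr, gg = radii[good], gaps[good]
        if rr.size < 5:
            fits.append(RayFit((ux, uy), radii, gaps, np.nan, np.nan, np.nan))
            continue
        coef = np.polyfit(rr, gg, 1)
        pred = np.polyval(coef, rr)
        ss_res = float(np.sum((gg - pred) ** 2))
        ss_tot = float(np.sum((gg - gg.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        fits.append(RayFit((ux, uy), radii, gaps, float(coef[0]),
                           float(coef[1]), r2))
    return fits
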