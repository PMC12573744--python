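"""Molecular geometries: XYZ I/O and parametric builders for the test systems.

Coordinates are kept in Ångström on the user-facing side; the integral layer
converts to Bohr. Only closed-shell (even-electron, singlet) systems are
accepted, matching the restricted references used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BOHR_PER_ANGSTROM = 1.0 / 0.52917721092
ANGSTROM_PER_BOHR = 0.52917721092
EV_PER_HARTREE = 27.211386245988

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7,
    "O": 8, "F": 9, "Ne": 10, "Ar": 18,
}


class GeometryError(ValueError):
    """Raised for malformed or unphysical molecular specifications."""


@dataclass(frozen=True)
class Geometry:
    """A molecule: element symbols, Cartesian coordinates (Å), charge.

    Only singlet multiplicity is supported; construction fails for an odd
    electron count.
    """

    elements: tuple[str, ...]
    coordinates: np.ndarray  # (natom, 3), Å
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) == 0:
            raise GeometryError("geometry needs at least one atom")
        if len(self.elements) != coords.shape[0]:
            raise GeometryError(
                f"{len(self.elements)} elements but {coords.shape[0]} coordinate rows")
        for sym in self.elements:
            if sym not in ATOMIC_NUMBERS:
                raise GeometryError(f"unknown element symbol {sym!r}")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        if self.multiplicity != 1:
            raise GeometryError("only singlet (multiplicity 1) references are supported")
        if self.n_electrons % 2 != 0:
            raise GeometryError(
                f"odd electron count {self.n_electrons}; closed-shell reference required")

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[s] for s in self.elements], dtype=int)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def coordinates_bohr(self) -> np.ndarray:
        return self.coordinates * BOHR_PER_ANGSTROM

    def nuclear_repulsion(self) -> float:
        """Point-charge Coulomb energy in Hartree."""
        z = self.atomic_numbers.astype(float)
        xyz = self.coordinates_bohr()
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += z[i] * z[j] / np.linalg.norm(xyz[i] - xyz[j])
        return e

    def displaced(self, delta: np.ndarray) -> "Geometry":
        """New geometry with Cartesian displacement ``delta`` (Å) added."""
        delta = np.asarray(delta, dtype=float).reshape(self.n_atoms, 3)
        return replace(self, coordinates=self.coordinates + delta)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Geometry":
        """Rigidly rotate (3x3 matrix) and/or translate (Å vector) the molecule."""
        xyz = self.coordinates
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return replace(self, coordinates=xyz)


def read_xyz(text: str, charge: int = 0) -> Geometry:
    """Parse an XYZ-format string (count line, comment line, atom lines, Å)."""
    lines = text.strip().splitlines()
    if not lines:
        raise GeometryError("empty XYZ input")
    try:
        natom = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise GeometryError(f"line 1: expected atom count, got {lines[0]!r}") from exc
    if len(lines) < natom + 2:
        raise GeometryError(
            f"XYZ declares {natom} atoms but only {max(len(lines) - 2, 0)} atom lines present")
    elements, coords = [], []
    for ln, line in enumerate(lines[2:2 + natom], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise GeometryError(f"line {ln}: expected 'El x y z', got {line!r}")
        sym = parts[0].capitalize()
        if sym not in ATOMIC_NUMBERS:
            raise GeometryError(f"line {ln}: unknown element symbol {parts[0]!r}")
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError as exc:
            raise GeometryError(f"line {ln}: malformed coordinate in {line!r}") from exc
        elements.append(sym)
    return Geometry(tuple(elements), np.array(coords), charge=charge)


def write_xyz(geometry: Geometry, comment: str = "") -> str:
    lines = [str(geometry.n_atoms), comment]
    for sym, xyz in zip(geometry.elements, geometry.coordinates):
        lines.append(f"{sym} {xyz[0]:.12f} {xyz[1]:.12f} {xyz[2]:.12f}")
    return "\n".join(lines) + "\n"


def make_hof_geometry(r_oh: float = 1.1, r_of: float = 1.33,
                      theta: float = 90.5) -> Geometry:
    """Planar hypofluorous acid from internal coordinates.

    O sits at the origin with the OF bond along +x and H in the xy-plane;
    ``theta`` is the H-O-F angle in degrees.
    """
    if r_oh <= 0 or r_of <= 0:
        raise GeometryError("bond lengths must be positive")
    if not 0.0 < theta < 180.0:
        raise GeometryError("HOF angle must lie strictly between 0 and 180 degrees")
    th = np.deg2rad(theta)
    coords = np.array([
        [0.0, 0.0, 0.0],                          # O
        [r_oh * np.cos(th), r_oh * np.sin(th), 0.0],  # H
        [r_of, 0.0, 0.0],                         # F
    ])
    return Geometry(("O", "H", "F"), coords)


def hof_internals(geometry: Geometry) -> tuple[float, float, float]:
    """Recover (r_oh, r_of, theta_deg) from a geometry in O, H, F order."""
    o, h, f = geometry.coordinates
    r_oh = float(np.linalg.norm(h - o))
    r_of = float(np.linalg.norm(f - o))
    cth = float(np.dot(h - o, f - o) / (r_oh * r_of))
    return r_oh, r_of, float(np.rad2deg(np.arccos(np.clip(cth, -1.0, 1.0))))


def make_h2_geometry(bond: float = 0.74, center: np.ndarray | None = None) -> Geometry:
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    coords = np.array([c + [0, 0, -bond / 2], c + [0, 0, bond / 2]])
    return Geometry(("H", "H"), coords)


def make_h2o_geometry(r_oh: float = 0.9584, theta: float = 104.45) -> Geometry:
    th = np.deg2rad(theta)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [r_oh, 0.0, 0.0],
        [r_oh * np.cos(th), r_oh * np.sin(th), 0.0],
    ])
    return Geometry(("O", "H", "H"), coords)


def make_h4_geometry(r: float = 1.0, theta: float = 90.0) -> Geometry:
    """Four H atoms on a circle of radius ``r`` (Å), the 'P4'-like ring model.

    ``theta`` (degrees) is the angular position of the second pair; at 90 the
    arrangement is a square, where the two lowest same-symmetry excited
    states become quasi-degenerate -- the classic playground for defective
    coupled cluster Jacobians.
    """
    if r <= 0:
        raise GeometryError("ring radius must be positive")
    th = np.deg2rad(theta)
    coords = np.array([
        [r, 0.0, 0.0],
        [-r, 0.0, 0.0],
        [r * np.cos(th), r * np.sin(th), 0.0],
        [-r * np.cos(th), -r * np.sin(th), 0.0],
    ])
    return Geometry(("H", "H", "H", "H"), coords)
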