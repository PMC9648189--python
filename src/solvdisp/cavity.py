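"""Solvent-dependent molecular cavity and exterior quadrature.

The cavity is a union of interlocking spheres centered on the solute
nuclei.  Each radius is the sum of a solute atomic radius (R_1/2 values:
C 3.26, O 2.81, H 2.33 bohr) and a solvent contact radius that encodes the
kind of solute-solvent contact:

* water: the solvent oxygen radius (2.96) is added on solute C and H, the
  solvent hydrogen radius (1.86) on solute O - a hydrogen-bond contact;
* ethanol: hydrogen contact (1.86) on solute O, a spherical CH3-group
  radius (3.932) elsewhere;
* cyclohexane / chloroform / carbon tetrachloride / toluene: one solvent
  sphere radius (5.20 / 4.82 / 5.20 / 5.01) on every solute atom.

Cavity scaling multiplies all radii by a common factor, except in water
where only the spheres centered on solute oxygens are scaled (the
hydrogen-bond contact on the other atoms is kept fixed).

The exterior quadrature integrates over the complement of the cavity out
to a truncation radius: for each angular direction from the cavity
centroid the exact exterior sub-intervals of the ray are found and
Gauss-Legendre radial nodes placed on them, so no node is ever inside a
sphere and the sharp boundary costs no radial accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._geometry import angular_grid, complement_intervals, ray_union_intervals
from ._tables import solvent_table
from .model_systems import Atom

#: Solute atomic radii (bohr), overridable in build_cavity.
SOLUTE_RADII = {"C": 3.26, "O": 2.81, "H": 2.33}


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float
    element: str


@dataclass(frozen=True)
class Cavity:
    spheres: tuple
    solvent_name: str
    scale: float = 1.0

    def __post_init__(self):
        if any(s.radius <= 0 for s in self.spheres):
            raise ValueError("cavity sphere radii must be positive")

    @property
    def centers(self):
        return np.array([s.center for s in self.spheres])

    @property
    def radii(self):
        return np.array([s.radius for s in self.spheres])

    @property
    def centroid(self):
        return self.centers.mean(axis=0)


def solvent_contact_radii(solvent_name: str):
    """(default contact radius, contact radius on solute oxygen) in bohr."""
    tab = solvent_table()
    if solvent_name not in tab.index:
        raise KeyError(f"unknown solvent {solvent_name!r}; known: {list(tab.index)}; "
                       "pass contact_radii= to override")
    row = tab.loc[solvent_name]
    return float(row.contact_radius_default), float(row.contact_radius_on_O)


def build_cavity(atoms: Sequence[Atom], solvent_name: str, scale: float = 1.0,
                 *, contact_radii: tuple[float, float] | None = None,
                 solute_radii: dict | None = None) -> Cavity:
    """Interlocking-sphere cavity for a solute in a named solvent.

    `contact_radii` = (default, on_O) overrides the packaged solvent table;
    `solute_radii` overrides the per-element solute radii.
    """
    radii_tab = dict(SOLUTE_RADII)
    if solute_radii:
        radii_tab.update(solute_radii)
    default_c, on_o = (contact_radii if contact_radii is not None
                       else solvent_contact_radii(solvent_name))
    spheres = []
    for a in atoms:
        if a.element not in radii_tab:
            raise KeyError(f"no solute radius for element {a.element!r}; "
                           "pass solute_radii= to override")
        contact = on_o if a.element == "O" else default_c
        spheres.append(Sphere(np.asarray(a.position, float),
                              radii_tab[a.element] + contact, a.element))
    cav = Cavity(tuple(spheres), solvent_name, 1.0)
    if scale != 1.0:
        cav = scale_cavity(cav, scale)
    return cav


def scale_cavity(cavity: Cavity, factor: float,
                 solvent_name: str | None = None) -> Cavity:
    """Scale cavity radii by `factor`.

    In water only the spheres centered on solute oxygen nuclei are scaled;
    in every other solvent all radii are scaled.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    name = solvent_name if solvent_name is not None else cavity.solvent_name
    water_rule = (name == "water")
    spheres = tuple(
        replace(s, radius=s.radius * factor)
        if (not water_rule or s.element == "O") else s
        for s in cavity.spheres)
    return Cavity(spheres, cavity.solvent_name, cavity.scale * factor)


def contains(cavity: Cavity, point) -> bool | np.ndarray:
    """Strict-interior membership test (boundary points count as outside)."""
    pts = np.asarray(point, float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    inside = np.zeros(pts.shape[0], dtype=bool)
    for s in cavity.spheres:
        inside |= np.linalg.norm(pts - s.center, axis=1) < s.radius
    return bool(inside[0]) if single else inside


@dataclass(frozen=True)
class ExteriorQuadrature:
    nodes: np.ndarray       # (n, 3) bohr, all strictly outside the cavity
    weights: np.ndarray     # (n,) bohr^3
    r_max: float
    tail_estimate: float = 0.0
    est_error: float = 0.0

    def integrate(self, f) -> float:
        """Integral over the truncated exterior of a callable f(points)->values."""
        return float(np.dot(self.weights, np.asarray(f(self.nodes), float)))


def exterior_quadrature(cavity: Cavity, radial_order: int = 24,
                        angular_order: int = 24, *, r_max: float | None = None,
                        margin: float = 25.0) -> ExteriorQuadrature:
    """Product quadrature over the cavity exterior within a ball of r_max.

    Rays from the cavity centroid are cast along a Gauss-Legendre x uniform
    angular grid (angular_order x 2*angular_order directions); on each ray
    the exterior segments of [0, r_max] are computed exactly and receive
    `radial_order` Gauss-Legendre nodes each, weighted by t^2 and the
    angular weight.  The O(1/r_max^3) tail beyond r_max is handled by the
    caller through the r^-6 decay of the integrand (see pipeline).
    """
    if len(cavity.spheres) == 0:
        raise ValueError("cavity has no spheres")
    if radial_order < 2 or angular_order < 2:
        raise ValueError("quadrature orders must be >= 2")
    center = cavity.centroid
    centers = [s.center for s in cavity.spheres]
    radii = [s.radius for s in cavity.spheres]
    if r_max is None:
        reach = max(float(np.linalg.norm(s.center - center)) + s.radius
                    for s in cavity.spheres)
        r_max = reach + margin
    dirs, wang = angular_grid(angular_order, 2 * angular_order)
    gl_x, gl_w = np.polynomial.legendre.leggauss(radial_order)
    nodes = []
    weights = []
    for d, wa in zip(dirs, wang):
        inside = ray_union_intervals(center, d, centers, radii, r_max)
        for a, b in complement_intervals(inside, r_max):
            t = 0.5 * (b - a) * (gl_x + 1.0) + a
            wt = 0.5 * (b - a) * gl_w * t * t * wa
            nodes.append(center + t[:, None] * d)
            weights.append(wt)
    nodes = np.concatenate(nodes)
    weights = np.concatenate(weights)
    return ExteriorQuadrature(nodes, weights, float(r_max))
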