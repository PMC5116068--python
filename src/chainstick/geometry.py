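"""Rigid-body geometry of the chain-stick model.

A gapped DNA duplex is coarse-grained as two hard cylinders (the stiff
double-stranded arms) joined by a fully flexible tether (the single-stranded
spacer).  Each cylinder carries two interaction sites on its symmetry axis:

* site A, just beyond the blunt end, mediating attractive blunt-end stacking;
* site B, beyond the opposite end, anchoring the tether constraint.

The cylinder axis is a unit vector pointing from the tethered (B) end toward
the blunt (A) end.  All lengths are in nanometres, all energies in units of
kT (beta = 1 internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "ModelParams",
    "Cylinder",
    "Box",
    "site_positions",
    "minimum_image",
    "cylinders_overlap",
    "folding_angle",
]


@dataclass(frozen=True)
class ModelParams:
    """Geometric and energetic parameters of the chain-stick model.

    Parameters
    ----------
    L : float
        Cylinder length in nm.  Default 16 nm (48 bp at 0.33 nm/bp).
    D : float
        Cylinder diameter in nm.  Default 3 nm, an effective hard diameter
        that subsumes electrostatic repulsion at high salt.
    sigma : float
        Tether range = diameter of the B-site sphere, nm.  Default 6.3 nm,
        half the 12.6 nm contour length of a 20-base single-stranded spacer
        (0.63 nm per base).
    delta : float
        Square-well range of the A (blunt-end stacking) site, nm.
        Default 0.25*D = 0.75 nm.
    beta_u0 : float
        Well depth of the A-A attraction in kT.  Default 8.06.
    """

    L: float = 16.0
    D: float = 3.0
    sigma: float = 6.3
    delta: float = 0.75
    beta_u0: float = 8.06

    def __post_init__(self) -> None:
        if self.L <= 0 or self.D <= 0:
            raise ValueError("cylinder dimensions must be positive")
        if self.sigma <= 0:
            raise ValueError("tether range sigma must be positive")
        if self.delta <= 0:
            raise ValueError("square-well range delta must be positive")
        if self.beta_u0 < 0:
            raise ValueError("attraction strength beta_u0 must be >= 0")

    @property
    def a_offset(self) -> float:
        """Distance of site A from the cylinder centre of mass (nm)."""
        return self.L / 2 + 0.15 * self.D / 2

    @property
    def b_offset(self) -> float:
        """Distance of site B from the cylinder centre of mass (nm)."""
        return self.L / 2 + self.sigma / 2

    @property
    def v0(self) -> float:
        """Volume of one cylinder, pi D^2 L / 4 (nm^3)."""
        return np.pi * self.D**2 * self.L / 4

    @property
    def aspect_ratio(self) -> float:
        """X0 = L / D."""
        return self.L / self.D

    @property
    def cutoff(self) -> float:
        """Centre-centre distance beyond which two cylinders cannot interact.

        Upper bound over both the hard core (bounding spheres) and the A-A
        square well (sites at ``a_offset`` from each centre).
        """
        bounding = np.sqrt(self.L**2 + self.D**2)
        return max(bounding, 2 * self.a_offset + self.delta)

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "D": self.D,
            "sigma": self.sigma,
            "delta": self.delta,
            "beta_u0": self.beta_u0,
        }


@dataclass
class Cylinder:
    """A rigid hard cylinder: the half-duplex unit."""

    com: np.ndarray
    axis: np.ndarray
    L: float = 16.0
    D: float = 3.0

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("axis must be a unit vector")
            self.axis = self.axis / n
        if self.L <= 0 or self.D <= 0:
            raise ValueError("L and D must be positive")


@dataclass
class Box:
    """Orthorhombic periodic simulation box."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.shape != (3,):
            raise ValueError("box needs three edge lengths")
        if np.any(self.edges <= 0):
            raise ValueError("box edges must be positive")

    @property
    def volume(self) -> float:
        return float(np.prod(self.edges))


def site_positions(c: Cylinder, p: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Positions of the A (blunt) and B (tethered) sites of a cylinder.

    Site A sits at ``com + a_offset * axis``; site B at
    ``com - b_offset * axis``.
    """
    a = c.com + p.a_offset * c.axis
    b = c.com - p.b_offset * c.axis
    return a, b


def minimum_image(dr: np.ndarray, box: Box) -> np.ndarray:
    """Wrap a separation vector into the primary cell of a periodic box.

    Each component of the result lies in ``[-edge/2, edge/2]``.  Works on a
    single vector or an ``(n, 3)`` array of vectors.
    """
    dr = np.asarray(dr, dtype=float)
    edges = box.edges
    return dr - edges * np.round(dr / edges)


def cylinders_overlap(
    c1: Cylinder,
    c2: Cylinder,
    box: Box | None = None,
    overlap_model: str = "cylinder",
    tol: float = 1e-9,
) -> bool:
    """Do two finite hard cylinders intersect with positive volume?

    The test is staged: bounding-sphere rejection, then the axis
    segment-segment distance (>= D means no overlap because each cylinder is
    contained in its spherocylinder), then a guaranteed-hit criterion for
    side-side contacts with interior closest points, and finally an exact
    GJK query on the two convex bodies for end-dominated contacts.  Grazing
    (zero-volume) contacts count as non-overlapping.

    With ``overlap_model="spherocylinder"`` the hard core is the
    spherocylinder of the same L and D (segment-segment distance < D).
    """
    if c1.D != c2.D or c1.L != c2.L:
        raise ValueError("overlap kernel assumes congruent cylinders")
    dr = c2.com - c1.com
    if box is not None:
        dr = minimum_image(dr, box)
    if overlap_model == "cylinder":
        return bool(
            _kernels.cyl_overlap(
                np.ascontiguousarray(dr, dtype=np.float64),
                np.ascontiguousarray(c1.axis, dtype=np.float64),
                np.ascontiguousarray(c2.axis, dtype=np.float64),
                c1.L,
                c1.D,
                tol,
            )
        )
    if overlap_model == "spherocylinder":
        d2 = _kernels.seg_seg_dist2(
            np.ascontiguousarray(dr, dtype=np.float64),
            np.ascontiguousarray(c1.axis, dtype=np.float64),
            np.ascontiguousarray(c2.axis, dtype=np.float64),
            c1.L / 2,
        )
        return bool(d2 < (c1.D - tol) ** 2)
    raise ValueError(f"unknown overlap_model: {overlap_model!r}")


def folding_angle(d) -> float:
    """Folding angle theta_f of a duplex, in degrees.

    The angle between the two B->A cylinder axes: 0 deg for the fully folded
    hairpin (both blunt ends on the same side), 180 deg for the collinear
    unfolded conformation.  Accepts a GappedDuplex or any object with
    ``cyl1``/``cyl2`` attributes.
    """
    u1 = d.cyl1.axis
    u2 = d.cyl2.axis
    c = float(np.clip(np.dot(u1, u2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))
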