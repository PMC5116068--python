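"""Hit-or-miss Monte Carlo estimation of pair excluded volumes.

The excluded volume of two rigid conformers is the measure of relative
displacements for which any of their hard cylinders overlap.  It is
estimated by sampling displacements uniformly in a bounding box that
strictly contains the contact region (verified by requiring zero hits in
the outer 5% shell) and, depending on the alignment mode, independent
random orientations of each conformer:

* ``fully_fixed`` -- both conformers keep their constructed orientation;
* ``parallel_azimuth`` -- both keep their cylinder axes parallel to z
  (strong uniaxial order, as in a smectic) but rotate independently and
  uniformly about z;
* ``isotropic`` -- fully random independent orientations of both.

The folded conformer puts the two cylinders side by side at lateral
contact with their tethered ends aligned; the unfolded conformer is
collinear and antiparallel with coincident B sites, spanning 2L + sigma
along its axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import ModelParams

__all__ = ["Conformation", "make_conformation", "excluded_volume_mc"]

_MODES = {"fully_fixed": 0, "parallel_azimuth": 1,
          "parallel_axes_azimuth_averaged": 1, "isotropic": 2}

_PAIR_GAP = 1e-3


@dataclass
class Conformation:
    """A rigid placement of the two cylinders of one duplex.

    Positions are relative to the conformer's own reference point, which is
    centred so that azimuthal rotations are taken about the z axis through
    it.  ``pos`` and ``ax`` have shape (2, 3).
    """

    label: str
    pos: np.ndarray
    ax: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.ascontiguousarray(self.pos, dtype=np.float64)
        self.ax = np.ascontiguousarray(self.ax, dtype=np.float64)

    def lateral_extent(self, D: float) -> float:
        """Max distance of any cylinder surface from the z axis (axes
        assumed parallel to z)."""
        r = np.linalg.norm(self.pos[:, :2], axis=1)
        return float(np.max(r) + D / 2)

    def axial_extent(self, L: float) -> float:
        """Half-span along z (axes assumed parallel to z)."""
        return float(np.max(np.abs(self.pos[:, 2])) + L / 2)

    def bounding_radius(self, p: ModelParams) -> float:
        """Circumscribed-sphere radius about the reference point."""
        r = np.linalg.norm(self.pos, axis=1)
        return float(np.max(r) + np.sqrt(p.L**2 + p.D**2) / 2)


def make_conformation(label: str, p: ModelParams) -> Conformation:
    """Construct the reference folded or unfolded conformer.

    folded:   both axes +z, side by side along x at lateral contact, B ends
              aligned (tether distance = D < sigma).
    unfolded: collinear antiparallel along z with B-B distance 0; the inner
              cylinder ends are separated by the full tether range sigma
              and the total span is 2L + sigma.
    """
    if label == "folded":
        off = 0.5 * (p.D + _PAIR_GAP)
        pos = np.array([[-off, 0.0, 0.0], [off, 0.0, 0.0]])
        ax = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
    elif label == "unfolded":
        # B sites coincide at the origin; axes point away from it
        pos = np.array([[0.0, 0.0, -p.b_offset], [0.0, 0.0, p.b_offset]])
        ax = np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 1.0]])
    else:
        raise ValueError(f"unknown conformation label: {label!r}")
    conf = Conformation(label, pos, ax)
    dr = conf.pos[1] - conf.pos[0]
    if _kernels.cyl_overlap(dr, conf.ax[0], conf.ax[1], p.L, p.D, 1e-9):
        raise RuntimeError(f"{label} conformer self-overlaps")
    return conf


def excluded_volume_mc(conf_a: Conformation, conf_b: Conformation,
                       p: ModelParams,
                       alignment: str = "parallel_azimuth",
                       n_samples: int = 1_000_000,
                       rng: np.random.Generator | int = 0,
                       margin: float = 1.0) -> tuple[float, float]:
    """Pair excluded volume in nm^3 with its binomial standard error.

    A hit is any hard overlap between the two rigid conformers for a
    uniform random relative displacement inside a bounding box (plus the
    orientation averaging of ``alignment``).  The bounding box is sized
    from the conformer extents so that the outer 5% shell can contain no
    hits; this containment is asserted on the sample.
    """
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 1e4")
    if alignment not in _MODES:
        raise ValueError(f"alignment must be one of {sorted(_MODES)}")
    mode = _MODES[alignment]
    seed = rng if isinstance(rng, (int, np.integer)) else \
        int(rng.integers(2**31 - 1))
    if mode == 2:
        r = conf_a.bounding_radius(p) + conf_b.bounding_radius(p) + margin
        half = np.array([r, r, r])
    else:
        lat = conf_a.lateral_extent(p.D) + conf_b.lateral_extent(p.D) + margin
        axi = conf_a.axial_extent(p.L) + conf_b.axial_extent(p.L) + margin
        half = np.array([lat, lat, axi])
    half /= 0.95  # hits must stay out of the outer 5% shell
    hits, outer = _kernels.xv_hits(conf_a.pos, conf_a.ax, conf_b.pos,
                                   conf_b.ax, p.L, p.D, half,
                                   int(n_samples), int(seed) % (2**31 - 1),
                                   mode, 1e-9)
    if outer:
        raise RuntimeError(
            f"{outer} hits in the outer shell: bounding box too small")
    v_box = float(np.prod(2 * half))
    f = hits / n_samples
    v = v_box * f
    se = v_box * np.sqrt(max(f * (1 - f), 1.0 / n_samples) / n_samples)
    return v, se
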