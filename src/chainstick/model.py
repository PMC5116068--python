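"""Interaction energies of the chain-stick model.

Two terms only:

* an intramolecular tether constraint between the B sites of the two
  cylinders of one duplex -- zero energy if their distance is below the
  tether range sigma, infinite otherwise (a pure constraint, no restoring
  force: the single-stranded spacer is fully flexible);
* an intermolecular square well between A (blunt-end) sites of distinct
  cylinders -- depth u0 (in kT) inside range delta, zero outside.  The well
  is attractive: a bonded pair lowers the energy by ``beta_u0``.

Hard-core cylinder overlap makes the energy infinite (sentinel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import Box, Cylinder, ModelParams, minimum_image, site_positions

__all__ = [
    "GappedDuplex",
    "EnergyReport",
    "tether_ok",
    "pair_energy",
    "total_energy",
    "ab_bond_graph",
]

OVERLAP_SENTINEL = np.inf


@dataclass
class GappedDuplex:
    """An ordered pair of cylinders sharing the tether constraint."""

    cyl1: Cylinder
    cyl2: Cylinder
    id: int = 0


@dataclass
class EnergyReport:
    """System energy summary.

    ``total`` is ``-beta_u0 * n_ab_bonds`` when no constraint is violated
    and ``+inf`` otherwise, in which case ``first_violation`` names the
    offending cylinder pair (hard overlap) or duplex pair (tether).
    """

    total: float
    n_ab_bonds: int
    overlap_flag: bool
    first_violation: tuple[int, int] | None = None


def tether_ok(d: GappedDuplex, p: ModelParams, box: Box) -> bool:
    """True iff the minimum-image B-B distance of the duplex is < sigma."""
    _, b1 = site_positions(d.cyl1, p)
    _, b2 = site_positions(d.cyl2, p)
    dr = minimum_image(b2 - b1, box)
    return float(np.dot(dr, dr)) < p.sigma**2


def pair_energy(ci: Cylinder, cj: Cylinder, p: ModelParams, box: Box) -> float:
    """Pair energy of two distinct cylinders in kT.

    ``+inf`` if the hard cores overlap, ``-beta_u0`` if the A-A
    (blunt-end) separation is inside the square well, else 0.
    """
    ov, bd = _kernels._pair_state(
        np.ascontiguousarray(ci.com, dtype=np.float64),
        np.ascontiguousarray(ci.axis, dtype=np.float64),
        np.ascontiguousarray(cj.com, dtype=np.float64),
        np.ascontiguousarray(cj.axis, dtype=np.float64),
        np.ascontiguousarray(box.edges, dtype=np.float64),
        p.L,
        p.D,
        p.a_offset,
        p.delta,
        1e-9,
        True,
    )
    if ov:
        return OVERLAP_SENTINEL
    return -p.beta_u0 if bd else 0.0


def total_energy(state, p: ModelParams, include_intra: bool = True) -> EnergyReport:
    """Total energy over all unordered distinct-cylinder pairs.

    ``state`` is any object exposing ``pos`` (M, 3), ``ax`` (M, 3) and
    ``box`` (a :class:`~chainstick.geometry.Box`).  Tether violations and
    hard overlaps yield the ``+inf`` sentinel with the first violating pair
    reported.
    """
    ok, bi, bj, nb, _bonds = _kernels.full_scan(
        state.pos,
        state.ax,
        state.box.edges,
        p.L,
        p.D,
        p.a_offset,
        p.b_offset,
        p.sigma,
        p.delta,
        1e-9,
        True,
        True,
        True,
        include_intra,
    )
    if not ok:
        return EnergyReport(OVERLAP_SENTINEL, 0, True, (int(bi), int(bj)))
    return EnergyReport(-p.beta_u0 * nb, int(nb), False, None)


def ab_bond_graph(state, p: ModelParams) -> np.ndarray:
    """Partition of duplexes into clusters connected by A-A contacts.

    The two cylinders of one duplex always belong to the same cluster (the
    tether links them).  Returns an integer label per duplex; labels number
    the connected components consecutively from 0.
    """
    ok, bi, bj, _nb, bonds = _kernels.full_scan(
        state.pos,
        state.ax,
        state.box.edges,
        p.L,
        p.D,
        p.a_offset,
        p.b_offset,
        p.sigma,
        p.delta,
        1e-9,
        True,
        True,
        False,
        True,
    )
    if not ok:
        raise ValueError(f"hard overlap between cylinders {bi} and {bj}")
    ndup = state.pos.shape[0] // 2
    labels, _ncl = _kernels._cluster_labels(bonds, ndup)
    return np.asarray(labels)
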