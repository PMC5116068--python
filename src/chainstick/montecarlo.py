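"""Constant-pressure Metropolis Monte Carlo for chain-stick duplexes.

The sampler combines three move classes:

* single-cylinder moves -- a random displacement (uniform in a cube) or a
  small rotation about the cylinder's own B site (which leaves the tether
  distance untouched);
* rigid-duplex moves -- translation or rotation of a whole duplex about its
  centroid;
* anisotropic volume moves -- the box edges fluctuate independently along
  x, y and z with logarithmic edge proposals.  The scaling units are either
  whole duplexes or, in cluster mode, the connected components of the A-A
  bond graph: unit centroids are rescaled affinely while internal
  coordinates stay rigid, and a proposal that alters the bond graph is
  rejected outright so the cluster decomposition stays self-consistent.

Acceptance for a volume move along one axis is
``min(1, exp(-dU - beta_P dV + (N_units + 1) ln(V'/V)))``.

One sweep = N single-cylinder attempts + max(1, N//4) rigid-duplex
attempts + 3 volume attempts (one per axis).  The hot loop is compiled
(:mod:`chainstick._kernels`); the thin per-move functions in this module
mirror the same logic for direct unit testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels, observables
from .geometry import Box, Cylinder, ModelParams
from .model import EnergyReport, GappedDuplex, total_energy

__all__ = [
    "SystemState",
    "MCParams",
    "Trajectory",
    "build_crystal_config",
    "build_isotropic_config",
    "move_single_cylinder",
    "move_rigid_duplex",
    "move_volume_axis",
    "run_npt",
    "run_eos",
]


@dataclass
class SystemState:
    """N duplexes in an orthorhombic periodic box.

    Cylinder ``2d`` and ``2d+1`` belong to duplex ``d``.  ``pos`` and ``ax``
    have shape (2N, 3).
    """

    pos: np.ndarray
    ax: np.ndarray
    box: Box
    step: int = 0
    cached_energy: EnergyReport | None = None

    def __post_init__(self) -> None:
        self.pos = np.ascontiguousarray(self.pos, dtype=np.float64)
        self.ax = np.ascontiguousarray(self.ax, dtype=np.float64)
        if self.pos.shape != self.ax.shape or self.pos.shape[1] != 3:
            raise ValueError("pos and ax must both be (2N, 3)")
        if self.pos.shape[0] % 2:
            raise ValueError("cylinder count must be even")

    @property
    def n_duplexes(self) -> int:
        return self.pos.shape[0] // 2

    @property
    def n_cylinders(self) -> int:
        return self.pos.shape[0]

    def duplex(self, d: int, p: ModelParams) -> GappedDuplex:
        return GappedDuplex(
            Cylinder(self.pos[2 * d].copy(), self.ax[2 * d].copy(), p.L, p.D),
            Cylinder(self.pos[2 * d + 1].copy(), self.ax[2 * d + 1].copy(), p.L, p.D),
            id=d,
        )

    def copy(self) -> "SystemState":
        return SystemState(self.pos.copy(), self.ax.copy(),
                           Box(self.box.edges.copy()), self.step,
                           self.cached_energy)

    def wrap(self, p: ModelParams | None = None) -> None:
        """Wrap duplex centroids into the box and re-image cylinder 2 next
        to cylinder 1 (both operations shift cylinders by lattice vectors,
        so every minimum-image quantity is unchanged).

        The re-imaging keeps each duplex's unwrapped internal geometry
        equal to its minimum-image geometry, which the rigid-unit volume
        scaling relies on: a duplex straddling the boundary in unwrapped
        coordinates would otherwise be torn by an affine rescaling.
        """
        edges = self.box.edges
        for d in range(self.n_duplexes):
            if p is not None:
                b1 = self.pos[2 * d] - p.b_offset * self.ax[2 * d]
                b2 = self.pos[2 * d + 1] - p.b_offset * self.ax[2 * d + 1]
                self.pos[2 * d + 1] -= edges * np.round((b2 - b1) / edges)
            cen = 0.5 * (self.pos[2 * d] + self.pos[2 * d + 1])
            shift = -edges * np.floor(cen / edges)
            self.pos[2 * d] += shift
            self.pos[2 * d + 1] += shift


@dataclass
class MCParams:
    """Monte Carlo run parameters.

    ``beta_P`` is the pressure in kT/nm^3; use :meth:`from_beta_P_v0` to set
    the dimensionless pressure beta*P*v0 with v0 the single-cylinder volume.
    Move sizes are half-widths of the symmetric proposals.
    """

    beta_P: float = 0.01
    max_trans: float = 0.6
    max_rot: float = 0.5
    max_lnedge: float = 0.01
    n_equil: int = 10_000
    n_prod: int = 20_000
    sample_every: int = 50
    seed: int = 0
    cluster_volume_moves: bool = True
    hard_core: bool = True
    wells: bool = True
    tether: bool = True
    include_intra: bool = True
    volume_moves: bool = True
    autotune: bool = True
    recheck_every: int = 10_000

    @classmethod
    def from_beta_P_v0(cls, beta_P_v0: float, p: ModelParams, **kw) -> "MCParams":
        return cls(beta_P=beta_P_v0 / p.v0, **kw)

    def beta_P_v0(self, p: ModelParams) -> float:
        return self.beta_P * p.v0


@dataclass
class Trajectory:
    """Thinned snapshots plus per-snapshot observable records."""

    snap_pos: np.ndarray  # (S, 2N, 3)
    snap_ax: np.ndarray
    snap_box: np.ndarray  # (S, 3)
    records: pd.DataFrame
    params: ModelParams
    mc: MCParams
    acceptance: dict
    seed: int

    @property
    def n_snapshots(self) -> int:
        return self.snap_pos.shape[0]

    def state(self, i: int = -1) -> SystemState:
        return SystemState(self.snap_pos[i].copy(), self.snap_ax[i].copy(),
                           Box(self.snap_box[i].copy()))


# ---------------------------------------------------------------------------
# initial-configuration builders
# ---------------------------------------------------------------------------

_PAIR_GAP = 1e-3  # clearance between the two folded cylinders, nm
_LATTICE_GAP = 0.02  # clearance between lattice neighbours, nm


def _water_fill(mins: np.ndarray, volume: float) -> np.ndarray | None:
    """Edges e_i >= mins_i with prod(e) = volume, as equal as possible."""
    if volume < np.prod(mins) * (1 - 1e-12):
        return None
    edges = mins.astype(float).copy()
    free = np.ones(3, dtype=bool)
    for _ in range(3):
        rem = volume / np.prod(edges[~free]) if (~free).any() else volume
        e_eq = rem ** (1.0 / free.sum())
        if np.all(e_eq >= mins[free] - 1e-12):
            edges[free] = e_eq
            return edges
        # pin the most constraining axis at its minimum
        idx = np.argmax(np.where(free, mins, -np.inf))
        edges[idx] = mins[idx]
        free[idx] = False
        if not free.any():
            break
    if abs(np.prod(edges) - volume) / volume > 1e-9:
        return None
    return edges


def build_crystal_config(n: int, p: ModelParams,
                         target_packing: float = 0.55) -> SystemState:
    """Crystalline lattice of fully folded parallel duplexes.

    Every duplex is folded (theta_f = 0): its two cylinders sit side by side
    along x at lateral contact, axes along +z.  Duplexes occupy an
    nx x ny x nz grid whose spacings are inflated above hard contact to hit
    ``target_packing`` while keeping the box as close to cubic as the
    lattice allows.
    """
    if not 0 < target_packing < 0.78:
        raise ValueError("target packing must be in (0, 0.78)")
    v_target = 2 * n * p.v0 / target_packing
    mins_cell = np.array([2 * p.D + _LATTICE_GAP + _PAIR_GAP,
                          p.D + _LATTICE_GAP,
                          p.L + _LATTICE_GAP])
    best = None
    for nx in range(1, n + 1):
        if n % nx:
            continue
        for ny in range(1, n // nx + 1):
            if (n // nx) % ny:
                continue
            nz = n // (nx * ny)
            counts = np.array([nx, ny, nz], dtype=float)
            edges = _water_fill(counts * mins_cell, v_target)
            if edges is None:
                continue
            aspect = edges.max() / edges.min()
            if best is None or aspect < best[0]:
                best = (aspect, (nx, ny, nz), edges)
    if best is None:
        raise ValueError(
            f"target packing {target_packing} infeasible for n={n}")
    aspect, (nx, ny, nz), edges = best
    if not 0.8 <= 1.0 / aspect or aspect > 1.25:
        if aspect > 1.25:
            warnings.warn(
                f"crystal box aspect ratio {aspect:.2f} outside [0.8, 1.25] "
                f"for n={n} at packing {target_packing}", stacklevel=2)
    s = edges / np.array([nx, ny, nz])
    pos = np.empty((2 * n, 3))
    ax = np.empty((2 * n, 3))
    d = 0
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                cx = (ix + 0.5) * s[0]
                cy = (iy + 0.5) * s[1]
                cz = (iz + 0.5) * s[2]
                off = 0.5 * (p.D + _PAIR_GAP)
                pos[2 * d] = (cx - off, cy, cz)
                pos[2 * d + 1] = (cx + off, cy, cz)
                ax[2 * d] = (0.0, 0.0, 1.0)
                ax[2 * d + 1] = (0.0, 0.0, 1.0)
                d += 1
    state = SystemState(pos, ax, Box(edges))
    rep = total_energy(state, p)
    if not np.isfinite(rep.total):
        raise RuntimeError(
            f"crystal builder produced a violating pair {rep.first_violation}")
    state.cached_energy = rep
    return state


def build_isotropic_config(n: int, p: ModelParams,
                           target_concentration: float,
                           rng: np.random.Generator,
                           molar_mass: float = observables.M_DUPLEX_KG_MOL,
                           max_attempts: int = 100_000) -> SystemState:
    """Random sequential insertion of duplexes with uniform random axes.

    ``target_concentration`` is in mg/ml; the box is cubic.  Each duplex is
    inserted with a uniform random conformation satisfying the tether
    (second B site uniform in the sigma-ball of the first).
    """
    volume = observables.volume_for_concentration(n, target_concentration,
                                                  molar_mass)
    edge = volume ** (1.0 / 3.0)
    box = Box(np.array([edge, edge, edge]))
    pos = np.zeros((2 * n, 3))
    ax = np.zeros((2 * n, 3))
    for d in range(n):
        placed = False
        for _try in range(max_attempts):
            com1 = rng.random(3) * edge
            u1 = _random_unit(rng)
            b1 = com1 - p.b_offset * u1
            # uniform point in the sigma ball
            while True:
                v = rng.random(3) * 2 - 1
                if v @ v < 1.0:
                    break
            b2 = b1 + v * p.sigma
            u2 = _random_unit(rng)
            com2 = b2 + p.b_offset * u2
            dr = com2 - com1
            dr -= box.edges * np.round(dr / box.edges)
            if _kernels.cyl_overlap(dr, u1, u2, p.L, p.D, 1e-9):
                continue
            if _kernels.any_overlap(com1, u1, pos[: 2 * d], ax[: 2 * d],
                                    box.edges, p.L, p.D, 1e-9, True):
                continue
            if _kernels.any_overlap(com2, u2, pos[: 2 * d], ax[: 2 * d],
                                    box.edges, p.L, p.D, 1e-9, True):
                continue
            pos[2 * d] = com1
            pos[2 * d + 1] = com2
            ax[2 * d] = u1
            ax[2 * d + 1] = u2
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"insertion failed for duplex {d} after {max_attempts} tries")
    state = SystemState(pos, ax, box)
    rep = total_energy(state, p)
    if not np.isfinite(rep.total):
        raise RuntimeError("isotropic builder produced a violating state")
    state.cached_energy = rep
    return state


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n2 = v @ v
        if n2 > 1e-12:
            return v / np.sqrt(n2)


# ---------------------------------------------------------------------------
# single-move reference implementations (mirrors of the compiled loop)
# ---------------------------------------------------------------------------


def _env_of(state: SystemState, i: int, cand_p, cand_u, p: ModelParams,
            mc: MCParams, skip: int = -1):
    return _kernels._cyl_env(
        i, np.ascontiguousarray(cand_p), np.ascontiguousarray(cand_u),
        state.pos, state.ax, state.box.edges, p.L, p.D, p.a_offset, p.delta,
        1e-9, mc.hard_core, mc.wells, mc.include_intra, skip)


def move_single_cylinder(state: SystemState, i_duplex: int, which: int,
                         p: ModelParams, mc: MCParams,
                         rng: np.random.Generator) -> bool:
    """One Metropolis attempt on a single cylinder; True if accepted."""
    i = 2 * i_duplex + which
    partner = i ^ 1
    if rng.random() < 0.5:
        cand_p = state.pos[i] + (rng.random(3) * 2 - 1) * mc.max_trans
        cand_u = state.ax[i].copy()
        if mc.tether and not _kernels.tether_sat(
                cand_p, cand_u, state.pos[partner], state.ax[partner],
                state.box.edges, p.b_offset, p.sigma):
            return False
    else:
        nvec = _random_unit(rng)
        theta = (rng.random() * 2 - 1) * mc.max_rot
        cand_u = _kernels._rodrigues(state.ax[i], nvec, theta)
        cand_u /= np.linalg.norm(cand_u)
        bsite = state.pos[i] - p.b_offset * state.ax[i]
        cand_p = bsite + p.b_offset * cand_u
    nb_new, ov = _env_of(state, i, cand_p, cand_u, p, mc)
    if ov:
        return False
    if mc.wells:
        nb_old, _ = _kernels._cyl_env(
            i, state.pos[i], state.ax[i], state.pos, state.ax,
            state.box.edges, p.L, p.D, p.a_offset, p.delta, 1e-9,
            False, True, mc.include_intra, -1)
        dU = -p.beta_u0 * (nb_new - nb_old)
        if dU > 0 and rng.random() >= np.exp(-dU):
            return False
    state.pos[i] = cand_p
    state.ax[i] = cand_u
    state.cached_energy = None
    return True


def move_rigid_duplex(state: SystemState, i_duplex: int, p: ModelParams,
                      mc: MCParams, rng: np.random.Generator) -> bool:
    """Rigid translation or rotation of a whole duplex; True if accepted."""
    i0, i1 = 2 * i_duplex, 2 * i_duplex + 1
    if rng.random() < 0.5:
        shift = (rng.random(3) * 2 - 1) * mc.max_trans
        cand = (state.pos[i0] + shift, state.ax[i0].copy(),
                state.pos[i1] + shift, state.ax[i1].copy())
    else:
        nvec = _random_unit(rng)
        theta = (rng.random() * 2 - 1) * mc.max_rot
        cen = 0.5 * (state.pos[i0] + state.pos[i1])
        p0 = cen + _kernels._rodrigues(state.pos[i0] - cen, nvec, theta)
        p1 = cen + _kernels._rodrigues(state.pos[i1] - cen, nvec, theta)
        u0 = _kernels._rodrigues(state.ax[i0], nvec, theta)
        u1 = _kernels._rodrigues(state.ax[i1], nvec, theta)
        cand = (p0, u0 / np.linalg.norm(u0), p1, u1 / np.linalg.norm(u1))
    p0, u0, p1, u1 = cand
    dr = p1 - p0
    dr -= state.box.edges * np.round(dr / state.box.edges)
    if mc.hard_core and _kernels.cyl_overlap(
            np.ascontiguousarray(dr), np.ascontiguousarray(u0),
            np.ascontiguousarray(u1), p.L, p.D, 1e-9):
        return False
    nb0, ov0 = _env_of(state, i0, p0, u0, p, mc, skip=i1)
    if ov0:
        return False
    nb1, ov1 = _env_of(state, i1, p1, u1, p, mc, skip=i0)
    if ov1:
        return False
    if mc.wells:
        ob0, _ = _kernels._cyl_env(i0, state.pos[i0], state.ax[i0],
                                   state.pos, state.ax, state.box.edges,
                                   p.L, p.D, p.a_offset, p.delta, 1e-9,
                                   False, True, mc.include_intra, i1)
        ob1, _ = _kernels._cyl_env(i1, state.pos[i1], state.ax[i1],
                                   state.pos, state.ax, state.box.edges,
                                   p.L, p.D, p.a_offset, p.delta, 1e-9,
                                   False, True, mc.include_intra, i0)
        dU = -p.beta_u0 * ((nb0 + nb1) - (ob0 + ob1))
        if dU > 0 and rng.random() >= np.exp(-dU):
            return False
    state.pos[i0], state.ax[i0] = p0, u0
    state.pos[i1], state.ax[i1] = p1, u1
    state.cached_energy = None
    return True


def move_volume_axis(state: SystemState, axis: int, p: ModelParams,
                     mc: MCParams, rng: np.random.Generator) -> bool:
    """Logarithmic edge move along one box axis; True if accepted."""
    uln = (rng.random() * 2 - 1) * mc.max_lnedge
    f = np.exp(uln)
    ndup = state.n_duplexes
    edges = state.box.edges
    if edges[axis] * f < _edge_floor(p, mc):
        return False
    V_old = state.box.volume
    if mc.cluster_volume_moves and mc.wells:
        _ok, _i, _j, _nb, bonds_old = _kernels.full_scan(
            state.pos, state.ax, edges, p.L, p.D, p.a_offset, p.b_offset,
            p.sigma, p.delta, 1e-9, False, True, False, mc.include_intra)
        labels, ncl = _kernels._cluster_labels(bonds_old, ndup)
    else:
        bonds_old = np.empty(0, dtype=np.int64)
        labels, ncl = np.arange(ndup), ndup
    cent = np.zeros(ncl)
    cnt = np.zeros(ncl)
    for d in range(ndup):
        cent[labels[d]] += 0.5 * (state.pos[2 * d, axis]
                                  + state.pos[2 * d + 1, axis])
        cnt[labels[d]] += 1
    cent /= cnt
    new_pos = state.pos.copy()
    for d in range(ndup):
        shift = cent[labels[d]] * (f - 1)
        new_pos[2 * d, axis] += shift
        new_pos[2 * d + 1, axis] += shift
    new_edges = edges.copy()
    new_edges[axis] *= f
    nb_cur = (state.cached_energy.n_ab_bonds
              if state.cached_energy is not None else
              _kernels.full_scan(state.pos, state.ax, edges, p.L, p.D,
                                 p.a_offset, p.b_offset, p.sigma, p.delta,
                                 1e-9, False, True, False,
                                 mc.include_intra)[3])
    ok, _i, _j, nb_new, bonds_new = _kernels.full_scan(
        new_pos, state.ax, new_edges, p.L, p.D, p.a_offset, p.b_offset,
        p.sigma, p.delta, 1e-9, mc.hard_core, mc.wells, False,
        mc.include_intra)
    if not ok:
        return False
    if mc.cluster_volume_moves and mc.wells:
        if (bonds_new.shape[0] != bonds_old.shape[0]
                or not np.array_equal(np.sort(bonds_new), np.sort(bonds_old))):
            return False
        dU = 0.0
    else:
        dU = -p.beta_u0 * (nb_new - nb_cur) if mc.wells else 0.0
    V_new = V_old * f
    arg = -dU - mc.beta_P * (V_new - V_old) + (ncl + 1) * uln
    if arg < 0 and rng.random() >= np.exp(arg):
        return False
    state.pos[:] = new_pos
    state.box.edges[:] = new_edges
    state.cached_energy = None
    return True


# ---------------------------------------------------------------------------
# production driver
# ---------------------------------------------------------------------------


def _edge_floor(p: ModelParams, mc: MCParams) -> float:
    """Smallest box edge for which nearest-image-only scans are exact.

    Hard cylinders can touch out to sqrt(L^2 + D^2) centre distance, so an
    edge of at least twice that keeps every pair's hard interaction
    confined to a single periodic image.  The short-ranged site wells and
    the tether cannot double-count images in any box larger than twice
    their own range, so no floor is needed without hard cores (and adding
    one would bias the shape ensemble of the floor-hugging ideal gas).
    """
    if mc.hard_core:
        return 2.0 * np.sqrt(p.L**2 + p.D**2)
    return 0.0


def _kernel_args(p: ModelParams, mc: MCParams, n_dup: int):
    return dict(
        L=p.L, D=p.D, a_off=p.a_offset, b_off=p.b_offset, sigma=p.sigma,
        delta=p.delta, u0=p.beta_u0, tol=1e-9, beta_P=mc.beta_P,
        n_single=n_dup, n_duplex=max(1, n_dup // 4),
        n_volume=3 if mc.volume_moves else 0,
        cluster_moves=mc.cluster_volume_moves,
        hard_on=mc.hard_core, wells_on=mc.wells, tether_on=mc.tether,
        include_intra=mc.include_intra, edge_floor=_edge_floor(p, mc))


def _run_chunk(state: SystemState, p: ModelParams, mc: MCParams,
               n_sweeps: int, seed: int, sample_every: int,
               n_bonds: int, acc: np.ndarray):
    n_samp = n_sweeps // sample_every if sample_every > 0 else 0
    M = state.n_cylinders
    snap_pos = np.empty((n_samp, M, 3))
    snap_ax = np.empty((n_samp, M, 3))
    snap_box = np.empty((n_samp, 3))
    snap_stats = np.empty((n_samp, 3))
    kw = _kernel_args(p, mc, state.n_duplexes)
    n_bonds = _kernels.run_sweeps(
        state.pos, state.ax, state.box.edges, n_sweeps, seed,
        kw["L"], kw["D"], kw["a_off"], kw["b_off"], kw["sigma"], kw["delta"],
        kw["u0"], kw["tol"], kw["beta_P"], mc.max_trans, mc.max_rot,
        mc.max_lnedge, kw["n_single"], kw["n_duplex"], kw["n_volume"],
        kw["cluster_moves"], kw["hard_on"], kw["wells_on"], kw["tether_on"],
        kw["include_intra"], kw["edge_floor"], n_bonds,
        sample_every if sample_every > 0 else 0,
        snap_pos, snap_ax, snap_box, snap_stats, acc)
    return int(n_bonds), snap_pos, snap_ax, snap_box, snap_stats


def _recheck(state: SystemState, p: ModelParams, mc: MCParams,
             n_bonds: int) -> None:
    rep = total_energy(state, p, include_intra=mc.include_intra)
    if mc.hard_core or mc.tether:
        if not np.isfinite(rep.total) and mc.hard_core and mc.tether:
            raise RuntimeError(
                f"consistency recheck failed: violation at {rep.first_violation}")
    if mc.wells and rep.n_ab_bonds != n_bonds and np.isfinite(rep.total):
        raise RuntimeError(
            f"bond bookkeeping drifted: cached {n_bonds}, "
            f"recomputed {rep.n_ab_bonds}")


def _chunk_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def run_npt(initial: SystemState, p: ModelParams, mc: MCParams,
            molar_mass: float = observables.M_DUPLEX_KG_MOL,
            progress: bool = False) -> Trajectory:
    """Equilibrate then sample an NPT trajectory.

    Move sizes are autotuned toward ~35% acceptance during equilibration
    (frozen in production).  A full consistency recheck (energy recompute
    and constraint scan) runs every ``mc.recheck_every`` sweeps and aborts
    on any drift.  The run is reproducible from ``mc.seed``.
    """
    state = initial.copy()
    mc = replace(mc)  # private copy: autotune mutates move sizes
    rep = total_energy(state, p, include_intra=mc.include_intra)
    if mc.hard_core and mc.tether and not np.isfinite(rep.total):
        raise ValueError(f"initial state invalid at {rep.first_violation}")
    floor = _edge_floor(p, mc)
    if float(state.box.edges.min()) < floor:
        raise ValueError(
            f"box edge {state.box.edges.min():.2f} nm below the "
            f"minimum-image validity floor {floor:.2f} nm; use more "
            f"particles or a lower packing")
    n_bonds = rep.n_ab_bonds if mc.wells else 0

    chunk = max(1, min(mc.recheck_every,
                       max(mc.n_equil // 10, mc.sample_every)))
    seeds = _chunk_seeds(mc.seed, 200)
    iseed = 0
    acc = np.zeros((3, 2), dtype=np.int64)

    # ---- equilibration ---------------------------------------------------
    done = 0
    while done < mc.n_equil:
        n = min(chunk, mc.n_equil - done)
        acc_chunk = np.zeros((3, 2), dtype=np.int64)
        n_bonds, *_ = _run_chunk(state, p, mc, n, seeds[iseed], 0,
                                 n_bonds, acc_chunk)
        iseed += 1
        done += n
        state.wrap(p)
        _recheck(state, p, mc, n_bonds)
        if mc.autotune:
            _tune(mc, acc_chunk, state)
        if progress:
            print(f"equil {done}/{mc.n_equil} sweeps; "
                  f"V={state.box.volume:.0f} nm^3")
    # ---- production ------------------------------------------------------
    all_pos, all_ax, all_box, all_stats = [], [], [], []
    done = 0
    while done < mc.n_prod:
        n = min(chunk, mc.n_prod - done)
        n_bonds, sp, sa, sb, st = _run_chunk(
            state, p, mc, n, seeds[iseed], mc.sample_every, n_bonds, acc)
        iseed += 1
        st[:, 0] += done  # sweep offset
        done += n
        all_pos.append(sp)
        all_ax.append(sa)
        all_box.append(sb)
        all_stats.append(st)
        state.wrap(p)
        _recheck(state, p, mc, n_bonds)
        if progress:
            print(f"prod {done}/{mc.n_prod} sweeps; "
                  f"V={state.box.volume:.0f} nm^3, bonds={n_bonds}")
    snap_pos = np.concatenate(all_pos) if all_pos else np.empty((0, state.n_cylinders, 3))
    snap_ax = np.concatenate(all_ax) if all_ax else np.empty((0, state.n_cylinders, 3))
    snap_box = np.concatenate(all_box) if all_box else np.empty((0, 3))
    snap_stats = np.concatenate(all_stats) if all_stats else np.empty((0, 3))

    records = _make_records(snap_pos, snap_ax, snap_box, snap_stats, p, mc,
                            molar_mass)
    att = acc[:, 0].astype(float)
    att[att == 0] = 1
    acceptance = {
        "single": float(acc[0, 1] / att[0]),
        "duplex": float(acc[1, 1] / att[1]),
        "volume": float(acc[2, 1] / att[2]),
    }
    return Trajectory(snap_pos, snap_ax, snap_box, records, p, mc,
                      acceptance, mc.seed)


def _tune(mc: MCParams, acc: np.ndarray, state: SystemState,
          target: float = 0.35) -> None:
    for row, attr, lim in ((0, "max_trans", state.box.edges.min() / 4),
                           (1, "max_trans", None),
                           (2, "max_lnedge", 0.05)):
        if row == 1:
            continue  # single and duplex moves share max_trans/max_rot
        if acc[row, 0] == 0:
            continue
        rate = acc[row, 1] / acc[row, 0]
        f = np.clip(rate / target, 0.5, 2.0)
        val = getattr(mc, attr) * f
        if lim is not None:
            val = min(val, lim)
        setattr(mc, attr, max(val, 1e-4))
    if acc[0, 0] > 0:
        rate = acc[0, 1] / acc[0, 0]
        f = np.clip(rate / target, 0.5, 2.0)
        mc.max_rot = float(np.clip(mc.max_rot * f, 1e-3, np.pi))


def _make_records(snap_pos, snap_ax, snap_box, snap_stats, p, mc,
                  molar_mass) -> pd.DataFrame:
    rows = []
    ndup = snap_pos.shape[1] // 2 if snap_pos.size else 0
    for s in range(snap_pos.shape[0]):
        box = Box(snap_box[s].copy())
        V = box.volume
        axes = snap_ax[s]
        S, director = observables.nematic_order(axes)
        eta = observables.folding_fraction_axes(axes)
        cent = 0.5 * (snap_pos[s, 0::2] + snap_pos[s, 1::2])
        d_layer = observables.smectic_spacing_centroids(cent, box, director)
        rows.append({
            "step": int(snap_stats[s, 0]),
            "V": V,
            "c_mg_ml": observables.concentration_from_volume(
                ndup, V, molar_mass),
            "betaPv0": mc.beta_P * p.v0,
            "U_kT": -p.beta_u0 * snap_stats[s, 2] if mc.wells else 0.0,
            "n_bonds": int(snap_stats[s, 2]),
            "S": S,
            "eta_f": eta,
            "d_layer": d_layer if d_layer is not None else np.nan,
        })
    return pd.DataFrame(rows)


def run_eos(n: int, p: ModelParams, schedule: list[float], mc: MCParams,
            start: str = "crystal", target_packing: float = 0.55,
            start_concentration: float = 30.0,
            molar_mass: float = observables.M_DUPLEX_KG_MOL,
            progress: bool = False) -> list[Trajectory]:
    """Scan a pressure schedule, chaining final states between points.

    ``schedule`` lists dimensionless pressures beta*P*v0.  The first state
    point starts from the requested builder; each subsequent one continues
    from the previous final configuration, as in a stepwise compression or
    expansion experiment.
    """
    if start == "crystal":
        state = build_crystal_config(n, p, target_packing)
    elif start == "isotropic":
        rng = np.random.default_rng(mc.seed)
        state = build_isotropic_config(n, p, start_concentration, rng,
                                       molar_mass)
    else:
        raise ValueError("start must be 'crystal' or 'isotropic'")
    out = []
    for i, bpv in enumerate(schedule):
        mci = replace(mc, beta_P=bpv / p.v0, seed=mc.seed + i)
        traj = run_npt(state, p, mci, molar_mass, progress=progress)
        out.append(traj)
        state = traj.state(-1)
    return out
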