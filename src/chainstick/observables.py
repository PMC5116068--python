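"""Order parameters and structural diagnostics for chain-stick trajectories.

* nematic order parameter S from the Q tensor over cylinder axes;
* folding fraction eta_f: duplexes whose two B->A axes enclose < 45 deg;
* director-frame 3D pair correlations g(0,y,z) and g(x,y,0) on duplex
  centroids;
* smectic layer spacing from the box-commensurate 1D structure factor;
* DNA mass concentration and the equation of state with block-bootstrap
  errors and heuristic phase labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .geometry import Box

__all__ = [
    "M_DUPLEX_KG_MOL",
    "ObservableRecord",
    "PairDistributionGrid",
    "nematic_order",
    "folding_fraction",
    "folding_fraction_axes",
    "pair_distribution_plane",
    "smectic_spacing",
    "smectic_spacing_centroids",
    "concentration",
    "concentration_from_volume",
    "volume_for_concentration",
    "equation_of_state",
    "in_plane_crystalline",
]

#: Molar mass of one gapped duplex in kg/mol: 212 nucleotides (2 x 48 bp
#: paired + 20 unpaired) at ~310 g/mol each.
M_DUPLEX_KG_MOL = 65.7

FOLD_THRESHOLD_DEG = 45.0


@dataclass
class ObservableRecord:
    """Per-snapshot scalar observables."""

    step: int
    volume: float
    concentration: float
    betaPv0: float
    S: float
    eta_f: float
    d_layer: float | None = None


@dataclass
class PairDistributionGrid:
    """A 2D slice of the 3D pair-distribution function in the director frame."""

    plane: str  # "0yz" or "xy0"
    edges1: np.ndarray
    edges2: np.ndarray
    g: np.ndarray

    def far_field_mean(self, fraction: float = 0.1) -> float:
        """Mean of g over the outermost ``fraction`` of bins (fluid check)."""
        n1, n2 = self.g.shape
        k1 = max(1, int(np.ceil(n1 * fraction / 2)))
        k2 = max(1, int(np.ceil(n2 * fraction / 2)))
        mask = np.zeros_like(self.g, dtype=bool)
        mask[:k1, :] = mask[-k1:, :] = True
        mask[:, :k2] = mask[:, -k2:] = True
        return float(np.nanmean(self.g[mask]))


def nematic_order(axes: np.ndarray, mode: str = "cylinders"
                  ) -> tuple[float, np.ndarray]:
    """Nematic order parameter and director.

    S is the largest eigenvalue of Q = (3 <u u> - I) / 2 over the supplied
    unit vectors; the sign of each axis is irrelevant (headless symmetry).
    ``axes`` is (M, 3).  With ``mode="duplexes"`` consecutive pairs of rows
    are combined into per-duplex bisector axes before the average.
    """
    u = np.asarray(axes, dtype=float)
    if u.ndim != 2 or u.shape[1] != 3 or u.shape[0] < 2:
        raise ValueError("need at least two 3-vectors")
    if mode == "duplexes":
        if u.shape[0] % 2:
            raise ValueError("duplex mode needs an even number of axes")
        b = u[0::2] + u[1::2]
        norms = np.linalg.norm(b, axis=1)
        good = norms > 1e-9
        u = b[good] / norms[good, None]
        if u.shape[0] < 2:
            raise ValueError("degenerate duplex axes")
    elif mode != "cylinders":
        raise ValueError("mode must be 'cylinders' or 'duplexes'")
    Q = 1.5 * (u.T @ u) / u.shape[0] - 0.5 * np.eye(3)
    w, v = np.linalg.eigh(Q)
    return float(w[-1]), v[:, -1].copy()


def folding_fraction_axes(axes: np.ndarray) -> float:
    """eta_f from an (2N, 3) array of cylinder axes (duplex = row pair)."""
    u1 = axes[0::2]
    u2 = axes[1::2]
    cosang = np.clip(np.einsum("ij,ij->i", u1, u2), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    return float(np.mean(theta < FOLD_THRESHOLD_DEG))


def folding_fraction(state) -> float:
    """Fraction of duplexes with folding angle theta_f < 45 deg."""
    return folding_fraction_axes(state.ax)


def _director_frame(director: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame (e1, e2, e3) with e3 = director."""
    e3 = np.asarray(director, dtype=float)
    e3 = e3 / np.linalg.norm(e3)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(e3 @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ e3) * e3
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    return np.vstack([e1, e2, e3])


def pair_distribution_plane(state, plane: str = "0yz",
                            bin_width: float = 1.0,
                            director: np.ndarray | None = None,
                            extent: float | None = None
                            ) -> PairDistributionGrid:
    """Planar slice of g(r) on duplex centroids in the director frame.

    ``plane="0yz"`` restricts pairs to a slab |x'| < bin_width around the
    plane containing the director (correlations along the director show the
    smectic layering); ``plane="xy0"`` slices perpendicular to the director
    (in-plane order).  Values are normalized by the ideal-gas expectation
    per bin, so g -> 1 at large separation in a fluid.
    """
    import warnings

    pos, box = state.pos, state.box
    cent = 0.5 * (pos[0::2] + pos[1::2])
    n = cent.shape[0]
    if director is None:
        S, director = nematic_order(state.ax)
        if S < 0.1:
            warnings.warn("director is degenerate (S < 0.1); "
                          "frame orientation is arbitrary", stacklevel=2)
    frame = _director_frame(director)
    dr = cent[None, :, :] - cent[:, None, :]
    dr = dr.reshape(-1, 3)
    dr = dr - box.edges * np.round(dr / box.edges)
    keep = np.any(dr != 0, axis=1)  # drop self pairs
    dr = dr[keep]
    proj = dr @ frame.T  # columns: x', y', z' (z' along director)
    if extent is None:
        extent = float(box.edges.min()) / 2
    nbins = max(2, int(np.floor(2 * extent / bin_width)))
    edges = np.linspace(-nbins * bin_width / 2, nbins * bin_width / 2,
                        nbins + 1)
    if plane == "0yz":
        slab = np.abs(proj[:, 0]) < bin_width
        c1, c2 = proj[slab, 1], proj[slab, 2]
    elif plane == "xy0":
        slab = np.abs(proj[:, 2]) < bin_width
        c1, c2 = proj[slab, 0], proj[slab, 1]
    else:
        raise ValueError("plane must be '0yz' or 'xy0'")
    H, e1, e2 = np.histogram2d(c1, c2, bins=[edges, edges])
    v_cell = (2 * bin_width) * bin_width * bin_width
    expected = n * (n - 1) / box.volume * v_cell
    return PairDistributionGrid(plane, e1, e2, H / expected)


def smectic_spacing_centroids(cent: np.ndarray, box: Box,
                              director: np.ndarray,
                              min_spacing: float = 4.0,
                              peak_factor: float = 5.0) -> float | None:
    """Layer spacing d = 2 pi / q* from the 1D structure factor.

    Wavevectors are restricted to box-commensurate q = 2 pi k / L along the
    box axis best aligned with the director (no PBC leakage).  Returns None
    when the largest peak does not stand out of the background spectrum:
    the background is estimated by the *median* of the remaining S(q)
    values (a true layer lattice puts coherent weight into several
    harmonics, so a mean would be contaminated), with a small extreme-value
    floor so that the maximum of ~kmax exponentially distributed
    ideal-gas values does not trigger a false detection.
    """
    axis = int(np.argmax(np.abs(director)))
    Laxis = float(box.edges[axis])
    z = cent[:, axis]
    kmax = max(2, int(np.floor(Laxis / min_spacing)))
    ks = np.arange(1, kmax + 1)
    q = 2 * np.pi * ks / Laxis
    phases = np.exp(1j * q[:, None] * z[None, :])
    Sq = np.abs(phases.sum(axis=1)) ** 2 / cent.shape[0]
    # a sharp layer lattice feeds several harmonics almost equally: prefer
    # the fundamental (smallest k) among near-maximal peaks
    near_max = np.nonzero(Sq >= 0.8 * Sq.max())[0]
    ipk = int(near_max[0])
    rest = np.delete(Sq, ipk)
    if rest.size == 0:
        return None
    threshold = (peak_factor * max(float(np.median(rest)), 1.0)
                 + 2.0 * np.log(kmax))
    if Sq[ipk] < threshold:
        return None
    return float(2 * np.pi / q[ipk])


def smectic_spacing(state, director: np.ndarray | None = None,
                    min_spacing: float = 4.0,
                    peak_factor: float = 5.0) -> float | None:
    """Layer spacing of a configuration, or None if not layered."""
    if director is None:
        _, director = nematic_order(state.ax)
    cent = 0.5 * (state.pos[0::2] + state.pos[1::2])
    return smectic_spacing_centroids(cent, state.box, director,
                                     min_spacing, peak_factor)


# 1 nm^3 = 1e-21 ml; M in kg/mol = 1e6 mg/mol
_MG_PER_ML = 1e6 / (Avogadro * 1e-21)


def concentration_from_volume(n: int, volume_nm3: float,
                              molar_mass: float = M_DUPLEX_KG_MOL) -> float:
    """DNA mass concentration in mg/ml: c = N M / (N_A V)."""
    if volume_nm3 <= 0:
        raise ValueError("volume must be positive")
    return n * molar_mass * _MG_PER_ML / volume_nm3


def concentration(state, molar_mass: float = M_DUPLEX_KG_MOL) -> float:
    """Concentration of a configuration in mg/ml."""
    return concentration_from_volume(state.n_duplexes, state.box.volume,
                                     molar_mass)


def volume_for_concentration(n: int, c_mg_ml: float,
                             molar_mass: float = M_DUPLEX_KG_MOL) -> float:
    """Box volume in nm^3 holding n duplexes at concentration c (mg/ml)."""
    if c_mg_ml <= 0:
        raise ValueError("concentration must be positive")
    return n * molar_mass * _MG_PER_ML / c_mg_ml


def in_plane_crystalline(state, director: np.ndarray | None = None,
                         peak_factor: float = 5.0,
                         min_spacing: float = 2.0) -> bool:
    """Heuristic in-plane crystal flag: >= 3 sharp harmonics in the 2D
    in-plane structure factor of duplex centroids."""
    if director is None:
        _, director = nematic_order(state.ax)
    axis = int(np.argmax(np.abs(director)))
    inplane = [a for a in range(3) if a != axis]
    cent = 0.5 * (state.pos[0::2] + state.pos[1::2])
    n = cent.shape[0]
    sharp = 0
    vals = []
    for a in inplane:
        La = float(state.box.edges[a])
        kmax = max(2, int(np.floor(La / min_spacing)))
        ks = np.arange(1, kmax + 1)
        q = 2 * np.pi * ks / La
        Sq = np.abs(np.exp(1j * q[:, None] * cent[None, :, a])
                    .sum(axis=1)) ** 2 / n
        vals.append(Sq)
    allv = np.concatenate(vals)
    mean = allv.mean()
    sharp = int(np.sum(allv > peak_factor * max(mean, 1.0)))
    return sharp >= 3


def equation_of_state(trajectories, n_blocks: int = 10, n_boot: int = 200,
                      seed: int = 0) -> pd.DataFrame:
    """Per-pressure averages with block-bootstrap standard errors.

    Takes the trajectories of an NPT pressure scan and returns one row per
    state point: mean concentration (with SE), nematic order, folding
    fraction, layer spacing, and a heuristic phase label -- I for S < 0.3,
    Sm-fA for ordered and layered states, K when the in-plane structure is
    also crystalline.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for traj in trajectories:
        rec = traj.records
        if len(rec) == 0:
            raise ValueError("trajectory has no production samples")
        c = rec["c_mg_ml"].to_numpy()
        nb = min(n_blocks, len(c))
        blocks = np.array_split(c, nb)
        bmeans = np.array([b.mean() for b in blocks])
        boot = rng.choice(bmeans, size=(n_boot, nb), replace=True).mean(axis=1)
        c_se = float(boot.std(ddof=1))
        S_mean = float(rec["S"].mean())
        eta_mean = float(rec["eta_f"].mean())
        d_vals = rec["d_layer"].dropna()
        layered = len(d_vals) >= len(rec) / 2
        d_layer = float(d_vals.median()) if layered else np.nan
        if S_mean < 0.3:
            phase = "I"
        else:
            phase = "Sm-fA" if layered else "N"
            if layered and in_plane_crystalline(traj.state(-1)):
                phase = "K"
        rows.append({
            "betaPv0": float(rec["betaPv0"].iloc[0]),
            "c_mean": float(c.mean()),
            "c_se": c_se,
            "S_mean": S_mean,
            "eta_f_mean": eta_mean,
            "d_layer": d_layer,
            "phase": phase,
        })
    return pd.DataFrame(rows)
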