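import numpy as np
import pytest

from chainstick.geometry import Box, Cylinder, ModelParams


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def open_box() -> Box:
    """A box so large that periodic images never matter."""
    return Box(np.array([1e6, 1e6, 1e6]))


def random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_cylinder(com, axis, p: ModelParams) -> Cylinder:
    return Cylinder(np.asarray(com, float), np.asarray(axis, float), p.L, p.D)


def cylinder_point_cloud(p: ModelParams, rng: np.random.Generator,
                         n: int) -> np.ndarray:
    """Uniform random points inside a reference cylinder (axis +z, origin)."""
    z = rng.uniform(-p.L / 2, p.L / 2, n)
    th = rng.uniform(0, 2 * np.pi, n)
    r = p.D / 2 * np.sqrt(rng.uniform(0, 1, n))
    return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)


def frame_of(u: np.ndarray) -> np.ndarray:
    """Orthonormal frame with third column u."""
    ref = np.array([1.0, 0, 0]) if abs(u[0]) < 0.9 else np.array([0.0, 1, 0])
    e1 = ref - (ref @ u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return np.stack([e1, e2, u], axis=1)


def overlap_fraction_oracle(points_local: np.ndarray, dr, u1, u2,
                            p: ModelParams) -> float:
    """Fraction of points of cylinder 1 (sampled in its local frame) that
    fall inside cylinder 2 at dr with axis u2 -- the independent
    point-sampling referee for the overlap kernel."""
    pts = points_local @ frame_of(np.asarray(u1, float)).T
    rel = pts - np.asarray(dr, float)
    z2 = rel @ np.asarray(u2, float)
    perp = rel - np.outer(z2, u2)
    inside = (np.abs(z2) <= p.L / 2) & ((perp**2).sum(1) <= (p.D / 2) ** 2)
    return float(inside.mean())
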