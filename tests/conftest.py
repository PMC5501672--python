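"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths: the probe
radius oracle is an exhaustive in-plane grid search with exact min-distance
evaluation, and the superposition oracle is Horn's quaternion
eigen-decomposition.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from porexlink.structure_io import RadiusTable, SegmentMap
from porexlink.synthetic_data import (
    ChannelSpec,
    channel_segment_map,
    default_channel_spec,
    make_channel,
    make_ring_channel,
)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def grid_slice_oracle(
    coords: np.ndarray,
    radii: np.ndarray,
    center: np.ndarray,
    normal: np.ndarray,
    extent: float = 4.0,
    step: float = 0.05,
) -> float:
    """Exhaustive in-plane grid search for the largest probe sphere.

    Evaluates min_i(|p - x_i| - r_i) on a square grid of spacing ``step``
    within ``extent`` of ``center`` in the plane through ``center`` with the
    given normal, and returns the maximum.  Exact nearest-atom evaluation via
    a KD-tree with a radii-spread safety margin.
    """
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)

    g = np.arange(-extent, extent + 0.5 * step, step)
    gx, gy = np.meshgrid(g, g)
    pts = center[None, :] + gx.ravel()[:, None] * u[None, :] + gy.ravel()[:, None] * v[None, :]

    tree = cKDTree(coords)
    r_max, r_spread = radii.max(), radii.max() - radii.min()
    k = min(16, len(coords))
    dist, idx = tree.query(pts, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    vals = (dist - radii[idx]).min(axis=1)
    # atoms outside the k nearest cannot beat the k-th distance minus the
    # largest radius; where they could, redo those points exactly
    unsafe = dist[:, -1] - r_max < vals
    if np.any(unsafe) and k < len(coords):
        for j in np.flatnonzero(unsafe):
            d_all = np.linalg.norm(coords - pts[j], axis=1) - radii
            vals[j] = d_all.min()
    return float(vals.max())


def quaternion_superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Horn's closed-form quaternion solution for the optimal-fit RMSD."""
    A = np.asarray(mobile, float)
    B = np.asarray(target, float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    M = Ac.T @ Bc
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, vec = np.linalg.eigh(K)
    q = vec[:, -1]  # quaternion of the optimal rotation
    q0, q1, q2, q3 = q
    R = np.array(
        [
            [q0**2 + q1**2 - q2**2 - q3**2, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), q0**2 - q1**2 + q2**2 - q3**2, 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0**2 - q1**2 - q2**2 + q3**2],
        ]
    )
    resid = Ac @ R.T - Bc
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def random_proper_rotation(rng: np.random.Generator) -> np.ndarray:
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


# --------------------------------------------------------------------------
# shared synthetic structures (session-scoped: built once)
# --------------------------------------------------------------------------

HOURGLASS_CP = [(-10.0, 6.35), (0.0, 4.35), (10.0, 6.35)]
CYLINDER_CP = [(-10.0, 4.5), (10.0, 4.5)]


@pytest.fixture(scope="session")
def channel_spec() -> ChannelSpec:
    return default_channel_spec()


@pytest.fixture(scope="session")
def open_channel(channel_spec):
    return make_channel(channel_spec, "open")


@pytest.fixture(scope="session")
def closed_channel(channel_spec):
    return make_channel(channel_spec, "closed")


@pytest.fixture(scope="session")
def channel_segments(channel_spec) -> SegmentMap:
    return channel_segment_map(channel_spec)


@pytest.fixture(scope="session")
def ring_segments() -> SegmentMap:
    return SegmentMap(segments={"membrane": [("R", 1, 41)]}, membrane_z=(-8.0, 8.0))


@pytest.fixture(scope="session")
def hourglass_rings():
    return make_ring_channel(HOURGLASS_CP, -10.0, 10.0)


@pytest.fixture(scope="session")
def cylinder_rings():
    return make_ring_channel(CYLINDER_CP, -10.0, 10.0)


@pytest.fixture(scope="session")
def radius_table() -> RadiusTable:
    return RadiusTable()
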