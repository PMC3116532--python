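"""Shared rigid-body geometry helpers (principal axes, axis rotations)."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit dominant direction of a point cloud (largest-variance axis).

    Sign is arbitrary; callers disambiguate (see ``oriented_axis``).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need >= 2 points for a principal axis")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    if w[-1] <= 0:
        raise ValueError("degenerate point cloud (zero extent)")
    return axis / np.linalg.norm(axis)


def oriented_axis(points: np.ndarray, away_from: np.ndarray) -> np.ndarray:
    """Principal axis oriented to point away from a reference position.

    The axis sign is chosen so that it runs from the end of the cloud
    nearest ``away_from`` toward the far end — i.e. outward from a hinge.
    """
    pts = np.asarray(points, dtype=float)
    axis = principal_axis(pts)
    center = pts.mean(axis=0)
    if np.dot(np.asarray(away_from) - center, axis) > 0:
        axis = -axis
    return axis


def rotate_about_axis(coords: np.ndarray, pivot: np.ndarray,
                      axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate points about the line through ``pivot`` along ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("degenerate rotation axis")
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n)
    return rot.apply(np.asarray(coords, dtype=float) - pivot) + pivot


def random_rotation(rng: np.random.Generator) -> Rotation:
    """Uniform random rotation (for test fixtures and invariance checks)."""
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
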