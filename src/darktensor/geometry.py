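"""Acquisition geometry: circular pose trajectories about a volume element.

Each trajectory models a tomographic scan with the sample mounted in one
orientation: the optical axis n_hat orbits a fixed rotation axis pointing at
the volume element, while the sensitivity axis e_hat stays tangential to the
orbit (grating bars parallel to the rotation axis).  The full scheme uses 13
trajectories -- about the 3 coordinate axes, the 6 face diagonals and the 4
space diagonals (one representative per antipodal pair) -- each sampled at 29
equidistant angles, for 377 distinct (n_hat, e_hat) combinations.  The
reduced scheme keeps only the 3 coordinate-axis trajectories (87 poses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward_model import Pose

_SQ2 = np.sqrt(2.0)
_SQ3 = np.sqrt(3.0)

#: Trajectory axes in spec order: coordinate axes, face diagonals, space diagonals.
COORDINATE_AXES = np.eye(3)
FACE_DIAGONALS = (
    np.array(
        [[1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1], [0, 1, 1], [0, 1, -1]],
        dtype=float,
    )
    / _SQ2
)
SPACE_DIAGONALS = (
    np.array([[1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1]], dtype=float) / _SQ3
)


def _in_plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # u: normalized rejection of the coordinate axis least aligned with `axis`
    # (ties broken by lowest index); v completes the right-handed triple.
    pick = int(np.argmin(np.abs(axis)))
    e_c = np.zeros(3)
    e_c[pick] = 1.0
    u = e_c - (e_c @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


@dataclass(frozen=True)
class Trajectory:
    """Circular orbit of poses about ``axis``."""

    axis: np.ndarray
    n_hat: np.ndarray  # (m, 3)
    e_hat: np.ndarray  # (m, 3)

    def __len__(self) -> int:
        return len(self.n_hat)

    @property
    def poses(self) -> list[Pose]:
        return [Pose(n, e) for n, e in zip(self.n_hat, self.e_hat)]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Concatenated trajectories: parallel arrays of poses and trajectory ids."""

    n_hat: np.ndarray  # (P, 3)
    e_hat: np.ndarray  # (P, 3)
    trajectory_ids: np.ndarray  # (P,)
    axes: np.ndarray  # (n_traj, 3)

    def __len__(self) -> int:
        return len(self.n_hat)

    @property
    def n_trajectories(self) -> int:
        return len(self.axes)

    @property
    def poses(self) -> list[Pose]:
        return [Pose(n, e) for n, e in zip(self.n_hat, self.e_hat)]

    def directions(self, model_tag: str) -> np.ndarray:
        """The orientation vectors parametrizing a surrogate model:
        the optical axes for tag ``"N"``, the sensitivity axes for ``"E"``."""
        if model_tag == "N":
            return self.n_hat
        if model_tag == "E":
            return self.e_hat
        raise ValueError(f"unknown model tag {model_tag!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pose_index": np.arange(len(self)),
                "trajectory_id": self.trajectory_ids,
                "nx": self.n_hat[:, 0],
                "ny": self.n_hat[:, 1],
                "nz": self.n_hat[:, 2],
                "ex": self.e_hat[:, 0],
                "ey": self.e_hat[:, 1],
                "ez": self.e_hat[:, 2],
            }
        )


def trajectory(axis, n_samples: int) -> Trajectory:
    """Sample one circular trajectory at ``n_samples`` equidistant angles.

    ``n_hat_j = -(cos(theta_j) u + sin(theta_j) v)`` with ``theta_j = 2 pi j /
    n_samples`` (no endpoint duplication) points toward the volume element;
    ``e_hat_j = axis x n_hat_j`` is tangential to the orbit.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("trajectory axis must be nonzero")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    axis = axis / norm
    u, v = _in_plane_basis(axis)
    theta = 2.0 * np.pi * np.arange(n_samples) / n_samples
    n_hat = -(np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v))
    e_hat = np.cross(axis, n_hat)
    return Trajectory(axis=axis, n_hat=n_hat, e_hat=e_hat)


def _concat(axes: np.ndarray, n_samples: int) -> AcquisitionGeometry:
    trajs = [trajectory(a, n_samples) for a in axes]
    return AcquisitionGeometry(
        n_hat=np.concatenate([t.n_hat for t in trajs]),
        e_hat=np.concatenate([t.e_hat for t in trajs]),
        trajectory_ids=np.repeat(np.arange(len(trajs)), n_samples),
        axes=np.asarray([t.axis for t in trajs]),
    )


def full_geometry(n_samples: int = 29) -> AcquisitionGeometry:
    """All 13 trajectories (coordinate axes, face diagonals, space diagonals)."""
    axes = np.concatenate([COORDINATE_AXES, FACE_DIAGONALS, SPACE_DIAGONALS])
    return _concat(axes, n_samples)


def orthogonal_subset(n_samples: int = 29) -> AcquisitionGeometry:
    """Only the 3 mutually orthogonal coordinate-axis trajectories."""
    return _concat(COORDINATE_AXES, n_samples)
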