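"""Ground-truth microstructure tensors for dark-field simulation.

A volume element's unresolved substructure is modelled as a 3D Gaussian
density whose precision (inverse-covariance) matrix ``T`` is a symmetric
positive-definite 3x3 tensor.  Its eigenvalues are the inverse variances
``sigma_i**-2`` along the principal axes; the eigenvector of the *smallest*
eigenvalue is the longest structural axis.  The absolute scale of ``T`` does
not affect the orientation dependence of the dark-field signal, so all
tensors are trace-normalized to 1.

This module generates the study ensemble: a regular grid over the feasible
eigenvalue simplex, Haar-uniform random orientations, and the assembled
tensors ``T = R diag(lam) R^T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

#: Floor applied to zero eigenvalues before tensor assembly.  A strictly zero
#: inverse variance corresponds to an infinitely extended structure and makes
#: the forward model diverge; the floor keeps the arithmetic finite while
#: preserving the (physically extreme) cases in the ensemble.
EIGENVALUE_FLOOR = 1e-9


def eigenvalue_grid(n_grid: int) -> np.ndarray:
    """Sample the feasible eigenvalue simplex on a regular grid.

    Two orthogonal linear ramps on an ``n_grid x n_grid`` index grid run from
    0 to 1/3 (first index) and from 0 to 1/2 (second index); the third value
    follows from the unit-trace constraint.  Each triplet is sorted ascending,
    so ``lam1 <= 1/3``, ``lam2 <= 1/2``, ``lam3 >= 1/3`` and the triplet sums
    to 1.  Redundant triplets arising from the generation scheme are retained.

    Parameters
    ----------
    n_grid : int
        Points per ramp (>= 2, endpoints inclusive).

    Returns
    -------
    ndarray, shape (n_grid**2, 3)
        Sorted eigenvalue triplets, row-major over the (i, j) index grid.
    """
    if n_grid < 2:
        raise ValueError(f"n_grid must be >= 2, got {n_grid}")
    a = np.linspace(0.0, 1.0 / 3.0, n_grid)
    b = np.linspace(0.0, 1.0 / 2.0, n_grid)
    aa, bb = np.meshgrid(a, b, indexing="ij")
    cc = 1.0 - aa - bb
    triplets = np.stack([aa, bb, cc], axis=-1).reshape(-1, 3)
    triplets.sort(axis=1)
    return triplets


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Draw one rotation matrix from the Haar-uniform measure on SO(3).

    Uses the normalized-Gaussian-quaternion construction: a 4-vector of iid
    standard normals, normalized, is uniform on S^3 and maps to a uniform
    rotation.  Reproducible for a seeded generator.
    """
    quat = rng.standard_normal(4)
    return Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized batch of ``n`` Haar-uniform rotation matrices, shape (n, 3, 3)."""
    quat = rng.standard_normal((n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return Rotation.from_quat(quat).as_matrix()


def clamp_triplet(eigs) -> tuple[np.ndarray, bool]:
    """Clamp eigenvalues at :data:`EIGENVALUE_FLOOR` and renormalize to unit sum.

    Returns the clamped triplet and whether clamping changed anything.
    """
    lam = np.asarray(eigs, dtype=float)
    clamped = bool(np.any(lam < EIGENVALUE_FLOOR))
    if clamped:
        lam = np.maximum(lam, EIGENVALUE_FLOOR)
        lam = lam / lam.sum()
    return lam, clamped


def assemble_tensor(eigs, R) -> np.ndarray:
    """Assemble ``T = R diag(lam1, lam2, lam3) R^T``.

    The eigenvalues of the result equal the input triplet and the trace is
    preserved; symmetry is exact by symmetrization of the product.
    """
    lam = np.asarray(eigs, dtype=float)
    R = np.asarray(R, dtype=float)
    T = (R * lam) @ R.T
    return 0.5 * (T + T.T)


def assemble_tensors(eigs, R) -> np.ndarray:
    """Batched :func:`assemble_tensor`: ``eigs`` (n, 3), ``R`` (n, 3, 3) -> (n, 3, 3)."""
    T = np.einsum("nij,nj,nkj->nik", R, np.asarray(eigs, float), R)
    return 0.5 * (T + np.swapaxes(T, -1, -2))


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Flip sign so the last component of magnitude > 1e-12 is non-negative."""
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[-1]] < 0:
        return -v
    return v


def principal_axis(T, which: str = "smallest") -> np.ndarray:
    """Unit eigenvector of the extreme eigenvalue of a symmetric tensor.

    ``which="smallest"`` selects the smallest eigenvalue -- for a ground-truth
    precision tensor this is the longest structural axis.  ``which="largest"``
    is appropriate for the optical-axis surrogate, whose spectrum
    anti-correlates with the ground truth.  The sign is fixed so the last
    nonzero component is non-negative.  For a degenerate extreme eigenvalue
    one vector of the eigenspace is returned.
    """
    if which not in ("smallest", "largest"):
        raise ValueError(f"which must be 'smallest' or 'largest', got {which!r}")
    w, V = np.linalg.eigh(np.asarray(T, dtype=float))
    v = V[:, 0] if which == "smallest" else V[:, -1]
    return _fix_sign(v)


@dataclass
class Ensemble:
    """Generated study ensemble of ground-truth tensors.

    Attributes
    ----------
    triplets : ndarray, (n_instances, 3)
        Clamped, renormalized eigenvalue triplets (ascending).
    rotations : ndarray, (n_instances, 3, 3)
        Haar-uniform rotation matrices.
    tensors : ndarray, (n_instances, 3, 3)
        Assembled trace-1 precision tensors.
    grid_i, grid_j, rotation_index : ndarray of int
        Provenance of each instance on the eigenvalue grid.
    clamped : ndarray of bool
        Whether the raw triplet contained a zero eigenvalue.
    degenerate : ndarray of bool
        Whether the two smallest eigenvalues coincide, leaving the
        ground-truth principal axis ill-defined.
    """

    triplets: np.ndarray
    rotations: np.ndarray
    tensors: np.ndarray
    grid_i: np.ndarray
    grid_j: np.ndarray
    rotation_index: np.ndarray
    clamped: np.ndarray
    degenerate: np.ndarray
    seed: int
    grid_size: int
    rotations_per_triplet: int
    instance_id: np.ndarray = field(init=False)

    def __post_init__(self):
        self.instance_id = np.arange(len(self.triplets))

    def __len__(self) -> int:
        return len(self.triplets)

    @property
    def principal_axes(self) -> np.ndarray:
        """Ground-truth longest structural axes: first rotation column (n, 3).

        The triplets are ascending, so the smallest-eigenvalue eigenvector of
        ``T = R diag(lam) R^T`` is exactly the first column of ``R``.
        """
        return self.rotations[:, :, 0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "instance_id": self.instance_id,
                "grid_i": self.grid_i,
                "grid_j": self.grid_j,
                "rotation_index": self.rotation_index,
                "lam1": self.triplets[:, 0],
                "lam2": self.triplets[:, 1],
                "lam3": self.triplets[:, 2],
            }
        )
        R = self.rotations.reshape(len(self), 9)
        for k in range(9):
            df[f"R{k // 3}{k % 3}"] = R[:, k]
        df["clamped"] = self.clamped
        df["degenerate"] = self.degenerate
        df["seed"] = self.seed
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Ensemble":
        triplets = df[["lam1", "lam2", "lam3"]].to_numpy(float)
        R = df[[f"R{i}{j}" for i in range(3) for j in range(3)]].to_numpy(float)
        R = R.reshape(-1, 3, 3)
        grid_i = df["grid_i"].to_numpy(int)
        grid_j = df["grid_j"].to_numpy(int)
        return cls(
            triplets=triplets,
            rotations=R,
            tensors=assemble_tensors(triplets, R),
            grid_i=grid_i,
            grid_j=grid_j,
            rotation_index=df["rotation_index"].to_numpy(int),
            clamped=df["clamped"].to_numpy(bool),
            degenerate=df["degenerate"].to_numpy(bool),
            seed=int(df["seed"].iloc[0]),
            grid_size=int(grid_i.max()) + 1,
            rotations_per_triplet=int(df["rotation_index"].max()) + 1,
        )


def make_ensemble(
    grid_size: int = 20,
    rotations_per_triplet: int = 300,
    seed: int = 0,
) -> Ensemble:
    """Generate the full study ensemble.

    Every grid triplet is combined with ``rotations_per_triplet`` independent
    Haar-uniform rotations.  Each instance's rotation is drawn from its own
    substream keyed by ``(seed, instance_id)``, so the ensemble is independent
    of chunking or parallelization order and bit-reproducible for a fixed
    seed.
    """
    if rotations_per_triplet < 1:
        raise ValueError("rotations_per_triplet must be >= 1")
    raw = eigenvalue_grid(grid_size)
    n_trip = len(raw)
    n_inst = n_trip * rotations_per_triplet

    quats = np.empty((n_inst, 4))
    for iid in range(n_inst):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(iid,))
        )
        quats[iid] = rng.standard_normal(4)
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rotations = Rotation.from_quat(quats).as_matrix()

    raw_rep = np.repeat(raw, rotations_per_triplet, axis=0)
    clamped = np.any(raw_rep < EIGENVALUE_FLOOR, axis=1)
    lam = np.maximum(raw_rep, EIGENVALUE_FLOOR)
    lam /= lam.sum(axis=1, keepdims=True)
    degenerate = (raw_rep[:, 1] - raw_rep[:, 0]) < 1e-12

    trip_idx = np.repeat(np.arange(n_trip), rotations_per_triplet)
    return Ensemble(
        triplets=lam,
        rotations=rotations,
        tensors=assemble_tensors(lam, rotations),
        grid_i=trip_idx // grid_size,
        grid_j=trip_idx % grid_size,
        rotation_index=np.tile(np.arange(rotations_per_triplet), n_trip),
        clamped=clamped,
        degenerate=degenerate,
        seed=seed,
        grid_size=grid_size,
        rotations_per_triplet=rotations_per_triplet,
    )
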