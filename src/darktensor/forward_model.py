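"""Nonlinear physical model of dark-field signal anisotropy.

The extinction coefficient mu_DF = -ln(v) of a grating interferometer, for a
volume element with Gaussian precision tensor ``T`` evaluated in the
instrument frame (sensitivity axis e_hat along x, optical axis n_hat along
z), is

    mu_DF  propto  (T_xx - T_xz**2 / T_zz) / sqrt(T_zz).

The prefactor ``T_zz**-1/2`` is the mass distribution's standard deviation
along the optical axis (leading-order scattering cross section); the bracket
is the precision of the projected density along the sensitivity axis (the
autocorrelation term) -- algebraically the Schur complement of the z-block of
``T``.  All purely scale-affecting factors are dropped (proportionality
constant 1): only the orientation dependence matters here, and the signal is
homogeneous of degree 1/2 in ``T`` so trace normalization is harmless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class Pose:
    """One acquisition orientation in the sample frame.

    ``n_hat`` is the optical axis (direction of projection), ``e_hat`` the
    interferometer sensitivity axis; they must be orthonormal.
    """

    n_hat: np.ndarray
    e_hat: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.n_hat, dtype=float)
        e = np.asarray(self.e_hat, dtype=float)
        object.__setattr__(self, "n_hat", n)
        object.__setattr__(self, "e_hat", e)
        if abs(np.linalg.norm(n) - 1.0) > _ORTHO_TOL:
            raise ValueError("n_hat is not unit-norm")
        if abs(np.linalg.norm(e) - 1.0) > _ORTHO_TOL:
            raise ValueError("e_hat is not unit-norm")
        if abs(float(n @ e)) > _ORTHO_TOL:
            raise ValueError("n_hat and e_hat are not orthogonal")

    def basis(self) -> np.ndarray:
        """Columns (e_hat, n_hat x e_hat, n_hat): right-handed instrument frame."""
        return np.column_stack([self.e_hat, np.cross(self.n_hat, self.e_hat), self.n_hat])


def instrument_frame_tensor(T, pose: Pose) -> np.ndarray:
    """Express ``T`` in the instrument frame of the given pose.

    Returns ``B^T T B`` with ``B = (e_hat, n_hat x e_hat, n_hat)`` as columns;
    a similarity transform, so the eigenvalues are unchanged.
    """
    B = pose.basis()
    T = np.asarray(T, dtype=float)
    return B.T @ T @ B


def darkfield_signal(T, pose: Pose) -> float:
    """Dark-field extinction coefficient for one tensor and pose.

    Raises for a non-positive ``T'_zz`` (reachable only when eigenvalue
    clamping is disabled upstream).
    """
    Tp = instrument_frame_tensor(T, pose)
    tzz = Tp[2, 2]
    if tzz <= 0.0:
        raise ValueError("degenerate input: T_zz <= 0 in the instrument frame")
    return float((Tp[0, 0] - Tp[0, 2] ** 2 / tzz) / np.sqrt(tzz))


def signal_factors(T, pose: Pose) -> tuple[float, float]:
    """The two orientation-dependence factors of the signal.

    Returns ``(cross_section_factor, correlation_factor)`` =
    ``(T'_zz**-1/2, T'_xx - T'_xz**2 / T'_zz)``; their product is
    :func:`darkfield_signal`.  For an ellipsoid uninclined w.r.t. the optical
    axis the off-diagonal ``T'_xz`` vanishes and the correlation factor
    reduces to ``T'_xx``.
    """
    Tp = instrument_frame_tensor(T, pose)
    tzz = Tp[2, 2]
    if tzz <= 0.0:
        raise ValueError("degenerate input: T_zz <= 0 in the instrument frame")
    return float(tzz ** -0.5), float(Tp[0, 0] - Tp[0, 2] ** 2 / tzz)


def darkfield_signals(tensors, n_hats, e_hats) -> np.ndarray:
    """Vectorized signal synthesis.

    Parameters
    ----------
    tensors : ndarray, (B, 3, 3)
    n_hats, e_hats : ndarray, (P, 3)
        Orthonormal pose pairs.

    Returns
    -------
    ndarray, (B, P)
        ``mu[b, p]`` for tensor ``b`` at pose ``p``.
    """
    T = np.atleast_3d(np.asarray(tensors, dtype=float))
    if T.ndim == 2:
        T = T[None]
    n = np.asarray(n_hats, dtype=float)
    e = np.asarray(e_hats, dtype=float)
    Tn = np.einsum("bij,pj->bpi", T, n)
    tzz = np.einsum("pi,bpi->bp", n, Tn)
    txz = np.einsum("pi,bpi->bp", e, Tn)
    txx = np.einsum("pi,bij,pj->bp", e, T, e)
    return (txx - txz**2 / tzz) / np.sqrt(tzz)
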