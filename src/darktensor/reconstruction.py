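"""Linear surrogate tensor models and their reconstruction from signals.

Classic tensor tomography replaces the nonlinear dark-field signal by a
quadratic form ``mu ~ r_hat^T U r_hat`` in a symmetric 3x3 tensor ``U``, with
``r_hat`` either the optical axis (model "N") or the sensitivity axis (model
"E").  ``U`` is fitted to a set of scalar signals by damped iterative
back-projection

    U <- U + lambda_k (r r^T) (mu_i - r^T U r),   lambda_k = lambda0 2**(-k/tau),

starting from U = 0, visiting each projection ``n_passes`` times.  For a unit
direction the update is a pseudo-inverse step: with lambda_k = 1 it makes the
model exactly consistent with the visited projection.  The geometric decay of
lambda_k drives convergence to a mean solution and suppresses the influence
of the projection ordering.  A closed-form least-squares fit over the 6 free
tensor components serves as the independent fixed-point oracle.

The statsmodels-flavoured front end is :class:`DarkfieldTensorModel`, whose
``fit`` returns a :class:`DarkfieldTensorFit` with the tensor estimate, its
eigen-structure, residual diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np

from .tensors import principal_axis

_UNIT_TOL = 1e-8

#: Index pairs of the 6 free components of a symmetric tensor, in storage order
#: (xx, yy, zz, xy, xz, yz).
COMPONENT_INDICES = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
COMPONENT_NAMES = ("xx", "yy", "zz", "xy", "xz", "yz")


class RankDeficiencyError(ValueError):
    """Raised when a direction set cannot determine all 6 tensor components."""

    def __init__(self, rank: int):
        super().__init__(
            f"design matrix has rank {rank} < 6; the directions do not "
            "determine a symmetric 3x3 tensor"
        )
        self.rank = rank


@dataclass(frozen=True)
class IterationSchedule:
    """Relaxation schedule of the iterative back-projection.

    ``lambda0`` is the initial relaxation factor, ``n_passes`` how often each
    projection is visited.  ``tau`` (halving constant) and ``k_max`` depend on
    the number of projections and are filled in by :meth:`bind`; left unset,
    ``tau`` defaults to ``3 * k_max / 25``.
    """

    lambda0: float = 0.2
    n_passes: int = 25
    tau: float | None = None
    k_max: int | None = None

    def __post_init__(self):
        if not 0.0 < self.lambda0 <= 1.0:
            raise ValueError("lambda0 must lie in (0, 1]")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")

    def bind(self, n_projections: int) -> "IterationSchedule":
        """Resolve ``k_max`` and ``tau`` for a concrete projection count."""
        k_max = self.n_passes * int(n_projections)
        tau = self.tau if self.tau is not None else 3.0 * k_max / 25.0
        return replace(self, tau=tau, k_max=k_max)

    def relaxation_factors(self) -> np.ndarray:
        """All ``k_max`` relaxation factors ``lambda0 * 2**(-k/tau)``."""
        if self.tau is None or self.k_max is None:
            raise ValueError("schedule is unbound; call bind(n_projections) first")
        return self.lambda0 * 2.0 ** (-np.arange(self.k_max) / self.tau)


def relaxation(k: int, schedule: IterationSchedule) -> float:
    """Relaxation factor ``lambda_k = lambda0 * 2**(-k/tau)`` of a bound schedule."""
    if schedule.tau is None:
        raise ValueError("schedule is unbound; call bind(n_projections) first")
    return schedule.lambda0 * 2.0 ** (-k / schedule.tau)


def components_to_matrix(u: np.ndarray) -> np.ndarray:
    """Symmetric matrices from free components; supports leading batch axes."""
    u = np.asarray(u, dtype=float)
    out = np.empty(u.shape[:-1] + (3, 3))
    for comp, (i, j) in enumerate(COMPONENT_INDICES):
        out[..., i, j] = u[..., comp]
        out[..., j, i] = u[..., comp]
    return out


def matrix_to_components(U: np.ndarray) -> np.ndarray:
    """Free components (xx, yy, zz, xy, xz, yz) of symmetric matrices."""
    U = np.asarray(U, dtype=float)
    return np.stack([U[..., i, j] for i, j in COMPONENT_INDICES], axis=-1)


def quadratic_form_design(directions: np.ndarray) -> np.ndarray:
    """Design rows q with ``q @ u = r^T U r`` for unit directions r, shape (P, 6)."""
    r = np.asarray(directions, dtype=float)
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    return np.column_stack([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z])


def _update_rows(directions: np.ndarray) -> np.ndarray:
    # Back-projection increments of the 6 free components: the outer product
    # r r^T touches each off-diagonal entry once in component storage.
    r = np.asarray(directions, dtype=float)
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    return np.column_stack([x * x, y * y, z * z, x * y, x * z, y * z])


def _validate(signals: np.ndarray, directions: np.ndarray) -> None:
    if signals.ndim != 2 or signals.shape[1] == 0:
        raise ValueError("signal list must be non-empty")
    if directions.shape != (signals.shape[1], 3):
        raise ValueError(
            f"directions shape {directions.shape} does not match "
            f"{signals.shape[1]} signals"
        )
    norms = np.linalg.norm(directions, axis=1)
    if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
        raise ValueError("all directions must be unit-norm")


def reconstruct_batch(
    signals,
    directions,
    schedule: IterationSchedule | None = None,
    shuffle_seed: int | None = None,
) -> np.ndarray:
    """Iterative back-projection for a batch of signal sets sharing one geometry.

    Parameters
    ----------
    signals : ndarray, (B, P)
    directions : ndarray, (P, 3)
        Unit orientation vectors (optical or sensitivity axes).
    schedule : IterationSchedule, optional
        Unbound schedule; defaults to the standard lambda0=0.2, 25 passes.
    shuffle_seed : int, optional
        If given, projections are visited in a freshly shuffled order on each
        pass; default is the deterministic cyclic sweep in geometry order.

    Returns
    -------
    ndarray, (B, 3, 3)
        Reconstructed symmetric surrogate tensors.
    """
    mu = np.atleast_2d(np.asarray(signals, dtype=float))
    directions = np.asarray(directions, dtype=float)
    _validate(mu, directions)
    n_proj = mu.shape[1]

    sched = (schedule or IterationSchedule()).bind(n_proj)
    lambdas = sched.relaxation_factors()
    q = quadratic_form_design(directions)
    p = _update_rows(directions)

    if shuffle_seed is None:
        order = np.tile(np.arange(n_proj), sched.n_passes)
    else:
        rng = np.random.default_rng(shuffle_seed)
        order = np.concatenate(
            [rng.permutation(n_proj) for _ in range(sched.n_passes)]
        )

    u = np.zeros((mu.shape[0], 6))
    for k, i in enumerate(order):
        resid = mu[:, i] - u @ q[i]
        u += (lambdas[k] * resid)[:, None] * p[i]
    return components_to_matrix(u)


def reconstruct(
    signals,
    directions,
    schedule: IterationSchedule | None = None,
    shuffle_seed: int | None = None,
) -> np.ndarray:
    """Single-instance iterative reconstruction; returns one symmetric 3x3 tensor."""
    out = reconstruct_batch(
        np.asarray(signals, dtype=float)[None, :], directions, schedule, shuffle_seed
    )
    return out[0]


def least_squares_fit(
    signals, directions, *, require_full_rank: bool = False
) -> np.ndarray:
    """Closed-form least-squares surrogate tensor (fixed-point oracle).

    Minimizes ``sum_i (mu_i - r_i^T U r_i)**2`` over the 6 free components.
    Fewer than 6 measurements can never determine the tensor and raise
    :class:`RankDeficiencyError`; a rank-deficient design with >= 6
    measurements yields the minimum-norm solution unless
    ``require_full_rank=True``.
    """
    mu = np.asarray(signals, dtype=float)
    directions = np.asarray(directions, dtype=float)
    _validate(mu[None, :], directions)
    if mu.size < 6:
        raise RankDeficiencyError(min(mu.size, int(np.linalg.matrix_rank(
            quadratic_form_design(directions)))))
    q = quadratic_form_design(directions)
    u, _, rank, _ = np.linalg.lstsq(q, mu, rcond=None)
    if require_full_rank and rank < 6:
        raise RankDeficiencyError(int(rank))
    return components_to_matrix(u)


class DarkfieldTensorModel:
    """Surrogate tensor model bound to one set of signals and directions.

    Parameters
    ----------
    signals : array-like, (P,)
        Scalar dark-field extinction values.
    directions : array-like, (P, 3)
        Unit orientation vectors parametrizing the model (optical axes for
        tag "N", sensitivity axes for tag "E").
    model_tag : {"N", "E"}

    Examples
    --------
    >>> from darktensor import geometry, forward_model, tensors
    >>> geom = geometry.full_geometry()
    >>> T = tensors.assemble_tensor([0.2, 0.3, 0.5], np.eye(3))
    >>> mu = forward_model.darkfield_signals(T[None], geom.n_hat, geom.e_hat)[0]
    >>> fit = DarkfieldTensorModel.from_geometry(mu, geom, "E").fit()
    >>> fit.nrmse < 1.0
    True
    """

    def __init__(self, signals, directions, model_tag: str = "E"):
        if model_tag not in ("N", "E"):
            raise ValueError(f"model_tag must be 'N' or 'E', got {model_tag!r}")
        self.signals = np.asarray(signals, dtype=float)
        self.directions = np.asarray(directions, dtype=float)
        self.model_tag = model_tag
        _validate(self.signals[None, :], self.directions)

    @classmethod
    def from_geometry(cls, signals, geometry, model_tag: str) -> "DarkfieldTensorModel":
        """Build the model from an :class:`~darktensor.geometry.AcquisitionGeometry`."""
        return cls(signals, geometry.directions(model_tag), model_tag)

    def predict(self, U) -> np.ndarray:
        """Model signals ``r^T U r`` at the bound directions."""
        return quadratic_form_design(self.directions) @ matrix_to_components(U)

    def fit(
        self,
        method: str = "iterative",
        schedule: IterationSchedule | None = None,
        shuffle_seed: int | None = None,
    ) -> "DarkfieldTensorFit":
        """Fit the surrogate tensor.

        ``method="iterative"`` runs the damped back-projection scheme (the
        production path); ``method="lstsq"`` solves the normal equations in
        closed form.
        """
        if method == "iterative":
            U = reconstruct(self.signals, self.directions, schedule, shuffle_seed)
        elif method == "lstsq":
            U = least_squares_fit(self.signals, self.directions)
        else:
            raise ValueError(f"unknown method {method!r}")
        return DarkfieldTensorFit(self, U, method)


class DarkfieldTensorFit:
    """Fit result: the surrogate tensor with diagnostics."""

    def __init__(self, model: DarkfieldTensorModel, tensor: np.ndarray, method: str):
        self.model = model
        self.tensor = np.asarray(tensor, dtype=float)
        self.method = method
        self.params = matrix_to_components(self.tensor)
        self.fittedvalues = model.predict(self.tensor)
        self.resid = model.signals - self.fittedvalues

    @property
    def model_tag(self) -> str:
        return self.model.model_tag

    @property
    def nrmse(self) -> float:
        """Root-mean-square residual normalized by the mean signal."""
        from .evaluation import nrmse

        return nrmse(self.model.signals, self.fittedvalues)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the surrogate tensor, ascending (may be negative)."""
        return np.linalg.eigvalsh(self.tensor)

    @property
    def mean_signal(self) -> float:
        return float(self.model.signals.mean())

    @property
    def mean_eigenvalue(self) -> float:
        """trace(U)/3 -- reproduces the mean signal under isotropic direction coverage."""
        return float(np.trace(self.tensor) / 3.0)

    def principal_axis(self) -> np.ndarray:
        """Estimated dominant structural axis.

        Smallest-eigenvalue eigenvector for model "E" (spectrum correlates
        with the ground-truth precision tensor), largest for model "N"
        (spectrum anti-correlates).
        """
        which = "largest" if self.model_tag == "N" else "smallest"
        return principal_axis(self.tensor, which)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        buf = io.StringIO()
        w = self.eigenvalues
        axis = self.principal_axis()
        print(f"Dark-field surrogate tensor fit (model {self.model_tag})", file=buf)
        print("=" * 58, file=buf)
        print(f"method: {self.method}    n_signals: {len(self.model.signals)}", file=buf)
        print(f"NRMSE: {self.nrmse:.4f}", file=buf)
        print(f"mean signal: {self.mean_signal:.6g}    trace(U)/3: "
              f"{self.mean_eigenvalue:.6g}", file=buf)
        print("components (xx, yy, zz, xy, xz, yz):", file=buf)
        print("  " + "  ".join(f"{c:+.5g}" for c in self.params), file=buf)
        print(f"eigenvalues (ascending): "
              + "  ".join(f"{x:+.5g}" for x in w), file=buf)
        print(f"principal axis: ({axis[0]:+.4f}, {axis[1]:+.4f}, {axis[2]:+.4f})",
              file=buf)
        return buf.getvalue()

    def plot_fit(self, ax=None):
        """Plot measured vs. fitted signal over pose index (thin matplotlib layer)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        idx = np.arange(len(self.model.signals))
        ax.plot(idx, self.model.signals, ".", label="synthesized $\\mu$")
        ax.plot(idx, self.fittedvalues, "-", lw=1,
                label=f"model {self.model_tag} fit")
        ax.set_xlabel("pose index")
        ax.set_ylabel("dark-field extinction (arb.)")
        ax.legend()
        return ax
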