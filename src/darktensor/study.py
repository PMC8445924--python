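"""End-to-end simulation study orchestration.

Builds the ground-truth ensemble, synthesizes dark-field signals for the
chosen acquisition geometry, reconstructs both linear surrogate tensors per
instance, evaluates all comparison statistics, and aggregates ensemble
summaries.  Everything is deterministic for a fixed seed; instances are
processed in chunks so memory stays flat for large ensembles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import evaluation, geometry as geometry_mod, tensors
from .forward_model import darkfield_signals
from .reconstruction import (
    COMPONENT_NAMES,
    IterationSchedule,
    matrix_to_components,
    quadratic_form_design,
    reconstruct_batch,
)

MODEL_TAGS = ("N", "E")


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one simulation run.

    Defaults are the full study conditions: a 20x20 eigenvalue grid with 300
    random orientations each (120 000 instances), the full 13-trajectory
    geometry at 29 poses per trajectory, and the standard relaxation schedule
    (lambda0=0.2, 25 passes).
    """

    grid_size: int = 20
    rotations_per_triplet: int = 300
    geometry: str = "full"
    n_samples_per_trajectory: int = 29
    lambda0: float = 0.2
    n_passes: int = 25
    seed: int = 0
    shuffle: bool = False
    chunk_size: int = 5000
    out_dir: str | None = None

    def __post_init__(self):
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.rotations_per_triplet < 1:
            raise ValueError("rotations_per_triplet must be >= 1")
        if self.geometry not in ("full", "orthogonal"):
            raise ValueError("geometry must be 'full' or 'orthogonal'")

    @classmethod
    def scaled(cls, **overrides) -> "StudyConfig":
        """Desk-scale profile: 10x10 grid x 50 rotations = 5000 instances."""
        base = dict(grid_size=10, rotations_per_triplet=50)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Load a config from a YAML or JSON file mirroring the field names."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    @property
    def n_instances(self) -> int:
        return self.grid_size**2 * self.rotations_per_triplet

    def schedule(self) -> IterationSchedule:
        return IterationSchedule(lambda0=self.lambda0, n_passes=self.n_passes)

    def build_geometry(self) -> geometry_mod.AcquisitionGeometry:
        if self.geometry == "full":
            return geometry_mod.full_geometry(self.n_samples_per_trajectory)
        return geometry_mod.orthogonal_subset(self.n_samples_per_trajectory)


@dataclass
class StudyResults:
    """Records table, summary and provenance of one run."""

    records: pd.DataFrame
    summary: dict
    config: StudyConfig
    ensemble: tensors.Ensemble | None = field(default=None, repr=False)

    def save(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": out / "records.csv",
            "summary": out / "summary.json",
            "config": out / "config.json",
        }
        self.records.to_csv(paths["records"], index=False)
        paths["summary"].write_text(json.dumps(self.summary, indent=1))
        paths["config"].write_text(json.dumps(asdict(self.config), indent=1))
        if self.ensemble is not None:
            paths["ensemble"] = out / "ensemble.csv"
            self.ensemble.to_frame().to_csv(paths["ensemble"], index=False)
        return paths


def synthesize_signals(
    ensemble: tensors.Ensemble, geometry: geometry_mod.AcquisitionGeometry
) -> np.ndarray:
    """Dark-field signals (n_instances, n_poses) for an ensemble and geometry."""
    return darkfield_signals(ensemble.tensors, geometry.n_hat, geometry.e_hat)


def evaluate_batch(
    ensemble_slice: dict,
    signals: np.ndarray,
    surrogates: np.ndarray,
    model_tag: str,
    directions: np.ndarray,
) -> pd.DataFrame:
    """Vectorized per-instance evaluation for one model over a chunk."""
    mu = signals
    u6 = matrix_to_components(surrogates)
    pred = u6 @ quadratic_form_design(directions).T

    nrmse_vec = np.sqrt(np.mean((mu - pred) ** 2, axis=1)) / mu.mean(axis=1)

    w, V = np.linalg.eigh(surrogates)
    v_est = V[..., -1] if model_tag == "N" else V[..., 0]
    dtheta = evaluation.angular_errors(ensemble_slice["v_truth"], v_est)

    trace_u = w.sum(axis=1)
    # Spectrum normalization is meaningless when the trace nearly cancels
    # against large opposite-sign eigenvalues; those records are flagged.
    flagged = np.abs(trace_u) < 1e-6 * np.max(np.abs(w), axis=1)
    safe = np.where(flagged, np.nan, trace_u)
    spec_u = w / safe[:, None]
    if model_tag == "N":
        spec_u = spec_u[:, ::-1]

    df = pd.DataFrame(
        {
            "instance_id": ensemble_slice["instance_id"],
            "grid_i": ensemble_slice["grid_i"],
            "grid_j": ensemble_slice["grid_j"],
            "rotation_index": ensemble_slice["rotation_index"],
            "model": model_tag,
            "nrmse": nrmse_vec,
            "delta_theta_deg": dtheta,
            "lam_T1": ensemble_slice["triplets"][:, 0],
            "lam_T2": ensemble_slice["triplets"][:, 1],
            "lam_T3": ensemble_slice["triplets"][:, 2],
            "lam_U1": spec_u[:, 0],
            "lam_U2": spec_u[:, 1],
            "lam_U3": spec_u[:, 2],
            "mean_signal": mu.mean(axis=1),
            "mean_eigenvalue": trace_u / 3.0,
            "trace_U": trace_u,
            "clamped": ensemble_slice["clamped"],
            "degenerate": ensemble_slice["degenerate"],
            "spectrum_flagged": flagged,
        }
    )
    for name, col in zip(COMPONENT_NAMES, u6.T):
        df[f"u_{name}"] = col
    return df


def reconstruct_ensemble(
    signals: np.ndarray,
    geometry: geometry_mod.AcquisitionGeometry,
    schedule: IterationSchedule,
    shuffle_seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Reconstruct both surrogate models for every signal set."""
    return {
        tag: reconstruct_batch(signals, geometry.directions(tag), schedule, shuffle_seed)
        for tag in MODEL_TAGS
    }


def run_study(config: StudyConfig, *, keep_ensemble: bool = True) -> StudyResults:
    """Execute the full pipeline for one configuration.

    For every instance: assemble the ground-truth tensor, synthesize signals
    at all poses, reconstruct surrogate tensors N (optical-axis directions)
    and E (sensitivity-axis directions), and evaluate the comparison
    statistics.  Deterministic for a fixed seed.
    """
    geom = config.build_geometry()
    sched = config.schedule()
    ens = tensors.make_ensemble(
        config.grid_size, config.rotations_per_triplet, config.seed
    )
    v_truth = ens.principal_axes

    frames = []
    for start in range(0, len(ens), config.chunk_size):
        sl = slice(start, min(start + config.chunk_size, len(ens)))
        chunk = {
            "instance_id": ens.instance_id[sl],
            "grid_i": ens.grid_i[sl],
            "grid_j": ens.grid_j[sl],
            "rotation_index": ens.rotation_index[sl],
            "triplets": ens.triplets[sl],
            "clamped": ens.clamped[sl],
            "degenerate": ens.degenerate[sl],
            "v_truth": v_truth[sl],
        }
        mu = darkfield_signals(ens.tensors[sl], geom.n_hat, geom.e_hat)
        if not np.all(np.isfinite(mu)):
            bad = np.flatnonzero(~np.isfinite(mu).all(axis=1))
            raise FloatingPointError(
                f"non-finite signals for instances {ens.instance_id[sl][bad][:5]}"
            )
        shuffle_seed = config.seed + 1 if config.shuffle else None
        for tag in MODEL_TAGS:
            U = reconstruct_batch(mu, geom.directions(tag), sched, shuffle_seed)
            frames.append(evaluate_batch(chunk, mu, U, tag, geom.directions(tag)))

    records = pd.concat(frames, ignore_index=True)
    records.sort_values(["model", "instance_id"], inplace=True, ignore_index=True)
    summary = summarize(records)
    summary["config"] = asdict(config)
    results = StudyResults(
        records=records,
        summary=summary,
        config=config,
        ensemble=ens if keep_ensemble else None,
    )
    if config.out_dir:
        results.save(config.out_dir)
    return results


def _json_safe(x):
    if isinstance(x, dict):
        return {k: _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_json_safe(v) for v in x]
    if isinstance(x, np.ndarray):
        return _json_safe(x.tolist())
    if isinstance(x, (np.floating, float)):
        x = float(x)
        return x if np.isfinite(x) else None
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    return x


def summarize(records: pd.DataFrame, *, spectra_bins: int = 40) -> dict:
    """Aggregate a records table into the ensemble-level summary.

    Per model: the sigma estimate of the angular-error distribution (with and
    without degenerate-orientation instances), the NRMSE histogram and its
    mode, binned eigenspectrum pair densities, and the regression slope of
    mean signal on mean surrogate eigenvalue.
    """
    if len(records) == 0:
        raise ValueError("records table is empty")
    out: dict = {"n_records": int(len(records)), "models": {}}
    for tag, sub in records.groupby("model"):
        dtheta = sub["delta_theta_deg"].to_numpy()
        clean = sub.loc[~sub["degenerate"], "delta_theta_deg"].to_numpy()
        sigma_all, details = evaluation.fit_sigma_theta(dtheta, return_details=True)
        sigma_clean = (
            evaluation.fit_sigma_theta(clean) if clean.size else float("nan")
        )

        nrmse_vals = sub["nrmse"].to_numpy()
        nrmse_mode, (nc, ne) = evaluation.histogram_mode(
            nrmse_vals, return_histogram=True
        )
        if nc.size > 400:  # keep the stored histogram compact; mode uses full bins
            nc2, ne2 = np.histogram(nrmse_vals, bins=400, range=(0.0, ne[-1]))
        else:
            nc2, ne2 = nc, ne

        valid = sub.loc[~sub["spectrum_flagged"]]
        xs = valid[["lam_T1", "lam_T2", "lam_T3"]].to_numpy().ravel()
        ys = valid[["lam_U1", "lam_U2", "lam_U3"]].to_numpy().ravel()
        ylo, yhi = np.percentile(ys, [0.5, 99.5]) if ys.size else (0.0, 1.0)
        h2, xe, ye = np.histogram2d(
            xs, ys, bins=spectra_bins, range=[[0.0, 1.0], [ylo, yhi]]
        )

        if len(sub) >= 2:
            reg = stats.linregress(sub["mean_eigenvalue"], sub["mean_signal"])
            slope, intercept, rvalue = reg.slope, reg.intercept, reg.rvalue
        else:
            slope = intercept = rvalue = float("nan")

        out["models"][tag] = {
            "sigma_delta_theta_deg": sigma_all,
            "sigma_delta_theta_deg_excl_degenerate": sigma_clean,
            "sigma_delta_theta_fit_up_to_max_deg": details["sigma_fit_up_to_max"],
            "delta_theta_n": details["n"],
            "nrmse_mode": nrmse_mode,
            "nrmse_max": float(nrmse_vals.max()),
            "nrmse_hist_counts": nc2,
            "nrmse_hist_edges": ne2,
            "spectra_hist_counts": h2.astype(int),
            "spectra_hist_x_edges": xe,
            "spectra_hist_y_edges": ye,
            "mean_signal_slope": slope,
            "mean_signal_intercept": intercept,
            "mean_signal_r": rvalue,
            "n_spectrum_flagged": int(sub["spectrum_flagged"].sum()),
            "n_clamped": int(sub["clamped"].sum()),
            "n_degenerate": int(sub["degenerate"].sum()),
        }
    return _json_safe(out)


def sigma_pair(summary: dict, *, exclude_degenerate: bool = False) -> tuple[float, float]:
    """(smaller, larger) of the two per-model sigma estimates in a summary."""
    key = (
        "sigma_delta_theta_deg_excl_degenerate"
        if exclude_degenerate
        else "sigma_delta_theta_deg"
    )
    vals = sorted(summary["models"][tag][key] for tag in MODEL_TAGS)
    return vals[0], vals[1]
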