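"""Beta-series GLM: one regressor per trial, estimated by ordinary least squares.

The design matrix holds one HRF-convolved unit stick per trial, one regressor
per run collecting all unconditioned-stimulus (US) events of that run, and a
discrete-cosine drift set implementing the high-pass filter.  Solving the
model per voxel yields the trial-by-trial BOLD amplitude ("beta series") that
all decoding stages operate on.

Conventions: the double-gamma HRF uses the standard parameterisation (response
delay 6 s, undershoot delay 16 s, unit dispersions, undershoot ratio 1/6,
32 s support) normalised to unit peak; convolution runs on a microtime grid of
``tr / oversample`` and is sampled at scan onsets k * TR; the high-pass cutoff
defaults to 128 s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .containers import TrialBetaMatrix
from .design import ExperimentDesign

__all__ = [
    "HrfKernel",
    "DesignMatrix",
    "canonical_hrf",
    "dct_drift_basis",
    "build_design_matrix",
    "estimate_trial_betas",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HrfKernel:
    """A sampled haemodynamic response kernel."""

    dt: float
    values: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def canonical_hrf(
    dt: float,
    *,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 6.0,
    duration: float = 32.0,
) -> HrfKernel:
    """Double-gamma canonical HRF sampled at step ``dt``, unit peak.

    h(t) = Gamma(t; peak_delay) - Gamma(t; undershoot_delay) / undershoot_ratio,
    with each Gamma a density with the given shape/dispersion.  An
    ``undershoot_ratio`` of 0 disables the undershoot term.
    """
    if not 0 < dt <= 1.0:
        raise ValueError(f"dt must lie in (0, 1] s, got {dt}")
    t = np.arange(0.0, duration, dt)
    peak = gamma_dist.pdf(t, peak_delay / peak_dispersion, scale=peak_dispersion)
    if undershoot_ratio > 0:
        under = gamma_dist.pdf(
            t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
        )
        h = peak - under / undershoot_ratio
    else:
        h = peak
    h = h / h.max()
    return HrfKernel(dt=dt, values=h, duration=duration)


def dct_drift_basis(n_scans: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine high-pass set: constant plus cosines up to 1/cutoff Hz.

    Column k (k >= 1) is cos(pi * k * (2n + 1) / (2 N)); the number of
    non-constant columns is floor(2 * duration / cutoff).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    duration = n_scans * tr
    n_cos = int(math.floor(2.0 * duration / cutoff))
    n_cos = min(n_cos, n_scans - 1)
    n = np.arange(n_scans)
    basis = np.ones((n_scans, n_cos + 1))
    for k in range(1, n_cos + 1):
        basis[:, k] = np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans))
    return basis


@dataclass
class DesignMatrix:
    """Scans x regressors matrix with labelled columns.

    ``trial_columns`` indexes the per-trial regressors, in chronological trial
    order; the remaining columns are US and drift regressors.
    """

    matrix: np.ndarray
    names: list[str]
    trial_columns: np.ndarray
    tr: float
    scan_times: np.ndarray

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def build_design_matrix(
    design: ExperimentDesign,
    tr: float,
    *,
    hrf: HrfKernel | None = None,
    highpass_cutoff: float = 128.0,
    n_scans: int | None = None,
    oversample: int = 16,
    n_blocks_per_run: int = 2,
    us_onset_offset: float | None = None,
    pad: float = 32.0,
) -> DesignMatrix:
    """Build the one-regressor-per-trial design matrix.

    Trial columns are unit sticks at each onset convolved with ``hrf`` on a
    microtime grid of ``tr / oversample`` and sampled at scan onsets.  US
    events (reinforced trials) are collected into one regressor per run, where
    a run spans ``n_blocks_per_run`` consecutive blocks; runs without US
    events contribute no column.  Drift columns are the DCT set up to
    ``highpass_cutoff``.  ``us_onset_offset`` places the US within the trial
    (default: co-terminating, stimulus_duration - 0.5 s).
    """
    if hrf is None:
        hrf = canonical_hrf(tr / oversample)
    elif abs(hrf.dt - tr / oversample) > 1e-12:
        raise ValueError("hrf.dt must equal tr / oversample")
    if us_onset_offset is None:
        us_onset_offset = max(design.params.stimulus_duration - 0.5, 0.0)

    last_end = max(t.onset for t in design.trials) + design.params.stimulus_duration
    if n_scans is None:
        n_scans = int(math.ceil((last_end + pad) / tr))
    window = n_scans * tr
    for t in design.trials:
        if t.onset >= window:
            raise ValueError(
                f"trial {t.index} onset {t.onset:.1f} s lies beyond the scan window "
                f"({window:.1f} s)"
            )

    dt = tr / oversample
    n_fine = n_scans * oversample
    scan_idx = np.arange(n_scans) * oversample

    def convolved_sticks(onsets: np.ndarray) -> np.ndarray:
        fine = np.zeros(n_fine)
        bins = np.round(np.asarray(onsets) / dt).astype(int)
        bins = bins[bins < n_fine]
        np.add.at(fine, bins, 1.0)
        full = np.convolve(fine, hrf.values)[:n_fine]
        return full[scan_idx]

    columns: list[np.ndarray] = []
    names: list[str] = []
    for t in design.trials:
        columns.append(convolved_sticks(np.array([t.onset])))
        names.append(f"trial_{t.index:03d}")
    trial_cols = np.arange(len(design.trials))

    # one US regressor per run (consecutive block groups) that contains US events
    runs: dict[int, list[float]] = {}
    for t in design.trials:
        if t.reinforced:
            run = (t.block - 1) // n_blocks_per_run
            runs.setdefault(run, []).append(t.onset + us_onset_offset)
    for run in sorted(runs):
        columns.append(convolved_sticks(np.array(runs[run])))
        names.append(f"us_run{run}")

    drift = dct_drift_basis(n_scans, tr, highpass_cutoff)
    for k in range(drift.shape[1]):
        columns.append(drift[:, k])
        names.append("constant" if k == 0 else f"drift_{k:02d}")

    X = np.column_stack(columns)
    return DesignMatrix(
        matrix=X,
        names=names,
        trial_columns=trial_cols,
        tr=tr,
        scan_times=np.arange(n_scans) * tr,
    )


def estimate_trial_betas(
    Y: np.ndarray,
    X: DesignMatrix,
    *,
    design: ExperimentDesign | None = None,
    participant: str | None = None,
    hemisphere: str | None = None,
    voxel_coords: np.ndarray | None = None,
) -> TrialBetaMatrix:
    """Per-voxel ordinary least squares; returns the trial coefficients only.

    Rank-deficient design matrices are solved by the minimum-norm
    pseudoinverse with a logged warning.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != X.n_scans:
        raise ValueError(
            f"Y must be scans x voxels with {X.n_scans} rows, got shape {Y.shape}"
        )
    rank = np.linalg.matrix_rank(X.matrix)
    if rank < X.n_columns:
        logger.warning(
            "design matrix is rank-deficient (rank %d < %d columns); "
            "using minimum-norm pseudoinverse",
            rank,
            X.n_columns,
        )
    beta = np.linalg.pinv(X.matrix) @ Y
    trial_betas = beta[X.trial_columns]
    return TrialBetaMatrix(
        data=trial_betas,
        trial_info=design.to_frame() if design is not None else None,
        participant=participant,
        hemisphere=hemisphere,
        voxel_coords=voxel_coords,
    )
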