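"""Synthetic voxel patterns and trial-wise data with known ground truth.

The generative model encodes the hypothesis the decoding analysis is built to
test.  Every stimulus pair (CS or NS, simple or complex) is separated by a
"physical stimulus" contrast vector, so that the two members of any pair are
discriminable to the same degree; the CS pair in the reinforcement context
additionally carries a "threat association" contrast that is absent for the
neutral sounds.  Setting the threat amplitude to zero therefore makes CS and
NS pairs statistically exchangeable, which is the null condition for
calibration tests.

Two output modes exist: "beta" mode draws trial-wise response amplitudes
directly (condition mean + i.i.d. Gaussian noise), and "time-series" mode
renders the amplitudes into a BOLD time series through HRF convolution, from
which the GLM stage can re-estimate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TrialBetaMatrix
from .design import ALL_STIMULI, COMPLEXITIES, CONTEXTS, ExperimentDesign, StimulusId
from . import glm as _glm

__all__ = [
    "SynthParams",
    "PatternBasis",
    "TimeseriesSim",
    "make_pattern_basis",
    "simulate_betas",
    "simulate_timeseries",
]


@dataclass(frozen=True)
class SynthParams:
    """Amplitudes and noise of the generative voxel-pattern model.

    ``stimulus_amp`` is the norm of the contrast vector separating the two
    members of every sound pair; ``complex_attenuation`` scales it for complex
    sounds (triads are harder to discriminate, so their pattern separation is
    smaller by default).  ``threat_amp`` is the norm of the extra contrast that
    separates CS+ from CS- only.  ``threat_shared`` controls whether simple
    and complex sounds share one threat contrast vector (cross-decodable) or
    carry independent ones.  ``noise_sd`` is the per-trial, per-voxel Gaussian
    noise standard deviation.
    """

    n_voxels: int = 200
    stimulus_amp: float = 1.0
    threat_amp: float = 1.2
    complex_attenuation: float = 0.6
    noise_sd: float = 1.0
    basis_mode: str = "gaussian_random"
    threat_shared: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be at least 2")
        if self.stimulus_amp < 0 or self.threat_amp < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.complex_attenuation < 0:
            raise ValueError("complex_attenuation must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.basis_mode not in ("gaussian_random", "orthogonal"):
            raise ValueError("basis_mode must be 'gaussian_random' or 'orthogonal'")


@dataclass
class PatternBasis:
    """Ground-truth mean patterns, with components stored separately.

    ``stimulus_contrasts[(context, complexity)]`` is the vector separating S2
    from S1 in that pair; ``threat_contrasts[complexity]`` the extra CS+/CS-
    separation (zero vectors for the nonreinforcement context by
    construction).  The mean pattern of a stimulus is
    ``baseline +/- contrast/2`` with sign +1 for S2 and -1 for S1.
    """

    baseline: np.ndarray
    stimulus_contrasts: dict[tuple[str, str], np.ndarray]
    threat_contrasts: dict[str, np.ndarray]

    @property
    def n_voxels(self) -> int:
        return self.baseline.shape[0]

    def mean_pattern(self, stim: StimulusId) -> np.ndarray:
        sign = 1.0 if stim.pair_role == "S2" else -1.0
        mean = self.baseline + 0.5 * sign * self.stimulus_contrasts[(stim.context, stim.complexity)]
        if stim.context == "reinforcement":
            mean = mean + 0.5 * sign * self.threat_contrasts[stim.complexity]
        return mean

    def mean_matrix(self, design: ExperimentDesign) -> np.ndarray:
        """Trials x voxels matrix of condition means in design order."""
        cache = {s: self.mean_pattern(s) for s in ALL_STIMULI}
        return np.array([cache[t.stimulus] for t in design.trials])


def _scaled(v: np.ndarray, amp: float) -> np.ndarray:
    norm = np.linalg.norm(v)
    if amp == 0 or norm == 0:
        return np.zeros_like(v)
    return v * (amp / norm)


def make_pattern_basis(
    params: SynthParams,
    *,
    threat_support: np.ndarray | None = None,
) -> PatternBasis:
    """Draw the ground-truth component vectors, deterministically in the seed.

    In ``gaussian_random`` mode each contrast is an independent Gaussian
    vector rescaled to its amplitude; in ``orthogonal`` mode all contrasts are
    mutually orthogonal (QR of a seeded Gaussian matrix), which requires at
    least as many voxels as components.  ``threat_support`` optionally
    restricts the threat contrasts to a boolean voxel subset (used to implant
    a localised association signal for searchlight simulations); the vector
    norm still equals ``threat_amp``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_voxels
    pair_keys = [(ctx, cx) for ctx in CONTEXTS for cx in COMPLEXITIES]
    threat_keys = list(COMPLEXITIES)
    n_components = len(pair_keys) + (1 if params.threat_shared else len(threat_keys))

    if params.basis_mode == "orthogonal":
        if n < n_components:
            raise ValueError(
                f"orthogonal mode needs n_voxels >= {n_components}, got {n}"
            )
        q, _ = np.linalg.qr(rng.normal(size=(n, n_components)))
        raw = [q[:, i] for i in range(n_components)]
    else:
        raw = [rng.normal(size=n) for _ in range(n_components)]

    stim_amp = {
        "simple": params.stimulus_amp,
        "complex": params.stimulus_amp * params.complex_attenuation,
    }
    stimulus_contrasts = {
        key: _scaled(raw[i], stim_amp[key[1]]) for i, key in enumerate(pair_keys)
    }

    threat_raw = raw[len(pair_keys):]
    if params.threat_shared:
        threat_raw = [threat_raw[0], threat_raw[0]]
    threat_contrasts = {}
    for cx, vec in zip(threat_keys, threat_raw):
        vec = vec.copy()
        if threat_support is not None:
            support = np.asarray(threat_support, dtype=bool)
            if support.shape != (n,):
                raise ValueError("threat_support must be a boolean vector of length n_voxels")
            vec[~support] = 0.0
        threat_contrasts[cx] = _scaled(vec, params.threat_amp)
    return PatternBasis(
        baseline=np.zeros(n),
        stimulus_contrasts=stimulus_contrasts,
        threat_contrasts=threat_contrasts,
    )


def simulate_betas(
    design: ExperimentDesign,
    basis: PatternBasis,
    params: SynthParams,
    *,
    rng: np.random.Generator | int | None = None,
    participant: str | None = None,
    hemisphere: str | None = None,
    voxel_coords: np.ndarray | None = None,
) -> TrialBetaMatrix:
    """Trial-wise amplitudes: condition mean + i.i.d. Gaussian noise per trial/voxel."""
    if basis.n_voxels != params.n_voxels:
        raise ValueError("basis and params disagree on n_voxels")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    means = basis.mean_matrix(design)
    data = means + params.noise_sd * rng.normal(size=means.shape)
    return TrialBetaMatrix(
        data=data,
        trial_info=design.to_frame(),
        participant=participant,
        hemisphere=hemisphere,
        voxel_coords=voxel_coords,
    )


@dataclass
class TimeseriesSim:
    """Simulated BOLD run: scans x voxels data plus the generating amplitudes."""

    data: np.ndarray
    truth: TrialBetaMatrix
    tr: float
    scan_times: np.ndarray


def simulate_timeseries(
    design: ExperimentDesign,
    basis: PatternBasis,
    params: SynthParams,
    tr: float = 2.5,
    *,
    scan_noise_sd: float = 0.0,
    drift_amp: float = 0.0,
    drift_period: float = 200.0,
    ar_coef: float = 0.0,
    us_amp: float = 0.0,
    oversample: int = 16,
    rng: np.random.Generator | int | None = None,
) -> TimeseriesSim:
    """Render trial amplitudes into a BOLD time series at repetition time ``tr``.

    Per voxel the signal is the sum over trials of the trial amplitude times
    an HRF-convolved stick at the trial onset.  Trial amplitudes are the
    condition mean plus ``params.noise_sd`` trial-to-trial variability (the
    same role noise plays in beta mode); ``scan_noise_sd`` adds independent
    (optionally AR(1), via ``ar_coef``) measurement noise per scan, and
    ``drift_amp`` adds a slow sinusoid of period ``drift_period`` seconds.
    US events evoke a response of amplitude ``us_amp`` uniform across voxels.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = _glm.build_design_matrix(design, tr, oversample=oversample)
    n_scans = X.n_scans
    n_vox = basis.n_voxels

    amplitudes = basis.mean_matrix(design)
    if params.noise_sd > 0:
        amplitudes = amplitudes + params.noise_sd * rng.normal(size=amplitudes.shape)

    Y = X.matrix[:, X.trial_columns] @ amplitudes
    us_cols = [i for i, name in enumerate(X.names) if name.startswith("us_run")]
    if us_cols and us_amp != 0.0:
        Y = Y + X.matrix[:, us_cols].sum(axis=1, keepdims=True) * us_amp

    if drift_amp != 0.0:
        t = X.scan_times
        Y = Y + drift_amp * np.sin(2 * np.pi * t / drift_period)[:, None]

    if scan_noise_sd > 0:
        eps = scan_noise_sd * rng.normal(size=(n_scans, n_vox))
        if ar_coef != 0.0:
            from scipy.signal import lfilter

            eps = lfilter([1.0], [1.0, -ar_coef], eps, axis=0)
        Y = Y + eps

    truth = TrialBetaMatrix(data=amplitudes, trial_info=design.to_frame())
    return TimeseriesSim(data=Y, truth=truth, tr=tr, scan_times=X.scan_times)
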