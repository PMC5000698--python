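"""Dual-rotating-retarder Mueller polarimeter: forward model and inversion.

The instrument places the sample between a polarization state generator
(fixed linear polarizer, then a rotating quarter-wave retarder at angle
``theta``) and an analyzer (a second quarter-wave retarder at ``ratio *
theta``, then a fixed polarizer).  With the generator retarder as the slow
axis variable, the detected intensity is a truncated Fourier series in the
slow angle with harmonics up to ``2 * 12 * theta`` for the classic 5:1
rate ratio (Azzam scheme):

    I(theta) = a0 + sum_{n=1..12} a_n cos(2 n theta) + b_n sin(2 n theta)

All 16 Mueller elements are linearly encoded in the 25 coefficients.  The
inversion here solves the equivalent direct linear system
``I_k = sum_ij c_ij(theta_k) m_ij`` built from the same ideal element
chain as the forward model; the analytic Fourier fit is kept as a
diagnostic and the two routes agree to numerical precision.

The ideal polarizer transmits half of unpolarized light; this overall scale
cancels under m11 normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mueller import MuellerMatrix

__all__ = [
    "PolarimeterConfig",
    "FourierCoefficients",
    "rotation_mueller",
    "polarizer_mueller",
    "retarder_mueller",
    "forward_intensity",
    "forward_intensities",
    "fit_fourier",
    "mueller_from_intensities",
]

N_HARMONICS = 12  # highest harmonic of 2*theta present for the 5:1 scheme


@dataclass(frozen=True)
class PolarimeterConfig:
    """Geometry of the dual-rotating-retarder measurement.

    theta_ratio
        Integer ratio of analyzer to generator retarder rotation rates.
    n_steps
        Number of evenly spaced generator angles over [0, 180) degrees;
        must be at least 25 (the number of Fourier unknowns).
    retardance_deg
        Waveplate retardance (90 = quarter wave).
    polarizer_deg / analyzer_deg
        Fixed polarizer transmission axes (0 = horizontal).
    oblique_angle_deg
        Illumination/detection opening angle; metadata only, the forward
        model treats the arms as collinear.
    """

    theta_ratio: int = 5
    n_steps: int = 30
    retardance_deg: float = 90.0
    polarizer_deg: float = 0.0
    analyzer_deg: float = 0.0
    oblique_angle_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.n_steps < 25:
            raise ValueError(
                f"n_steps={self.n_steps} < 25: fewer intensity samples than "
                "Fourier unknowns"
            )
        if self.theta_ratio < 1:
            raise ValueError("theta_ratio must be a positive integer")

    def slow_angles_deg(self) -> np.ndarray:
        """Even sampling of the generator retarder angle over [0, 180)."""
        return np.arange(self.n_steps) * (180.0 / self.n_steps)


@dataclass(frozen=True)
class FourierCoefficients:
    """Truncated Fourier series of the detected intensity (25 coefficients)."""

    alpha0: float
    alpha: np.ndarray  # harmonics 1..12 of cos(2 n theta)
    beta: np.ndarray  # harmonics 1..12 of sin(2 n theta)
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_HARMONICS,):
                raise ValueError(f"{name} must have {N_HARMONICS} entries")
            object.__setattr__(self, name, arr)

    def evaluate(self, theta_deg: np.ndarray) -> np.ndarray:
        t = np.deg2rad(np.asarray(theta_deg, dtype=float))[..., None]
        n = np.arange(1, N_HARMONICS + 1)
        return (
            self.alpha0
            + (self.alpha * np.cos(2 * n * t)).sum(-1)
            + (self.beta * np.sin(2 * n * t)).sum(-1)
        )


def rotation_mueller(angle_deg: float) -> np.ndarray:
    """Mueller rotation matrix for a frame rotation by ``angle_deg``."""
    c, s = np.cos(2 * np.deg2rad(angle_deg)), np.sin(2 * np.deg2rad(angle_deg))
    return np.array(
        [[1, 0, 0, 0], [0, c, s, 0], [0, -s, c, 0], [0, 0, 0, 1]], dtype=float
    )


def polarizer_mueller(axis_deg: float) -> np.ndarray:
    """Ideal linear polarizer at ``axis_deg`` (transmits 1/2 of unpolarized)."""
    p0 = 0.5 * np.array(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]], dtype=float
    )
    return rotation_mueller(-axis_deg) @ p0 @ rotation_mueller(axis_deg)


def retarder_mueller(fast_axis_deg: float, retardance_deg: float = 90.0) -> np.ndarray:
    """Ideal linear retarder with fast axis at ``fast_axis_deg``."""
    d = np.deg2rad(retardance_deg)
    cd, sd = np.cos(d), np.sin(d)
    r0 = np.array(
        [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, cd, sd], [0, 0, -sd, cd]], dtype=float
    )
    return rotation_mueller(-fast_axis_deg) @ r0 @ rotation_mueller(fast_axis_deg)


def _generator_stokes(slow_angle_deg: float, cfg: PolarimeterConfig) -> np.ndarray:
    """Stokes vector produced by the PSG for unit unpolarized input."""
    s0 = np.array([1.0, 0.0, 0.0, 0.0])
    g = retarder_mueller(slow_angle_deg, cfg.retardance_deg) @ polarizer_mueller(
        cfg.polarizer_deg
    )
    return g @ s0


def _analyzer_row(slow_angle_deg: float, cfg: PolarimeterConfig) -> np.ndarray:
    """First row of the PSA Mueller chain (intensity projection)."""
    a = polarizer_mueller(cfg.analyzer_deg) @ retarder_mueller(
        cfg.theta_ratio * slow_angle_deg, cfg.retardance_deg
    )
    return a[0]


def forward_intensity(
    M: MuellerMatrix | np.ndarray,
    slow_angle_deg: float,
    cfg: PolarimeterConfig = PolarimeterConfig(),
) -> float:
    """Detected intensity for one generator retarder angle."""
    m = M.m if isinstance(M, MuellerMatrix) else np.asarray(M, dtype=float)
    return float(_analyzer_row(slow_angle_deg, cfg) @ m @ _generator_stokes(slow_angle_deg, cfg))


def forward_intensities(
    M: MuellerMatrix | np.ndarray, cfg: PolarimeterConfig = PolarimeterConfig()
) -> np.ndarray:
    """Intensity curve over the configured rotation steps."""
    return np.array(
        [forward_intensity(M, a, cfg) for a in cfg.slow_angles_deg()]
    )


def fit_fourier(
    intensities: np.ndarray,
    slow_angles_deg: np.ndarray,
    cfg: PolarimeterConfig = PolarimeterConfig(),
) -> FourierCoefficients:
    """Least-squares fit of the 25-term truncated Fourier series.

    Raises
    ------
    ValueError
        On mismatched/short inputs or a rank-deficient design (repeated
        angles).
    """
    y = np.asarray(intensities, dtype=float)
    t = np.deg2rad(np.asarray(slow_angles_deg, dtype=float))
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("intensities and slow_angles must be equal-length vectors")
    if y.size < 2 * N_HARMONICS + 1:
        raise ValueError(f"need at least {2 * N_HARMONICS + 1} samples, got {y.size}")
    n = np.arange(1, N_HARMONICS + 1)
    design = np.concatenate(
        [
            np.ones((t.size, 1)),
            np.cos(2 * n * t[:, None]),
            np.sin(2 * n * t[:, None]),
        ],
        axis=1,
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "rank-deficient Fourier design: rotation angles are not distinct "
            "enough for 25 coefficients"
        )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = float(np.linalg.norm(design @ coef - y))
    return FourierCoefficients(
        alpha0=float(coef[0]),
        alpha=coef[1 : N_HARMONICS + 1],
        beta=coef[N_HARMONICS + 1 :],
        residual_norm=resid,
    )


def _design_matrix(slow_angles_deg: np.ndarray, cfg: PolarimeterConfig) -> np.ndarray:
    """Rows c_ij(theta_k) of the direct linear map intensity = C . vec(M)."""
    rows = []
    for a in slow_angles_deg:
        rows.append(np.outer(_analyzer_row(a, cfg), _generator_stokes(a, cfg)).ravel())
    return np.asarray(rows)


def mueller_from_intensities(
    intensities: np.ndarray,
    cfg: PolarimeterConfig = PolarimeterConfig(),
    slow_angles_deg: np.ndarray | None = None,
) -> MuellerMatrix:
    """Recover the 16 Mueller elements from a measured intensity curve.

    Solves the direct least-squares system built from the same ideal element
    chain as :func:`forward_intensity`; the forward->recover round trip is
    exact to numerical precision.

    Raises
    ------
    ValueError
        If the design matrix is numerically singular for the given
        configuration (advises changing n_steps or theta_ratio).
    """
    y = np.asarray(intensities, dtype=float)
    angles = (
        cfg.slow_angles_deg() if slow_angles_deg is None else np.asarray(slow_angles_deg)
    )
    if y.shape != angles.shape:
        raise ValueError("intensities do not match the configured rotation steps")
    if y.size < 25:
        raise ValueError("need at least 25 intensity samples")
    design = _design_matrix(angles, cfg)
    cond = np.linalg.cond(design)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"singular measurement design (cond={cond:.3g}); choose a different "
            "n_steps / theta_ratio combination"
        )
    m, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MuellerMatrix(m.reshape(4, 4))
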