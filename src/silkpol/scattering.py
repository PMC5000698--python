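"""Single-scattering operators for the sphere-cylinder medium model.

The medium contains two scatterer species: small spheres (surface
roughness, particles) and long circular cylinders (fibers).  This module
turns their amplitude functions (:mod:`silkpol.mie`,
:mod:`silkpol.cylinder`) into single-scattering Mueller matrices, tabulates
polarization-dependent phase functions, and importance-samples scattering
directions for the Monte Carlo transport.

Basis conventions
-----------------
Field components are (E_par, E_perp) with "parallel" in the scattering
plane (spheres) or in the plane containing the propagation direction and
the cylinder axis (cylinders).  Stokes vectors use
``Q = |E_par|^2 - |E_perp|^2``, ``U = 2 Re(E_par E_perp*)``,
``V = -2 Im(E_par E_perp*)``, matching the frame-rotation matrix in
:func:`silkpol.polarimeter.rotation_mueller`.  The amplitude matrix is
``[[S2, S3], [S4, S1]]`` acting on (E_par, E_perp); the Mueller matrix is
the exact quadratic (Kronecker) image of that Jones-like matrix, so sign
bookkeeping is delegated to linear algebra rather than transcribed
formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cylinder import GRAZING_CUTOFF_RAD, cylinder_amplitudes
from .mie import mie_amplitudes, size_parameter

__all__ = [
    "SphereSpecies",
    "CylinderSpecies",
    "PhaseSample",
    "phase_matrix_from_amplitudes",
    "SpherePhaseTable",
    "CylinderPhaseTable",
    "sample_scattering_direction",
]

# (I,Q,U,V) = _A @ (E1E1*, E1E2*, E2E1*, E2E2*)
_A = np.array(
    [
        [1, 0, 0, 1],
        [1, 0, 0, -1],
        [0, 1, 1, 0],
        [0, 1j, -1j, 0],
    ],
    dtype=complex,
)
_A_INV = np.linalg.inv(_A)


@dataclass(frozen=True)
class SphereSpecies:
    """Spherical scatterer population (diameter in um, mu_s in 1/cm)."""

    diameter_um: float = 0.2
    refractive_index: float = 1.56
    scattering_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("sphere diameter must be positive")
        if self.scattering_coefficient < 0:
            raise ValueError("scattering coefficient must be non-negative")


@dataclass(frozen=True)
class CylinderSpecies:
    """Cylindrical scatterer population with a Gaussian in-plane orientation.

    ``orientation_mean_deg`` is measured from the image x-axis;
    ``orientation_std_deg`` is the standard deviation of the per-event
    Gaussian orientation draw.
    """

    diameter_um: float = 1.5
    refractive_index: float = 1.56
    scattering_coefficient: float = 0.0
    orientation_mean_deg: float = 0.0
    orientation_std_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("cylinder diameter must be positive")
        if self.scattering_coefficient < 0:
            raise ValueError("scattering coefficient must be non-negative")
        if self.orientation_std_deg < 0:
            raise ValueError("orientation std must be non-negative")


@dataclass
class PhaseSample:
    """One sampled scattering event."""

    theta_s: float  # polar scattering angle (spheres) or cone azimuth (cylinders)
    phi_s: float  # azimuth of the scattering plane about the incoming direction
    mueller: np.ndarray  # 4x4 single-scattering Mueller matrix at the sampled angles
    new_direction: np.ndarray
    weight: float = 1.0


def phase_matrix_from_amplitudes(s1, s2, s3=0.0, s4=0.0) -> np.ndarray:
    """Mueller matrix/matrices from amplitude components (broadcastable).

    Parameters are the amplitude-matrix entries ``[[S2, S3], [S4, S1]]``
    (for spheres S3 = S4 = 0; for cylinders S2=T1, S1=T2, S4=T3, S3=T4).
    Returns an array of shape ``broadcast_shape + (4, 4)``.
    """
    s1, s2, s3, s4 = np.broadcast_arrays(
        *(np.asarray(a, dtype=complex) for a in (s1, s2, s3, s4))
    )
    if not all(np.all(np.isfinite(a)) for a in (s1, s2, s3, s4)):
        raise ValueError("amplitudes must be finite")
    j = np.empty(s1.shape + (2, 2), dtype=complex)
    j[..., 0, 0] = s2
    j[..., 0, 1] = s3
    j[..., 1, 0] = s4
    j[..., 1, 1] = s1
    # Kronecker square J (x) J*, then conjugate by the Stokes map _A.
    jj = np.einsum("...ij,...kl->...ikjl", j, j.conj()).reshape(s1.shape + (4, 4))
    m = np.einsum("ab,...bc,cd->...ad", _A, jj, _A_INV)
    return np.ascontiguousarray(m.real)


def _rotation_block(phi: np.ndarray) -> np.ndarray:
    """Stokes frame-rotation matrices for angles ``phi`` (rad), shape (...,4,4)."""
    phi = np.asarray(phi, dtype=float)
    c, s = np.cos(2 * phi), np.sin(2 * phi)
    out = np.zeros(phi.shape + (4, 4))
    out[..., 0, 0] = 1.0
    out[..., 3, 3] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = s
    out[..., 2, 1] = -s
    out[..., 2, 2] = c
    return out


class SpherePhaseTable:
    """Tabulated Mie phase function for one sphere species.

    The polar marginal of the polarization-dependent phase function is
    ``M11(theta) sin(theta)`` independent of the incident Stokes vector;
    it is inverted from a tabulated CDF (default 721 polar nodes).  The
    azimuth conditional ``a + b cos(2 phi) + c sin(2 phi)`` is sampled by
    rejection in the Monte Carlo.
    """

    def __init__(
        self,
        x: float | None = None,
        m: float | None = None,
        n_theta: int = 721,
        theta: np.ndarray | None = None,
        mueller: np.ndarray | None = None,
    ) -> None:
        if mueller is None:
            if x is None or m is None:
                raise ValueError("provide (x, m) or an explicit (theta, mueller) table")
            theta = np.linspace(0.0, np.pi, n_theta)
            res = mie_amplitudes(x, m, theta)
            mueller = phase_matrix_from_amplitudes(res.s1, res.s2)
        self.theta = np.asarray(theta, dtype=float)
        self.mueller = np.asarray(mueller, dtype=float)
        if self.mueller.shape != self.theta.shape + (4, 4):
            raise ValueError("mueller table must have shape (n_theta, 4, 4)")
        if np.any(self.mueller[:, 0, 0] < 0):
            raise ValueError("phase-function element (1,1) must be non-negative")
        pdf = self.mueller[:, 0, 0] * np.sin(self.theta)
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(self.theta))])
        self._cdf = cdf / cdf[-1]

    def sample_theta(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Inverse-CDF draw of the polar scattering angle (linear interp)."""
        return np.interp(rng.random(n), self._cdf, self.theta)

    def mueller_at(self, theta: np.ndarray) -> np.ndarray:
        """Linearly interpolated Mueller matrices at arbitrary angles."""
        theta = np.asarray(theta, dtype=float)
        idx = np.clip(np.searchsorted(self.theta, theta) - 1, 0, self.theta.size - 2)
        t0 = self.theta[idx]
        w = ((theta - t0) / (self.theta[idx + 1] - t0))[..., None, None]
        return (1 - w) * self.mueller[idx] + w * self.mueller[idx + 1]


class CylinderPhaseTable:
    """Tabulated cylinder phase function over axial angle and cone azimuth.

    The scattered direction lies on the cone of the incident axial angle
    ``zeta``; only the cone azimuth ``Theta`` is random.  Mueller matrices
    are tabulated on a (zeta, Theta) grid (default 91 x 360) and looked up
    at the nearest zeta node during transport (sub-degree resolution).
    """

    def __init__(
        self,
        x: float,
        m: float,
        n_zeta: int = 91,
        n_phi: int = 360,
        zeta_min: float = 2.0 * GRAZING_CUTOFF_RAD,
    ) -> None:
        self.zeta_grid = np.linspace(zeta_min, np.pi / 2, n_zeta)
        self.phi_grid = np.linspace(-np.pi, np.pi, n_phi, endpoint=False)
        tables = []
        for z in self.zeta_grid:
            res = cylinder_amplitudes(x, m, z, self.phi_grid)
            tables.append(
                phase_matrix_from_amplitudes(res.t2, res.t1, res.t4, res.t3)
            )
        self.mueller = np.stack(tables)  # (n_zeta, n_phi, 4, 4)

    def zeta_index(self, zeta: np.ndarray) -> np.ndarray:
        """Nearest tabulated axial-angle node."""
        z = np.clip(np.asarray(zeta, dtype=float), self.zeta_grid[0], self.zeta_grid[-1])
        step = self.zeta_grid[1] - self.zeta_grid[0]
        return np.clip(
            np.rint((z - self.zeta_grid[0]) / step).astype(int), 0, self.zeta_grid.size - 1
        )


def _perpendicular(v: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to unit vector ``v``."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def sample_scattering_direction(
    species: SphereSpecies | CylinderSpecies,
    direction: np.ndarray,
    stokes: np.ndarray,
    rng: np.random.Generator,
    wavelength_nm: float = 633.0,
    background_index: float = 1.0,
    table: SpherePhaseTable | CylinderPhaseTable | None = None,
    reference: np.ndarray | None = None,
) -> PhaseSample:
    """Draw one scattering direction from the polarization-dependent phase function.

    ``stokes`` is expressed in the local basis ``(reference, direction x
    reference, direction)``; ``reference`` defaults to an arbitrary
    perpendicular.  The returned sample carries the Mueller matrix at the
    drawn angles and unit statistical weight (the estimator stays unbiased
    because the draw follows the scattered-intensity law exactly and the
    transported Stokes vector is renormalized to it).
    """
    u = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    s = np.asarray(stokes, dtype=float)
    e1 = _perpendicular(u) if reference is None else np.asarray(reference, dtype=float)
    e2 = np.cross(u, e1)
    x = size_parameter(species.diameter_um, wavelength_nm, background_index)
    rel_m = species.refractive_index / background_index

    if isinstance(species, SphereSpecies):
        tab = table or SpherePhaseTable(x, rel_m)
        theta = float(tab.sample_theta(rng, 1)[0])
        mu = tab.mueller_at(np.array([theta]))[0]
        a = mu[0, 0] * s[0]
        b = mu[0, 1] * s[1]
        c = mu[0, 1] * s[2]
        bound = a + np.hypot(b, c)
        while True:
            phi = rng.uniform(0.0, 2 * np.pi)
            if rng.random() * bound <= a + b * np.cos(2 * phi) + c * np.sin(2 * phi):
                break
        w = np.cos(phi) * e1 + np.sin(phi) * e2
        new_dir = np.cos(theta) * u + np.sin(theta) * w
        return PhaseSample(theta_s=theta, phi_s=phi, mueller=mu, new_direction=new_dir)

    # Cylinder: redraw the fiber orientation, scatter on the cone.
    tab = table or CylinderPhaseTable(x, rel_m)
    while True:
        alpha = np.deg2rad(
            rng.normal(species.orientation_mean_deg, species.orientation_std_deg)
        )
        axis = np.array([np.cos(alpha), np.sin(alpha), 0.0])
        ca = float(u @ axis)
        if ca < 0:  # fold: the cylinder is symmetric under axis flip
            axis, ca = -axis, -ca
        if ca < 1.0 - 1e-9:
            break
    zeta = np.arccos(ca)
    zi = int(tab.zeta_index(zeta))
    # Incidence-plane basis and the rotation angle from the photon frame.
    f1 = axis - ca * u
    f1 /= np.linalg.norm(f1)
    phi = float(np.arctan2(f1 @ e2, f1 @ e1))
    srot = _rotation_block(np.array(phi)) @ s
    row = tab.mueller[zi, :, 0, :]
    pmf = np.maximum(row @ srot, 0.0)
    if pmf.sum() <= 0:
        raise RuntimeError("degenerate cylinder phase function")
    k = rng.choice(tab.phi_grid.size, p=pmf / pmf.sum())
    theta_cone = float(tab.phi_grid[k])
    mu = tab.mueller[zi, k]
    c1 = u - ca * axis
    c1 /= np.linalg.norm(c1)
    c2 = np.cross(axis, c1)
    new_dir = ca * axis + np.sin(zeta) * (np.cos(theta_cone) * c1 + np.sin(theta_cone) * c2)
    return PhaseSample(theta_s=theta_cone, phi_s=phi, mueller=mu, new_direction=new_dir)
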