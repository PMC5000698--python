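"""Scattering by an infinite circular cylinder at oblique incidence.

Partial-wave solution for a homogeneous dielectric cylinder (real index)
illuminated at angle ``zeta`` from the cylinder axis; scattered light lies
on a cone of the same axial angle.  The four amplitude functions on the
cone azimuth ``Theta`` (0 = forward) are

    T1: parallel -> parallel      T2: perpendicular -> perpendicular
    T3: parallel -> perpendicular T4: perpendicular -> parallel

with "parallel" meaning in the plane containing the propagation direction
and the cylinder axis.  At normal incidence (zeta = pi/2) the cross terms
T3, T4 vanish identically and the two principal modes decouple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import jv, jvp, yv, yvp

__all__ = ["CylinderResult", "cylinder_coefficients", "cylinder_amplitudes"]

GRAZING_CUTOFF_RAD = 1e-3  # below this axial angle the series is ill-conditioned


@dataclass(frozen=True)
class CylinderResult:
    """Amplitudes on an azimuth grid plus the partial-wave coefficients."""

    phi: np.ndarray  # cone azimuth Theta (rad), 0 = forward
    t1: np.ndarray
    t2: np.ndarray
    t3: np.ndarray
    t4: np.ndarray
    a1: np.ndarray  # case-I cross coefficients a_nI, n = 0..nmax
    b1: np.ndarray  # case-I principal coefficients b_nI
    a2: np.ndarray  # case-II principal coefficients a_nII
    b2: np.ndarray  # case-II cross coefficients b_nII


def _n_terms(x: float) -> int:
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 4.0))


def cylinder_coefficients(
    x: float, m: float, zeta: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Partial-wave coefficients (a_nI, b_nI, a_nII, b_nII), n = 0..nmax.

    Parameters
    ----------
    x
        Size parameter pi d / lambda (> 0).
    m
        Relative refractive index (> 0, real).
    zeta
        Angle between the incident direction and the cylinder axis,
        in (GRAZING_CUTOFF_RAD, pi/2].
    """
    if not (x > 0):
        raise ValueError(f"size parameter must be positive, got {x}")
    if not (GRAZING_CUTOFF_RAD < zeta <= np.pi / 2 + 1e-12):
        raise ValueError(
            f"incidence angle {zeta} rad outside ({GRAZING_CUTOFF_RAD}, pi/2]"
        )
    nmax = _n_terms(x)
    n = np.arange(0, nmax + 1)
    cz, sz = np.cos(zeta), np.sin(zeta)
    xi = x * sz
    eta = x * np.sqrt(m**2 - cz**2)

    jn_eta, jn_eta_p = jv(n, eta), jvp(n, eta)
    jn_xi, jn_xi_p = jv(n, xi), jvp(n, xi)
    hn_xi = jn_xi + 1j * yv(n, xi)
    hn_xi_p = jn_xi_p + 1j * yvp(n, xi)

    an = 1j * xi * (xi * jn_eta_p * jn_xi - eta * jn_eta * jn_xi_p)
    bn = xi * (m**2 * xi * jn_eta_p * jn_xi - eta * jn_eta * jn_xi_p)
    cn = n * cz * eta * jn_eta * jn_xi * (xi**2 / eta**2 - 1.0)
    dn = n * cz * eta * jn_eta * hn_xi * (xi**2 / eta**2 - 1.0)
    vn = xi * (m**2 * xi * jn_eta_p * hn_xi - eta * jn_eta * hn_xi_p)
    wn = 1j * xi * (eta * jn_eta * hn_xi_p - xi * jn_eta_p * hn_xi)

    denom = wn * vn + 1j * dn**2
    a1 = (cn * vn - bn * dn) / denom
    b1 = (wn * bn + 1j * dn * cn) / denom
    a2 = -(an * vn - 1j * cn * dn) / denom
    b2 = -1j * (cn * wn + an * dn) / denom
    return a1, b1, a2, b2


def cylinder_amplitudes(
    x: float, m: float, zeta: float, phi: np.ndarray
) -> CylinderResult:
    """Amplitude functions T1..T4 on the cone azimuth grid ``phi`` (rad)."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if phi.size == 0:
        raise ValueError("azimuth grid must be non-empty")
    a1, b1, a2, b2 = cylinder_coefficients(x, m, zeta)
    nmax = a1.size - 1
    n = np.arange(1, nmax + 1)
    cosn = np.cos(np.outer(n, phi))
    sinn = np.sin(np.outer(n, phi))
    t1 = b1[0] + 2.0 * (b1[1:, None] * cosn).sum(axis=0)
    t2 = a2[0] + 2.0 * (a2[1:, None] * cosn).sum(axis=0)
    t3 = -2j * (a1[1:, None] * sinn).sum(axis=0)
    t4 = -2j * (b2[1:, None] * sinn).sum(axis=0)
    return CylinderResult(phi=phi, t1=t1, t2=t2, t3=t3, t4=t4, a1=a1, b1=b1, a2=a2, b2=b2)


def scattering_cross_section_sums(res: CylinderResult) -> tuple[float, float]:
    """Parseval sums ``|b0I|^2 + 2 sum(|b_nI|^2 + |a_nI|^2)`` per incident mode.

    Equals ``(1/2pi) int (|T1|^2 + |T3|^2) dTheta`` (case I, incident
    parallel) and the analogue with (T2, T4) for case II; proportional to
    the scattering cross section per unit length for each incident
    polarization.
    """
    c1 = float(np.abs(res.b1[0]) ** 2 + 2.0 * (np.abs(res.b1[1:]) ** 2 + np.abs(res.a1[1:]) ** 2).sum())
    c2 = float(np.abs(res.a2[0]) ** 2 + 2.0 * (np.abs(res.a2[1:]) ** 2 + np.abs(res.b2[1:]) ** 2).sum())
    return c1, c2
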