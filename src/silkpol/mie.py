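"""Lorenz-Mie solution for homogeneous spheres (real refractive index).

Scattering amplitudes S1 (perpendicular) and S2 (parallel) are defined in
the scattering-plane basis, with the amplitude scattering matrix
``[[S2, 0], [0, S1]]`` acting on (E_par, E_perp).  The partial-wave series
is truncated at the standard ``x + 4 x^(1/3) + 2`` term count; the
logarithmic derivative is evaluated by downward recurrence.

Absorption is not modeled (the fibrous-medium model uses a real index of
1.56 in an index-1.0 interstitial medium); the single-scattering albedo is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MieResult", "mie_coefficients", "mie_amplitudes", "size_parameter"]


def size_parameter(diameter_um: float, wavelength_nm: float, n_background: float = 1.0) -> float:
    """Size parameter x = pi d n_bg / lambda (diameter in um, wavelength in nm)."""
    return float(np.pi * diameter_um * n_background / (wavelength_nm * 1e-3))


@dataclass(frozen=True)
class MieResult:
    """Mie amplitudes on an angle grid plus efficiencies."""

    theta: np.ndarray  # scattering angle grid (rad)
    s1: np.ndarray  # complex perpendicular amplitude
    s2: np.ndarray  # complex parallel amplitude
    qext: float
    qsca: float


def _n_terms(x: float) -> int:
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(x: float, m: float) -> tuple[np.ndarray, np.ndarray]:
    """Partial-wave coefficients a_n, b_n for n = 1..nmax.

    Parameters
    ----------
    x
        Size parameter (> 0).
    m
        Refractive index relative to the background (> 0, real).
    """
    if not (x > 0):
        raise ValueError(f"size parameter must be positive, got {x}")
    if not (m > 0):
        raise ValueError(f"relative index must be positive, got {m}")
    nmax = _n_terms(x)
    mx = m * x
    # Downward recurrence for the logarithmic derivative D_n(mx).
    nstart = nmax + 15
    d = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)
    d = d[1 : nmax + 1]

    n = np.arange(1, nmax + 1)
    # Riccati-Bessel psi_n(x) = x j_n(x), chi_n(x) = -x y_n(x) by upward recurrence.
    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi_m1, psi0 = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi0 = -np.sin(x), np.cos(x)
    for k in range(1, nmax + 1):
        psi_k = (2 * k - 1) / x * psi0 - psi_m1
        chi_k = (2 * k - 1) / x * chi0 - chi_m1
        psi[k - 1], chi[k - 1] = psi_k, chi_k
        psi_m1, psi0 = psi0, psi_k
        chi_m1, chi0 = chi0, chi_k
    psi_prev = np.empty(nmax)
    chi_prev = np.empty(nmax)
    psi_prev[0], chi_prev[0] = np.sin(x), np.cos(x)
    psi_prev[1:], chi_prev[1:] = psi[: nmax - 1], chi[: nmax - 1]
    psi = psi[:nmax]
    chi = chi[:nmax]
    xi = psi - 1j * chi
    xi_prev = psi_prev - 1j * chi_prev

    ta = d / m + n / x
    tb = d * m + n / x
    a = (ta * psi - psi_prev) / (ta * xi - xi_prev)
    b = (tb * psi - psi_prev) / (tb * xi - xi_prev)
    return a, b


def _pi_tau(nmax: int, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Angular functions pi_n(mu), tau_n(mu), shape (nmax, len(mu))."""
    pi = np.zeros((nmax + 1, mu.size))
    tau = np.zeros((nmax + 1, mu.size))
    pi[1] = 1.0
    tau[1] = mu
    for n in range(2, nmax + 1):
        pi[n] = ((2 * n - 1) * mu * pi[n - 1] - n * pi[n - 2]) / (n - 1)
        tau[n] = n * mu * pi[n] - (n + 1) * pi[n - 1]
    return pi[1:], tau[1:]


def mie_amplitudes(x: float, m: float, theta: np.ndarray) -> MieResult:
    """Scattering amplitudes S1, S2 on ``theta`` (rad) plus Qext/Qsca.

    At theta = 0 the two amplitudes coincide (forward-scattering degeneracy).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    a, b = mie_coefficients(x, m)
    nmax = a.size
    n = np.arange(1, nmax + 1)
    w = (2 * n + 1) / (n * (n + 1))
    pi_n, tau_n = _pi_tau(nmax, np.cos(theta))
    s1 = (w[:, None] * (a[:, None] * pi_n + b[:, None] * tau_n)).sum(axis=0)
    s2 = (w[:, None] * (a[:, None] * tau_n + b[:, None] * pi_n)).sum(axis=0)
    qext = float(2.0 / x**2 * ((2 * n + 1) * (a + b).real).sum())
    qsca = float(2.0 / x**2 * ((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2)).sum())
    return MieResult(theta=theta, s1=s1, s2=s2, qext=qext, qsca=qsca)
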