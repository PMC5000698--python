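import numpy as np
import pytest

from silkpol.mueller import MuellerImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_image(rng):
    """Small random positive Mueller image (unnormalized)."""
    planes = rng.uniform(0.1, 2.0, size=(16, 12, 10))
    return MuellerImage(planes=planes, wavelength_nm=633.0)


def random_physical_mueller(rng):
    """A physical (non-depolarizing) Mueller matrix from a random Jones matrix.

    Built directly from field action, so it is usable as ground truth for
    round-trip tests without invoking the package's quadratic map.
    """
    j = rng.normal(size=(2, 2)) + 1j * rng.normal(size=(2, 2))
    return mueller_from_jones(j)


def stokes_of_field(e):
    """Stokes vector of a Jones field under the package's conventions."""
    e1, e2 = e
    return np.array(
        [
            abs(e1) ** 2 + abs(e2) ** 2,
            abs(e1) ** 2 - abs(e2) ** 2,
            2 * np.real(e1 * np.conj(e2)),
            -2 * np.imag(e1 * np.conj(e2)),
        ]
    )


def mueller_from_jones(j):
    """Mueller matrix of a Jones matrix via explicit field probing.

    Probes with four fully polarized fields, converts outputs to Stokes,
    and solves the linear system - an independent route to the same object
    as any Kronecker-product construction.
    """
    probes = [
        np.array([1.0, 0.0]),  # H
        np.array([0.0, 1.0]),  # V
        np.array([1.0, 1.0]) / np.sqrt(2),  # +45
        np.array([1.0, 1.0j]) / np.sqrt(2),  # circular
    ]
    s_in = np.column_stack([stokes_of_field(p) for p in probes])
    s_out = np.column_stack([stokes_of_field(j @ p) for p in probes])
    return s_out @ np.linalg.inv(s_in)
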