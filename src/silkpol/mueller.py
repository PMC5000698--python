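"""Core Stokes/Mueller containers, m11 normalization and physical validity checks.

Conventions used throughout the package:

* Stokes vector ``(S0, S1, S2, S3)``: total intensity, linear H/V, linear
  +/-45 deg, right-circular.  ``S0 >= 0`` and ``S0**2 >= S1**2+S2**2+S3**2``
  (equality for fully polarized light).
* Mueller matrices are real 4x4 arrays; elements are named ``m11 .. m44``
  with 1-based row/column indices, row-major.
* A :class:`MuellerImage` stores 16 co-registered scalar planes in row-major
  element order plus a boolean validity mask.  Image row 0 is the top of the
  frame and the x-axis (fiber 0 deg direction) is the horizontal image axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ELEMENT_NAMES",
    "StokesVector",
    "MuellerMatrix",
    "MuellerImage",
    "Violation",
    "normalize_by_m11",
    "physical_validity_report",
]

#: Row-major element names m11..m44; the canonical on-disk plane order.
ELEMENT_NAMES: tuple[str, ...] = tuple(
    f"m{i}{j}" for i in range(1, 5) for j in range(1, 5)
)

_ELEMENT_INDEX = {name: k for k, name in enumerate(ELEMENT_NAMES)}


@dataclass(frozen=True)
class StokesVector:
    """A single Stokes vector (intensity and polarization state)."""

    s0: float
    s1: float
    s2: float
    s3: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("Stokes components must be finite")
        if self.s0 < 0:
            raise ValueError(f"S0 must be non-negative, got {self.s0}")
        pol2 = self.s1**2 + self.s2**2 + self.s3**2
        if pol2 > self.s0**2 * (1.0 + 1e-9) + 1e-300:
            raise ValueError(
                f"unphysical Stokes vector: S1^2+S2^2+S3^2={pol2} exceeds S0^2={self.s0**2}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2, self.s3], dtype=float)

    @property
    def degree_of_polarization(self) -> float:
        if self.s0 == 0:
            return 0.0
        return float(np.sqrt(self.s1**2 + self.s2**2 + self.s3**2) / self.s0)


@dataclass(frozen=True)
class MuellerMatrix:
    """A 4x4 real Mueller matrix with named-element access (``m11`` .. ``m44``)."""

    m: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.m, dtype=float)
        if arr.shape != (4, 4):
            raise ValueError(f"Mueller matrix must be 4x4, got {arr.shape}")
        object.__setattr__(self, "m", arr)

    def __getattr__(self, name: str):
        if name in _ELEMENT_INDEX:
            k = _ELEMENT_INDEX[name]
            return float(self.m[divmod(k, 4)])
        raise AttributeError(name)

    def normalized(self) -> "MuellerMatrix":
        """Divide all elements by m11 (requires m11 != 0)."""
        if self.m[0, 0] == 0:
            raise ZeroDivisionError("cannot normalize: m11 is zero")
        return MuellerMatrix(self.m / self.m[0, 0])

    def apply(self, s: StokesVector) -> StokesVector:
        out = self.m @ s.as_array()
        return StokesVector(*out)


@dataclass
class MuellerImage:
    """16 co-registered element planes plus a validity mask.

    Parameters
    ----------
    planes
        Array of shape ``(16, H, W)`` in row-major element order m11..m44.
    mask
        Boolean ``(H, W)`` array of valid pixels; defaults to all-valid.
    wavelength_nm, pixel_pitch
        Optional acquisition metadata (pixel pitch in physical units/pixel).
    """

    planes: np.ndarray
    mask: np.ndarray | None = None
    wavelength_nm: float | None = None
    pixel_pitch: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or self.planes.shape[0] != 16:
            raise ValueError(
                f"planes must have shape (16, H, W), got {self.planes.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.planes.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.planes.shape[1:]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match plane shape "
                    f"{self.planes.shape[1:]}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def plane(self, element: str) -> np.ndarray:
        """Return one element plane by name, e.g. ``img.plane('m23')``."""
        try:
            return self.planes[_ELEMENT_INDEX[element]]
        except KeyError:
            raise KeyError(
                f"unknown element {element!r}; expected one of {ELEMENT_NAMES}"
            ) from None

    def matrix_at(self, row: int, col: int) -> MuellerMatrix:
        return MuellerMatrix(self.planes[:, row, col].reshape(4, 4))

    def region_mean_matrix(self, mask: np.ndarray | None = None) -> MuellerMatrix:
        """Mean Mueller matrix over valid pixels (optionally restricted further)."""
        sel = self.mask if mask is None else (self.mask & mask)
        if not sel.any():
            raise ValueError("no valid pixels in requested region")
        return MuellerMatrix(self.planes[:, sel].mean(axis=1).reshape(4, 4))


def normalize_by_m11(img: MuellerImage, epsilon: float | None = None) -> MuellerImage:
    """Normalize every element plane pixel-wise by the m11 plane.

    Pixels where ``m11 < epsilon`` are removed from the validity mask instead
    of producing infinities (backscattering images have dark borders outside
    the illuminated spot).  ``epsilon`` defaults to ``1e-6 * max(m11)``.

    Raises
    ------
    ValueError
        If no pixel survives the mask (all-dark image) or epsilon <= 0.
    """
    if not np.all(np.isfinite(img.planes)):
        raise ValueError("image planes contain non-finite values")
    m11 = img.planes[0]
    if epsilon is None:
        peak = float(m11[img.mask].max()) if img.mask.any() else 0.0
        epsilon = 1e-6 * peak if peak > 0 else 1e-30
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    mask = img.mask & (m11 >= epsilon)
    if not mask.any():
        raise ValueError("normalization leaves no valid pixels (empty mask)")
    out = np.array(img.planes, dtype=float, copy=True)
    denom = np.where(mask, m11, 1.0)
    out /= denom
    out[:, ~mask] = 0.0
    out[0, mask] = 1.0  # exact unity, not m11/m11 rounding
    return MuellerImage(
        planes=out,
        mask=mask,
        wavelength_nm=img.wavelength_nm,
        pixel_pitch=img.pixel_pitch,
        meta=dict(img.meta),
    )


@dataclass(frozen=True)
class Violation:
    """One violated physical bound of a Mueller matrix."""

    element: str
    value: float
    bound: str
    magnitude: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.element}={self.value:.6g} violates {self.bound} by {self.magnitude:.3g}"


def physical_validity_report(
    M: MuellerMatrix | np.ndarray, tol: float = 0.0
) -> list[Violation]:
    """List elementary physicality violations of a Mueller matrix.

    Checks that every entry is finite and that ``|m_ij| <= m11 * (1 + tol)``.
    An empty list means the matrix passes these necessary conditions.
    """
    arr = M.m if isinstance(M, MuellerMatrix) else np.asarray(M, dtype=float)
    if arr.shape != (4, 4):
        raise ValueError("expected a 4x4 matrix")
    report: list[Violation] = []
    m11 = arr[0, 0]
    for k, name in enumerate(ELEMENT_NAMES):
        v = arr[divmod(k, 4)]
        if not np.isfinite(v):
            report.append(Violation(name, float(v), "finite", np.inf))
            continue
        if not np.isfinite(m11):
            continue
        excess = abs(v) - m11 * (1.0 + tol)
        if excess > 0:
            report.append(Violation(name, float(v), f"|m_ij| <= m11={m11:.6g}", float(excess)))
    return report


def stack_matrices(mats: Sequence[MuellerMatrix]) -> np.ndarray:
    """Stack matrices into an ``(n, 4, 4)`` array (testing convenience)."""
    return np.stack([m.m for m in mats])
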