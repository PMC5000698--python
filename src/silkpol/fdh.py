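"""Frequency-distribution-histogram statistics of Mueller-element images.

Each Mueller-element plane is reduced to a frequency distribution histogram
(FDH) - a density histogram over 400 uniform bins whose area is normalized
to 1 - and to the first four central-moment parameters of its pixel values:

    P1 = E(X)            (mean)
    P2 = Var(X)          (population variance, denominator n)
    P3 = E(X - mu)^3 / sigma^3   (skewness)
    P4 = E(X - mu)^4 / sigma^4   (kurtosis, Gaussian -> 3)

Moments are computed from the raw pixel values, not from the binned FDH,
which removes binning bias from the derived parameters; the FDH itself is
kept for reporting and plotting.

Three wash-trajectory parameters are derived from the moments of the
central elements (wash index i, wash 0 = unwashed):

    c1_p1  = |m22.P1 - m33.P1| / m22.P1    anisotropy degree
    d22_p1 = (m22_i.P1 - m22_0.P1) / m22_0.P1   depolarization-linked shift
    d23_p2 = (m23_i.P2 - m23_0.P2) / m23_0.P2   disorder-linked widening
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mueller import ELEMENT_NAMES, MuellerImage

__all__ = [
    "FDH",
    "ElementMoments",
    "MomentSet",
    "DerivedParams",
    "WashSeries",
    "compute_fdh",
    "central_moments",
    "moment_set_from_image",
    "derived_params",
    "anisotropy_difference",
    "series_report",
]

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 400
#: Element value range for m11-normalized images (physical bound).
DEFAULT_RANGE = (-1.0, 1.0)
#: Narrow display range used for off-diagonal elements in image colorbars.
OFFDIAG_DISPLAY_RANGE = (-0.1, 0.1)


@dataclass(frozen=True)
class FDH:
    """Area-normalized density histogram of one element plane."""

    bin_edges: np.ndarray  # n_bins + 1 ascending edges
    density: np.ndarray  # n_bins non-negative densities, area 1
    element_label: str
    n_clipped: int = 0  # out-of-range pixels counted into boundary bins

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if edges.ndim != 1 or dens.shape != (edges.size - 1,):
            raise ValueError("bin_edges must be 1-D with len(density)+1 entries")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        if np.any(dens < 0):
            raise ValueError("densities must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "density", dens)

    @property
    def area(self) -> float:
        return float((self.density * np.diff(self.bin_edges)).sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def compute_fdh(
    plane: np.ndarray,
    element_label: str = "",
    mask: np.ndarray | None = None,
    n_bins: int = DEFAULT_N_BINS,
    value_range: tuple[float, float] = DEFAULT_RANGE,
) -> FDH:
    """FDH of a (masked) element plane over uniform bins.

    Values outside ``value_range`` are clipped into the boundary bins and
    counted (logged), so the area normalization holds exactly.

    Raises
    ------
    ValueError
        If no valid pixel remains or the range is empty.
    """
    lo, hi = value_range
    if not lo < hi:
        raise ValueError(f"empty value range [{lo}, {hi}]")
    vals = np.asarray(plane, dtype=float)
    if mask is not None:
        vals = vals[np.asarray(mask, dtype=bool)]
    vals = vals.ravel()
    if vals.size == 0:
        raise ValueError("no valid pixels to histogram (empty mask)")
    n_clipped = int(((vals < lo) | (vals > hi)).sum())
    if n_clipped:
        logger.info(
            "FDH %s: %d/%d pixels outside [%g, %g] clipped into boundary bins",
            element_label, n_clipped, vals.size, lo, hi,
        )
        vals = np.clip(vals, lo, hi)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    density = counts / (vals.size * (hi - lo) / n_bins)
    return FDH(bin_edges=edges, density=density, element_label=element_label,
               n_clipped=n_clipped)


@dataclass(frozen=True)
class ElementMoments:
    """P1..P4 of one element; P3/P4 are None when undefined (zero variance)."""

    p1: float
    p2: float
    p3: float | None = None
    p4: float | None = None


def central_moments(
    plane: np.ndarray, mask: np.ndarray | None = None
) -> ElementMoments:
    """Population central-moment parameters of the raw pixel values.

    Requires at least 2 valid pixels; when the variance is zero the
    normalized moments P3/P4 are returned as ``None`` rather than numbers.
    """
    vals = np.asarray(plane, dtype=float)
    if mask is not None:
        vals = vals[np.asarray(mask, dtype=bool)]
    vals = vals.ravel()
    if vals.size < 2:
        raise ValueError(f"need at least 2 valid pixels, got {vals.size}")
    mu = float(vals.mean())
    dev = vals - mu
    var = float((dev**2).mean())
    if var == 0.0:
        return ElementMoments(p1=mu, p2=0.0, p3=None, p4=None)
    sigma = np.sqrt(var)
    p3 = float((dev**3).mean() / sigma**3)
    p4 = float((dev**4).mean() / sigma**4)
    return ElementMoments(p1=mu, p2=var, p3=p3, p4=p4)


@dataclass
class MomentSet:
    """Moments for the elements of one sample state (one wash count)."""

    moments: dict[str, ElementMoments]
    n_pixels: int = 0

    def __getitem__(self, element: str) -> ElementMoments:
        try:
            return self.moments[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} not present; have {sorted(self.moments)}"
            ) from None

    def __contains__(self, element: str) -> bool:
        return element in self.moments

    @property
    def elements(self) -> list[str]:
        return list(self.moments)


def moment_set_from_image(img: MuellerImage) -> MomentSet:
    """MomentSet over all 16 element planes of a (normalized) image."""
    return MomentSet(
        moments={
            name: central_moments(img.plane(name), img.mask) for name in ELEMENT_NAMES
        },
        n_pixels=int(img.mask.sum()),
    )


@dataclass(frozen=True)
class DerivedParams:
    """The three wash-trajectory parameters at one wash count."""

    c1p1: float
    d22p1: float
    d23p2: float
    wash_index: int

    def __post_init__(self) -> None:
        if self.c1p1 < 0:
            raise ValueError("c1p1 is non-negative by definition")


@dataclass
class WashSeries:
    """Ordered MomentSets for wash counts 0..N of one detergent."""

    detergent_label: str
    moments: list[MomentSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.moments:
            raise ValueError("a wash series needs at least the unwashed state")

    @property
    def n_washes(self) -> int:
        return len(self.moments) - 1

    def derived(self) -> list[DerivedParams]:
        return [derived_params(self, i) for i in range(len(self.moments))]


def _require(value: float, name: str, wash: int) -> float:
    if value == 0.0:
        raise ZeroDivisionError(
            f"derived parameter undefined: {name} is zero at wash {wash}"
        )
    return value


def derived_params(series: WashSeries, wash_index: int) -> DerivedParams:
    """Eq.-(3)-style parameters of wash ``wash_index`` against wash 0.

    ``c1p1`` uses the m22/m33 means of the requested wash itself; the two
    d-parameters are relative changes against the unwashed state and are 0
    at wash 0 by definition.
    """
    try:
        cur = series.moments[wash_index]
        ref = series.moments[0]
    except IndexError:
        raise IndexError(
            f"wash {wash_index} not in series 0..{series.n_washes}"
        ) from None
    m22p1 = _require(cur["m22"].p1, "m22 P1", wash_index)
    c1p1 = abs(m22p1 - cur["m33"].p1) / m22p1
    d22p1 = (m22p1 - ref["m22"].p1) / _require(ref["m22"].p1, "m22 P1", 0)
    d23p2 = (cur["m23"].p2 - ref["m23"].p2) / _require(ref["m23"].p2, "m23 P2", 0)
    return DerivedParams(c1p1=c1p1, d22p1=d22p1, d23p2=d23p2, wash_index=wash_index)


def anisotropy_difference(momset: MomentSet) -> float:
    """Signed m22.P1 - m33.P1, the element-mean anisotropy readout."""
    return momset["m22"].p1 - momset["m33"].p1


def series_report(series: WashSeries) -> pd.DataFrame:
    """Per-wash table of derived parameters and change diagnostics.

    One row per wash count with the three derived parameters, the
    anisotropy difference, the m22 P2 fold-change against wash 0, and the
    absolute P1 change of every tabulated element against wash 0.
    """
    ref = series.moments[0]
    rows = []
    for i, mom in enumerate(series.moments):
        d = derived_params(series, i)
        row = {
            "wash": i,
            "c1p1": d.c1p1,
            "d22p1": d.d22p1,
            "d23p2": d.d23p2,
            "aniso_diff": anisotropy_difference(mom),
            "m22_p2_fold": mom["m22"].p2 / _require(ref["m22"].p2, "m22 P2", 0),
        }
        for el in mom.elements:
            if el in ref:
                row[f"abs_dP1_{el}"] = abs(mom[el].p1 - ref[el].p1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("wash")
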