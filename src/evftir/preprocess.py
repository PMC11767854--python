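"""Fingerprint-region preprocessing for absorbance spectra.

The chain applied before any multivariate or peak analysis is, in fixed order:

1. crop to the analysis region (default 1280-900 cm^-1),
2. per-spectrum baseline correction,
3. per-spectrum area normalization (integral of ``|A|`` set to 1),
4. Savitzky-Golay second differentiation, which "deconvolutes" overlapping
   absorption bands into resolvable negative troughs,
5. sign inversion (x -1) so absorption maxima become local maxima again.

The Savitzky-Golay window is parameterized by *side points*: 3 side points
give the classical 7-point quadratic window.  Derivatives are taken with
respect to wavenumber on the ascending axis; because the canonical storage
order is descending, rows are reversed before convolution and reversed back,
which keeps odd derivative orders correctly signed.  The filter never pads:
``side_points`` grid points are dropped from each end of the output axis,
because padded derivatives fabricate band-like artifacts exactly where the
region edges sit near reported peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .spectra import SpectraSet, WavenumberAxis, crop_region

BASELINE_METHODS = ("linear_endpoints", "rubber_band", "offset")


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``sg_side_points=3`` encodes the 7-point quadratic Savitzky-Golay window
    (3 smoothing points per side); a bare central second difference is
    available via ``sg_side_points=1``.
    """

    region_high: float = 1280.0
    region_low: float = 900.0
    baseline_method: str = "linear_endpoints"
    sg_side_points: int = 3
    sg_poly_order: int = 2
    sg_deriv_order: int = 2
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.baseline_method not in BASELINE_METHODS:
            raise ValueError(
                f"baseline_method must be one of {BASELINE_METHODS}, "
                f"got {self.baseline_method!r}"
            )
        window = 2 * self.sg_side_points + 1
        if self.sg_side_points < 1:
            raise ValueError("sg_side_points must be >= 1")
        if not (window > self.sg_poly_order >= self.sg_deriv_order >= 0):
            raise ValueError(
                f"require window ({window}) > poly_order ({self.sg_poly_order}) "
                f">= deriv_order ({self.sg_deriv_order}) >= 0"
            )
        if not self.region_high > self.region_low:
            raise ValueError("region_high must exceed region_low")


# ---------------------------------------------------------------------------
# baseline correction
# ---------------------------------------------------------------------------


def _lower_hull_baseline(x_asc: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Piecewise-linear lower convex hull of ``(x, y)`` evaluated on the grid.

    Monotone-chain construction on x-ascending points; collinear points are
    dropped from the hull, which leaves the evaluated baseline unchanged.
    """
    hull: list[int] = []
    for i in range(x_asc.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (x_asc[i2] - x_asc[i1]) * (y[i] - y[i1]) - (
                y[i2] - y[i1]
            ) * (x_asc[i] - x_asc[i1])
            if cross <= 0:  # hull turns upward (or is collinear) -> pop
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x_asc, x_asc[hull], y[hull])


def baseline_correct(s: SpectraSet, method: str = "linear_endpoints") -> SpectraSet:
    """Subtract a per-spectrum baseline estimated within the current region.

    * ``linear_endpoints`` -- the straight line through the first and last
      point of the region; both endpoints become exactly zero.
    * ``rubber_band`` -- the lower convex hull of ``(wavenumber, A)``;
      corrected values are >= 0 up to floating point.
    * ``offset`` -- the per-spectrum minimum.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline method {method!r}")
    if len(s.axis) < 2:
        raise ValueError("baseline correction needs at least 2 axis points")
    v = s.axis.values
    A = s.absorbance
    if method == "offset":
        corrected = A - A.min(axis=1, keepdims=True)
    elif method == "linear_endpoints":
        # line through (v[0], A[:,0]) and (v[-1], A[:,-1]) per spectrum
        frac = (v - v[0]) / (v[-1] - v[0])
        corrected = A - (A[:, :1] + (A[:, -1:] - A[:, :1]) * frac[None, :])
    else:  # rubber_band
        order = np.argsort(v)
        x_asc = v[order]
        corrected = np.empty_like(A)
        for i in range(A.shape[0]):
            base_asc = _lower_hull_baseline(x_asc, A[i, order])
            base = np.empty_like(base_asc)
            base[order] = base_asc
            corrected[i] = A[i] - base
    return s.with_data(corrected, log=f"baseline_correct: method={method}")


# ---------------------------------------------------------------------------
# area normalization
# ---------------------------------------------------------------------------


def spectrum_areas(s: SpectraSet) -> np.ndarray:
    """Trapezoidal integral of ``|A|`` over the region, per spectrum (>= 0)."""
    v = s.axis.values
    # integrate on the ascending axis so the area is positive
    order = np.argsort(v)
    return np.trapezoid(np.abs(s.absorbance[:, order]), x=v[order], axis=1)


def area_normalize(s: SpectraSet) -> SpectraSet:
    """Divide each spectrum by its trapezoidal integral of ``|A|``.

    After normalization every spectrum has unit absolute area over the current
    region, which removes multiplicative scale differences (deposited mass,
    contact pressure) between replicates.
    """
    areas = spectrum_areas(s)
    tiny = areas < 1e-12
    if tiny.any():
        bad = s.meta[int(np.argmax(tiny))].sample_id
        raise ValueError(
            f"cannot area-normalize spectrum {bad!r}: integral of |A| is "
            f"{areas[tiny][0]:.3e} (< 1e-12)"
        )
    return s.with_data(
        s.absorbance / areas[:, None], log="area_normalize: |A| area -> 1"
    )


# ---------------------------------------------------------------------------
# Savitzky-Golay differentiation
# ---------------------------------------------------------------------------


def sg_filter_coefficients(
    side_points: int, poly_order: int, deriv_order: int, spacing: float = 1.0
) -> np.ndarray:
    """Savitzky-Golay convolution weights on a centered window.

    Weights are the least-squares polynomial-fit functional for the
    ``deriv_order``-th derivative at the window center, scaled by
    ``deriv_order! / spacing**deriv_order``; they are exact for polynomials of
    degree <= ``poly_order``.  Returned in ascending-abscissa order, for a dot
    product with window values ordered by increasing wavenumber.
    """
    window = 2 * side_points + 1
    if side_points < 1:
        raise ValueError("side_points must be >= 1")
    if not (window > poly_order >= deriv_order >= 0):
        raise ValueError(
            f"require window ({window}) > poly_order ({poly_order}) "
            f">= deriv_order ({deriv_order}) >= 0"
        )
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    x = np.arange(-side_points, side_points + 1, dtype=float)
    V = x[:, None] ** np.arange(poly_order + 1)[None, :]
    # row deriv_order of pinv(V) maps window values to the fitted coefficient
    # c_k of x^k at the center; derivative value is k! * c_k / spacing^k.
    weights = np.linalg.pinv(V)[deriv_order]
    return weights * math.factorial(deriv_order) / spacing**deriv_order


def second_derivative(s: SpectraSet, cfg: PreprocessConfig) -> SpectraSet:
    """Savitzky-Golay derivative of every spectrum with edge trimming.

    The ``cfg.sg_side_points`` outermost grid points on each side are dropped
    from the output axis; no padding is ever applied.
    """
    m = cfg.sg_side_points
    window = 2 * m + 1
    if len(s.axis) < window:
        raise ValueError(
            f"region has {len(s.axis)} points but the Savitzky-Golay window "
            f"needs {window}"
        )
    w = sg_filter_coefficients(
        m, cfg.sg_poly_order, cfg.sg_deriv_order, s.axis.spacing
    )
    # differentiate on the ascending axis, then restore the stored order
    flip = s.axis.descending
    data = s.absorbance[:, ::-1] if flip else s.absorbance
    windows = np.lib.stride_tricks.sliding_window_view(data, window, axis=1)
    deriv = windows @ w
    if flip:
        deriv = deriv[:, ::-1]
    axis = WavenumberAxis(s.axis.values[m:-m].copy())
    return s.with_data(
        deriv,
        axis=axis,
        log=(
            f"second_derivative: SG window={window} poly={cfg.sg_poly_order} "
            f"deriv={cfg.sg_deriv_order} spacing={s.axis.spacing:g}, "
            f"trimmed {m} points per edge"
        ),
    )


def invert(s: SpectraSet) -> SpectraSet:
    """Multiply every value by -1.

    Applied to a second-derivative set so that absorption maxima of the
    original spectrum become local *maxima*, the convention under which peak
    intensities are read.
    """
    return s.with_data(-s.absorbance, log="invert: multiplied by -1")


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------


def preprocess_pipeline(
    s: SpectraSet, cfg: PreprocessConfig | None = None
) -> tuple[SpectraSet, SpectraSet, SpectraSet]:
    """Run crop -> baseline -> area-normalize -> SG second derivative -> invert.

    Returns
    -------
    normalized, second_deriv, inverted
        The area-normalized region spectra, their Savitzky-Golay derivative,
        and the sign-inverted derivative.  Provenance is extended at every
        stage; when ``cfg.normalize`` is off the skipped stage is logged.
    """
    cfg = cfg or PreprocessConfig()
    lo, hi = s.axis.values.min(), s.axis.values.max()
    if cfg.region_high > hi or cfg.region_low < lo:
        raise ValueError(
            f"region {cfg.region_high:g}-{cfg.region_low:g} cm^-1 exceeds the "
            f"axis range {hi:g}-{lo:g} cm^-1"
        )
    region = crop_region(s, cfg.region_high, cfg.region_low)
    corrected = baseline_correct(region, cfg.baseline_method)
    if cfg.normalize:
        normalized = area_normalize(corrected)
    else:
        normalized = corrected.with_data(
            corrected.absorbance, log="area_normalize: skipped (normalize=False)"
        )
    deriv = second_derivative(normalized, cfg)
    inverted = invert(deriv)
    return normalized, deriv, inverted
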