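"""Helix tilt-angle statistics and derivation of the span-tilt penalty.

Membrane spans in natural proteins prefer small tilt angles relative
to the membrane normal, whereas unbiased rigid-body sampling produces
tilt angles distributed like sin(θ) — the circumference effect.  The
penalty is built in three steps:

1. fit a quadratic to the observed tilt-angle histogram,
2. convert observed and expected (sin θ) distributions to energies by
   inverse Boltzmann and subtract:  penalty(θ) = -(ln f(θ) - ln sin θ),
3. approximate the result by a cubic for cheap runtime evaluation
   (the log form is undefined where the quadratic turns negative,
   around 48°; the cubic extrapolates smoothly and keeps rising).

The histogram convention follows the published density's scale:
per-bin fractions with 5° bins (heights sum to 1).  Bins are fitted
by weighted least squares with 1/sqrt(p) weights — the chi-square
weighting for multinomial counts — which keeps the relative fit tight
in sparsely populated bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import SpanPenaltyModel
from .errors import ParameterError

#: quadratic density of observed membrane-span tilt angles (per 5° bin)
OBSERVED_TILT_DENSITY = (-2.36e-4, 0.01095, 0.0202)


@dataclass
class TiltSample:
    """A sample of helix tilt angles, degrees in [0, 90]."""

    angles: np.ndarray

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1:
            raise ParameterError("angles must be a 1-D sequence")
        if np.any((self.angles < 0) | (self.angles > 90)):
            raise ParameterError("tilt angles must lie in [0, 90] degrees")

    @property
    def n(self) -> int:
        return len(self.angles)


def quadratic(coeffs, theta):
    c2, c1, c0 = coeffs
    t = np.asarray(theta, dtype=float)
    v = (c2 * t + c1) * t + c0
    return float(v) if v.ndim == 0 else v


def fit_tilt_density(sample: TiltSample, bin_width: float = 5.0,
                     angle_range: tuple[float, float] = (0.0, 90.0),
                     normalisation: str = "bin_fraction",
                     ) -> tuple[float, float, float]:
    """Least-squares quadratic fit to the tilt-angle histogram.

    Returns ``(c2, c1, c0)``.  ``normalisation="bin_fraction"``
    (default) fits per-bin probabilities, the scale of
    :data:`OBSERVED_TILT_DENSITY`; ``"density"`` fits a unit-area
    density (per degree).  Only occupied bins enter the fit, weighted
    by the inverse Poisson standard deviation of each bin.
    """
    if sample.n < 100:
        raise ParameterError(f"need >= 100 angles, got {sample.n}")
    lo, hi = angle_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(sample.angles, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    heights = counts / counts.sum()
    if normalisation == "density":
        heights = heights / bin_width
    elif normalisation != "bin_fraction":
        raise ParameterError(f"unknown normalisation {normalisation!r}")
    mask = counts > 0
    weights = 1.0 / np.sqrt(heights[mask])
    c2, c1, c0 = np.polyfit(centers[mask], heights[mask], 2, w=weights)
    return float(c2), float(c1), float(c0)


def derive_penalty(observed_density, theta, match_scale: bool = False):
    """Inverse-Boltzmann tilt penalty: -(ln f(θ) - ln sin θ).

    ``observed_density`` is a quadratic coefficient triple (c2, c1, c0)
    with θ in degrees.  Raises where f(θ) <= 0 or sin θ <= 0 — callers
    restrict the evaluation grid to the positive domain.

    With ``match_scale=True`` (array input only) both densities are
    first normalised to unit area over the evaluated grid, removing
    the arbitrary additive constant between the two energy scales:
    identical observed and expected distributions then give a penalty
    of identically zero.
    """
    t = np.atleast_1d(np.asarray(theta, dtype=float))
    f = quadratic(observed_density, t)
    s = np.sin(np.radians(t))
    if np.any(f <= 0):
        bad = t[np.atleast_1d(f <= 0)][0]
        raise ParameterError(f"observed density non-positive at θ={bad:g}°")
    if np.any(s <= 0):
        raise ParameterError("sin(θ) must be positive (θ in (0, 90])")
    if match_scale:
        if t.size < 2:
            raise ParameterError("match_scale needs a grid of angles")
        f = f / np.trapezoid(f, t)
        s = s / np.trapezoid(s, t)
    pen = -(np.log(f) - np.log(s))
    return float(pen[0]) if np.isscalar(theta) else pen


def approximate_penalty(observed_density,
                        fit_range: tuple[float, float] = (5.0, 45.0),
                        grid_step: float = 1.0) -> SpanPenaltyModel:
    """Cubic least-squares approximation of the derived penalty.

    Samples the inverse-Boltzmann penalty on a 1° grid over
    ``fit_range`` and fits a degree-3 polynomial, the form used at
    runtime.  The default range keeps both the observed quadratic and
    sin θ strictly positive.
    """
    lo, hi = fit_range
    if not 0 < lo < hi:
        raise ParameterError("fit_range must satisfy 0 < lo < hi")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    pen = derive_penalty(observed_density, grid)  # raises on domain error
    a3, a2, a1, a0 = np.polyfit(grid, pen, 3)
    return SpanPenaltyModel(a3=float(a3), a2=float(a2),
                            a1=float(a1), a0=float(a0))


def read_angles(path) -> TiltSample:
    """Plain-text tilt angles, one value in degrees per line."""
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                vals.append(float(line))
    return TiltSample(np.asarray(vals))
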