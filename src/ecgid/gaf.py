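"""Gramian Angular Field (GASF) encoding of fixed-length signal windows.

A window ``x = (x_1, ..., x_n)`` is encoded in three steps:

1. **Rescale** into ``[-1, 1]`` (symmetric mode) or ``[0, 1]`` (unit mode)
   by the min-max maps

   .. math::

       \\tilde{x}_i = \\frac{(x_i - \\max x) + (x_i - \\min x)}{\\max x - \\min x}
       \\qquad\\text{or}\\qquad
       \\tilde{x}_i = \\frac{x_i - \\min x}{\\max x - \\min x}.

2. **Polar mapping**: each value becomes an angle
   :math:`\\varphi_i = \\arccos \\tilde{x}_i \\in [0, \\pi]` and each (1-based)
   time index a radius :math:`r_i = t_i / N` for a regulation constant ``N``.

3. **Angular-sum Gramian**: the image is the matrix
   :math:`G_{ij} = \\cos(\\varphi_i + \\varphi_j)`, algebraically equal to
   :math:`\\tilde{x}_i \\tilde{x}_j -
   \\sqrt{1-\\tilde{x}_i^2}\\,\\sqrt{1-\\tilde{x}_j^2}`.

The diagonal carries :math:`G_{ii} = 2\\tilde{x}_i^2 - 1`, so the rescaled
series is recoverable from the image (exactly in unit mode; in symmetric mode
up to a global sign, resolved here via a stored reference index — see
:func:`recover_series`).

Piecewise Aggregate Approximation (PAA) reduces an ``n``-sample window to
``m`` frame means before encoding, so the image is ``m x m`` rather than
``n x n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .records import Segment

RescaleMode = Literal["symmetric", "unit"]

#: values this far outside [-1, 1] are treated as rounding spill and clamped
CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class RescaledSeries:
    """A min-max rescaled series with the original extrema retained."""

    values: np.ndarray
    mode: RescaleMode
    original_min: float | None = None
    original_max: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        lo = -1.0 if self.mode == "symmetric" else 0.0
        v = self.values
        if v.ndim != 1 or v.size < 1:
            raise ValidationError("rescaled series must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValidationError("rescaled series contains non-finite values")
        if v.min() < lo - CLAMP_TOL or v.max() > 1.0 + CLAMP_TOL:
            raise ValidationError(
                f"rescaled values outside [{lo}, 1] beyond tolerance "
                f"(min={v.min()}, max={v.max()})"
            )

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class PolarSeries:
    """Angles/radii representation of a rescaled series.

    ``angles`` lie in [0, pi]; ``radii`` are the 1-based time indices divided
    by the regulation constant ``n_reg`` and are strictly increasing.  The
    radii do not enter the Gramian matrix; they exist so the polar picture is
    bijective (plottable) in time.
    """

    angles: np.ndarray
    radii: np.ndarray
    n_reg: float

    def __post_init__(self) -> None:
        if self.n_reg <= 0:
            raise ConfigurationError("regulation parameter must be positive")
        a = np.asarray(self.angles, dtype=np.float64)
        if a.min() < 0.0 or a.max() > math.pi:
            raise ValidationError("angles must lie in [0, pi]")
        r = np.asarray(self.radii, dtype=np.float64)
        if np.any(np.diff(r) <= 0):
            raise ValidationError("radii must increase strictly with time")


@dataclass
class GAFImage:
    """A square, symmetric angular-sum Gramian with entries in [-1, 1].

    ``ref_index`` is the position of the window's maximum (whose rescaled
    value has known sign +1 in symmetric mode); it makes symmetric-mode
    series recovery single-valued.
    """

    matrix: np.ndarray
    mode: RescaleMode = "symmetric"
    ref_index: int | None = None
    subject_id: str | None = None
    segment_index: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.matrix, dtype=np.float64)
        if g.ndim != 2 or g.shape[0] != g.shape[1] or g.shape[0] < 1:
            raise ValidationError("GAF matrix must be square and non-empty")
        if not np.array_equal(g, g.T):
            raise ValidationError("GAF matrix must be exactly symmetric")
        if g.min() < -1.0 - CLAMP_TOL or g.max() > 1.0 + CLAMP_TOL:
            raise ValidationError("GAF entries must lie in [-1, 1]")
        self.matrix = g

    @property
    def paa_size(self) -> int:
        return int(self.matrix.shape[0])


def rescale(series: Sequence[float] | np.ndarray, mode: RescaleMode = "symmetric") -> RescaledSeries:
    """Min-max rescale a series into [-1, 1] (symmetric) or [0, 1] (unit).

    Raises
    ------
    DegenerateInputError
        If the series is constant (zero range: no angular spread exists).
    ValidationError
        If the series is shorter than 2 samples or non-finite.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("series to rescale must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError("series to rescale contains non-finite values")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateInputError("constant series has zero range; cannot rescale")
    if mode == "symmetric":
        values = ((x - hi) + (x - lo)) / (hi - lo)
    elif mode == "unit":
        values = (x - lo) / (hi - lo)
    else:
        raise ConfigurationError(f"unknown rescale mode: {mode!r}")
    # force exact endpoints against rounding
    values = np.clip(values, -1.0 if mode == "symmetric" else 0.0, 1.0)
    return RescaledSeries(values, mode, original_min=lo, original_max=hi)


def to_polar(rescaled: RescaledSeries, n_reg: float | None = None) -> PolarSeries:
    """Map a rescaled series to polar coordinates (angle=arccos, radius=t/N).

    ``n_reg`` defaults to the series length, placing radii in (0, 1].
    Values outside [-1, 1] by more than ``CLAMP_TOL`` raise; smaller spill is
    clamped silently.
    """
    v = rescaled.values
    if v.min() < -1.0 - CLAMP_TOL or v.max() > 1.0 + CLAMP_TOL:
        raise ValidationError("rescaled values outside [-1, 1] beyond tolerance")
    n = v.size
    if n_reg is None:
        n_reg = float(n)
    angles = np.arccos(np.clip(v, -1.0, 1.0))
    radii = np.arange(1, n + 1, dtype=np.float64) / float(n_reg)
    return PolarSeries(angles=angles, radii=radii, n_reg=float(n_reg))


def paa(series: Sequence[float] | np.ndarray, target_size: int) -> np.ndarray:
    """Piecewise Aggregate Approximation: reduce ``n`` samples to ``m`` frame means.

    Frames partition the series; when ``m`` does not divide ``n`` boundary
    samples are split fractionally between adjacent frames, so the frame
    means are exact integrals of the sample step function.  ``m == n`` is the
    identity.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 1:
        raise ValidationError("series for PAA must be a non-empty 1-D array")
    n = x.size
    m = int(target_size)
    if m < 1:
        raise ConfigurationError("PAA target size must be >= 1")
    if m > n:
        raise ConfigurationError(f"PAA target size {m} exceeds series length {n}")
    if m == n:
        return x.copy()
    if n % m == 0:
        return x.reshape(m, n // m).mean(axis=1)
    # fractional frames via the piecewise-linear cumulative sum
    edges = np.linspace(0.0, float(n), m + 1)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    at_edges = np.interp(edges, np.arange(n + 1, dtype=np.float64), csum)
    return np.diff(at_edges) / (n / m)


def gasf(rescaled: RescaledSeries) -> GAFImage:
    """Gramian Angular Summation Field: ``G[i, j] = cos(phi_i + phi_j)``."""
    polar = to_polar(rescaled)
    phi = polar.angles
    g = np.cos(phi[:, None] + phi[None, :])
    np.clip(g, -1.0, 1.0, out=g)
    ref = int(np.argmax(rescaled.values))
    meta = {}
    if rescaled.original_min is not None:
        meta = {"original_min": rescaled.original_min, "original_max": rescaled.original_max}
    return GAFImage(matrix=g, mode=rescaled.mode, ref_index=ref, meta=meta)


def encode_segment(
    segment: Segment,
    paa_size: int = 128,
    mode: RescaleMode = "symmetric",
) -> GAFImage:
    """Encode one fixed-length window: PAA (raw samples) -> rescale -> GASF.

    The returned image is ``paa_size x paa_size`` and carries the segment's
    subject/activity provenance.
    """
    reduced = paa(segment.samples, paa_size)
    rs = rescale(reduced, mode=mode)
    image = gasf(rs)
    image.subject_id = segment.subject_id
    image.segment_index = segment.index
    image.meta.update(
        {
            "activity": segment.activity,
            "window_samples": int(segment.samples.size),
            "paa_size": int(paa_size),
            "rescale_mode": mode,
        }
    )
    return image


def recover_series(image: GAFImage, mode: RescaleMode | None = None) -> RescaledSeries:
    """Recover the rescaled series from a GASF image's diagonal.

    Unit mode is exact: ``x_i = sqrt((G_ii + 1) / 2)``.  Symmetric mode
    recovers magnitudes from the diagonal and resolves each sign against the
    reference index (the stored index of the window maximum, whose rescaled
    value is +1).  The image itself is invariant under global negation of the
    series, so without a stored reference the element of largest magnitude at
    the smallest index is assumed positive — a convention, not a deduction.
    """
    if mode is None:
        mode = image.mode
    g = image.matrix
    d = np.diagonal(g)
    if d.min() < -1.0 - 1e-9 or d.max() > 1.0 + 1e-9:
        raise ValidationError("diagonal entries outside [-1, 1] beyond tolerance")
    mag = np.sqrt(np.clip((np.clip(d, -1.0, 1.0) + 1.0) / 2.0, 0.0, 1.0))
    if mode == "unit":
        return RescaledSeries(mag, "unit")
    ref = image.ref_index
    if ref is None:
        ref = int(np.argmax(mag))
    ref_mag = mag[ref]
    # sign(x_i * x_ref) from G[i, ref] = x_i x_ref - sqrt(1-x_i^2) sqrt(1-x_ref^2)
    cross = g[:, ref] + np.sqrt(np.clip(1.0 - mag**2, 0.0, 1.0)) * math.sqrt(
        max(0.0, 1.0 - ref_mag**2)
    )
    signs = np.where(cross < 0.0, -1.0, 1.0)
    return RescaledSeries(np.clip(signs * mag, -1.0, 1.0), "symmetric")


def gasf_oracle(values: np.ndarray) -> np.ndarray:
    """Closed-form GASF: ``x x' - sqrt(1 - x^2) sqrt(1 - x'^2)`` elementwise.

    Algebraically identical to :func:`gasf`; kept as an independent check of
    the angular construction.
    """
    x = np.asarray(values, dtype=np.float64)
    s = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    return np.outer(x, x) - np.outer(s, s)
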