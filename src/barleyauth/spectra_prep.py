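"""FT-NIR preprocessing: rubber-band baseline correction, range restriction,
replicate averaging and binning into the 300-variable representation.

A :class:`Spectrum` stores the acquisition axis as recorded (descending
wavenumber, 12,500 -> 3,600 cm^-1 at 16 cm^-1 steps for the instrument
emulated here), but every operation works for any strictly monotone axis.
Binning integrates the piecewise-linear interpolant of the spectrum over 300
equal-width buckets spanning 4,000-11,000 cm^-1, so bucket values are areas
(absorbance * cm^-1), not point averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "Spectrum",
    "BinnedSpectrum",
    "rubberband_baseline",
    "restrict_range",
    "average_replicates",
    "bin_spectrum",
    "read_spectrum",
    "write_spectrum",
    "BIN_RANGE",
    "N_BINS",
]

#: Wavenumber range (lo, hi) retained for chemometric analysis, cm^-1.
BIN_RANGE = (4000.0, 11000.0)
#: Number of equidistant buckets the retained range is divided into.
N_BINS = 300


@dataclass(frozen=True)
class Spectrum:
    """A wavenumber-indexed absorbance trace.

    Parameters
    ----------
    wavenumbers : ndarray
        Strictly monotone axis in cm^-1 (descending in acquisition order).
    absorbance : ndarray
        Dimensionless absorbance, same length as the axis.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.shape != w.shape:
            raise ValueError("wavenumbers and absorbance must be 1-D and equal length")
        if w.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        d = np.diff(w)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber axis must be strictly monotone")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis and values sorted by ascending wavenumber."""
        if self.wavenumbers[0] < self.wavenumbers[-1]:
            return self.wavenumbers, self.absorbance
        return self.wavenumbers[::-1], self.absorbance[::-1]


@dataclass(frozen=True)
class BinnedSpectrum:
    """Integrated absorbance per equidistant bucket.

    ``bin_centers`` are bucket midpoints in ascending wavenumber order;
    ``bin_values`` are trapezoidal integrals (absorbance * cm^-1).
    """

    bin_centers: np.ndarray
    bin_values: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.bin_centers, dtype=float)
        v = np.asarray(self.bin_values, dtype=float)
        if c.shape != v.shape or c.ndim != 1:
            raise ValueError("bin_centers and bin_values must be 1-D and equal length")
        object.__setattr__(self, "bin_centers", c)
        object.__setattr__(self, "bin_values", v)

    def __len__(self) -> int:
        return self.bin_centers.size


def _lower_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull of (x, y), x strictly ascending.

    Andrew's monotone chain restricted to the lower chain; collinear points
    are dropped so hull vertices are extreme points only.
    """
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # cross product of (p1->p2) x (p1->p3); <= 0 means p2 not below chord
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def rubberband_baseline(
    s: Spectrum, n_points: int = 64, iterations: int = 10
) -> Spectrum:
    """Subtract a concave rubber-band baseline estimate.

    ``n_points`` equidistant anchor candidates are placed along the axis; the
    baseline is the linear interpolation of the lower convex hull of the
    anchors.  Each of the ``iterations`` passes pulls every anchor down to
    ``min(anchor, current baseline)`` and recomputes the hull, so the band can
    only tighten.  The corrected spectrum is non-negative at every anchor that
    supports the final hull.
    """
    if len(s) < n_points:
        raise ValueError(
            f"spectrum has {len(s)} points, fewer than n_points={n_points}"
        )
    x, y = s.ascending()
    anchor_idx = np.unique(np.round(np.linspace(0, x.size - 1, n_points)).astype(int))
    ax = x[anchor_idx]
    ay = y[anchor_idx].copy()
    for _ in range(iterations):
        hull = _lower_hull(ax, ay)
        baseline_at_anchors = np.interp(ax, ax[hull], ay[hull])
        ay = np.minimum(ay, baseline_at_anchors)
    hull = _lower_hull(ax, ay)
    baseline = np.interp(x, ax[hull], ay[hull])
    corrected = y - baseline
    if s.wavenumbers[0] > s.wavenumbers[-1]:
        corrected = corrected[::-1]
    return Spectrum(s.wavenumbers.copy(), corrected)


def restrict_range(s: Spectrum, hi: float = 11000.0, lo: float = 4000.0) -> Spectrum:
    """Keep points with ``lo <= wavenumber <= hi`` (closed interval)."""
    if not hi > lo:
        raise ValueError("hi must exceed lo")
    keep = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not np.any(keep):
        raise ValueError(f"no points in [{lo}, {hi}]")
    return Spectrum(s.wavenumbers[keep], s.absorbance[keep])


def average_replicates(replicates: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate measurements of one sample."""
    if not replicates:
        raise ValueError("no replicates given")
    ref = replicates[0]
    for r in replicates[1:]:
        if r.wavenumbers.shape != ref.wavenumbers.shape or not np.array_equal(
            r.wavenumbers, ref.wavenumbers
        ):
            raise ValueError("replicates must share an identical wavenumber axis")
    mean = np.mean([r.absorbance for r in replicates], axis=0)
    return Spectrum(ref.wavenumbers.copy(), mean)


def bin_spectrum(
    s: Spectrum,
    n_bins: int = N_BINS,
    lo: float = BIN_RANGE[0],
    hi: float = BIN_RANGE[1],
) -> BinnedSpectrum:
    """Integrate the spectrum over ``n_bins`` equal buckets spanning [lo, hi].

    The bucket value is the trapezoidal integral of the piecewise-linear
    interpolant over [edge_k, edge_{k+1}]; a data point on an internal edge
    therefore contributes to both neighbouring buckets.  The spectrum must
    cover [lo, hi] to within one grid spacing (an instrument grid whose
    extreme points fall just inside the range is accepted; edge values are
    then held constant over the sub-spacing overhang).
    """
    x, y = s.ascending()
    step = np.max(np.diff(x))
    if x[0] > lo + step or x[-1] < hi - step:
        raise ValueError(
            f"spectrum covers [{x[0]:g}, {x[-1]:g}] which leaves a gap in [{lo:g}, {hi:g}]"
        )
    edges = lo + (hi - lo) / n_bins * np.arange(n_bins + 1)
    interior = x[(x > lo) & (x < hi)]
    grid = np.union1d(edges, interior)
    vals = np.interp(grid, x, y)
    cum = cumulative_trapezoid(vals, grid, initial=0.0)
    at_edges = np.interp(edges, grid, cum)
    bin_values = np.diff(at_edges)
    bin_centers = 0.5 * (edges[:-1] + edges[1:])
    return BinnedSpectrum(bin_centers, bin_values)


def read_spectrum(path, descending: bool = True) -> Spectrum:
    """Read a two-column text spectrum (x, y); '#' starts a comment line."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    x, y = data[:, 0], data[:, 1]
    if descending and x[0] < x[-1]:
        x, y = x[::-1], y[::-1]
    return Spectrum(x, y)


def write_spectrum(path, s: Spectrum) -> None:
    np.savetxt(
        path,
        np.column_stack([s.wavenumbers, s.absorbance]),
        header="x y",
        fmt="%.8g",
    )
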