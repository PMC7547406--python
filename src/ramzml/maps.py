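"""In-memory hyperspectral map containers.

A Raman imaging measurement is a set of spectra acquired on a rectangular
stage raster. :class:`RamanMap` holds the shared Raman-shift axis (cm^-1,
strictly ascending), the 1-based integer pixel coordinates, and the
n_pixels x n_channels intensity matrix. :class:`GridMapping` records how
physical stage positions (micrometres) map onto integer pixel indices —
the translation imzML requires, since the format stores only integer
positions plus an optional pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyMap, IrregularGrid

__all__ = ["GridMapping", "RamanMap", "infer_grid"]

DIALECTS = ("renishaw_long", "witec_wide", "imzml", "synthetic")


@dataclass(frozen=True)
class GridMapping:
    """Affine mapping between stage coordinates (um) and 1-based pixel indices.

    ``col = round((x - origin_x) / step_x) + 1`` and likewise for rows; row 1
    corresponds to the minimum physical y. The grid may be sparse: it bounds
    the pixel set but every cell need not hold a spectrum.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    step_x: float = 1.0
    step_y: float = 1.0
    width: int = 1
    height: int = 1

    def __post_init__(self):
        if self.step_x <= 0 or self.step_y <= 0:
            raise ValueError("grid steps must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive integers")

    def to_indices(self, xs, ys, tol: float = 0.1) -> np.ndarray:
        """Snap physical coordinates to (col, row) pairs.

        Raises :class:`IrregularGrid` if any coordinate deviates from its
        snapped lattice point by more than ``tol`` of a step.
        """
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        cols = _snap(xs, self.origin_x, self.step_x, tol, "x")
        rows = _snap(ys, self.origin_y, self.step_y, tol, "y")
        return np.column_stack([cols, rows])

    def to_physical(self, cols, rows) -> tuple[np.ndarray, np.ndarray]:
        cols = np.asarray(cols, dtype=float)
        rows = np.asarray(rows, dtype=float)
        return (self.origin_x + (cols - 1) * self.step_x,
                self.origin_y + (rows - 1) * self.step_y)


def _snap(vals: np.ndarray, origin: float, step: float, tol: float, axis_name: str):
    frac = (vals - origin) / step
    idx = np.rint(frac)
    dev = np.abs(frac - idx)
    if np.any(dev > tol):
        worst = int(np.argmax(dev))
        raise IrregularGrid(
            f"{axis_name}-coordinate {vals[worst]} is {dev[worst]:.3f} steps "
            f"off the lattice (tolerance {tol})"
        )
    return idx.astype(int) + 1


def infer_grid(xs, ys, tol: float = 0.1) -> GridMapping:
    """Infer the rectangular grid underlying physical pixel coordinates.

    The step along each axis is the minimum positive gap between sorted
    unique coordinate values (1.0 if the axis has a single unique value);
    the origin is the minimum coordinate. Every coordinate must land within
    ``tol`` of a step from an integer lattice point.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0:
        raise EmptyMap("cannot infer a grid from zero pixels")
    if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))):
        raise IrregularGrid("non-finite stage coordinates")

    def _axis(vals):
        uniq = np.unique(vals)
        if uniq.size == 1:
            return float(uniq[0]), 1.0
        gaps = np.diff(uniq)
        return float(uniq[0]), float(gaps[gaps > 0].min())

    ox, sx = _axis(xs)
    oy, sy = _axis(ys)
    cols = _snap(xs, ox, sx, tol, "x")
    rows = _snap(ys, oy, sy, tol, "y")
    return GridMapping(origin_x=ox, origin_y=oy, step_x=sx, step_y=sy,
                       width=int(cols.max()), height=int(rows.max()))


@dataclass
class RamanMap:
    """A hyperspectral Raman map with a shared spectral axis.

    Parameters
    ----------
    axis : (n_channels,) float array, strictly ascending Raman shift in cm^-1.
    pixels : (n_pixels, 2) int array of 1-based (col, row) pairs, unique.
    intensities : (n_pixels, n_channels) float array, finite.
    grid : GridMapping bounding the pixel set.
    source_dialect : one of {renishaw_long, witec_wide, imzml, synthetic}.

    Pixels are stored in canonical row-major order (row ascending, then
    column), which is also the spectrum order used in the .ibd layout.
    """

    axis: np.ndarray
    pixels: np.ndarray
    intensities: np.ndarray
    grid: GridMapping = field(default_factory=GridMapping)
    source_dialect: str = "synthetic"

    def __post_init__(self):
        self.axis = np.ascontiguousarray(self.axis, dtype=np.float64).ravel()
        self.pixels = np.ascontiguousarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        self.intensities = np.ascontiguousarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (n_pixels x n_channels)")
        order = np.lexsort((self.pixels[:, 0], self.pixels[:, 1]))
        self.pixels = self.pixels[order]
        self.intensities = self.intensities[order]
        self.validate()

    # -- structural invariants -------------------------------------------------
    def validate(self) -> None:
        if self.axis.size < 1 or self.pixels.shape[0] < 1:
            raise EmptyMap("map needs at least one pixel and one channel")
        if not np.all(np.isfinite(self.axis)):
            raise ValueError("axis contains non-finite values")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly ascending")
        if self.intensities.shape != (self.pixels.shape[0], self.axis.size):
            raise ValueError(
                f"intensities shape {self.intensities.shape} inconsistent with "
                f"{self.pixels.shape[0]} pixels x {self.axis.size} channels"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if len({tuple(p) for p in self.pixels}) != self.pixels.shape[0]:
            raise ValueError("duplicate pixel coordinates")
        cols, rows = self.pixels[:, 0], self.pixels[:, 1]
        if cols.min() < 1 or rows.min() < 1:
            raise ValueError("pixel indices are 1-based")
        if cols.max() > self.grid.width or rows.max() > self.grid.height:
            raise ValueError("pixel indices exceed grid dimensions")
        if self.source_dialect not in DIALECTS:
            raise ValueError(f"unknown source dialect {self.source_dialect!r}")

    # -- convenience -----------------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    @property
    def axis_range(self) -> tuple[float, float]:
        return float(self.axis[0]), float(self.axis[-1])

    def is_dense(self) -> bool:
        """True when every grid cell holds a spectrum."""
        return self.n_pixels == self.grid.width * self.grid.height

    def physical_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        return self.grid.to_physical(self.pixels[:, 0], self.pixels[:, 1])

    def with_dialect(self, dialect: str) -> "RamanMap":
        return replace(self, source_dialect=dialect)

    def equals(self, other: "RamanMap", *, rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Content equality: axis, pixel set, intensities and grid dimensions.

        Physical calibration (grid origin and step) is metadata and excluded:
        a single-column map carries no evidence of its x step, and imzML
        records pixel sizes but no absolute stage origin, so neither can
        survive every round trip.
        """
        if not isinstance(other, RamanMap):
            return NotImplemented
        if self.grid.width != other.grid.width or self.grid.height != other.grid.height:
            return False
        if not np.array_equal(self.pixels, other.pixels):
            return False
        if rtol == 0.0 and atol == 0.0:
            return (np.array_equal(self.axis, other.axis)
                    and np.array_equal(self.intensities, other.intensities))
        return (np.allclose(self.axis, other.axis, rtol=rtol, atol=atol)
                and np.allclose(self.intensities, other.intensities, rtol=rtol, atol=atol))

    def __eq__(self, other):
        if not isinstance(other, RamanMap):
            return NotImplemented
        return self.equals(other)
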