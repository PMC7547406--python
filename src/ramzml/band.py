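"""Band-image extraction and annotation helpers.

A *band image* is the Raman analogue of an MSI ion image: the per-pixel
intensity at (or aggregated around) one Raman shift, laid out on the pixel
grid. The classic example is the CH2 symmetric stretch near 2850 cm^-1,
which highlights lipid-rich structures such as white-matter tracts.

The module also provides the standard MSI annotation accuracy measure:
the signed relative deviation of an observed from a theoretical mass in
parts per million, plus a monoisotopic adduct-mass helper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyteomics import mass as _ptmass

from .errors import DomainError, EmptyWindow, IOFailure
from .maps import RamanMap

__all__ = ["BandImage", "nearest_index", "extract_band_image",
           "relative_ppm_error", "monoisotopic_mass", "adduct_mz"]

STATS = ("max", "sum", "mean")

#: monoisotopic masses of the supported adduct cations, electron removed
_ELECTRON = 0.00054857990907
_ADDUCTS = {
    "[M+H]+": _ptmass.calculate_mass(formula="H") - _ELECTRON,
    "[M+Na]+": _ptmass.calculate_mass(formula="Na") - _ELECTRON,
    "[M+K]+": _ptmass.calculate_mass(formula="K") - _ELECTRON,
}


@dataclass
class BandImage:
    """2-D intensity image extracted at one Raman-shift window.

    ``grid`` has shape (height, width); grid cells without a source pixel
    hold NaN — zero is a valid intensity and is never used as the missing
    marker.
    """

    grid: np.ndarray
    band_center: float
    half_width: float
    stat: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.grid)

    def to_text(self, path, delimiter: str = "\t") -> None:
        """Write the image as a delimited text matrix; missing cells as 'nan'."""
        try:
            np.savetxt(path, self.grid, delimiter=delimiter, fmt="%.9g")
        except OSError as exc:
            raise IOFailure(f"cannot write {path}: {exc}") from exc

    def to_pgm(self, path) -> None:
        """Write an 8-bit binary PGM (P5) for quick viewing.

        Intensities are min-max scaled to 0..255; missing cells render as 0.
        """
        filled = np.nan_to_num(self.grid, nan=np.nanmin(self.grid)
                               if not np.all(np.isnan(self.grid)) else 0.0)
        lo, hi = filled.min(), filled.max()
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        img = ((filled - lo) * scale).round().astype(np.uint8)
        h, w = img.shape
        try:
            with open(path, "wb") as fh:
                fh.write(f"P5\n{w} {h}\n255\n".encode("ascii"))
                fh.write(img.tobytes())
        except OSError as exc:
            raise IOFailure(f"cannot write {path}: {exc}") from exc


def nearest_index(axis: np.ndarray, value: float) -> int:
    """Index of the axis entry closest to ``value``; ties go to the lower index."""
    axis = np.asarray(axis)
    pos = int(np.searchsorted(axis, value))
    if pos == 0:
        return 0
    if pos == axis.size:
        return axis.size - 1
    below, above = axis[pos - 1], axis[pos]
    # tie -> lower index
    return pos - 1 if value - below <= above - value else pos


def extract_band_image(ramap: RamanMap, center: float, half_width: float = 0.0,
                       stat: str = "max") -> BandImage:
    """Extract a 2-D image of per-pixel intensity in a Raman-shift window.

    The window ``[center - half_width, center + half_width]`` is closed at
    both ends; ``half_width=0`` degenerates to the single nearest channel.
    ``stat`` aggregates the in-window channels per pixel (max, sum or mean).
    Grid cells without a spectrum hold NaN.
    """
    if stat not in STATS:
        raise ValueError(f"stat must be one of {STATS}")
    if half_width < 0:
        raise ValueError("half_width must be non-negative")
    axis = ramap.axis
    if half_width == 0:
        sel = np.array([nearest_index(axis, center)])
    else:
        lo, hi = center - half_width, center + half_width
        if hi < axis[0] or lo > axis[-1]:
            raise EmptyWindow(
                f"window [{lo}, {hi}] does not intersect the axis range "
                f"[{axis[0]}, {axis[-1]}]")
        sel = np.flatnonzero((axis >= lo) & (axis <= hi))
        if sel.size == 0:
            raise EmptyWindow(f"no channel inside [{lo}, {hi}]")

    window = ramap.intensities[:, sel]
    reducer = {"max": np.max, "sum": np.sum, "mean": np.mean}[stat]
    values = reducer(window, axis=1)

    grid = np.full((ramap.grid.height, ramap.grid.width), np.nan)
    cols, rows = ramap.pixels[:, 0], ramap.pixels[:, 1]
    grid[rows - 1, cols - 1] = values
    return BandImage(grid=grid, band_center=float(center),
                     half_width=float(half_width), stat=stat)


def relative_ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative deviation in parts per million.

    ``(observed - theoretical) / theoretical * 1e6``; zero iff equal.
    """
    if theoretical <= 0:
        raise DomainError(f"theoretical value must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of a neutral molecular formula, in Da."""
    return float(_ptmass.calculate_mass(formula=formula))


def adduct_mz(formula: str, adduct: str = "[M+K]+") -> float:
    """m/z of a singly charged cation adduct of the neutral molecule.

    Supported adducts: [M+H]+, [M+Na]+, [M+K]+. The electron mass is
    subtracted, as the ion lacks one electron.
    """
    if adduct not in _ADDUCTS:
        raise DomainError(f"unsupported adduct {adduct!r}; "
                          f"choose from {sorted(_ADDUCTS)}")
    return monoisotopic_mass(formula) + _ADDUCTS[adduct]
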