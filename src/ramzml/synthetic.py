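"""Synthetic Raman maps with known ground truth.

Generates hyperspectral maps of Gaussian bands on a rectangular pixel grid,
each band gated by a spatial amplitude mask (uniform, disk or stripe), on a
linear baseline with additive Gaussian noise. The default preset emulates
the kind of scene a tissue measurement produces: a lipid CH2-stretch band
near 2850 cm^-1 confined to a stripe (a white-matter tract) on top of a
weaker uniform tissue band, sampled at a 2 um stage step.

Gaussian profiles (rather than Lorentzian/Voigt) are deliberate: the maps
exist to exercise parsing, conversion and band extraction end to end, not
to model Raman line-shape physics. Generated axis and intensity values are
rounded through IEEE-754 single precision so that text and imzML round
trips are exact.

The module also writes maps back out in both vendor text dialects, which
makes every parser testable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IOFailure, SparseMapUnsupported
from .maps import GridMapping, RamanMap

__all__ = ["Band", "SyntheticSpec", "GroundTruth", "generate_map",
           "write_renishaw_text", "write_witec_text", "write_ground_truth",
           "preset", "PRESETS"]


@dataclass(frozen=True)
class Band:
    """One Gaussian band: centre and sigma in cm^-1, amplitude in counts.

    ``mask`` selects which pixels carry the band at full amplitude
    (``uniform`` everywhere; ``disk`` with params center_col/center_row/
    radius in pixels; ``stripe`` with params position/thickness in pixels
    and orientation ``horizontal`` (a run of rows) or ``vertical``).
    """

    center: float
    sigma: float
    amplitude: float
    mask: str = "uniform"
    mask_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("band sigma must be positive")
        if self.mask not in ("uniform", "disk", "stripe"):
            raise ValueError(f"unknown mask {self.mask!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Scene description for :func:`generate_map`.

    Defaults reproduce the ``brain-stripe`` preset: a 32 x 32 map at a 2 um
    step over 600-3200 cm^-1, with a uniform tissue band at 1450 cm^-1 and
    a stripe-masked lipid band at 2850 cm^-1, noise at 1% of the lipid
    amplitude.
    """

    axis_start: float = 600.0
    axis_end: float = 3200.0
    n_channels: int = 651
    width: int = 32
    height: int = 32
    step: float = 2.0
    bands: tuple[Band, ...] = (
        Band(center=1450.0, sigma=25.0, amplitude=40.0, mask="uniform"),
        Band(center=2850.0, sigma=10.0, amplitude=100.0, mask="stripe",
             mask_params={"position": 13, "thickness": 6,
                          "orientation": "horizontal"}),
    )
    baseline_slope: float = 0.005
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.axis_end <= self.axis_start:
            raise ValueError("axis_end must exceed axis_start")
        if self.n_channels < 2:
            raise ValueError("need at least two channels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.width < 1 or self.height < 1 or self.step <= 0:
            raise ValueError("invalid grid geometry")


@dataclass
class GroundTruth:
    """What the generator actually put into each pixel."""

    masks: list[np.ndarray]          # per band, (height, width) bool
    amplitudes: np.ndarray           # (n_pixels, n_bands) counts
    bands: tuple[Band, ...]


def _mask_array(band: Band, width: int, height: int) -> np.ndarray:
    cols, rows = np.meshgrid(np.arange(1, width + 1), np.arange(1, height + 1))
    if band.mask == "uniform":
        return np.ones((height, width), dtype=bool)
    p = band.mask_params
    if band.mask == "disk":
        cc = p.get("center_col", (width + 1) // 2)
        cr = p.get("center_row", (height + 1) // 2)
        radius = p.get("radius", min(width, height) / 4)
        return (cols - cc) ** 2 + (rows - cr) ** 2 <= radius ** 2
    # stripe
    pos = p.get("position", 1)
    thick = p.get("thickness", 1)
    run = rows if p.get("orientation", "horizontal") == "horizontal" else cols
    return (run >= pos) & (run < pos + thick)


def generate_map(spec: SyntheticSpec = SyntheticSpec()) -> tuple[RamanMap, GroundTruth]:
    """Generate a dense map per the spec; reproducible under ``spec.seed``.

    Per pixel p and channel nu:
    ``I(p, nu) = sum_k A_k(p) exp(-(nu - c_k)^2 / (2 sigma_k^2))
    + baseline_slope * (nu - axis_start) + Normal(0, noise_sd^2)``,
    with A_k(p) the band amplitude inside its mask and 0 outside.
    """
    rng = np.random.default_rng(spec.seed)
    axis = np.linspace(spec.axis_start, spec.axis_end, spec.n_channels)
    n_px = spec.width * spec.height

    masks = [_mask_array(b, spec.width, spec.height) for b in spec.bands]
    # row-major pixel order: row ascending, column fastest
    flat_masks = np.array([m.ravel() for m in masks])        # (n_bands, n_px)
    amplitudes = (flat_masks.T *
                  np.array([b.amplitude for b in spec.bands]))  # (n_px, n_bands)

    profiles = np.array([np.exp(-(axis - b.center) ** 2 / (2 * b.sigma ** 2))
                         for b in spec.bands])               # (n_bands, n_ch)
    intensities = amplitudes @ profiles
    intensities += spec.baseline_slope * (axis - spec.axis_start)
    if spec.noise_sd > 0:
        intensities += rng.normal(0.0, spec.noise_sd, size=intensities.shape)

    # single-precision rounding: text and imzML round trips are then exact
    axis = axis.astype(np.float32).astype(np.float64)
    intensities = intensities.astype(np.float32).astype(np.float64)

    k = np.arange(n_px)
    pixels = np.column_stack([k % spec.width + 1, k // spec.width + 1])
    grid = GridMapping(step_x=spec.step, step_y=spec.step,
                       width=spec.width, height=spec.height)
    ramap = RamanMap(axis=axis, pixels=pixels, intensities=intensities,
                     grid=grid, source_dialect="synthetic")
    return ramap, GroundTruth(masks=masks, amplitudes=amplitudes,
                              bands=spec.bands)


# ---------------------------------------------------------------------------
# vendor-dialect writers (round-trip contracts with vendor_text)
# ---------------------------------------------------------------------------

def write_renishaw_text(ramap: RamanMap, path, header: bool = True) -> None:
    """Write the long 4-column dialect (X um, Y um, shift, intensity).

    Full shortest-round-trip decimal precision, so parsing the file back
    reproduces the map exactly.
    """
    xs, ys = ramap.physical_coordinates()
    try:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write("#X\t#Y\tWave\tIntensity\n")
            for x, y, spectrum in zip(xs, ys, ramap.intensities):
                for shift, inten in zip(ramap.axis, spectrum):
                    fh.write(f"{float(x)!r}\t{float(y)!r}\t"
                             f"{float(shift)!r}\t{float(inten)!r}\n")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc


def write_witec_text(ramap: RamanMap, path, header: bool = False) -> None:
    """Write the wide dialect: axis column plus one column per pixel.

    The wide table cannot express holes, so the map must be dense; pixel
    columns follow row-major order (row ascending, column fastest), matching
    the default fill order of the wide parser.
    """
    if not ramap.is_dense():
        raise SparseMapUnsupported(
            f"{ramap.n_pixels} spectra cannot fill a "
            f"{ramap.grid.width} x {ramap.grid.height} grid")
    try:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                names = "\t".join(f"px{c}_{r}" for c, r in ramap.pixels)
                fh.write(f"Wave\t{names}\n")
            for j, shift in enumerate(ramap.axis):
                row = "\t".join(repr(float(v)) for v in ramap.intensities[:, j])
                fh.write(f"{float(shift)!r}\t{row}\n")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write per-band masks and amplitudes as a TSV sidecar."""
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("band\tcenter\tsigma\tamplitude\tmask\tcol\trow\tin_mask\n")
            for b, (band, mask) in enumerate(zip(gt.bands, gt.masks)):
                h, w = mask.shape
                for r in range(1, h + 1):
                    for c in range(1, w + 1):
                        fh.write(f"{b}\t{float(band.center)!r}\t"
                                 f"{float(band.sigma)!r}\t"
                                 f"{float(band.amplitude)!r}\t{band.mask}\t"
                                 f"{c}\t{r}\t{int(mask[r - 1, c - 1])}\n")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc


def preset(name: str, *, width: int | None = None, height: int | None = None,
           seed: int | None = None, noise_sd: float | None = None) -> SyntheticSpec:
    """Look up a named scene, optionally overriding size, seed or noise."""
    base = PRESETS[name]
    kwargs = {}
    if width is not None:
        kwargs["width"] = width
    if height is not None:
        kwargs["height"] = height
    if seed is not None:
        kwargs["seed"] = seed
    if noise_sd is not None:
        kwargs["noise_sd"] = noise_sd
    if not kwargs:
        return base
    from dataclasses import replace
    return replace(base, **kwargs)


PRESETS = {
    "brain-stripe": SyntheticSpec(),
}
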