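"""Parsers for Raman map text exports.

Two vendor dialects are supported:

* **renishaw_long** — long format, one row per (pixel, channel) with four
  columns: stage X (um), stage Y (um), Raman shift (cm^-1), intensity.
  Rows are grouped by pixel; leading non-numeric header lines are skipped.
* **witec_wide** — wide format, first column the Raman-shift axis and one
  column per spectrum. The export carries no stage coordinates, so the
  caller must supply the map dimensions (and optionally the stage step).

Both parsers normalise the axis to strictly ascending order and return a
:class:`~ramzml.maps.RamanMap` with an inferred (or synthesised) integer
pixel grid. A file whose numeric rows all have exactly four columns is
ambiguous in principle; the sniffer resolves the tie in favour of
``renishaw_long``, and the CLI ``--vendor`` flag overrides detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (AxisMismatch, DimensionMismatch, ParseError, RaggedPixel)
from .maps import GridMapping, RamanMap, infer_grid

__all__ = ["ParseOptions", "sniff_dialect", "parse_renishaw", "parse_witec"]


@dataclass(frozen=True)
class ParseOptions:
    """Tokenisation settings for locale-exported files.

    ``delimiter=None`` splits on any run of whitespace; ``decimal=','``
    accepts comma decimal separators (tokens then must not be
    comma-delimited).
    """

    delimiter: str | None = None
    decimal: str = "."


def _tokens(line: str, opts: ParseOptions) -> list[str]:
    parts = line.split(opts.delimiter) if opts.delimiter else line.split()
    return [p for p in parts if p]


def _floats(tokens: list[str], opts: ParseOptions) -> list[float] | None:
    """Parse all tokens as floats, or None if any token is non-numeric."""
    out = []
    for tok in tokens:
        if opts.decimal != ".":
            tok = tok.replace(opts.decimal, ".")
        try:
            out.append(float(tok))
        except ValueError:
            return None
    return out


def sniff_dialect(text_sample: str, opts: ParseOptions = ParseOptions()) -> str:
    """Guess the vendor dialect from the first lines of a file.

    Returns ``"renishaw_long"`` when all numeric rows have exactly four
    columns, ``"witec_wide"`` when numeric rows have a constant width of at
    least two columns (other than four), and ``"unknown"`` otherwise.
    Never raises on decodable text.
    """
    widths = []
    for line in text_sample.splitlines()[:50]:
        toks = _tokens(line, opts)
        if not toks:
            continue
        if _floats(toks, opts) is not None:
            widths.append(len(toks))
    if not widths:
        return "unknown"
    if all(w == 4 for w in widths):
        return "renishaw_long"
    if len(set(widths)) == 1 and widths[0] >= 2:
        return "witec_wide"
    return "unknown"


def _iter_numeric_rows(path, opts: ParseOptions, *, skip_leading_text: bool,
                       max_header_rows: int | None = None):
    """Yield (line_number, floats) for numeric rows; skip permitted headers."""
    data_seen = False
    skipped = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            toks = _tokens(raw, opts)
            if not toks:
                continue
            vals = _floats(toks, opts)
            if vals is None:
                headers_allowed = skip_leading_text and not data_seen and (
                    max_header_rows is None or skipped < max_header_rows)
                if headers_allowed:
                    skipped += 1
                    continue
                raise ParseError(f"malformed numeric field in {toks!r}", line=lineno)
            data_seen = True
            yield lineno, vals


def parse_renishaw(path, opts: ParseOptions = ParseOptions(),
                   grid_tol: float = 0.1) -> RamanMap:
    """Parse a Renishaw-style long-format export into a :class:`RamanMap`.

    Each row is ``X(um)  Y(um)  shift(cm^-1)  intensity``; rows are grouped
    by pixel. All pixels must share an identical Raman-shift axis (exact
    value equality after ascending normalisation). The integer pixel grid
    is inferred from the stage coordinates.
    """
    # dict keyed on exact (x, y) floats, insertion-ordered
    by_pixel: dict[tuple[float, float], tuple[list[float], list[float]]] = {}
    for lineno, vals in _iter_numeric_rows(path, opts, skip_leading_text=True):
        if len(vals) != 4:
            raise ParseError(f"expected 4 columns, found {len(vals)}", line=lineno)
        x, y, shift, inten = vals
        shifts, intens = by_pixel.setdefault((x, y), ([], []))
        shifts.append(shift)
        intens.append(inten)

    if not by_pixel:
        raise ParseError("no data rows found", line=None)

    lengths = {len(s) for s, _ in by_pixel.values()}
    if len(lengths) != 1:
        raise RaggedPixel(f"pixels have differing channel counts: {sorted(lengths)}")

    axis_ref = None
    spectra = []
    coords = []
    for (x, y), (shifts, intens) in by_pixel.items():
        shifts = np.asarray(shifts)
        intens = np.asarray(intens)
        order = np.argsort(shifts, kind="stable")
        shifts, intens = shifts[order], intens[order]
        if np.any(np.diff(shifts) == 0):
            raise ParseError(f"duplicate Raman shift value within pixel ({x}, {y})")
        if axis_ref is None:
            axis_ref = shifts
        elif not np.array_equal(shifts, axis_ref):
            raise AxisMismatch(f"pixel ({x}, {y}) axis differs from the first pixel's")
        coords.append((x, y))
        spectra.append(intens)

    xs = np.array([c[0] for c in coords])
    ys = np.array([c[1] for c in coords])
    grid = infer_grid(xs, ys, tol=grid_tol)
    pixels = grid.to_indices(xs, ys, tol=grid_tol)
    return RamanMap(axis=axis_ref, pixels=pixels, intensities=np.vstack(spectra),
                    grid=grid, source_dialect="renishaw_long")


def parse_witec(path, width: int, height: int, *,
                fill_order: str = "row_major",
                step_x: float = 1.0, step_y: float = 1.0,
                opts: ParseOptions = ParseOptions()) -> RamanMap:
    """Parse a WITec-style wide-format export into a :class:`RamanMap`.

    Column 1 holds the Raman-shift axis; columns 2..P+1 hold one spectrum
    per pixel. The file stores no coordinates: pixel positions are
    synthesised from ``(width, height, fill_order)``; under the default
    ``row_major`` order (x fastest) spectrum *k* (0-based) lands at
    ``(col = k % width + 1, row = k // width + 1)``.
    """
    if width < 1 or height < 1:
        raise DimensionMismatch(f"invalid dimensions {width} x {height}")
    if fill_order not in ("row_major", "column_major"):
        raise ValueError(f"unknown fill order {fill_order!r}")

    rows = []
    ncols = None
    for lineno, vals in _iter_numeric_rows(path, opts, skip_leading_text=True,
                                           max_header_rows=1):
        if ncols is None:
            ncols = len(vals)
            if ncols < 2:
                raise ParseError("wide format needs an axis column plus "
                                 "at least one spectrum column", line=lineno)
        elif len(vals) != ncols:
            raise ParseError(f"expected {ncols} columns, found {len(vals)}",
                             line=lineno)
        rows.append(vals)

    if not rows:
        raise ParseError("no data rows found", line=None)

    table = np.asarray(rows)
    n_spectra = table.shape[1] - 1
    if n_spectra != width * height:
        raise DimensionMismatch(
            f"{n_spectra} spectra in file, but width x height = {width * height}")

    axis = table[:, 0]
    intensities = table[:, 1:].T  # one row per pixel
    order = np.argsort(axis, kind="stable")
    axis, intensities = axis[order], intensities[:, order]
    if np.any(np.diff(axis) == 0):
        raise ParseError("duplicate Raman shift value in axis column")

    k = np.arange(n_spectra)
    if fill_order == "row_major":
        cols, rws = k % width + 1, k // width + 1
    else:
        cols, rws = k // height + 1, k % height + 1
    grid = GridMapping(step_x=step_x, step_y=step_y, width=width, height=height)
    return RamanMap(axis=axis, pixels=np.column_stack([cols, rws]),
                    intensities=intensities, grid=grid,
                    source_dialect="witec_wide")
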