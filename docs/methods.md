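# Methods

## Data model

A Raman map is modelled as a shared, strictly ascending spectral axis
ν₁ < … < ν_N (Raman shift, cm⁻¹), a set of unique 1-based integer pixel
coordinates (col, row), and an n_pixels × N intensity matrix (detector
counts). Pixels are held in canonical row-major order (row ascending, column
fastest), which is also the spectrum order in the binary layout, so equal
maps have equal serialisations.

The integer grid is tied to physical stage coordinates by an affine
`GridMapping`: `col = round((x − origin_x)/step_x) + 1`, row 1 at minimum y.
Grid inference takes the step along each axis as the minimum positive gap
between sorted unique coordinates (1 µm when an axis has a single value) and
the origin as the minimum coordinate; a coordinate farther than `tol` steps
(default 0.1) from its snapped lattice point raises `IrregularGrid`. The
default tolerance accepts ordinary stage jitter (a few percent of a step)
while rejecting genuinely off-lattice points; inference is translation
invariant by construction. Grids may be sparse — interrupted acquisitions
leave cells without spectra — and a missing cell is never confused with zero
intensity downstream.

**Equality semantics.** Two maps are equal when axis, pixel set, intensities
and grid dimensions agree. Physical calibration (origin, step) is metadata
and excluded: a one-column map carries no evidence of its x step, and imzML
stores pixel sizes but no absolute stage origin, so neither can survive
every round trip. Steps are still written to and recovered from imzML via
the pixel-size scan-settings terms, and tests assert that separately.

## Vendor text dialects

The long dialect (four whitespace- or tab-separated numeric columns
X, Y, shift, intensity; leading non-numeric header lines skipped) and the
wide dialect (axis column plus one column per spectrum, one optional header
row) mirror the common table exports of the two major Raman instrument
families. The wide export carries no coordinates, so map width and height
must be supplied; positions are synthesised in row-major order (x fastest)
by default, with a column-major option.

Dialect sniffing inspects up to 50 lines: all numeric rows of exactly four
columns → long; constant width ≥ 2 otherwise → wide. A wide file that
happens to have three spectra per row is indistinguishable from the long
format; the sniffer deterministically prefers the long reading and the
`--vendor` flag overrides. The decimal separator defaults to `.` with a `,`
option for locale exports.

Axes are always normalised to strictly ascending order (intensities
reordered in step); duplicate shift values within a pixel are rejected
because they make band lookup ill-defined. All pixels of a long file must
share an identical axis after normalisation — exact value equality, not a
tolerance — since a single acquisition has one spectrometer calibration;
differing channel counts raise `RaggedPixel`, differing values
`AxisMismatch`, both with line-number context where available.

## imzML layout and integrity

The `.ibd` layout is computed before any byte is written: continuous mode is
`[UUID 16 B][axis 4N B][intensity₁ 4N B]…`, processed mode interleaves per-
spectrum axis and intensity arrays. All arrays are little-endian IEEE-754
single precision (round-to-nearest), uncompressed; encoded length is
therefore exactly 4 × array length. Continuous is the default — every parsed
map has a shared axis, and the shared layout halves file size and matches
what MSI readers expect; processed mode is kept for generality.

The XML document carries the binary-mode term, the UUID (hyphenated hex,
identical to the 16 header bytes), the lowercase SHA-1 of the entire `.ibd`
file, referenceable param groups declaring external 32-bit float arrays, the
grid dimensions and pixel sizes in scan settings, and per spectrum the
integer position plus external offset / array length / encoded length for
both arrays. The Raman-shift axis occupies the "m/z array" slot with no unit
extension: the imzML controlled vocabulary has no Raman terms, and reusing
the slot keeps converted files readable by every existing MSI tool. The
consequence — only numeric imaging information survives; integration time,
excitation wavelength and similar acquisition metadata do not — is reported
at conversion time rather than silently accepted.

On read, a SHA-1 or UUID mismatch warns by default and hard-fails under
`strict_checksum`: corrupted data may still be worth recovering, and the
validator exists for strictness. The validator never raises; it returns
findings (code, severity, detail) for UUID mismatch, checksum mismatch,
out-of-bounds regions, encoded-length inconsistency, non-shared continuous
axis offsets, duplicated or missing mode terms, region overlaps and
malformed XML. A flipped payload byte therefore yields exactly one finding
(checksum), and truncation yields an offset finding.

## Band images and annotation

A band image applies max, sum or mean over the channels whose shift lies in
the closed window [c − w, c + w]; closed boundaries make behaviour at window
edges deterministic. `half_width = 0` degenerates to the single nearest
channel, with ties between equidistant channels broken toward the lower
index. Cells without a spectrum hold NaN — zero is a valid intensity and is
never used as a missing marker; the PGM export (8-bit, min–max scaled)
renders missing cells as black and is intended for quick viewing only, with
the text matrix as the lossless output.

The annotation helper returns the signed relative error
(m_obs − m_theo)/m_theo × 10⁶. Adduct masses ([M+H]⁺, [M+Na]⁺, [M+K]⁺) are
monoisotopic formula masses (via pyteomics) plus the cation minus one
electron mass. The package's worked check: observed m/z 850.58 against
computed [M+K]⁺ of phosphatidylcholine 38:3 (C₄₆H₈₆NO₈P, 850.5723 Da) gives
+9.1 ppm.

## Synthetic scenes

The generator produces, per pixel p and channel ν,
`I(p, ν) = Σ_k A_k(p)·exp(−(ν − c_k)²/(2σ_k²)) + s·(ν − ν₁) + ε`,
with A_k equal to the band amplitude inside its spatial mask (uniform, disk
or stripe) and zero outside, baseline slope s, and ε ~ N(0, noise_sd²) from
a seeded generator. The default `brain-stripe` scene emulates a tissue
section: a 32×32 grid at a 2 µm step, axis 600–3200 cm⁻¹ in 651 channels
(4 cm⁻¹ spacing), a uniform tissue band at 1450 cm⁻¹ (σ 25, amplitude 40), a
lipid band at 2850 cm⁻¹ (σ 10, amplitude 100) on a 6-row stripe standing in
for a white-matter tract, baseline slope 0.005 counts/cm⁻¹ and noise SD 1
count (1% of the lipid amplitude — a clean but not noiseless map).

Generated axis and intensity values are rounded through float32 once at
generation, so text and imzML round trips are exact rather than
approximately equal; the text writers print shortest-round-trip decimals.

What the generator does **not** emulate: Lorentzian/Voigt line shapes,
baseline curvature, shot noise, cosmic-ray spikes, detector saturation, or
stage-coordinate jitter. Passing tests demonstrate that parsing, layout,
serialisation and extraction are exact and structurally sound — not that the
pipeline is robust to real-instrument artefacts, which are out of scope
(despiking and baseline correction belong upstream).

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on the
32×32 × 651-channel scene (≈2.7 M values per round trip), verify the layout
against a brute-force append simulator on 200 random maps up to 5×5×16, and
inject single-byte faults at every payload position of a small pair —
exhaustive where the space is small, sampled where it is not. These sizes
exercise every code path at desk scale; nothing in the implementation is
size-dependent beyond memory.

Other fixed choices: spectra are written row-major; fresh random v4 UUIDs
per conversion with an override for reproducible output (fixed UUID ⇒
bit-identical `.ibd`); SHA-1 is compared case-insensitively on read and
rendered lowercase; CLI exit codes are 0/1/2/3 (success / usage or parse
error / strict-mode findings / I/O failure).

## Limitations

Vendor binary formats (.wdf, WITec projects) are not read; compression and
64-bit output are not written; the wide dialect cannot express sparse maps;
maps are held fully in memory (a 10⁶-pixel map at 1000 channels would need
~8 GB — streaming conversion is a possible extension); and nothing beyond
structural validity is checked against the imzML XSD schema.
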