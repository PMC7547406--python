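# ramzml

Raman imaging maps and mass spectrometry imaging (MSI) data describe the same
kind of object — a grid of pixels, each carrying a spectrum — but live in
incompatible formats: Raman microscopes export plain-text tables, MSI software
speaks [imzML](https://ms-imaging.org/imzml/) (an XML index plus a `.ibd`
binary file linked by a UUID). `ramzml` converts Raman text exports into
standards-conformant imzML so both modalities can be explored with one set of
tools, and provides the reading, validation and image-extraction pieces around
that conversion.

It is aimed at spectroscopists and MSI practitioners who co-register Raman and
MSI measurements of the same tissue, and at anyone who needs a scriptable,
dependency-light imzML writer for non-MS hyperspectral data.

## What it does

* **Parse vendor text** — the Renishaw-style *long* dialect (one row per
  pixel/channel: `X(µm) Y(µm) shift(cm⁻¹) intensity`) and the WITec-style
  *wide* dialect (axis column plus one spectrum column per pixel), with
  dialect sniffing, locale options and integer pixel-grid inference from
  stage coordinates.
* **Write/read/validate imzML** — computes the exact `.ibd` byte layout in
  both *continuous* (shared axis stored once) and *processed* (per-spectrum
  arrays) modes, encodes all arrays as little-endian IEEE-754 32-bit floats,
  and records the UUID and the SHA-1 of the binary file in the XML. The
  validator checks UUID/SHA-1 agreement, offset bounds, encoded-length
  consistency (`encoded = 4 × length`), shared-axis structure and region
  overlaps, reporting findings rather than raising.
* **Extract band images** — per-pixel intensity at a Raman-shift window
  (max/sum/mean over a closed window `[c − w, c + w]`), the Raman analogue of
  an MSI ion image; export as a text matrix or binary PGM. A ppm mass-error
  helper covers the standard MSI annotation check,
  `ppm = (m_obs − m_theo)/m_theo × 10⁶`.
* **Generate synthetic maps** — Gaussian bands with spatial masks on a
  baseline with Gaussian noise, written in both vendor dialects with a
  ground-truth sidecar, so the whole pipeline is testable offline.

Only numeric imaging information survives conversion (pixel positions, the
Raman-shift axis — stored in imzML's "m/z array" slot — and intensities);
acquisition metadata such as integration time or excitation wavelength has no
imzML vocabulary and is deliberately dropped, with a notice at conversion time.

## Worked example

```sh
ramzml synth --preset brain-stripe --seed 1 -o fixture
ramzml convert fixture/renishaw.txt -o brain
ramzml validate brain.imzML brain.ibd
ramzml image brain.imzML brain.ibd --center 2850 --halfwidth 30 --stat max -o lipid.pgm
```

prints (data on stdout, logs on stderr):

```
INFO synthesised 32x32 map, 651 channels
fixture/renishaw.txt
fixture/witec.txt
fixture/ground_truth.tsv
INFO converted 1024 pixels x 651 channels, axis 600.0-3200.0 cm^-1
INFO Only numeric imaging information (pixel positions, Raman shift axis, intensity values) is preserved; ...
brain.imzML	brain.ibd	sha1=2bf268cce962b899450c1d071c87dda884f6bc67
INFO pair is structurally valid
INFO band image 32x32 at 2850.0 +/- 30.0 cm^-1 (max) -> lipid.pgm
lipid.pgm
```

The synthetic scene is a 32×32 map (2 µm step, axis 600–3200 cm⁻¹) with a
lipid CH₂-stretch band at 2850 cm⁻¹ confined to a horizontal stripe — a
white-matter tract — over a weaker uniform tissue band at 1450 cm⁻¹. In the
extracted 2850 cm⁻¹ band image the stripe pixels average 109.8 counts against
13.0 off-stripe, so thresholding at half the band amplitude recovers the
tract. The same can be done from Python:

```python
import ramzml
m = ramzml.read_imzml("brain.imzML", "brain.ibd")
img = ramzml.extract_band_image(m, center=2850, half_width=30, stat="max")
img.to_text("lipid.tsv")
```

Exit codes are stable: 0 success, 1 usage/parse error, 2 validation findings
under `--strict`, 3 I/O failure.

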