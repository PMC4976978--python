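# Methods

## Rendering model

The renderer treats a multichannel epi-fluorescence image as a map of dye
concentrations and simulates a transillumination microscope shining white
light through them. For display channel *M* ∈ {R, G, B} and dyes *i* with
normalized intensities `I_i ∈ [0, 1]`:

```
T_M = ∏_i max( exp(−β_{M,i} · I_i · k), floor )
```

Assumptions: fluorescence is linear in fluorophore concentration (true at
realistic staining concentrations), dye absorption spectra are broad enough
that integrating attenuation over each display channel's band (the β
values) loses little relative to a full spectral model, and the virtual
specimen is non-scattering. The β matrix is the dye's color in the output
space; the shipped values are matched to H&E-stained tissue in sRGB:

|        | eosin | hematoxylin (DAPI) |
|--------|-------|--------------------|
| red    | 0.050 | 0.860              |
| green  | 1.000 | 1.000              |
| blue   | 0.544 | 0.300              |

Both dyes absorb green strongly — the spectral overlap that breaks additive
color mapping. β values for other labs' staining protocols can be supplied
via the JSON stain config; green = 1.000 for both dyes is taken as given
reference data (plausibly a normalization of each dye's strongest-absorbed
channel to unity) and is not renormalized by the code.

### Parameters

- `k` (default **2.5**, dimensionless): global exponent scale folding in
  detector sensitivity and gain. A full-scale pixel of a β = 1 dye
  transmits exp(−2.5) ≈ 8.2% before flooring. The exponent is read as the
  product β·I·k; with the default k this makes the floor/contrast
  arithmetic below consistent, whereas dividing by k would give implausibly
  weak virtual staining. The exact value mostly shifts the darkest pixels.
- `floor` (default **0.0075** of peak display intensity, linear light):
  per-absorber transmission clamp. Displays have ~256 levels and limited
  contrast; an unclamped exponential would waste range on invisible
  differences. The clamp is applied per dye factor *before* multiplication
  ("for each absorber"), so a channel's product can reach `floor^D` with D
  dyes.
- `apply_gamma` (default true): transmissions are computed in linear light
  and the standard two-segment sRGB transfer (linear slope 12.92 below
  0.0031308, offset power 1/2.4 above) is applied last. The effective
  contrast ratio `srgb(1.0) / srgb(floor²) ≈ 1376` — the "≈1000:1" display
  assumption — is only reproduced with the true piecewise transfer; a pure
  power law is deliberately not offered. The forward/inverse transfers snap
  inputs ≥ 1 to exactly 1 so the white point survives floating-point
  rounding of `1.055 − 0.055`.

Channels are matched to stain rows **by label**, never silently by
position, to prevent swapped DAPI/eosin renderings; `match_by_position=True`
is an explicit opt-in. The renderer accepts any number of dyes; H&E is the
bundled default. Quantization to 8 bits happens only in the file writer
(`round(v·255)`), all internal math is float64.

## Additive baselines

The two literature-style methods are reconstructions, not ports: the
original implementations are not printed in full anywhere we could follow,
so they are modeled as `clamp(backlight − Σ_i color_i · I_i^γ, 0, 1)` with
γ = 1 (linear method, white backlight) or γ = 0.5 by default (nonlinear
method, green-shifted backlight (0.9, 1.0, 0.9)); the exponent is
configurable rather than asserted as ground truth. Default dye colors are
the β rows scaled to unit peak so a full-scale single dye spans the display
range, keeping all three renderers comparable. Predictions of more than
total absorption are clamped at zero transmission — the dynamic-range loss
the multiplicative model avoids — and `dynamic_range_report` counts exactly
those clamped pixels.

## Auto-gain normalization

Each fluorescence channel is rescaled so a fixed tiny fraction of pixels
(default 1 per 100,000) sits at full scale. The rule is a rank statistic:
with N pixels and fraction s, the pivot is the r-th largest value of the
channel, r = max(1, floor(N·s)); gain = 1/pivot; pixels ≥ pivot saturate,
ties at the pivot all saturate (deterministic and order-independent). The
pivot is taken over the whole channel rather than only the not-yet-saturated
pixels: the two readings coincide whenever no pixel is saturated yet (the
normal case for raw acquisitions), and the whole-channel rule makes the map
idempotent — once the saturation quota exists the pivot is full scale and
the gain is 1 — where the excluding rule would saturate r further pixels on
every reapplication. Gains below 1 (over-exposed input) are permitted with
a logged warning, as is the degenerate constant channel (everything
saturates, with a warning); an all-zero channel is an error. For mosaics,
`normalize_stack` pools the histogram across all fields and applies one
gain per channel so adjacent fields stay consistent. Flat-field correction
and stitching are out of scope.

## Synthetic phantom

`generate_phantom` emulates the image content the renderer exists for —
nuclei on fibrous breast stroma — without claiming biological calibration:

- **nuclei**: `n_nuclei` ellipses with semi-axes uniform in
  `nucleus_axes_um` (default 3–6 µm), uniform orientation, centers uniform
  inside a margin that guarantees fit (an error if they cannot fit);
  interior intensity 0.65–1.0 modulated by smoothed-noise "chromatin"
  texture.
- **stroma**: three layers of white noise smoothed anisotropically
  (σ = 0.8 px across, 9 px along) and rotated to random orientations; the
  top `stroma_density` quantile becomes the stroma mask and scaled fiber
  texture in the eosin channel.
- **eosin haze**: a constant `eosin_background` (default 0.06) everywhere,
  emulating faint residual eosin in the buffer around a specimen, plus
  `nuclear_bleed` (default 0.10) of the nuclear signal in the eosin
  channel.
- **noise**: Gaussian with variance `mean/photon_scale + read_sigma²`,
  divided by `frames_averaged` (default 16, matching typical
  frame-averaged acquisition) — a Gaussian approximation of averaged
  Poisson shot noise plus detector read noise; output clipped to [0, 1].

Defaults (512×512 px at 0.5 µm/px) echo the scale of 20× multiphoton
acquisitions of ~500 µm fields while staying desk-sized. One `seed` feeds
`numpy.random.SeedSequence`, whose first two children drive structure and
noise separately, so outputs are bit-reproducible and a scene can be
re-noised independently. What the phantom does **not** model: 3-D duct
geometry, optical sectioning PSFs, stain diffusion, scattering, vignetting.
Tests that pass on the phantom therefore validate the rendering and
normalization contracts, not diagnostic image quality on real tissue.

## Numerical choices and degenerate inputs

- All image math in float64; `exp` underflow cannot occur before the floor
  clamp engages.
- Auto-gain pivot via `np.partition` (O(N)); the saturation mask is applied
  as `value ≥ pivot` explicitly so the tie rule is exact under rounding.
- sRGB round trip is exact to ≤ 1e−9 across [0, 1]; endpoints exact.
- Readers scale uint8 by 1/255 and uint16 by 1/65535; mixed bit depths or
  dimensions across pages are errors, as are non-grayscale pages.
- File writes go through a sibling temp file and `os.replace`, so a failed
  write leaves no partial output.
- CLI errors exit nonzero with a one-line stderr message.

## Known limitations

- The additive baselines are faithful to their published *descriptions*
  (backlight colors, clamping, nonlinearity), not to unpublished code;
  quantitative comparisons against them characterize this reconstruction.
- β values are display-referred constants for one staining protocol; no
  spectral/hyperspectral rendering path is provided.
- No GPU implementation; the vectorized NumPy renderer targets
  reproducibility and testability, not video-rate display.
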