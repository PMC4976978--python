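# virtualhe

Virtual transillumination H&E rendering of epi-fluorescence microscopy.

Techniques like multiphoton and confocal microscopy can image thick,
unsectioned tissue in minutes, but pathologists read brightfield
hematoxylin-and-eosin (H&E) slides, not grayscale fluorescence. `virtualhe`
converts multichannel fluorescence images — a nuclear stain such as DAPI
(the fluorescent hematoxylin analog) plus eosin — into images that look like
transmitted-white-light H&E histology, by physically modeling how the real
dyes would absorb a backlight rather than by additively blending false
colors.

## The model

In a transillumination microscope, the Beer–Lambert law attenuates each
display color channel *M* exponentially in the path-integrated concentration
of every absorbing dye. Because fluorescence intensity is approximately
linear in fluorophore concentration, the virtual transmission is

```
T_M = ∏_i  max( exp(−β_{M,i} · I_i · k),  floor )
```

where `I_i ∈ [0, 1]` is the normalized fluorescence of dye *i*, `β_{M,i}` is
the dye's attenuation integrated over channel *M*'s spectral band (its
"color": eosin β = (0.050, 1.000, 0.544), hematoxylin β = (0.860, 1.000,
0.300) in sRGB), `k = 2.5` is a global scaling constant, and each
absorber's exponential is clamped at a transmission floor of 0.0075 so the
result fits a finite-contrast display. Transmissions are computed in linear
light; the standard sRGB transfer is applied last. Zero input renders a
perfect white point, overlapping absorbers multiply instead of clamping to
zero, and arbitrarily many dyes are supported.

The package also provides:

- the two **additive baselines** this model improves on (backlight minus
  weighted dye colors, with linear or power-law intensity transfer and the
  green-shifted backlight RGB (0.9, 1.0, 0.9)), reconstructed for
  quantitative dynamic-range comparisons;
- **auto-gain normalization**: each channel is rescaled so one pixel per
  100,000 reaches full scale, standardizing stain intensity across
  acquisitions;
- a seeded **synthetic tissue phantom** (elliptical nuclei, fibrous stroma,
  diffuse eosin haze, shot + read noise reduced by frame averaging) with
  ground-truth masks, so the whole pipeline is testable without a
  microscope;
- TIFF/PNG/JSON I/O and a `virtualhe` command-line interface
  (`render`, `phantom`, `compare`, `contrast-report`).

## Worked example

```python
import numpy as np
from virtualhe import (PhantomSpec, generate_phantom, normalize_frame,
                       render_beer_lambert, effective_contrast_ratio)

image, truth = generate_phantom(PhantomSpec(width=256, height=256, n_nuclei=25, seed=3))
image, gains = normalize_frame(image)
for g in gains:
    print(f"{g.channel}: gain {g.gain:.3f}, newly saturated "
          f"{g.n_saturated_after - g.n_saturated_before}")
rgb = render_beer_lambert(image)
print("mean sRGB in nuclei :", np.round(rgb.data[truth.nucleus_mask].mean(axis=0), 3))
print("mean sRGB in stroma :", np.round(rgb.data[truth.stroma_mask & ~truth.nucleus_mask].mean(axis=0), 3))
print(f"effective contrast ratio: {effective_contrast_ratio():.0f}:1")
```

prints

```
dapi: gain 1.084, newly saturated 1
eosin: gain 1.154, newly saturated 1
mean sRGB in nuclei : [0.425 0.242 0.596]
mean sRGB in stroma : [0.964 0.48  0.674]
effective contrast ratio: 1376:1
```

The auto-gain brings each channel's brightest pixel-per-100,000 to full
scale (here gains of 8–15%). Nuclei render blue-purple (blue transmitted,
green strongly absorbed) and stroma renders pink (red transmitted), exactly
the H&E appearance; the effective display contrast between an unstained
pixel and one with both dyes at the floor is ≈1376:1.

The same pipeline from the shell:

```sh
virtualhe phantom --seed 3 --width 256 --height 256 -o phantom.tif
virtualhe render phantom.tif -o virtual_he.png
virtualhe compare phantom.tif -o comparison/     # all three methods + report
virtualhe contrast-report
```

Every rendered output gets a JSON run log (inputs, config digest, gains)
written beside it.

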