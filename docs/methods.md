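# Methods

## The operator

Light-sheet fluorescence microscopy produces volumetric stacks whose
meaningful intensities span several orders of magnitude — far more than a
monitor or the eye resolves. The tone-mapping operator implemented here
compresses that range locally so that small dim objects and large bright
ones are visible in one view. For a 2-D plane `I` it computes

```
O = B_r( sqrt( s · I / (G_σ(I) + ε) ) )
```

where `G_σ` is a Gaussian blur, `B_r` subtracts a rolling-ball background
(gray-scale opening with a ball structuring element of XY radius `r`), `s`
is a display scale and `ε` a division guard. A single user parameter `p` —
the pixel size of the largest object of interest — sets `σ = 2p` and
`r = p`; both remain individually overridable.

The three stages act as: local gain control (division by the blurred self,
a pseudo flat-field that acts as a high-pass filter), non-linear range
compression (square root, i.e. gamma 0.5), and removal of the smooth
pedestal that the division leaves (rolling ball). The transform is
deliberately *not* intensity-linear: after processing, intensity must not be
interpreted quantitatively.

## Parameters

| parameter | unit | default | meaning |
|---|---|---|---|
| `p` | px | (required) | size of the largest object of interest |
| `sigma` | px | `2p` | blur width of the division image |
| `ball_radius` | px | `p` | XY radius of the rolling-ball element |
| `division_scale` | — | `"auto"` = 1e6 | multiplier after division |
| `epsilon` | intensity | `1e-6 ×` mean of blurred plane | division guard |
| `conv_min`, `conv_max` | intensity | −100, 10000 | 8/16-bit conversion window |
| `out_depth` | bit | 16 | output depth (32 = no conversion) |

Choosing `p` below the size of the largest object produces a characteristic
interior dip in that object (quantified by the edge-artifact index, the
ratio of the outer-band mean to the interior mean of a footprint); raising
`p` to the object size removes it.

## The division scale

The divided image `I/G` is O(1), so a multiplier is needed before the square
root to reach a useful display range. Two scales exist in the package:

- The **display scale** (default for `"auto"`, `1e6`): the post-division
  background sits near `sqrt(1e6) = 1000`, so outputs land in the thousands
  and the default conversion window (−100, 10000) is meaningful.
- The **measurement-anchored scale** (`calibrate_scale`): the scale at which
  the intensity-20 column of the disk phantom has unit mean amplification,
  solved iteratively on the noise-free phantom.

The distinction matters because the rolling-ball element has *fixed
curvature in intensity units*: the operator is only approximately
scale-homogeneous. At the display scale the ball's height (≤ `r`) is small
relative to the signal, the element acts nearly flat, and ratio summaries
become independent of `s` (verified at `s` and `4s`). At the
measurement-anchored scale (~10²) the ball curvature is comparable to the
signal and erodes large objects much more aggressively. Amplification
reports are therefore computed at the display scale and *normalized*
(below) rather than physically rescaled.

## The disk-grid phantom

The synthetic benchmark emulates a test image of 49 uniform disks: seven
intensities (5, 10, 20, 50, 100, 150, 250) left to right, seven diameters
(7, 9, 11, 15, 20, 25, 50 px) top to bottom, a constant background of 2,
Gaussian noise of SD 0.5, clipped to [0, 255]. The grid pitch is 70 px with
an 11 px margin (512×512 total); pitch and margin are layout choices — the
pitch must exceed the largest diameter and the blur couples neighbouring
cells, so amplification values depend mildly on it. Disk masks are exact
pixel-centre-in-circle footprints; measurements use the 1-px-eroded
footprint to avoid partial edge pixels (tiny disks fall back to the full
footprint, flagged).

**Amplification** of a disk is its processed footprint mean divided by its
input object intensity (input footprint mean minus the declared background:
the disks are defined by their intensity, the background is added on top).
Reported factors are normalized so the smallest-diameter disk of the
intensity-20 column has amplification 1; the normalization makes the report
invariant to the division scale. The headline summary is the fold-ratio
between the most-amplified (smallest/dimmest) and least-amplified
(largest/brightest) disks, ≈ 28–30 under the default conditions.

What the phantom does *not* emulate: point-spread blur of real optics,
tile shading, depth-dependent attenuation, autofluorescence, or any real
anatomy. Passing the phantom benchmark shows the operator's size- and
intensity-compression behaviour, not its performance on a specific sample.

Noise behaviour: the division amplifies noise in the faintest regions, and
after background subtraction the rectified noise floor biases dim-object
means upward (≈ +50% at intensity 5, ≈ +3% at 250, relative to a
noise-free run). The noisy phantom is the benchmark's defined condition;
per-disk factors are reproducible across noise seeds to a few percent.

## Stack pipeline

Stacks are addressed as (t, c, z) planes, 0-based, loaded on demand
(uncompressed TIFF series are memory-mapped). Each plane is processed
independently, so a thread pool of any size produces bitwise-identical
output; peak held image data is bounded by the worker count, not the stack.
Outputs follow `<stem>_t{TTT}_c{CC}_z{ZZZZ}.tif` (zero-padded), a folder
convention the reader can reconstitute exactly, erroring on gaps. The
optional HDF5 export writes the BigDataViewer layout (one setup per
channel, per-timepoint `cells` datasets at a single resolution level,
chunks of at most 64 per axis, unsigned 16-bit) with the XML sidecar
describing setups, voxel size and registrations. Per-plane statistics
(mean, max) are computed on the converted output — what a viewer sees.

## Numerical choices

- Gaussian blur: edge-replicated boundaries, kernel truncated at 4σ
  (σ = 2p is often large relative to a plane, so the boundary rule is part
  of the operator's definition).
- Rolling ball: exact gray-scale opening (erosion then dilation) with a
  hemisphere cap of XY radius `r`, without the shrink/interpolate
  approximation common in interactive implementations; exactness makes the
  primitive testable against a brute-force oracle. Note the top-hat
  residual is only approximately idempotent for a non-flat element
  (re-subtraction removes at most the ball height).
- Negatives are clamped to 0 before the square root (float round-off after
  division can produce tiny negatives).
- Auto-contrast bounds: the saturation allowance splits equally between the
  tails of a 256-bin histogram of the plane's range; constant planes return
  `(min, min+1)`.
- 8/16-bit conversion: linear map of (conv_min, conv_max) to the integer
  range with clipping and round-half-even; 32-bit output is untouched.
- Calibration (`calibrate_scale`) iterates the `s ← s/a²` update (exact
  under the √s pre-subtraction law) until the anchor column's amplification
  is within 0.5% of 1, on the noise-free phantom, so it is deterministic.

## Problem sizes

The test suite exercises oracles on ≤ 32×32 planes, pipeline behaviour on
stacks of a few dozen small planes, and the full 512×512 phantom at p=25
and p=50 for the benchmark claims; the complete suite runs in well under a
minute. The acceptance script processes one default phantom (a few
seconds).

## Known limitations

- The exact gray-scale opening is O(image × element area); radius-50 balls
  on 512×512 planes take ~10 s. Production-scale stacks rely on plane
  parallelism, not on a fast approximate opening.
- Reported amplification factors depend mildly on the phantom's grid
  geometry (pitch/margin), which couples disks through the blur; the
  defaults are part of the benchmark's definition.
- Only multi-page TIFF (and the per-plane folder convention) is read;
  proprietary microscope formats must be converted first.
- The HDF5 export writes a single resolution level; very large volumes
  would want a multiscale pyramid, which is out of scope.
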