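# Methods

## Segmentation model

The pipeline assumes neurons rendered by a cytoplasmic marker as two
morphological classes on a darker background: globular somata (here
~24–30 px across at the working magnification) and fibre-like neurites
(1–3 px wide). Greyscale opening with a disk whose radius lies between a
neurite half-width and a soma radius separates the classes exactly: the
opened image retains somata and background, the top-hat (original −
opened) retains fibres. Both branches are binarized with fixed, preset
thresholds and cleaned with a connected-component size filter that also
removes objects enclosed by larger ones (e.g. specks trapped inside
neurite loops), then the fibre mask is thinned to a one-pixel skeleton
(Zhang–Suen-class; any homotopy-preserving thinning is acceptable, and
per-algorithm skeleton pixel counts differ by at most a few percent).

Two conventions are fixed package-wide: strict `>` thresholding (which
makes all masks exactly invariant under joint positive rescaling of image
and thresholds — the formal basis for using one threshold across an
experiment regardless of staining intensity), and 8-connectivity for
foreground with 4-connectivity for holes.

### Endpoints and attachments operate on the pre-subtraction skeleton

The clean neurite image (skeleton minus soma overlap) is the *length*
image only. Endpoint detection runs on the full fibre skeleton: a neurite
attached to a soma continues into the cell body (the marker fills the
cell), so its root is not a terminal pixel there, and terminals that fall
inside the soma mask are discarded — leaving exactly the distal tips.
Attachment points are terminals of the fibre skeleton clipped to a
3-px dilation band around the somata, again minus the soma mask: one per
neurite-soma junction in the generic case. Running these steps on the
soma-subtracted skeleton instead would turn every root into a spurious
endpoint and split every junction into two proximal terminals; the
package deliberately does not do that, and `SegmentationResult` exposes
both skeletons so the distinction is auditable.

This construction has three inherent failure modes, preserved because
they are properties of the method, not bugs: a V-shaped double attachment
merges inside the band (undercounted as zero), an unattached neurite
crossing a soma exits the band twice (overcounted as two attachments,
with a gap in the length image), and interrupted fibre fragments
contribute free terminals that inflate the endpoint — and therefore the
deduced branch — count.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `soma_open_se` | disk, r = 8 | px | opening kernel; > neurite half-width, ≤ soma radius |
| `soma_threshold` | 1000 | intensity | binarization of the opened image |
| `neurite_threshold` | 300 | intensity | binarization of the top-hat |
| `soma_min_area` | 60 | px | soma debris floor (kept conservatively low) |
| `neurite_min_area` | 30 | px | fibre debris floor |
| `attachment_dilation_se` | disk, r = 3 | px | proximal band; bridges the 1–2 px soma seam without merging neighbours |
| `reference_soma_area` | 315 | px | user-defined typical cell-body area for neuron-count estimation |
| `ratio_length_floor` / `ratio_soma_floor` | 50 / 100 | px | below these, ratio statistics are flagged low-content |

The intensity thresholds are meaningful only relative to an image set's
amplitude; the defaults match the synthetic generator's photometry and
must be re-chosen (once) per real experiment. Branch count uses
endpoints − attachments, clamped at zero; the average individual-neurite
length divides total length by attachment count (primary neurites),
with an endpoint-count alternative behind `avg_neurite_denominator`.
Undefined ratios (zero denominators) propagate as NaN and are excluded —
and counted — by the condition aggregation rather than aborting a batch.
`mean_intensity` is the mean of the raw input over the whole field,
before any inversion. Dark-on-light input (e.g. silver-stained sections)
is handled by a plain intensity complement; no illumination correction is
attempted.

## Synthetic fields

`generate_field` renders somata as soft-edged disks (radius 12–15 px,
intensity ramp over 3.5 px) and neurites as anti-aliased tubes (width
2.2 px) along jittered polylines, additively composed over background
200 with soma amplitude 1600 and neurite amplitude 1000 on a 16-bit
1024×1024 canvas, followed by Gaussian blur (σ 0.8) and Gaussian noise
(σ 25). One integer seed drives all randomness; identical seeds give
bit-identical images and truth. Two geometry choices make the ground
truth meaningful rather than merely decorative:

* **Axis-biased headings.** Raw skeleton pixel count — the pipeline's
  length metric — undercounts Euclidean length by up to 29% on diagonal
  runs. Paths therefore follow compass base directions with bounded
  ±15° jitter, keeping the pixel-count/arc-length mismatch within a few
  percent; the residual ~2% shortfall comes from skeleton tip retraction
  (about half a tube width per end) and the soma-edge cut.
* **Disjoint territories.** Somata sit on a jittered grid and each
  neuron's arbor is confined to a territory that stays disjoint from its
  neighbours' even under maximal jitter, with sibling neurites in
  distinct compass cones and branches grown only into unused
  perpendicular cones. Clean fields therefore contain no crossings, and
  tip/attachment/junction counts are exactly recoverable — which is what
  makes exact-count acceptance checks possible at all.

Soma radii are drawn so the full-intensity core stays larger than the
opening kernel; smaller somata would be gutted by the opening and their
rims would flood the top-hat (a real phenomenon the pipeline shares with
any opening-based detector, but one that would make ground-truth
bookkeeping meaningless).

`overlap` fields deliberately add unattached soma-crossing neurites and
fragmented (interrupted) neurites to exercise the failure modes in their
documented directions; `debris` fields sprinkle sub-size bright specks
from a dedicated RNG stream, so a debris field is bit-identical to its
clean twin outside the specks.

Budget mode (`total_length_target`) allocates unbranched primary-neurite
length targets round-robin across neurons until the requested total
outside-soma arc length is spent; achieved totals land within ~±5 px of
the request, which is what lets the two-condition screen emulator realize
prescribed N(μ, σ) well distributions faithfully (undifferentiated
N(800, 133.3) vs differentiated N(2400, 133.3) px per well — closed-form
Z exactly 0.5).

### What the generator does not emulate

No PSF beyond Gaussian blur, no uneven illumination or vignetting, no
fasciculation, no glia/soma texture, no cell-density-dependent background.
Passing the recovery tests therefore demonstrates that the algorithm and
its implementation are correct under the stated image model, not that any
particular threshold pair will work on a given microscope's output; on
real data the thresholds, the reference soma size and the opening radius
must be set per experiment, and ratio statistics should be read alongside
the primary measurements via the review browser.

## Numerical and design choices

* Subtraction clamps at zero (no wraparound); all arithmetic before
  thresholding is float64, so joint rescaling by 0.5/1.5/2 is exact.
* Lengths are raw pixel counts (no diagonal correction), matching the
  skeleton-pixel definition of total neurite length.
* `soma_count` is the number of 8-connected soma components; the
  area-based neuron estimate is reported separately and never silently
  substituted. Cluster size is the mean component area.
* The size filter applies to both the soma and neurite masks (separate
  floors); degenerate inputs (blank fields, empty masks) yield zeros, not
  errors.
* Batch row order is fixed by (plate, well, field, channel) sorting and
  no output embeds a timestamp, so whole runs — tables, heatmaps, audit
  tables, HTML — are byte-reproducible.
* Heatmap normalization maps 0/mean/2×mean to 0/128/255 per channel,
  with the plate mean taken over annotated wells only (so sentinel wells
  do not crush the dynamic range; falls back to all wells when nothing
  is annotated); an audit table stores every raw and normalized value
  behind every rendered pixel.
* The browser is plain static HTML with inline-SVG scatter tooltips —
  self-contained, relative links only, no scripts or server.
* The screen-level Z-factor check averages three 16-well plates: a
  single plate's sample Z has sd ≈ 0.09 from the n = 8 sd estimates
  alone, so a mean over three plates is the smallest design whose
  sampling noise is comfortably below the scientific effect being
  verified.

## Problem sizes

Default test and acceptance workloads use 1024×1024 fields (50 clean
fields for recovery; three 16-well plates for the screen), with 256–448 px
canvases for plumbing tests; one 1024² field segments in well under a
second on a single CPU.

## Known limitations

Fasciculated bundles are measured as single structures; neurites are not
tracked across soma footprints; per-cell arbor statistics are out of
scope by design (per-field aggregation is the point); branch counts are
only as good as soma/neurite detection — fields with little content are
flagged rather than trusted.
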