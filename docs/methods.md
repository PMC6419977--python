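# Methods

This note records the analysis model, the numerical choices made where
the procedure was genuinely open, what the synthetic generator does and
does not emulate, and the known limitations. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Pipeline model

Input is a bi- or tri-channel TIFF; intensities are normalised to
[0, 1] by the dtype's full range on load (never per-image min/max —
per-image contrast handling belongs to the segmentation stages, so that
loading is information-preserving and reversible). Channel indices are
1-based (1=red, 2=green, 3=blue), matching the published command-line
convention; defaults are channel 2 for the cytoskeletal marker and
channel 3 for DAPI.

### Myotube segmentation

1. *Illumination flattening.* The channel is divided by a Gaussian
   background estimate with σ = 4 × `MaxCircleRad` (160 px at defaults)
   and rescaled to [0, 1]. The σ is chosen an order of magnitude above
   any nucleus so structures survive while slow shading is removed;
   division (rather than subtraction) makes multiplicative vignetting
   exactly flat, which is why the generator's shading model is
   multiplicative too. The divisor is floored at 1% of the image peak
   to avoid blow-up in fully dark regions; an all-zero image passes
   through unchanged.
2. *Thresholding.* Foreground is `pixel > TubeThresh x T_auto`, with
   `T_auto` the global between-class-variance (Otsu) threshold. The
   scale-on-automatic-threshold reading gives `TubeThresh` its
   documented behaviour (lower ⇒ fainter staining detected) while
   keeping the base threshold parameter-free; lowering `TubeThresh`
   always produces a superset of foreground (tested property).
3. *Fill and smooth.* Holes are filled, then morphological closing and
   opening with a disc of radius `FillSize` (closing first, so gaps are
   bridged before protrusions are shaved; holes are re-filled between
   the two so closing-created cavities cannot survive).
4. *Size floor.* 8-connected components with area strictly below
   `SmallestMyotubePixelCount` are deleted — a component of exactly the
   floor survives. The strict reading of "below the threshold size" is
   pinned by boundary tests with engineered 499 px and 500 px
   components.

### Nucleus detection

1. *Denoising.* A 5×5 adaptive Wiener filter (window chosen as the
   smallest neighbourhood that still estimates a stable local variance
   at the 15 px minimum nuclear radius). The image is reflect-padded
   first so the filter's zero-padding cannot darken borders; flat
   regions pass through unchanged.
2. *Binarise and clean.* Otsu threshold, then fill/close/open with a
   disc of radius `NucFillSize`, then both size gates: area ≥
   `SmallestNucleusPixelCount` and area ≤ H·W/`MaxNucSizeDivisor`. Both
   bounds are inclusive — a blob of exactly 1% of the image survives;
   only *larger* blobs are discarded (strict reading of "larger than
   1%", pinned by a 9,900/10,000/10,100 px sweep on a 1000×1000 field).
3. *Circle Hough.* The accumulator is computed over integer radii
   `[MinCircleRad, MaxCircleRad]` on the cleaned mask's 1 px inner edge
   map, normalised by each radius's perimeter so a peak value is the
   fraction of the circle present. Peaks ≥ 0.5 are candidates; greedy
   non-maximum suppression (strongest vote first, ties broken
   row-major) forbids two accepted centres closer than `MinCircleRad`,
   and a centre falling outside the mask is rejected. The 0.5 fraction
   is deliberately conservative: digitisation and noise smear a true
   circle's votes across adjacent radius planes (measured per-plane
   peaks for noisy discs sit near 0.5–0.9), and a lower threshold would
   admit crescent-shaped false positives. Nuclei the Hough stage misses
   are not lost — they fall through to the watershed.
4. *Erase and watershed.* Pixels within each detected circle, plus a
   2 px margin, are erased. The margin absorbs the integer quantisation
   of the radius estimate: without it, a 1–2 px annulus of a large
   nucleus can survive, exceed the nucleus size floor, and be counted
   twice. The remaining regions are split by watershed on the inverted
   Euclidean distance transform, with markers at distance maxima;
   maxima closer than `MinCircleRad` are merged into one marker (minima
   imposition via `peak_local_max` min-distance), so one convex nucleus
   cannot be split twice. Fragments below the nucleus size floor are
   discarded. A fragment centroid that falls outside its own pixels
   (possible for crescents) is snapped to the nearest fragment pixel so
   every reported centre lies inside the nuclear mask.

Detections are merged into one set (Hough detections carry a radius,
watershed fragments an area), sorted row-major, with coinciding centres
collapsed. The whole pipeline is deterministic: identical input and
parameters give identical output.

### Fusion analysis

A nucleus belongs to the tube component containing its centre point —
centre containment rather than pixel-overlap fraction, because it is
unambiguous and assigns each nucleus to exactly one structure.
Structures with fewer than `MinNuclei` nuclei are flagged as myoblasts
and excluded. Reported per image: total nuclei, nuclei in any
cytoskeleton-positive structure, nuclei in retained structures,
retained structure area (px), and NFI. The NFI numerator is the
*retained*-structure count, consistent with excluding myoblasts before
analysis; the raw in-any-structure count is reported alongside so the
alternative index can be recomputed. An image with no nuclei reports
NFI = 0 by convention. An optional µm-per-pixel scale adds the retained
area in µm² (= px × scale²); no image metadata is read for this.

## Parameters

| CLI name | default | unit | role |
|---|---|---|---|
| SmallestMyotubePixelCount | 500 | px | myotube area floor (strict <) |
| SmallestNucleusPixelCount | 300 | px | nucleus area floor (strict <) |
| MyotubeChannel | 2 | 1-based index | cytoskeletal channel (green) |
| NucChannel | 3 | 1-based index | DAPI channel (blue) |
| FillSize | 10 | px | disc radius for tube smoothing |
| NucFillSize | 5 | px | disc radius for nucleus smoothing |
| MinCircleRad | 15 | px | lower nuclear radius bound |
| MaxCircleRad | 40 | px | upper nuclear radius bound |
| TubeThresh | 1.0 | — | scale on the automatic tube threshold |
| MinNuclei | 3 | count | myoblast-exclusion floor |
| MaxNucSizeDivisor | 100 | — | discard nuclei > image/n |

Defaults target 20× images; the radius bounds and size divisor are the
knobs to adjust for other magnifications.

## Synthetic generator

`make_culture` emulates the input domain: myotubes as thick capsule
strokes (stroke radius 16–26 px, surviving default smoothing),
myoblasts as compact 700–1,900 px ellipses (above the tube area floor,
so only the nucleus count excludes them — isolating the `MinNuclei`
rule), nuclei as anti-aliased discs with radii in [15, 25] (inside the
default Hough prior), additive Gaussian noise (default σ = 0.02, a
high-SNR stained culture), optional multiplicative linear shading
(0.65→1.0), and everything reproducible from one seed with exact ground
truth (centres, radii, per-structure membership). Touching disc pairs
(centre distance 0.8 × the radius sum) exercise clump splitting.
In-tube nuclei are spread evenly along the tube axis rather than
rejection-sampled, so placement succeeds for any seed when the
geometry allows it at all.

It does **not** emulate point-spread blur, chromatic aberration,
pyknotic/apoptotic intensity variation, out-of-focus nuclei, or
overlapping myotubes. A green recovery test therefore establishes that
the algorithm is implemented correctly on well-formed fields, not that
it matches human raters on real micrographs — that comparison requires
real validation images and is out of scope here.

`make_boundary_case` controls *post-smoothing* pixel areas exactly:
morphological smoothing changes pixel counts, so the generator searches
a family of thick bent strokes (a digital path dilated by a disc whose
radius equals the smoothing radius, making opening exactly the identity
on it), measuring every candidate through the real `fill_and_smooth`
until the smoothed area equals the target to the pixel. Far from the
bends, each extra horizontal path step adds exactly one stroke column
(2ρ+1 px); the bend-step counts sweep the remaining residue classes.
Solutions are memoised (and re-verified by measurement on use, so a
stale memo falls back to search). Very large targets use a
proportionally thicker stroke so the shape fits a modest field.

## Numerical choices and degenerate inputs

- 8-connectivity for all component analysis.
- Constant (blank) channels: Otsu is undefined, so binarisation
  returns an empty mask instead of raising; downstream stages handle
  empty masks and report zeros.
- Hough tie-breaks: candidates sorted by (−vote, row, col, radius)
  before suppression, so ordering is platform-independent.
- Detection ordering is canonicalised row-major; duplicate centres are
  collapsed (first detection wins, which after sorting is
  deterministic).
- Batch mode processes `*.tif`/`*.tiff` non-recursively in
  lexicographic order; a failing image is logged and skipped, the exit
  status reflects whether any image failed, and two inputs with the
  same stem get numeric collision suffixes on their outputs.
- Output images are 8-bit RGB PNG (lossless, universally viewable);
  the summary text file is stable `key: value` lines.

## Known limitations

- Touching myotubes are segmented as one component; per-myotube size
  distributions are not reported.
- Non-circular (elongated, mitotic) nuclei rely entirely on the
  watershed path; strongly concave nuclei can in principle be split.
- The 0.5 Hough acceptance fraction means noisy-but-round nuclei are
  often claimed by the watershed stage instead — counts are unaffected,
  but the per-detection provenance tag is not a reliable roundness
  classifier.
- Physical-unit areas require a user-supplied µm-per-pixel factor;
  embedded TIFF scale metadata is ignored.
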