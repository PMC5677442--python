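# Methods

## The detection model

A pre-existing termite mound presents two co-located material signatures in
VNIR imagery: an eroded-soil core with near-zero vegetation, and a collar
of bright grass at the core's outer boundary. The pipeline detects mounds
as *pairs* of classified regions satisfying shape and proximity
constraints, never from a single material signature — field spectra showed
no single material that isolates mounds from the surrounding bush and
grass.

### Radiometric preparation

Cubes are radiance, `(rows, cols, bands)`, with a strictly increasing
wavelength axis. Pre-cleaning is one grayscale morphological closing per
band with a 3×3 rectangle (extensive and idempotent; fills dark speckle).
Reflectance is the plain per-band ratio to a constant white-reference
spectrum, linearly interpolated onto the cube's wavelength axis
(extrapolation refused), clipped to a ceiling of 2.0 (configurable) so
specular or mis-calibrated pixels cannot dominate classification. No
dark-current subtraction is modelled: the reflectance model is
ratio-to-white, which the synthetic illuminant inverts exactly.

### Material library and classification

Deterministic annealing (mass-constrained, squared-Euclidean) clusters a
demonstrative reflectance scene into at most 10 materials. Distances are
*mean squared difference per band*, which places the configured
temperatures (t_max 0.02 → t_min 0.00025, cooling 0.8) on the scale of
squared reflectance contrasts: two materials whose spectra differ by ~0.15
over a third of the bands have a critical temperature near 0.01, inside
the schedule, while pixel noise of sd 0.01 has a critical temperature
below t_min and therefore never splits a cluster. A cluster splits
(centroid duplicated with a seeded 1e-4 perturbation) when
`T < split_threshold × 2λ_max/B` with λ_max the dominant eigenvalue of its
weighted covariance. The per-pixel association count is capped at
`max_materials_per_pixel = 5` by truncating the Gibbs posteriors.
Unseparated duplicates are merged at the end (RMS distance < 1e-3) and
empty clusters dropped. Pixels beyond 4000 are subsampled (seeded).

Classification is a hard-label, one-vs-rest **linear SVM** (C = 1.0) over
per-band-standardized spectra. The library supplies one signature per
material; training uses that signature plus 200 multiplicative Gaussian
jitters (sd 0.02) of it per class. Linear margins suffice because the
library spectra are smooth and well separated; every unperturbed library
signature classifies to its own label. The detection stage consumes only
the binary *Eroded Soil* and *Light Grass* presence masks.

### Contour extraction and shape matching

Soil conditioning is a 3×3 median then one 3×3 binary closing; grass
conditioning is median only (the asymmetry is deliberate — the grass
branch of the procedure lists no closing). The overlap gate computes
`T2 = grass AND dilate²(soil)` with the 3×3 cross ("3×3 ellipse")
structuring element and rejects the ROI if T2's mean is zero.

Contours are the outer borders of 8-connected components, traced by
Moore-neighbour border following from the first pixel in raster-scan
order (holes ignored; components with < 3 boundary points dropped).
Per contour:

* **area**: Green's theorem (shoelace) on the boundary polygon through
  pixel centres — a filled h×w rectangle scores (h−1)(w−1);
* **perimeter**: closed polygonal arc length;
* **centroid and Hu invariants**: raster moments of the filled component
  (unit mass per pixel), raw → central → normalized → the 7 Hu invariants;
* **rad**: minimum enclosing circle radius of the boundary points
  (shapely), floored at 0.5 px for degenerate point sets.

Hu vectors are compared in signed-log space, `m_i = sign(h_i)·log10|h_i|`;
terms with `|h_i| < 1e-30` are *absent* and excluded from
`ratio = Σ |1/m_i^S − 1/m_i^T|` for either shape (all-absent pairs raise
an error). For centred symmetric shapes several h_i are true zeros, so
exclusion — not a floor substitution — is the only reading that keeps the
ratio finite and discriminative. The template ratio is the minimum over
the whole template set and the arg-min template is recorded.

Thresholds (defaults): keep a soil contour iff `ratio ≤ 0.15` and
`P_sc ≥ 10 px`; pair it with a grass contour iff centroid distance
`d ≤ 1.2·rad`, `P_gc ≥ P_sc` **or** `P_gc/P_sc ≥ 0.8` (the first implies
the second at the default; both are evaluated), and point-set minimum
distance `ILD ≤ 2.5 px`. Thresholds are raster-space pixels and are not
rescaled by GSD. A soil contour with several qualifying grass partners
yields one detection listing all of them, reporting the nearest partner's
d/ILD/proportion.

### Evaluation

Greedy one-to-one matching by ascending centroid distance; the per-mound
distance budget defaults to 1.5× that mound's core major axis (visual
co-location without overlap computation). Matched mound → TP, unmatched
mound → FN, unmatched detection → FP; `accuracy = TP/(TP+FN+FP)` per ROI
and on pooled counts (the pooled value is not the mean of per-ROI values).
Percentages are reported to one decimal.

## The synthetic world

`default_spectra` builds 10 smooth signatures over 385–1000 nm whose
contrast concentrates in three windows (540–700, 720–800, 924–1000 nm,
Gaussian bumps of material-specific amplitude) with only small flat
offsets elsewhere — the empirical structure of vegetation/soil spectra in
this landscape. `generate_scene` paints mound cores (default semi-axes
17×13 px: the mean field mound bounding rectangle of 1.951 m² at the
survey GSD of 4.7 cm/px) with a 3-px grass collar broken by one 25° gap
(field collars are rarely closed; an open collar also reaches the core on
its inner contour edge, as real patchy collars do). Backgrounds are
seeded-Voronoi patches of the remaining 8 materials. Reflectance becomes
radiance through a smooth synthetic illuminant, then Gaussian blur
(default sd 0.5 px), optional sinusoidal spatial distortion (amplitude in
px, wavelength 48 px, applied to the material index map with
nearest-neighbour resampling), and per-pixel Gaussian noise (default sd
0.01 in reflectance units). Everything is reproducible from the scene
seed.

What a green synthetic test does **not** establish: performance on real
orthorectified flight lines (no deposited imagery), robustness to
illumination drift (the illuminant is constant by design), mixed-pixel
effects at coarse GSD, or the adequacy of the template library for mound
shapes outside the oval/diamond family.

## Numerical and design choices

* Threshold directions in the published procedure listing are typeset
  ambiguously ("if ratio≤0.15 Psc≥10 then Discard"); the prose is
  unambiguous that *low* ratio means a close match, so contours are
  **kept** under those conditions.
* "rad" is read as the minimum enclosing circle radius — the only scale
  measure for which `d ≤ 1.2·rad` captures a surrounding collar; "ILD" as
  the minimum point-pair distance between contours; the "3×3 ellipse" as
  the 4-connected cross; "double dilation" as two iterations.
* Binary closing uses border values (dilate with 0, erode with 1) that
  leave frame-touching objects intact.
* ENVI support: BIL/BIP/BSQ, little-endian data types {1,2,3,4,5,12,13};
  0-based half-open ROI windows.
* Cluster libraries are ordered by decreasing mean reflectance and named
  `Material NN`; pipeline layer names come from a curated library CSV.
* Test suites and the acceptance script run at 24–64 bands and 192×192 px
  rather than the sensor's 274 bands and full flight lines: runtime
  scaling only — each discriminative spectral window is still sampled by
  several bands.

## Known limitations

* The soil-conditioning operator (3×3 median then closing) is **not
  idempotent**: a 2-D median filter has no one-pass fixed point, so a
  second conditioning pass can still move a few boundary pixels (tens of
  pixels on a 192² raster) and rounds the corners of solid rectangles.
  The operator is kept exactly as specified; the idempotence check in the
  acceptance suite fails by design and documents this.
* Deterministic-annealing details beyond the printed parameters
  (distortion measure, split test) follow the standard squared-Euclidean
  formulation; other readings of the split criterion are possible.
* The greedy evaluation matcher is a proxy for visual matching; it can
  differ from a human count when detections fall between adjacent mounds.
* Linear spectral unmixing and PCA classification are deliberately not
  implemented (evaluated and rejected upstream), nor is threshold learning.
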