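# Methods

This note records the models, conventions and numerical choices behind
`gliaclone`, in the order the pipeline applies them.

## Clone decoding

Cells are partitioned by **exact bitwise equality** of their 12-component
color code (6 fluorescent proteins × nuclear/cytoplasmic localization;
2¹² = 4096 combinations). No partial-match tolerance is applied: codes are
treated as discrete heritable identities, and decoding from raw
fluorescence intensities (channel unmixing) is out of scope — the pipeline
starts from discretized codes. Groups smaller than `min_clone_size`
(default 3, the smallest clone size the analysis retains; configurable down
to 1) are returned as *unassigned*, never silently dropped, and an
all-false code is an error naming the offending cell, since unlabelled
cells must be excluded upstream.

Clone descriptors follow directly: the **dispersion pattern** is the exact
set of region labels occupied by members (vocabulary fixed to
{St, CC, L-Cx, U-Cx, Pia}; mapping atlas coordinates to labels is the
caller's responsibility); **pattern frequencies** are counts over total
clones, sorted by descending frequency with a lexicographic tie-break; the
**rostro-caudal extent** is `(max section − min section) × thickness`
(50 µm default), so a single-section clone has extent 0 — the alternative
`(span + 1) × thickness` convention is *not* used. No spatial-plausibility
constraint is applied to code-identical cells in disjoint locations; the
cohort tables retain per-clone spatial spreads so such cases remain
visible as diagnostics.

## Lesion rings and distances

The lesion core is a per-section 2D polygon. The four concentric
perimeters are **true Euclidean buffers** (Minkowski dilation by a disc) at
50/100/150/200 µm, discretized at 64 segments per quarter circle
(boundary error < 0.1 µm at 200 µm offset). An ROI-*scaling* mode is
available behind `mode="scale"` for comparison with workflows that enlarge
a region by scaling about its centroid, but buffering is the default and
the documented behaviour: buffered boundaries lie at constant distance
from the core, which is what makes ring membership consistent with
point-to-boundary distances.

Distance is measured to the **core boundary**, not the centroid, and is 0
inside the core. Cells are compared only against lesions on their own
section (matching a per-slice workflow); with several lesions the minimum
distance governs. Ring membership uses half-open intervals
`(lower, upper]`, and the 200 µm inner/outer threshold is **inclusive**:
a clone is *inner* iff any member's distance is ≤ 200 µm. Cells on
sections without a lesion receive NaN distance and the label `outside`.
The inner-vs-outer clone-size comparison is a two-tailed unpaired t-test,
pooled-variance by default with a Welch option (`equal_var=False`), since
which variant the original workflow used is not documented.

## Morphometry

Skeletons follow SWC semantics (id, type, x, y, z, radius, parent; type 1
= soma; radii and coordinates in µm). Rendering sweeps each
parent→child segment as a **conical frustum without spherical end caps**
(so a straight cylinder renders at its analytic volume) and stamps soma
nodes as spheres; occupied voxels are accumulated sparsely, so memory
scales with cell volume, not bounding box. Defaults: 0.2 µm pixels for
silhouettes and 0.2 µm voxels for volumes.

- **Cell body area / volume**: occupied pixel/voxel count × pixel²/voxel³
  of the rendered projection / z-series.
- **Domain area / volume**: convex hull over the *corners* of occupied
  pixels/voxels. Using corners (rather than centers) guarantees
  `A_cb ≤ A_hull` and `V_cb ≤ V_hull` under any discretization, because
  the hull then contains every occupied pixel/voxel outright.
- **Perimeter**: marching-squares contours simplified with a
  Douglas-Peucker tolerance of one pixel. Raw marching-squares stair-steps
  overestimate smooth boundaries by ~5–10% while Crofton-style estimators
  misjudge true corners; the simplified contour keeps a digital disc
  within ~1% of 2πr *and* a digital square within ~1% of 4s.
- **Circularity** is 4πA/P² (the standard image-analysis definition,
  1 for a perfect circle). A bare area/perimeter ratio is dimensionally
  inconsistent with a unit value for circles, so the normalized form is
  used.
- **Solidity** is A_cb/A_hull ∈ (0, 1], with "cell body area" read as the
  whole filled-cell silhouette, not the soma alone — otherwise solidity
  could exceed 1 and would not measure hull filling.
- **Branch count** is the number of maximal unbranched paths delimited by
  the soma, branch points and tips: one unbranched process counts 1, a
  single bifurcation gives 3 (primary + two daughters), a binary tree with
  k tips gives 2k − 1.
- **Total thickness** sums conical-frustum volumes
  πL(r₁² + r₁r₂ + r₂²)/3 over process segments whose mean radius is at or
  above the minimum-radius threshold (default 0.05, interpreted as µm —
  the only reading under which it filters branch volume); soma-internal
  segments are excluded. It is monotone non-increasing in the threshold.
- **Sholl analysis** uses concentric *spheres* (3D) at 4 µm spacing
  centred on the soma centroid, with a 2D circles-on-projection mode
  behind a flag. A segment crosses the shell of radius r when one endpoint
  is at distance < r and the other ≥ r — an endpoint exactly on the shell
  counts as crossed. This endpoint rule equals the dense path-sampling
  count whenever distance from the center is monotone along each segment,
  which holds for outward-growing processes; a segment that dipped inside
  a shell and back out would count as zero net crossings. Total
  intersections, the ending radius (largest shell still crossed) and total
  branch length (summed segment length) come from the same profile.

Scaling a skeleton (and grid) by s scales lengths by s, areas by s², and
volumes by s³, leaving circularity and solidity invariant; this is covered
by tests at s ∈ {0.5, 2}.

## Phenotype classification and statistics

A cell's **primary-branch thickness** is the mean node radius along each
primary branch (the maximal unbranched path from a soma child), averaged
across primary branches; a max-across-branches variant sits behind
`method="max"`. The type II call is `thickness ≥ threshold`; the source
analysis gives no numeric cutoff, so the threshold is an explicit
configuration value (default 0.5 µm, midway between the synthetic
regimes) and is recorded with every call. Clones are typed type I /
type II when homogeneous, *mixed* otherwise.

Group comparisons against sham use one-way ANOVA followed by **Dunnett's
post hoc test** (two-sided, multivariate-t critical values via
`scipy.stats.dunnett` with a fixed integration rng so outputs reproduce
byte-identically), starred at 0.05/0.01/0.001. Parameters where any group
has n < 2 are skipped with a logged reason. Note that Dunnett calibrates
the *family-wise* error: under the null at n = 6/6/4 the family-wise
rejection rate is ≈ 0.05 while each individual adjusted comparison rejects
less often (≈ 0.02–0.03) — the calibration tests assert the family-wise
quantity, which is what the procedure controls.

## The synthetic cohort generator

The generator is first-class code that emulates the *statistical*
structure the analysis assumes; it does not simulate optics (PSF,
crosstalk, bleed-through) or immunostaining signal. Defaults encode the
study conditions:

- **Clone sizes**: discretized log-normal truncated to [3, 80] with the
  log-mean calibrated numerically so the truncated mean is exactly 17
  cells (σ_log = 0.75 for a realistic right skew); only the range and mean
  are externally constrained, the log-normal shape is this package's
  choice.
- **Codes**: sampled without replacement from the 4096-code space with the
  all-zero code ordered last, so it is used only if all 4096 codes are
  requested (an all-zero "clone" is unlabelled and undecodable; capacity
  checks still count the full 2¹² space). A `collision_rate` lets clones
  reuse earlier codes to probe decoding degradation; the default is 0, as
  are code dropout/mis-assignment rates, since no detection-noise rates
  are documented for this kind of data.
- **Dispersion patterns**: ten patterns with L-Cx-only at 58%, CC+L-Cx at
  13% and CC-only at 8% (the dominant observed frequencies); the remaining
  21% is spread over seven further plausible patterns, none pia-only.
- **Inner/outer structure**: each clone is inner with probability 0.6;
  inner clones are anchored with one cell at ≤ 180 µm from the core (25%
  of anchors inside the core), outer clones are kept strictly beyond
  250 µm. Larger sizes are steered towards inner clones by rank-coupling
  (coupling 0.4) *without changing the marginal size distribution*, so
  inner clones average more cells, as observed.
- **Sections**: z = section × 50 µm (0-based); the number of occupied
  sections grows binomially with clone size (spread 0.12/cell), producing
  the observed positive size–extent association, with an optional hard
  cap on extent.
- **Cell types**: P(type II) is 0.8 within 150 µm of a core and 0.1
  beyond, seeding the near-lesion hypertrophic concentration.
- **Skeletons**: trees grow outward in ~2 µm steps with angular jitter,
  an outward bias, and a per-µm branching probability. Regime defaults
  (sham / type I / type II): mean branch radius 0.25 / 0.35 / 0.8 µm,
  branching 0.010 / 0.016 / 0.020 µm⁻¹, radial extent 40 / 50 / 55 µm,
  3–5 / 4–6 / 6–9 primaries. The radii are invented values chosen only to
  make the regimes separable; branching rates were chosen so branch counts
  (≈ 14 / 33 / 70) and total cable (≈ 0.4 / 0.8 / 2 mm) sit in a realistic
  range for quiescent vs reactive NG2-glia. All are configuration values.

All randomness flows from one integer seed through numpy's seed-sequence
spawning, so cohorts, skeletons and the full pipeline are reproducible
byte-for-byte.

**What passing tests do and do not show.** The generator realizes the
assumed structure exactly (exact code identity within clones, circular
lesion cores, Gaussian in-plane scatter, two cleanly separated
morphological regimes); real data add code mis-detection, irregular lesion
shapes, section-registration error and a morphological continuum. Green
tests therefore validate the *computations* — decoding, geometry,
morphometry, statistics — under the stated assumptions, not the biological
conclusions drawn from any particular imaging dataset.

## Problem sizes and degenerate inputs

The bundled pipeline demo simulates 10 clones and skeletonizes up to 60
cells (whole clones kept together) plus 6 sham cells; the acceptance
script uses 48–500-clone cohorts, 1000-point distance oracles, 100 random
trees for the Sholl oracle, and 1000/200 Monte-Carlo replicates for the
statistical calibration — sizes chosen to keep a full run in the minutes
range on one CPU while leaving Monte-Carlo noise well inside the asserted
bands. Degenerate inputs fail loudly: empty silhouettes, collinear/
coplanar hull input, cyclic or orphaned SWC nodes (with line numbers),
self-intersecting lesion polygons, duplicate cell ids, all-false codes.
A voxel size exceeding the smallest node radius warns that thin branches
may vanish from the rendering.

## Known limitations

- Lesion distances are per-section 2D; cross-section 3D distance is out
  of scope by design.
- The 2D silhouette sweeps discs along projected segments, which adds
  rounded end caps relative to the exact projection of a tilted frustum;
  the bias is far below the discretization tolerance at default pixel
  sizes but is not exactly zero.
- The binary type I/II split does not model the graded continuum of
  reactive morphologies; mixed clones are the only intermediate notion.
- ImageJ-style ROI "enlarge" may not be a true Euclidean buffer in all
  implementations; the scaling mode exists for comparison but equivalence
  is only exact for circles.
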