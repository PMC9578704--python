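# Methods

`gutlapse` re-implements, as a tested library, the image-analysis and
lineage-dynamics computations used to study intestinal stem cell (ISC)
behavior in long-term *Drosophila* midgut explant time-lapse movies:
local drift registration, per-cell fluorescence and morphology
quantification, lineage-tree reconstruction, sibling-pair classification
and kinematics, and the associated statistics. Because raw movies are not
part of the package, a first-class synthetic-data module generates
lineages and movies with the statistical structure the analysis assumes,
so that every downstream stage can be verified against a known ground
truth.

## The lineage simulator

The generator is a forward agent-based model on a 2D epithelial plane
with small z jitter (the epithelium is pseudostratified, so nuclei sit at
different heights; distances and angles are therefore 3D).

**Division.** Each proliferative cell draws a cycle time from a normal
distribution (default mean 8 h, SD 2.76 h — the moments reported for
genetically stimulated progenitors), floored at one frame. Only the first
two moments of the cycle-time distribution are constrained by
observation, so a truncated normal is the least-committal choice. A
cell's last observed frame is its division frame; its two daughters
appear the following frame, 2.5 µm on either side of the mother (the
mitotic frame itself is unscorable in nuclear-GFP movies because the
nuclear envelope breaks down). With probability `p_symmetric` (default
0.3, matching roughly 8 of 25 classified sibling pairs) both daughters
are proliferative and receive opposed directional velocities of magnitude
`separation_speed` (default 1.5 µm/frame) for five frames — the window
over which sibling kinematics are analyzed. Otherwise one daughter is
proliferative and the other quiescent: it random-walks, doubles its
nuclear area over 48 h (`differentiation_area_growth`), and loses GFP
with a 24 h half-life, emulating enteroblast-to-enterocyte
differentiation.

**Motility.** All cells take isotropic Gaussian steps with mean length
`motility_step_mean` per frame. No motility magnitude is reported for the
real tissue, so the default is set by the constraint the observations do
impose: non-co-dividing sisters stay close (a flat internuclear-distance
curve over the first 5 h) while co-dividing sisters separate by ~8–15 µm.
Under pure diffusion the sister-sister distance is a submartingale with
upward drift ≈ σ²t/(2·d₀); the defaults (step 0.2 µm/frame, z jitter
0.15 µm, newborn separation 5 µm) keep that drift an order of magnitude
below sampling noise at the ensemble sizes used, so the asymmetric-pair
curve is flat as observed. Walls reflect; the field defaults to
200 × 200 µm.

**Volume exclusion.** Nuclei are solid bodies: a hard-core constraint
keeps nuclear centers at least 3.5 µm apart (three relaxation sweeps per
frame, symmetric push along the 3D separation axis). Besides realism,
this is what makes lineage reconstruction from positions well-posed at
realistic clone densities — without it the model lets two mothers divide
1 µm apart, a configuration no positional linker (and no real tissue)
could produce.

**GFP dynamics.** Each cell samples a transgene-induction onset uniformly
in `gfp_onset_range` (default 8–36 h, the reported span between the first
detectable cells and full-population expression), clipped from above by
its mother's onset because induction is monotone within a lineage. GFP
rises linearly to plateau over 4 h, then dims by `bleach_rate` per imaged
frame (photobleaching); quiescent daughters decay additionally as above.

**Rendering.** `render_movie` rasterizes nuclei as anisotropic Gaussian
blobs (xy sigma = half the nuclear radius, z sigma doubled — the simplest
point-spread model adequate for registration and segmentation tests) into
a (t, z, channel, y, x) stack: channel 0 is GFP-weighted, channel 1 a
constant-amplitude nuclear stain. A per-frame global drift stored in the
scene is added before rasterization; Poisson noise with a chosen
background mean is optional. Default geometry follows the imaging setup
the analysis targets: 3 µm z-steps through a 45 µm stack, one frame per
hour.

**What the generator does not emulate** — and hence what passing tests do
not show about real movies: segmentation error and tracking mistakes
(tracks are exact), non-rigid tissue deformation beyond piecewise
translation, enterocyte extrusion, cell death, uneven illumination,
focus drift, and cycle-time heritability. Recovery results on synthetic
data are upper bounds for real data.

## Registration

The first frame is tiled once into overlapping ROIs (default 256 px with
64 px overlap; the last row/column is shifted inward so boxes never leave
the frame). For each ROI and each consecutive frame pair, the integer
translation maximizing the normalized (Pearson) cross-correlation within
±`max_shift` (default 20 px) is found on the z maximum-intensity
projection; ties break by smallest shift magnitude, then lexicographic
(dy, dx). Zero-variance patches are flagged degenerate and repaired with
the median shift of neighboring ROIs; a frame pair with more than half
its ROIs degenerate aborts with a diagnostic. Shifts are composed
cumulatively (t → t+1, summed from frame 0) and applied to *coordinates*:
a point observed at frame t is mapped to the frame-0 reference by
subtracting the cumulative shift of its containing ROI (highest
correlation score on ties). Integer shifts mean a fractional drift leaves
a sub-pixel sawtooth residual that grows with per-frame rounding error;
over the ~10-frame horizons tested the residual SD stays below 1 px. No
rotation, scaling, or sub-pixel refinement is attempted.

## Quantification

* **Otsu threshold** — authored as an explicit between-class-variance
  scan over occupied histogram levels (lower class = values ≤ level; ties
  take the lowest level). Exact for up to 4096 distinct values; denser
  images are binned to 256 levels. With an empty inter-mode gap every cut
  in the gap ties, so the threshold lands at the top of the lower mode —
  equivalent as a classifier.
* **Dual-channel mask** — GFP and nuclear channels are thresholded
  independently; the AND of the masks is labeled (8-connectivity) and
  components under 20 px dropped. Per-cell mean GFP is averaged
  *unweighted* into the per-organ value, so large cells do not dominate.
* **Local background** — the median of a 50 µm square window centered on
  the nucleus, nuclear pixels excluded, is *subtracted* from the raw mean
  (floored at 0). Subtraction rather than division was chosen because the
  photobleaching dip in per-cell GFP traces behaves additively. Windows
  clipped below 100 usable pixels carry a "border" flag.
* **Nuclear area** — shoelace area of the sub-pixel outline polygon
  × pixel_size²; outlines carrying sub-pixel vertices make image
  upscaling unnecessary. Self-intersecting polygons are rejected
  (shapely validity).
* **Cell-death series** — each day's projection is divided by its median
  pixel value (cancelling global gain/background changes — the series is
  provably invariant under per-image multiplicative gain), summed inside
  the organ mask, and normalized to day 0. Division, not subtraction, was
  chosen for the median normalization; the gain-invariance property only
  holds under division.

## Lineage reconstruction

Tracks (one observation per frame) tolerate a single missing frame by
flagged linear interpolation; gaps of two or more frames split the track,
the distal fragment becoming a parentless root. With annotated parent ids
trees are assembled directly and validated (exactly two daughters per
division, daughters' first frame = mother's last + 1, acyclic). Without
parent ids, mothers ending at frame f are matched to newborn tracks at
f + 1 within `link_radius_um` (default 10 µm; 5 µm suffices for the
simulator's geometry). Matching is by *pair midpoint*: cytokinesis splits
the mother in place, so the true daughter pair straddles the mother's
last position; all (mother, newborn-pair) proposals in a frame are ranked
by midpoint distance and accepted greedily. A newborn pool in which more
than two candidates are exclusive to one mother raises an explicit
unresolved-division error rather than guessing; orphan appearances become
new roots with a warning.

Cycle duration = (a cell's last observed frame − its first frame) ×
frame interval, counted only for cells that both appear by division and
later divide. Completed-cycle means measured this way are slightly
length-biased downward relative to the configured mean, because cycles
too long to finish before the movie ends are excluded — the same
censoring a real imaging session imposes.

## Sibling-pair analysis

One candidate pair per division. Labels: **co-dividing** when both
daughters divide within the movie (the co-division interval is reported
rather than capped, so users can filter); **non-co-dividing** when
exactly one divides and the other is observed quiescent for ≥ 6 h after
its sister's division; **unclassifiable** otherwise. Kinematics over the
first six hourly frames after the pair appears (t0..t5): 3D internuclear
distance (truncated when a sister is lost or divides); per-step 3D
motility with 1.5×IQR outlier flagging (flagged steps are excluded and
logged); xy relative movement |ΔA − ΔB| per step (common tissue motion
cancels; z is excluded by construction of the decomposition); and the
sister-axis angle arctan(|Δz|/lateral) at the pair's first shared frame,
computed only where a least-squares plane fit to ≥5 neighbor nuclei tilts
less than 10° from the imaging plane (defaults: 30 µm neighborhood). The
manual triplicate-and-average angle protocol is replaced by one
deterministic computation. Differentiation of a tracked cell between two
frames is called when nuclear area grows ≥1.5× and GFP falls to ≤0.5×;
zero reference GFP downgrades the call to area-only with a warning flag.

## Statistics and reporting

Fisher's exact test is computed in exact rational arithmetic: with
margins fixed the 2×2 tables form a hypergeometric family, and the
two-sided p is the summed probability of all tables no more probable
than the observed one — this convention reproduces the printed
p = 0.0106 for the 1/17 vs 6/12 co-dividing lineage contrast (the
"double the one-sided p" convention does not). Mann-Whitney U uses
midrank ties, the exact null when the smaller sample has ≤ 8
observations and no ties, and the tie-corrected normal approximation
otherwise; the method used is recorded. Reports (co-dividing frequency
per lineage, cycle summaries, distance-vs-time ensembles, optional
proliferating fractions) are written as sorted CSV at fixed float
precision, so regeneration from identical inputs is byte-identical; a
JSON manifest embeds the config, seed and input hashes.

## Problem sizes

The test-suite and acceptance computations run at desk scale, chosen so
each statistical check has comfortable power: simulations of 20–40
founders over 40–72 h on 300–600 µm fields (≈150–400 divisions, ≥200
completed cycles, ≥100 classifiable pairs, ≥50 pairs per kinematic
group), and registration on 128 × 128 px, 11-frame renders with
(1.8, 1.2) px/frame fractional drift.

## Known limitations

* Integer-pixel registration accumulates rounding bias ~0.2 px/frame for
  fractional drifts; long movies would need sub-pixel refinement.
* Parentless linking uses positions alone; densely packed simultaneous
  divisions outside the simulator's exclusion geometry can still be
  ambiguous, and are surfaced as errors, not guesses.
* The co-dividing label is censored by the movie end: a symmetric
  division late in the movie is unclassifiable or mislabeled if a
  daughter's division falls outside the recording; classification
  accuracy is therefore assessed on pairs with sufficient observation
  windows.
* The Otsu scan assumes a meaningful bimodal histogram; organ-scale
  vignetting or autofluorescence gradients should be corrected first.
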