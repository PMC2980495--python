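# Methods

This note documents the models, conventions and numerical choices behind
`wormhcs`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## The analysis model

A whole-organism high-content screen images each well of a microtiter
plate in brightfield plus fluorescence channels and reduces the images to
one readout per well.  The package models this in four stages.

**Object detection.** Animals are dark elongated objects on a bright
background.  Segmentation thresholds the brightfield image (Otsu by
default, with a fixed-threshold override, because the commercial
instrument's settings are not public) and takes 8-connected components;
8-connectivity is required so thin diagonal bodies do not fragment.  Per
object we measure area, length as the longest geodesic path through the
morphological skeleton (+1 px for the endpoint half-pixels), and width as
the mean of twice the Euclidean distance transform sampled along the
skeleton.  A size gate with inclusive bounds on all three measures selects
animals of the target stage; boundary ties pass, border-touching objects
are always rejected as partial animals.  Gates are calibrated from
reference objects as padded [q, 1−q] quantiles (defaults q = 0.01, pad =
10% of the span) and require at least 10 references.  Overlapping animals
are deliberately *not* untangled: a touching pair segments as one object,
which is the documented failure mode of whole-body counting and the reason
the head-marker counting mode exists.

**Fluorescent quantification.** Spots are 8-connected components of pixels
strictly above an intensity threshold within a region (an object mask or
the whole well), each at least a minimum pixel size; the per-region
readouts are spot count, total spot area and total summed intensity.  The
puncta threshold for autophagy-type readouts is calibrated from the
diffuse signal of reference animals as mean + k·SD of pooled in-worm
pixels (default k = 3; the choice of k trades puncta sensitivity against
false spots in diffuse signal).  Animal counting uses the pharyngeal
red-head marker in whole-well mode: a spot counts as one animal iff its
area **and** mean intensity both clear a calibrated gate — a conjunction
rather than a weighted score, because it is the simplest rule that
separates adult from larval heads and each bound is interpretable on its
own.  Per-animal readouts divide the whole-well GFP metrics by the head
count; a zero head count flags the well excluded rather than erroring.
Percent dead is 100 × (dye-stained bodies / heads), clipped to 100 with a
warning since merged dead bodies can double-count.  Dead-body counting
uses a minimum component size of about one body cross-section to suppress
debris, and optionally apportions large components by a calibrated
typical single-body area (`round(area / body_area)`, at least 1), since
adjacent dead animals fuse into one component; what separates "one body"
from "several adjacent bodies" is a stated convention of this package, not
an instrument behavior.  One practical rule matters here: the green
threshold must be calibrated once from reference wells and reused —
per-well automatic thresholding on a well with *no* signal splits the
noise floor and manufactures arbitrarily large foreground.

**Plate statistics.** Z′ = 1 − 3(σ_p+σ_n)/|μ_p−μ_n| from the control
populations.  z-scores standardize sample wells against the sample-well
mean and SD (sample estimator, ddof = 1); controls and excluded wells
never enter, unless control pooling is explicitly enabled for runs where
control and sample levels are similar.  B-scores divide two-way
median-polish residuals by the raw MAD of the sample residuals.  The MAD
is deliberately unscaled (no 1.4826 Normal-consistency factor), so B-score
thresholds are read on the MAD scale.  Rank-scores average each compound's
ascending-B-score rank (ties averaged) across replicate screens; hit cuts
are strict inequalities at 110 / 1225 for a 1280-compound library and
scale as the same fractions for other library sizes.  Dose-response
verification is a two-part convention (the underlying notion of
"dose-dependent" is not otherwise pinned down): at least 2 of the upper
half of tested concentrations significant at one-tailed P < 0.01 against
DMSO in the hypothesized direction, and a Spearman correlation between
concentration and mean readout of the hypothesized sign.  No
multiple-testing correction is applied in the primary screen — selection
is rank-based — and the dose stage uses raw P-values by design.

**Agreement regression.** Detector validation regresses detected on true
values by OLS and tests slope = 1 with a two-sided t-test on n−2 degrees
of freedom; a perfect identity fit has zero slope error and is reported as
non-significant (P = 1).

## Median polish: convergence choice

Sweeps alternate row and column medians (even counts use the mean of the
two central values) and iterate until the largest median subtracted in a
full sweep falls below 10⁻¹² times the plate's median absolute readout
(cap 500 sweeps).  An earlier criterion — stop when the sum of absolute
residuals stalls — terminates inside a plateau of the L1 objective where
the decomposition still depends on the data's additive offsets: two plates
differing only by a constant added to one column ended up with residuals
differing by ~10⁻² of a standard deviation.  Running the sweeps to their
fixed point makes the residuals, and hence the B-scores, invariant to
whole-row/whole-column offsets at the 10⁻¹² level, which is the property
the B-score exists to provide.  The decomposition is finalized by
recomputing residuals as y − (μ̂ + R̂_i + Ĉ_j), so reconstruction is exact
by construction.  Degenerate plates are flagged rather than scored: the
MAD floor is 10⁻¹² times the plate's median absolute readout.

A related distributional fact, established with an independent pure-Python
sweep implementation: median polish zeroes every row and column median,
which concentrates residuals near zero, so the residual MAD/SD ratio on
Normal noise is ≈ 0.59 rather than the i.i.d.-Normal 0.6745.  Null-plate
B-scores are therefore genuinely heavier-tailed than a naive
Normal-with-consistency-factor calculation predicts (≈1.3% beyond
|B| > 3/0.6745, not 0.27%); thresholds on B should be chosen with that in
mind.  z-score null tails do match the Normal mass.

## What the generator emulates

Worms are smooth correlated-random-walk centerlines dilated to a width
profile tapering at both ends.  Stage geometry at the default
2.5×-equivalent scale: adult length 70 px (SD 7%), each earlier stage
0.65× the next (L4 45.5, L3 29.6, L2 19.2, L1 12.5 px), widths 6.0 down to
1.4 px.  The default 256×256 frame keeps the adult-length-to-frame ratio
of a full-well image of a 384-well plate (≈0.27); the percent-dead
experiments use 320×320 with ~50 animals, mirroring the roomier 96-well
format of that assay.  The head marker occupies ~12% of body area (10%
noise) at the head end of the centerline; head area therefore scales with
stage, which is what makes area-gated head counting stage-selective.
Inclusions, puncta and neurons are small bright disks placed inside the
body mask (neurons spaced along the centerline, at most 6 — the
mechanosensory complement); dead bodies fill the whole mask in the green
channel.  Channels get additive Gaussian read noise and an optional
per-well illumination offset.  Placement is uniform-random, so overlaps
arise naturally and are recorded as pixel-adjacent pairs; an
`avoid_overlap` mode rejection-samples placements for tests that need
clean ground truth.  Head tips of marker-bearing animals keep a minimum
separation (default 9 px, about one pharynx): bodies may cross, as real
worms do, but two pharynges cannot occupy the same space, and without the
constraint independent placement lets rendered heads coincide — an
artifact with no physical counterpart.

The measurement-table simulator draws negative controls from
N(1.3, 1.5²) and positive controls and non-hit samples from N(98.1, 9.0²)
— the control statistics of the aggregation assay this package models,
where sample wells contain aggregate-bearing animals.  Planted hits
multiply the positive mean (defaults 0.25× down, 1.6× up; fractions 2.5% /
1.2%, matching the ~33/1280 and ~15/1280 candidate rates of such screens).
Row/column gradients are additive linear spans, day drift is a per-plate
offset (default day assignment: plate 1 on day 1, the rest on day 2, the
sort-day pattern of the screen modeled), and autofluorescent nuisance
wells get a large additive offset independent of the animals.  Dose series
draw per-animal readouts around a supplied effect function with
control-level noise; concentration 0 is always the DMSO distribution.

**What it does not emulate**, and hence what passing tests cannot show
about real data: optics (PSF, vignetting, focus failure), real worm
posture and thrashing, biological variability beyond Gaussian readout
noise, plate-edge evaporation effects, bacterial debris, or compounds with
partial/composite phenotypes (e.g. killing half the animals while leaving
the signal of the rest intact).  Detection accuracies measured on the
synthetic wells are upper bounds for instrument data.

## Problem sizes

The validation experiments use 20 mixed-stage wells of 36 animals (head
counting), 12 wells of ~50 animals across six kill-dose levels (percent
dead), and 15 + 24 wells at two densities (brightfield undercounting);
distributional tests use ≥10⁴ simulated sample wells (32 plates of 384).
These sizes give Monte-Carlo error comfortably inside the asserted
margins while keeping the default suite fast.

## Limitations

- Overlap resolution is out of scope by design; brightfield counts are
  biased low in crowded wells (that bias is itself asserted by the tests).
- Calibrated gates are dataset-specific.  No universal size window exists:
  gates must be recalibrated per magnification and strain.
- The spot detector is a plain global-threshold component labeler; it
  reproduces configured behavior, not the proprietary algorithm of any
  instrument.
- B-score tie structure makes compound ranks sensitive at the last ulp of
  the readout; intermediate CSVs are therefore written and re-read with
  round-trip float precision.
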