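# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that make runs reproducible.

## Coordinate and calibration conventions

Raster data are 0-based `(row, col)` with the origin at the top-left
pixel. Physical coordinates (EM scenes, track tables) are `(x_nm, y_nm)`.
The default fluorescence calibration is 100 nm/px — near-Nyquist sampling
for a widefield system whose optical resolution is 200–250 nm with a
100×/1.4 NA objective; EM-scale scenes default to 10 nm/px. All
randomness flows from one explicit integer seed through a
`numpy.random.Generator`; no global random state is touched, and
identical parameters yield bit-identical outputs.

## Cell segmentation (WGA membrane stain)

The membrane stain forms a bright, closed ridge around every cell, so
segmentation is a marker-controlled watershed on the Gaussian-smoothed
membrane image (σ = 1.5 px): ridges act as flooding barriers, and the
watershed line between adjacent markers settles on the ridge crest.
Markers are either user-supplied seed points (the semi-automatic mode —
one click per chosen cell, with marker *i* + 1 grown from seed *i* so
label identity follows seed order) or, automatically, the connected
sub-threshold basins enclosed by the ridge mask; basins touching the
image frame seed the background. The ridge threshold defaults to Otsu's
value on the smoothed image. Regions below 500 px² are discarded
(≈ a quarter of the smallest plausible cell at the default calibration).

Failure is reported, never raised: a scene with no supra-threshold ridge
returns an empty label map with a warning, and a cell whose final
boundary runs more than 10% over sub-threshold membrane (a ridge gap
letting the background flood in) triggers an undetected-border warning,
mirroring a supervised workflow in which such cells are re-inspected.

Boundary convention: a cell's boundary pixel is a pixel of that label
with at least one 8-neighbour outside the label (inner-boundary
convention — boundary pixels stay inside the area they contribute to). A
boundary pixel is *cluster-internal* iff one of those differing
neighbours carries another nonzero label, and *cluster-outer* otherwise;
the two sets partition the boundary exactly, which the tests check
against brute-force adjacency enumeration.

## Surface ribbon and densitometry

The outer border of each cell is dilated by `width_each_side` pixels
(default 3) on *each* side, read as a symmetric Chebyshev (8-connected)
dilation of the 1-px border — the only construction in which "each side"
has geometric meaning for a curve — giving a 7-px ribbon. Ribbon pixels
falling inside another cell's label are removed, so ribbons never sample
a neighbour's cytoplasm across a touching border. Cells with an empty
outer border (fully internal in a cluster) or whose ribbon would be
truncated by the image frame are flagged unquantifiable and excluded,
with a log entry.

Per cell, the SgII surface signal is `total intensity in ribbon / ribbon
area`. The background is the *unweighted* mean of the per-cell means of
an unstimulated control population (a per-cell average, not an
area-weighted pool), subtracted from every stimulated cell. A cell is a
**responder** iff its corrected mean is strictly positive. The boundary
case is deliberately resolved to non-responder: for continuous
intensities the event has measure zero, and the strict rule is the
conservative choice. The population summary reports, per stage class,
the responder percentage and the mean corrected intensity of responders,
plus the metaphase/interphase ratio of those means (×100).

A property worth stating because the classifier inherits it from the
thresholding rule rather than from any implementation detail: under
symmetric zero-mean measurement noise, a truly null cell's corrected
mean is positive with probability ½, so the responder percentage of a
noisy null population tends to 50%, not 0%. Parameter-recovery runs
therefore use noise-free rendering (below); with noise enabled the
recovered percentage estimates `p + (1 − p)/2`, not `p`.

## Cortical-shell statistic

A granule is cortical iff the Euclidean distance from its centroid to
the membrane polygon is ≤ the shell thickness (default 500 nm; granules
exactly at the shell boundary are cortical — closed shell). Distance is
measured from the centroid, not the granule edge: granule radii
(40–75 nm) are below the comparison scale and granule size is not an
input. Distances are exact polygon distances (shapely); the tests check
them against an independent dense-raster distance transform on a 10-nm
grid, with classification required to agree for every granule farther
than 15 nm (1.5 grid steps) from the shell boundary.

Group comparison uses the classical pooled-variance two-sample t-test on
per-cell percentages (df = n₁ + n₂ − 2), matching the named test of the
original analysis; Welch's correction is available but non-default. A
summary-statistic entry path (means/SDs/sizes) exists because per-cell
values are often the only published record. Degenerate inputs: zero
pooled variance with equal means gives t = 0, p = 1; with unequal means
the p-value is reported at the machine floor with a `zero_variance`
flag. The test *procedure* is the package's contract — a published
p-value cannot be reproduced without the per-cell observations behind
it, and none are bundled here.

## Tracking

Detection is scale-normalized negative Laplacian-of-Gaussian filtering
(default σ = 1.3 px, matched to the rendered spot size; the response
peak for a matched Gaussian spot is ≈ half its amplitude, hence the
default threshold of 15 for spots of amplitude 100) followed by
response-weighted centroid refinement over a 5×5 window, which localizes
isolated spots to well under half a pixel.

Linking is greedy mutual nearest neighbour between consecutive frames:
a link forms only if each detection is the other's nearest neighbour and
the displacement is ≤ `max_disp_px` (default 8 px, ≈ 3.5× the typical
directed step at the default calibration). Conflicting assignments stay
unlinked and start new tracks; there is no gap closing — a missed
detection ends the track. The rule is deterministic and depends only on
positions, not on detection order.

A track's mean velocity is total path length over duration (the
conventional average velocity of motile-organelle work; a
net-displacement variant is a flag). "Directed" means straightness
(net displacement / path length) ≥ 0.8 over ≥ 4 consecutive detections;
a stationary track has straightness 0 by convention and is never
directed. Microtubule colocalization is the fraction of a track's
detections within `radius_px` (default 2 px = 200 nm, the lower bound of
the stated optical resolution) of the filament skeleton, via a Euclidean
distance transform sampled at the nearest pixel.

Localization noise inflates path length and therefore velocity; no
correction is applied. At the default 20-nm noise and 230-nm steps the
expected inflation is below 1%, and the measured end-to-end inflation
(including detection error) stays within the 5% allowance the recovery
tests budget for.

## Synthetic generators

The generators produce the statistical structure the analyses assume,
with exact ground truth; they are first-class, tested code.

**Fluorescence scenes.** Cells are smoothed random-radius stars (10
control points, periodic cubic spline through jittered radii), so
outlines are irregular and segmentation is non-trivial, yet star-shaped
and hence never self-intersecting. Layouts: `grid` (isolated cells,
jittered) and `pairs` (touching pairs sharing a ridge segment; bounded
retries guard against degenerate placements, and exhaustion raises a
placement error naming the seed). The WGA channel renders a bright ring
(width 3 px, intensity 200 a.u.) with a dim 15% cytoplasmic fill,
combined across cells by maximum so shared ridges stay uniform. Hoechst
renders an interphase nucleus blob or a metaphase condensed-plate bar —
annotation plumbing only, never used for automated classification; stage
classes are split deterministically (exact counts) and carried in the
annotation table. SgII is a uniform background (20 a.u.) plus, on
responder cells only, Gaussian puncta (σ 1.3 px, ≈ 0.06 per px of
perimeter) scattered along a ±3 px band straddling the true outline;
the rendered field is rescaled per cell so that its realized mean over
the true band equals that cell's ground-truth surface mean exactly.
Per-cell surface means draw a 25% CV around the class mean
(`responder_surface_mean` × class factor), emulating the strong
cell-to-cell variability of real surface staining. Spots are stamped on
bounded local windows, so pixels away from a cell stay *exactly* at
background — the exact-zero contract the responder boundary rule relies
on. Read noise is additive Gaussian on top of Poisson-free means, the
simplest model sufficient for the pipeline's contracts; the
paper-anchored presets default to `noise_sd = 0` so recovered responder
fractions estimate the preset probabilities (see the thresholding
property above), and noise sensitivity is exercised through the
parameter in unit tests.

**EM scenes.** One star-shaped outline per cell (radius 5000 nm ± 7%,
a typical half-diameter for this cell type) at 10 nm/px calibration.
Each granule is placed in the cortical shell with probability
`cortical_probability` (uniform over the shell by rejection sampling)
and otherwise uniformly over the *deep* interior — strictly farther than
the shell — so the measured shell fraction is a binomial draw around the
probability and recovery is unbiased. Fixture presets condition per-cell
counts on an exact total via a multinomial draw. Shell membership at
placement time is stored as ground truth and, at zero noise, matches the
geometric classification exactly.

**Track sets.** Directed tracks move at a constant per-track speed drawn
from N(mean, sd) truncated at zero, along a straight free path or along
one of six straight skeleton filaments spanning a 256×256 px field;
non-directed tracks are Gaussian random walks (80 nm step SD). Reported
coordinates add isotropic localization noise (20 nm SD); rendered movies
place spots at the *true* positions, so the detect→link→summarize
pipeline contributes its own localization error exactly once rather than
twice.

What the generators do **not** emulate: photobleaching, focus drift,
3-D point-spread functions, Poisson shot noise, EM texture,
out-of-focus haze, or segmentation-confounding debris. Passing recovery
tests therefore demonstrates that the measurement chain is unbiased and
correctly calibrated under the stated image model — not that it is
robust to every artefact of real microscopy.

## Problem sizes and reproducibility

The recovery runs use 20 cells per stage class for the cortical
statistic (~75 and ~125 granules per cell), 100 cells per stage class
plus a 200-cell control arm for the exocytosis pipeline, and 50 tracks
per condition for velocities — large enough that sampling error is a few
percent of each target, small enough that the whole acceptance script
completes in well under a minute on one CPU. `scripts/acceptance.py`
derives every stream from its single `--seed`; reruns with the same seed
are byte-identical, and outputs embed the config hash of the run.

## Known limitations

- Watershed boundaries sit on the ridge crest, i.e. mid-membrane; at the
  default 3-px ring this is within ~2 px of the geometric outline, which
  the ±3 px ribbon absorbs, but very thick membranes would bias ribbon
  placement.
- The responder rule's 50% false-positive rate on truly null cells under
  noise is inherent to thresholding at zero; interpreting responder
  percentages from noisy data requires the `p + (1 − p)/2` mapping above.
- Mutual-nearest-neighbour linking has no motion model; crossing tracks
  can swap identities. At the simulated densities this is rare and
  velocity statistics are insensitive to it.
- The cortical statistic treats granules as points; for granule radii
  approaching the shell thickness an edge-to-membrane definition would
  differ systematically.
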