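# Methods

## Scope and model

`hepzone` quantifies two-channel laser-excited liver-section images: a
second-harmonic-generation (SHG) channel that reports fibrillar collagen
label-free, and a two-photon excitation fluorescence (TPEF) channel in which
hepatocyte cytoplasm autofluoresces while lumens, lipid vacuoles, vessels, and
cracks appear as dark "hollows". The pipeline produces three structural
readouts of the regenerating hepatic acinus:

1. **Zone-wise collagen.** Tissue and collagen are thresholded with Otsu's
   method on 256-bin histograms; SHG signal outside the specimen and
   sub-fibril residual specks are removed as noise. The acinus is partitioned
   into five zones -- portal tract (PT), periportal (PP), transitional (TS),
   pericentral (PC), central vein (CV) -- and collagen is reported both as a
   share of total collagen per zone (headline) and as within-zone areal
   density. The shares-vs-density ambiguity is inherent to the phrase
   "percentage of total collagen in each area"; both are emitted.
2. **Steatosis.** Dark cavities are detected on the pre-hole-fill complement
   of the TPEF foreground and classified by a decision tree over morphology
   (area, equivalent diameter, circularity 4piA/P^2 with a Crofton perimeter,
   solidity, border contact) plus the collagen coverage of a 5 um outer
   annulus. One vacuole-class object counts as one steatotic hepatocyte; the
   denominator is the hepatocyte-occupiable area (section support minus all
   cavity pixels) divided by a nominal cell area.
3. **Foci density.** PT- and CV-class objects per mm^2 of section support.

Because the underlying study's measurements come from murine tissue that is
not redistributable, correctness is established by parameter recovery: a
synthetic generator plants known structures and the pipeline must read them
back.

## Zone geometry

Zone bands are measured from the landmark **object boundary** (not centroid)
with a Euclidean distance transform: a pixel is periportal when its center
lies within `band_um` (default 100 um) of any PT pixel. Pixels inside both
bands go to the nearer landmark class; exact ties go to PP -- deterministic,
and conservative for portal-centric readouts. The same routine builds the
generator's ground-truth zone map and the analysis map (single source of
truth), and it is verified against an exhaustive per-pixel nearest-boundary
oracle on small images. With no landmarks at all the whole tissue is labeled
transitional and a warning is raised.

The tissue mask fills only holes below `max_hole_um2` (default
400 um^2, intracellular scale), so large lumens stay holes there; the zone
map, foci denominator, and steatosis denominator instead use the **section
support** (tissue with all enclosed cavities filled), which is the natural
footprint for "per mm^2" readouts and makes the zone labels a true partition
of the specimen. Because a crack open to the section edge is not a closed
hole, the support additionally seals fissures thinner than ~12 um with a
Euclidean closing (radius `seal_um` = 6 um) before filling, so cracks belong
to the footprint and are detectable as border-flagged cavities.

## Default object-classification tree

When no training data are given, an inspectable rule cascade is used
(thresholds in um / um^2 / fractions): border contact -> crack; area > 2000
and ring < 0.2 -> CV; ring >= 0.5 and area in [300, 20000] -> PT;
circularity >= 0.6, diameter in [5, 40], ring < 0.2 -> vacuole; else
vessel/duct. Nodes test `value <= threshold` (the CART convention);
strict-vs-inclusive boundary differences are measure-zero. `fit_tree` wraps a
Gini-impurity CART (scikit-learn) behind the same tree surface, seeded and
depth-bounded, and single-class input degenerates to a one-leaf tree with a
warning. Border-flagged objects are never classed as vacuole, regardless of
the tree.

## Synthetic generator

The generator emulates the study's imaging conditions at the native
calibration of 200/512 = 0.390625 um/px:

* **Landmarks.** PT lumens are dark discs (default radius 25 um) with a dense
  collagen annulus (5 um, ~85% fill); CV lumens are larger (40 um) and
  collagen-poor (a 5 um collar is kept clear). Centers are placed by seeded
  rejection sampling with a minimum separation (default 150 um) and a bounded
  attempt budget (raising a placement-infeasible error otherwise).
* **Hepatocyte sites.** A jittered hexagonal lattice (nominal cell diameter
  24 um, jitter sigma 2 um) fixes the steatosis denominator. Each site is
  vacuolated independently with probability equal to the profile's steatotic
  fraction; vacuole diameters are log-normal (median 12 um, sigma_log 0.35)
  truncated to [5, 40] um. Sites hugging lumens, vessels, or cracks are
  excluded.
* **Confounders.** Small vessels/ducts (radius 5-8.5 um, ~8 per mm^2) carry a
  collagen ring; one border-anchored crack (6 um wide random walk, deflecting
  around rigid structures) exercises the border flag; salt specks outside the
  tissue and isolated in-tissue residuals exercise SHG noise removal.
* **Collagen budget.** Rings are drawn first; short fibril strokes
  (15-40 um) are then added zone by zone until each zone's realized collagen
  count matches the profile's target areal density over the true zone map, so
  group ratios of total collagen are planted accurately by construction.
* **Rendering.** Cytoplasm 170 +/- 8 (smoothed texture; the texture sd is
  kept well below the cavity/cytoplasm contrast so thresholding lands in the
  gap even on near-featureless sham sections), cavities 18, background 8,
  collagen 160, plus additive Gaussian noise (sigma 5/255) on both 8-bit
  channels. Vacuoles shrink against adjacent lumens, vessels, and cracks
  (peri-structural hepatocytes are smaller) so cavities remain separable;
  fibril strokes are clipped to their zone so planted zonal densities are
  exact. All randomness flows from one seeded generator; identical
  (profile, dims, seed) are bit-identical.

What the generator does **not** emulate: real fibril anisotropy and texture,
inflammation and ballooning, multi-vacuole cells, sinusoidal fine structure,
uneven illumination, and section-to-section thickness variation. Passing
recovery tests therefore demonstrates the correctness of the measurement
chain, not robustness to every property of real tissue.

## Condition profiles

`builtin_profiles()` carries one parameter set per reported (group, day) cell
of the sham/hepatectomy x glutamine design: steatotic fractions, PT/CV foci
densities, zonal collagen densities, and endpoint means +/- SEM (remnant
liver weight / body weight %, AST, ALT, albumin, PCNA %). Printed group
means are transcribed; cells the figures do not print (baselines, day-6
tails, absolute collagen densities) are smooth interpolations declared here
once. The day-2 and day-4 collagen maps are solved so the planted group
ratios of total collagen reproduce the reported 1.2x and 4.9x effects: the
glutamine-arm periportal density is calibrated against the generator's
realized mean zone-area fractions (which account for periportal band overlap
between nearby portal tracts and edge losses), with the remaining zones held
at the declared baselines. Group size is never stated in the source
(beyond "at least 3 replicates"); profiles carry n = 6.

## Cohort simulation and statistics

Each mouse x day endpoint is drawn with the profile mean and per-animal SD =
SEM * sqrt(n); within-mouse correlation across days enters through a shared
standardized random intercept (ICC default 0.5). AST/ALT are simulated
log-normal with matched mean and SD (right-skewed, strictly positive);
mean-matching uses sigma^2 = ln(1 + (s/m)^2), mu = ln m - sigma^2/2. The
reporting stage uses Welch's t for two arms, one-way ANOVA with Tukey HSD
beyond two, and a random-intercept mixed model (fixed: group + day; random:
mouse; ML fits) whose group effect is a likelihood-ratio chi-square. A
failed fit raises; a boundary fit (zero random-effect variance) is surfaced
through a warning and the result's `converged` flag. The protocol's "2-tailed alpha of 0.1" line is kept
as a footnote constant while the p < 0.05/0.01/0.001 star convention is the
decision rule; the inconsistency is documented, not resolved.

## Numerical choices and problem sizes

* Otsu operates on exact 256-bin integer histograms (cumulative sums are
  exact in float64 below 2^53), with ties broken to the lowest level; it is
  tested against an exhaustive-search oracle.
* Connectivity is 8-connected for cavities and collagen (preserves thin
  fibrils); hole filling uses the 4-connected background dual.
* A collagen-free SHG channel is recognized by Otsu's separability measure
  (eta = between-class / total variance): eta ~ 0.5-0.6 when the threshold
  merely bisects unimodal noise vs >= 0.7 for genuine collagen down to
  ~0.3% areal fraction; below `min_separability` = 0.62 the mask is empty.
* Cleaning defaults: min tissue component 10,000 um^2; max filled hole
  400 um^2; min fibril 5 um^2; min cavity 15 um^2 (just under the smallest
  5 um vacuole's 19.6 um^2 footprint).
* Circularity uses the Crofton perimeter and is capped at 1.05 to absorb
  discretization of small discs.
* Recovery experiments run at desk scale: ten 1 mm^2 sections for steatosis
  recovery, five per arm for the collagen ratio, ten ROIs for foci counting;
  unit tests use a coarser 200/256 um/px calibration on 0.25 mm^2 fields.
  Monte-Carlo calibration of the comparison stage uses 2000 null replicates
  (Welch) and 150 mixed-model replicates (KS uniformity).

## Known limitations and biases

* **Steatosis denominator bias.** The area quotient with a 450 um^2 nominal
  cell area undercounts slightly relative to the hexagonal-lattice site area
  ((sqrt(3)/2) * 24^2 ~ 499 um^2), and ~2-3% of vacuoles are lost to border
  contact, merging, or sub-threshold size; the net pipeline estimate runs
  ~2 percentage points below the planted fraction at high steatosis. This
  stays within the binomial placement band used for acceptance and is
  reported as-is rather than post-hoc corrected, since the real denominator
  (true hepatocyte count) is unobservable in TPEF.
* One vacuole = one steatotic hepatocyte; multi-vacuole cells are out of
  reach without cell boundaries.
* The vacuole/vessel discrimination relies on the planted contrast (collagen
  ring present/absent); heavily fibrotic periportal tissue could push vacuole
  ring fractions above the 0.2 cutoff.
* ROI placement emulates tissue-biased manual placement with a greedy,
  seeded rule; the study's actual placement protocol is unknown.
* The mixed-model LRT p-value is asymptotic; at n = 6 mice per arm its null
  distribution is only approximately uniform (verified by KS at desk scale).
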