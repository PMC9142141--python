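# Methods

`glomcode` reimplements, as a tested and reusable pipeline, the analysis
stack of a plant-odor coding study in a hawkmoth: processing of in vivo
calcium-imaging movies of the antennal lobe, statistical calling of
headspace-activated glomeruli, GC-EAD active-peak analysis with Kovats
retention indices, and Bray–Curtis/ANOSIM/NMDS multivariate statistics.
Because the original raw data are not bundled, a first-class synthetic-data
module generates ground-truthed inputs for every stage, and the package's
claims about itself are exactly the recovery and calibration results its
tests and `scripts/acceptance.py` compute.

## Imaging model and processing chain

A trial is a 40-frame fluorescence stack recorded at 4 Hz; the odor pulse
occupies 1-based frames 9–16. Paper-mode geometry is 344 × 260 px at
4 µm/px. Processing follows four steps:

1. **Background correction.** ΔF/F = (F − F̄)/F̄ per pixel, with F̄ the mean
   of pre-stimulus frames 3–7. After this step the baseline frames average
   exactly zero at every pixel; a nonpositive baseline pixel raises (it
   signals corrupt input).
2. **Bleaching correction.** The dye bleaches slowly under illumination; the
   decay is modeled as offset-plus-exponential, a + b·exp(−t/τ), fitted by
   least squares to the ΔF/F course over frames 3–7 and 26–40 (outside the
   stimulus/response window) and subtracted from every frame. τ is bounded
   to [1, 1000] frames; a non-convergent fit falls back to a linear fit,
   flagged in provenance. The fit granularity follows the use: for
   movie-level output a single field-mean fit is subtracted from all pixels;
   for response extraction the fit is done per ROI trace (default in
   `process_experiment`). The per-ROI form is preferred because any residual
   response tail inside the fit window is then absorbed approximately
   multiplicatively per ROI, which preserves amplitude ranks, whereas a
   global fit converts the same contamination into a trial-wide additive
   bias.
3. **Median filtering.** A 7 × 7 spatial median per frame removes outlier
   pixels; borders use edge-including reflection.
4. **Movement correction.** The reference trial is the one whose frame 20
   has the median spatial-mean intensity across trials (ties → earliest);
   every trial is aligned to it by the integer translation maximizing
   normalized cross-correlation of frame 20 within a ±10 px search radius,
   the same translation applied to all frames. A best match on the search
   boundary raises (movement exceeds the radius). Shifts are estimated from
   the *raw* frames: the anatomical texture (lobe outline, tracheae) lives
   in raw fluorescence, while ΔF/F of a solvent-control trial is featureless
   noise. The estimated translation is then applied to the processed stack.

**Response extraction.** The ROI is a 60 µm × 60 µm square (15 px at
4 µm/px) centered on a glomerulus. Its mean ΔF/F trace is smoothed with a
centered 3-frame moving average; the response is the maximum of the smoothed
trace at frames ≥ 9 — restricted to frames where both smoothed neighbors
exist, i.e. 9–38 — averaged with the smoothed values immediately before and
after the maximum.

## Synthetic movies

`synthetic.generate_movie` renders
F(x, t) = baseline(x) · (1 + Σ_s A_s g_s(x) w(t)) · B(t), then the trial's
integer shift, then additive Gaussian noise with per-pixel SD
noise_sd · baseline(x). Components:

* **Baseline** — a positive field (default 100 a.u.) with smoothed-noise
  texture (SD 20 a.u., correlation length 4 px) standing in for the
  anatomical features that make raw frames registrable.
* **Spots** — spatial Gaussians (σ = 12 px in paper mode) whose gain is
  scaled so that the **ROI-mean** ΔF/F at the waveform peak equals the
  nominal amplitude A_s; amplitudes are therefore directly comparable with
  extracted responses.
* **Waveform** w(t) — zero before frame 9, linear rise to 1 at frame 12,
  exponential return with τ = 8 frames. Any smooth unimodal shape would do;
  fixing one makes oracle values reproducible. Note that with τ = 8 about
  17% of the peak persists at frame 26, so the bleach-fit window is mildly
  contaminated by design — the processing chain must cope with it (see the
  per-ROI fit rationale above).
* **Bleaching** B(t) — offset-plus-exponential with B(0) = 1 and
  B(T−1) = 1 − bleach_frac (defaults: bleach_frac 0.2, τ 40 frames), the
  same family the correction fits.
* **Shifts** — integer pixels, matching the integer-translation registration
  contract.

Default noise_sd is 0.005 (0.5% of baseline per pixel per frame); averaged
over the 225-pixel ROI and the 3-frame smoother, the extraction noise floor
is ≈ 2·10⁻⁴ ΔF/F, more than an order of magnitude below the weakest planted
responses. What the generator deliberately does **not** model: optics/PSF,
photon (shot) noise statistics, within-trial drift, sub-pixel motion,
glomerulus shape variability, and temporal response diversity across
glomeruli. Passing tests therefore demonstrate correctness of the
processing algebra and robust parameter recovery under realistic amplitude,
bleaching, shift and noise scales — not performance on real movies.

## Activation calling

Within one mating-status group and glomerulus, animals are blocks and the
stimuli are treatments of a Friedman design: 18 headspaces plus the
per-animal **average** of the two dichloromethane (DCM) control trials,
19 treatments in all. The Friedman chi-square (tie-corrected, k − 1 df) is
recorded; activation tiers come from Dunn's multiple-comparisons test
against the DCM-average control: within-block mean ranks,
z = (R̄_j − R̄_c) / √(k(k+1)/(6n)), two-sided normal p, Bonferroni-adjusted
over the m = 18 vs-control comparisons. Adjusted p < 0.01 and < 0.001 give
the two activation tiers. For tiny designs `friedman_test(method="exact")`
enumerates all (k!)ⁿ within-block orderings instead of using the asymptotic
distribution.

A structural property of this design worth knowing: with n = 10 blocks and
k = 19 treatments, the z threshold for adjusted p < 0.01 is 3.45, while the
largest *expected* z when all non-target stimuli are exchangeable with the
control is 9.5/√(19·20/60) ≈ 3.77 — the control's mean rank then sits
mid-pack among the null stimuli. Detection of even a huge single effect is
therefore borderline (~70% at the p < 0.01 tier) under a pure-noise
background, and reliable (>99%) precisely when non-target stimuli evoke
weak generic responses that push the solvent control toward the bottom
rank. That is the situation in real headspace data (plant bouquets share
ubiquitous volatiles; the solvent sits at the bottom of the normalized
range), so the synthetic study includes a weak generic response floor
(0.008 ΔF/F, ~40× the extraction noise floor) on the nectar/host/sympatric
stimulus rows. The calibration simulations keep both regimes visible: the
type-I simulation uses the exchangeable floor-free null (per-comparison
false-call rate ≈ 0.1%, well under the 2% bound), and the sensitivity
simulation plants a 5-SD effect over a 3-SD generic floor.

**Normalization** rescales each animal × glomerulus to 0–100 over the 18
headspaces plus the DCM average (lowest = 0, highest = 100); an all-equal
cell maps to all zeros with a `degenerate` flag. Downstream summaries:
per-headspace fractions of cells where it is the response maximum (argmax
over headspaces, ties to canonical order and flagged), activated-glomerulus
counts with category summaries, and median normalized responses across
animals restricted to activated cells.

## GC-EAD layer

Retention times are converted to Kovats retention indices against an
n-alkane ladder: RI = 100(n + (n₁−n)(rt−rt_n)/(rt_{n₁}−rt_n)) with the
bracketing alkanes; alkane Cₙ maps to exactly 100n, values outside the
ladder span are linearly extrapolated with a warning. EAD-responsive peaks
of one headspace are aligned across antennae by single-linkage clustering
on RI with a ±5 RI-unit gap tolerance (a typical reproducibility scale on a
polar column; configurable). Single linkage bounds the gap between
neighbors, not the cluster diameter, so chained clusters can exceed the
tolerance end to end; the partition equals the connected components of the
all-pairs within-tolerance graph, which is what the test oracle computes.
A group is **EAD-active** iff at least 3 distinct antennae support it *and*
a peak at matching RI (area > 0) occurs in at least one other replicate
sample of the same headspace type — replicate presence is judged on
FID/MS peaks, since the criterion requires the fraction to be *present*,
not antennally active, elsewhere. Missing replicate information makes a
group indeterminate, never active. Summaries: compound × headspace matrix
of median EAD amplitudes (rows sorted strongest first), single-point
internal-standard quantitation (ng = 5 ng · area/area_istd, no response
factors), peak-count classification against the closed [min, max] blank
interval, and an RI-binned sample × feature abundance table as a simplified
stand-in for nontargeted feature detection.

## Multivariate statistics

Bray–Curtis dissimilarity d = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on nonnegative rows (one
all-zero row is tolerated at distance 1 from any non-zero row; two all-zero
rows raise). One-way ANOSIM ranks all n(n−1)/2 distances and computes
R = (r̄_between − r̄_within)/(M/2); p comes from label permutations with the
add-one convention p = (1+#{R* ≥ R})/(1+B), or from exhaustive enumeration
of all distinct labelings when their number is at most `n_perm` (then
p = #{R* ≥ R}/total, the identity included). The two-way crossed design
computes, for factor A, the unweighted mean of one-way R values within each
level of factor B — each stratum's sub-matrix re-ranked on its own — and
permutes A labels only within B strata; strata without two A groups or any
within pair are excluded (their count is reported), and a factor with no
testable stratum returns NaN. ANOSIM is rank-based and therefore invariant
to monotone transforms of the distances (property-tested).

Non-metric MDS minimizes Kruskal stress-1 by SMACOF with monotone
regression; the best of one classical-scaling warm start plus 50 random
restarts is reported. Abundance tables are used untransformed.

## Benchmark study design

`pipeline.run_synthetic_benchmark` builds 2 mating-status groups × 10
animals × 23 glomeruli × (18 headspaces + 2 DCM controls). The planted
amplitude design mirrors the qualitative biology: four nectar-source
headspaces with broad strong activation (0.06–0.10 ΔF/F), two host plants
each driving a single glomerulus (one switching glomerulus between groups),
three sympatric-host headspaces activating more glomeruli after mating, and
background headspaces activating a few glomeruli in virgins and almost none
in mated females — plus the generic weak floor described above. Per-animal
amplitudes jitter log-normally (σ = 0.2); trial shifts are drawn in ±4 px so
shifts relative to the reference trial stay inside the ±10 px search radius.

The benchmark runs at a half-scale "desk" geometry — 172 × 130 px with
σ = 5 px spots on a 23-point grid — which keeps spot crosstalk into
neighboring ROIs negligible and one full run in a few minutes; the
generator's paper-mode default remains full size. Reported metrics:
Spearman correlation between injected and extracted amplitudes over
positive-amplitude cells (zero-amplitude cells have no defined ordering
among themselves; the all-cells value is reported alongside), the fraction
of trials whose corrective shift composes exactly with the injected shift,
activation sensitivity on strong cells / specificity on zero cells / call
rate on floor cells, and the two-way ANOSIM (mating status × headspace) on
per-animal normalized 23-glomerulus response vectors, one sample per
animal × headspace, with 999 permutations.

## Numerical choices and degenerate inputs

* Frame numbering is 1-based in every public parameter and log, matching
  lab convention; storage is 0-based internally.
* Friedman with every block fully tied returns statistic 0, p 1 (the tie
  correction would otherwise divide by zero).
* Dunn adjusted p is clipped to 1; m = 1 leaves raw p unchanged.
* Argmax ties in the maximum tally resolve to the first headspace in
  canonical stimulus order and are counted separately.
* Registration refuses a best match on the search boundary instead of
  silently returning it.
* Exact ANOSIM inference triggers automatically when the number of distinct
  labelings is at most `n_perm`; permutation p can never be 0 in sampled
  mode by the add-one convention.
* All generators and permutation tests take explicit seeds; identical
  configs reproduce outputs bit-identically.

## Known limitations

* No glomerulus segmentation or cross-animal atlas registration: ROI
  centers are supplied (the original workflow identified glomeruli manually
  with diagnostic odorants).
* Registration is integer-translation only; no rotation, scaling or
  sub-pixel motion.
* The GC layer starts from peak tables; raw chromatogram signal processing
  and mass-spectral identification are out of scope.
* The activation caller corrects within a glomerulus's treatment family
  only, as in the source workflow; no correction across glomeruli.
* Synthetic data validate the algebra and calibration of the pipeline, not
  its behavior on real movies (see the generator's non-goals above).
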