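# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage of the package, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Video tracking

Each frame runs greyscale → CLAHE → Gaussian smoothing → binarisation →
largest-connected-component centroid. The smoothing σ = 4 px is the one
fixed constant of the chain; the binarisation threshold and CLAHE settings
are not recoverable from any published description, so the defaults are
declared choices: Otsu's threshold on the smoothed frame (parameter-free
and reproducible, with a fixed-threshold override) and CLAHE with clip
limit 0.01 on tiles of 1/8 of the frame side. Polarity is explicit
(`dark-body` default — a fly on a bright arena).

Coordinates are pixel centres, origin top-left, x right / y down. The path
length sums Euclidean steps over consecutive *valid* frame pairs; frames
with an empty mask get a NaN sentinel rather than aborting, and a video
with > 50 % invalid frames raises as untrackable. Spatial calibration reads
a photographed square grid: the median peak-to-peak spacing of the mean
row/column intensity profiles (peak prominence ≥ 25 % of the profile
range, ≥ 3 lines per axis required).

Body length is the median over frames of the best-fit-ellipse major-axis
length of the per-frame body mask. (An earlier design measured the
time-median mask; that is empty for any animal that moves more than its
own width during the recording, so the per-frame median is used instead —
it agrees with the rendered ground truth to ~1 px on synthetic videos.)

The walking criterion is inclusive: path ≥ 1.0 × body length. The
hind-to-front (T3→T2→T1) leg-recruitment criterion is consumed as a manual
annotation flag only; the package does not attempt leg detection.

A caveat quantified by the tests: with σ fixed at 4 px, segmentation
fidelity depends on magnification. At 0.05 mm/px (≈ 50 px body) the mask
IoU against the rendered ground-truth ellipse exceeds 0.9; at 0.1 mm/px
(≈ 25 px body) blur rounds the body outline and IoU drops to ≈ 0.7, while
the *centroid* remains accurate to well under a pixel — the tracker's
output is robust to this even when the mask is not.

## Treadmill kinematics and epochs

Speeds are linear in rotation rate: v = rate × 31.42 mm per rotation
(translational axes) and × 360° per rotation (yaw). The resting thresholds
0.12 mm, 0.12 mm and 5° are interpreted as **per-frame displacements**
(speed/fps) because their units are mm and degrees, not mm s⁻¹ and
° s⁻¹; a `per_second` flag reinterprets them as speed thresholds.
"Below" is strict: a displacement exactly at threshold is walking.
Absolute values are used on all three axes — a leftward or backward step is
still walking. No minimum epoch duration or smoothing is applied by
default. Epochs are maximal runs of equal frame labels and tile the
session exactly; this invariant is property-tested over random traces.

## Ratiometric %ΔR/R

R = F_activity/F_reference per frame; frames with a non-positive reference
are invalid (NaN), and an all-invalid trace is an error. The baseline R₀
defaults to the 8th percentile of R over the session — robust to
transients while tolerating slow drift; alternatives (`min-smoothed:w`
rolling-minimum baseline, `fixed:v`) are selectable. %ΔR/R is undefined
(error) for non-positive R₀.

Epoch-aligned averaging aligns segments by epoch **start** only, and the
average is emitted only where at least 4 segments are still running
(`min_support=4`). Support is non-increasing in the aligned index.
Normalisation of average traces divides by the maximum absolute value
(peak maps to ±1); line profiles are normalised per channel by that
channel's own maximum, independently — so each channel spans 0–1 and
rescaling one channel never changes another. Sub-ROI traces aggregate
pixels by mean (median selectable) inside circular ROIs; an ROI extending
past the frame edge is an error naming the ROI. Rigid registration is
integer-pixel phase correlation against the first frame — deliberately
simple plumbing standing in for full motion-correction, sufficient for
translation-dominated drift.

## Categorical statistics

Pearson χ² is computed without continuity correction — this choice is
validated by the test suite reproducing all seven published statistics
(17.6, 0.2, 10.2, 16.8, 9.1, 1.4, 2.9) from their count tables to 1 d.p.

Exact tests enumerate every table with the observed margins, weighting
each by its multivariate hypergeometric probability; enumerated masses sum
to 1 within 1e-9 (tested). Two tail orderings are exposed: `prob` (tables
at least as improbable as observed — the Fisher/Freeman–Halton convention,
default) and `chi2` (tables with at least the observed Pearson statistic).
On the published 3×2 subgroup table ([[4,2],[3,1],[2,5]]) both orderings
give exactly 0.262855, so the two conventions are indistinguishable there.
Tail membership uses an absolute tolerance of 1e-9 on log-probability /
statistic to absorb float round-off. Enumeration is guarded at a table
total of 200; beyond it a seeded Monte-Carlo mode samples 10⁵
margins-fixed tables (Patefield sampling via `scipy.stats.random_table`).
Fisher's 2×2 test is the same engine restricted to 2×2; it matches
`scipy.stats.fisher_exact` to 1e-10 on random tables (independent oracle)
and a zero margin returns p = 1, flagged.

The pairwise group comparison builds each 2×2 walked/not-walked table and
routes by the expected-count rule: minimum expected count > 5 → the
Pearson p-value, otherwise Fisher's exact test. On the large-expected
branch the **asymptotic** Pearson p is the default: on the four-group
walking data this choice reproduces every published Bonferroni-adjusted
value exactly (0.0002, 6, 0.0135, 0.0002, 1.4283, 0.0242), whereas the
margin-constrained exact significance yields 1.83 instead of 1.4283 for
the positive-vs-undead pair. The exact variant remains available
(`exact_pearson=True`, and as the public `exact_pearson_p`). A minimum
expected count of exactly 5 routes to Fisher. Bonferroni multiplication is
uncapped by default (adjusted p may exceed 1, e.g. "p = 6"), with a
cap-at-one flag.

Mann-Whitney U is reported as min(U₁, U₂) — the convention under which
complete separation gives U = 0 — with the exact null distribution for
n₁·n₂ ≤ 400 and tie-free data, the tie-corrected normal approximation
otherwise. The two-group decision tree screens each sample with the
Lilliefors form of the Kolmogorov–Smirnov normality test (parameters
estimated from the data) and homogeneity of variances with Levene's test
on means, both at α = 0.05: both screens pass → pooled t-test; normality
passes but homogeneity fails → Welch; normality fails → Mann-Whitney;
n < 3 → Mann-Whitney with a warning. Note the ceiling this implies: two
independent 5 %-level normality screens pass together only ~90 % of the
time even for perfectly normal data, so the t-test branch is selected in
~88/100 seeded replicates, not more.

## Lineage-composition model

Parameters: NB cycle 55 min, GMC cycle 6.5 h, 7 GMCs present at any time,
2 siblings per GMC division. For a labelled cluster of *n* cells:
neurons = n − 1 − 7; divisions = ⌈neurons/2⌉ (odd counts arise when one
sibling has already died and been cleared); age window = [0, divisions ×
55 min]. The GMC cycle is carried as a parameter but does not enter the
bound — only the NB cycle spaces successive sibling pairs. The model is
monotone in cluster size; clusters of ≤ 8 cells carry no inferable neurons
and come back flagged.

Death staging: translocation index = nuclear/(nuclear + membrane) signal
of the cleaved reporter, in [0, 1] and gain-invariant. Stage thresholds
θ₁ = 0.3 (alive/early) and θ₂ = 0.7 (early/late) are declared defaults for
a qualitative published description; both are configurable. "Progression"
is operationalised as a strictly positive Spearman correlation between
distance-from-NB and translocation index over a lineage's dying cells
(≥ 2 dying cells required; constant ranks count as no progression).

## Synthetic data

The generators are pure functions of their specs (seed included); every
run is bit-reproducible, and sub-streams are derived from the single seed.

*Videos*: the fly is a filled ellipse (major axis = body length 2.5 mm,
minor 1.2 mm) on a uniform bright arena, with additive Gaussian pixel
noise (sd 0.02) clipped to [0, 1]. No legs, shadows, reflections or
illumination gradients — so passing tracking tests demonstrate correctness
of the geometric pipeline, not robustness to real-world imaging artefacts.
Trajectories: stationary, straight, circular, and a random walk with
Gaussian heading diffusion.

*Treadmill sessions*: a two-state Markov chain (rest→walk 0.02/frame,
walk→rest 0.05/frame at 25 fps — bouts of a few seconds, roughly the bout
statistics visible in tethered-fly recordings) drives per-frame speeds
(forward 8 ± 2 mm s⁻¹, yaw 40 ± 20 ° s⁻¹, sideways zero-mean) converted to
ball rotations through the kinematics constants; resting frames have
exactly zero rotation. The activity channel is baseline × (1 + a · drive)
with a = 0.5 and drive = walk-state convolved with a
difference-of-exponentials indicator kernel (rise 0.2 s, decay 1 s, unit
peak); the reference channel is constant. Both channels carry
multiplicative Gaussian noise (CV 0.02). The generator exports the drive
as ground truth. Because transients decay over seconds, densely spaced
bouts contaminate the percentile baseline and attenuate recovered
amplitudes by a few percent — the amplitude-recovery test therefore uses
sparse, long bouts where the baseline genuinely returns; the bias at
default bout density is visible and expected, and mirrors what happens in
real recordings with high event rates.

*Lineages*: 10–20 cells per lineage at ~3 µm spacing from the NB, per-cell
death probability 1.3/15 (so the population mean is ~1.3 dying cells per
lineage at the observed cluster-size regime), and a translocation index
that grows with distance at 0.02 /µm for doomed cells (membrane-dominant
otherwise). The generator is unconditional — real tallies of "doomed
lineages" condition on ≥ 1 dying cell — and encodes death stage only
through the reporter split, not through morphology.

*Two-group samples*: normal, shifted-normal, heteroscedastic-normal
(variance ratio 10), heavy-tailed (log-normal, σ = 1.5) and fully
separated families.

## Problem sizes

The test suite and acceptance checks run at desk scale, chosen as the
smallest sizes at which each property is statistically unambiguous:
20 seeded videos of 40 frames at 128² px for tracking recovery; 10
sessions of 60 s at 25 fps for epoch recovery; 3 sessions of 300 s for
amplitude recovery; 444 lineages for the dying-cell tally; 2,000 simulated
null tables for the exact-test level check; 100 seeded replicates per
branch of the decision tree.

## Known limitations

- No leg kinematics, gait analysis or multi-animal tracking.
- Registration is integer-pixel translation only.
- Exact tests beyond a total of 200 fall back to Monte-Carlo; p-values
  then carry sampling error ~(p/10⁵)^½.
- The lineage model treats the GMC pool as a constant 7 and assumes
  divisions are spaced by exactly one NB cycle; the GMC cycle length never
  enters the age bound.
- The synthetic generators emulate the statistical structure the analyses
  assume, not the optics of real microscopy; green tests certify the
  algorithms, not performance on real video.
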