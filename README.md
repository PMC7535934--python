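# undeadlab

Analysis pipeline for studies of programmed cell death (PCD) in the
*Drosophila* ventral nerve cord — in particular experiments in which
"undead" neurons (cells rescued from developmental apoptosis) are assayed
for function. The package covers the four quantitative legs of such a
study:

1. **Behavioural video tracking** — centroid tracking of a single
   (decapitated) fly filmed from above at 25 fps: per frame, the image is
   contrast-enhanced (CLAHE), Gaussian-smoothed (σ = 4 px), binarised, and
   the centroid of the largest connected component extracted. A fly
   *walked* when its cumulative path covers at least one body length (a
   manual T3→T2→T1 leg-order annotation can be required as a second
   criterion).
2. **Spherical-treadmill kinematics** — ball rotation rates are converted
   to body-frame speeds (1 rot s⁻¹ = 31.42 mm s⁻¹; 1 rot s⁻¹ = 360° s⁻¹)
   and frames are classified resting when the per-frame forward, sideways
   and yaw displacements are all below 0.12 mm, 0.12 mm and 5°; maximal
   runs of equal labels form walking/resting epochs.
3. **Ratiometric calcium imaging** — %ΔR/R = 100·(R − R₀)/R₀ with
   R = F_activity/F_reference (e.g. GCaMP6s/tdTomato); epoch-aligned
   averages are reported only where ≥ 4 traces overlap; per-channel
   max-normalised line profiles and circular sub-ROI traces included.
4. **Exact categorical statistics** — Pearson χ² without continuity
   correction; the expected-count rule (min Eᵢⱼ > 5 → Pearson significance,
   otherwise Fisher's exact test); exact r×c tests by margin-constrained
   enumeration (Freeman–Halton, and the exact significance of the Pearson
   statistic); uncapped Bonferroni correction (adjusted p can exceed 1);
   Mann-Whitney U reported as min(U₁, U₂); and the
   normality/homoscedasticity decision tree (Lilliefors screen → t-test /
   Welch / Mann-Whitney).

A fifth component, the **lineage-composition model**, converts a labelled
neuroblast-lineage cluster size into a bound on neuron age: a cluster of
*n* cells contains 1 neuroblast (NB), ~7 ganglion mother cells (GMCs) and
*n − 8* neurons; each GMC division yields two siblings, so the neurons
arose from ⌈(n − 8)/2⌉ divisions spaced one 55-min NB cycle apart. For the
largest observed clusters (20 cells) this bounds death initiation to within
0–5.5 h of a neuron's birth. Per-cell death *stages* are scored from a
caspase reporter as the nuclear fraction of the cleaved fluorophore, and a
lineage "displays a progression" when stage increases with distance from
the NB (positive Spearman correlation).

Every input class can be generated synthetically with known ground truth
(`undeadlab.synthio`): arena videos of an ellipse-rendered fly, two-state
Markov walk/rest sessions with kernel-convolved fluorescence coupling,
lineage snapshots with distance-graded death stages, and two-group numeric
samples.

## Worked example

The walking counts of a four-group thermogenetic activation experiment —
negative control 1/19, positive control 13/18, MARCM control 2/22, undead
neurons 9/17 — analysed with the full pairwise scheme:

```python
>>> from undeadlab import pairwise_group_comparison
>>> for r in pairwise_group_comparison([(1, 19), (13, 18), (2, 22), (9, 17)],
...                                    labels=["neg", "pos", "marcm", "undead"]):
...     print(r.notes["pair"], f"chi2={r.statistic:.1f}",
...           r.branch_taken, f"p_adj={r.p_adjusted:.4f}")
('neg', 'pos') chi2=17.6 pearson-asymptotic p_adj=0.0002
('neg', 'marcm') chi2=0.2 fisher-exact p_adj=6.0000
('neg', 'undead') chi2=10.2 fisher-exact p_adj=0.0135
('pos', 'marcm') chi2=16.8 pearson-asymptotic p_adj=0.0002
('pos', 'undead') chi2=1.4 pearson-asymptotic p_adj=1.4283
('marcm', 'undead') chi2=9.1 fisher-exact p_adj=0.0242
```

Each pair forms a 2×2 walked/not-walked table. When the smallest expected
count exceeds 5 the Pearson χ² p-value is used; otherwise Fisher's exact
test. All six raw p-values are multiplied by 6 (the family of pairwise
tests) without capping — hence the adjusted value of 6.0 for two groups
that both essentially never walked, and 1.4283 for the statistically
indistinguishable positive-control vs undead pair. The undead-neuron group
differs from its MARCM control (p = 0.0242): activating undead neurons
induces walking.

The same engine from the shell:

```sh
$ undeadlab stats chi2 --counts "[[4,2],[3,1],[2,5]]"
{
  "method": "pearson-chi2",
  "statistic": 2.9036044973544977,
  ...
}
$ undeadlab lineage compose --n 20
{
  "labelled_count": 20,
  "n_neurons": 12,
  "n_divisions": 6,
  "age_upper_min": 330.0,
  "age_upper_hr": 5.5,
  "flagged": false
}
```

Twenty labelled cells → 12 neurons from 6 divisions → the oldest neuron is
at most 6 × 55 min = 5.5 h old, bounding how early PCD is initiated.

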