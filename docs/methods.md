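# Methods

This note documents the models, statistical procedures and design choices
behind `colsen`, and what the synthetic-data generator does and does not
emulate.

## Experimental designs

Two selection regimes are represented.  The *fixed* regime propagates 10
replicate lines per panel antibiotic at a constant sublethal dose (the
ancestral IC50) for ~140 generations; over the 24-drug panel this yields 240
evolved lineages, plus 10 drug-free "adapted control" lines that serve as
the reference group for every comparison.  The *gradient* (dose-escalation)
regime uses the 12 flagged panel drugs with 96 replicate populations each;
the dose starts at the IC50 and multiplies by 1.5 every fourth transfer.

Serial transfer dilutes ~100-fold daily, so each surviving transfer
contributes log2(100) ≈ 6.64 doublings; cumulative generations are exactly
(surviving transfers) × log2(dilution).  The source protocol's 1–1.2 µl into
100 µl implies a dilution of 83–100×; the simulator fixes 100.  The fixed
regime's transfer count is not stated anywhere; 21 transfers is used as the
value consistent with 140 generations at 6.64 doublings per transfer.

## Evolution simulator

The tolerated dose of a lineage (in IC50 units) follows a minimal stochastic
gain process: one Bernoulli draw per transfer with probability
`gain_prob = 0.15` multiplies the tolerance by `gain_factor = 1.5`.  Growth
at dose d with tolerance m is Hill-type, `od = od_capacity / (1 + (d/m)^4)`
plus Gaussian noise (SD 0.05), and a population ending a transfer below
OD600 = 0.05 is extinct and stays extinct.  An escalation campaign stops at
the first transfer after which at most 10 populations survive, or before a
transfer whose dose exceeds the solubility limit.

`gain_prob = 0.15` is the calibration implied by the protocol's stated
dynamics: the ramp demands one gain per four transfers (rate 0.25), so 0.15
produces progressive attrition with a lucky minority keeping pace — stop
transfers between ~33 and ~53 (≈ 220–350 generations) and survivor doses of
~25–330× the start, matching the regime's reported generation window and
fold-increase range.  No within-transfer population genetics is modelled;
the Bernoulli increment stands in for the fixation of a resistance mutation
during one growth cycle.

## Synthetic susceptibility screen

Every line is read in every condition (each panel drug at ~half-maximal
inhibition, plus drug-free medium) in 4 technical replicates on shared
384-well plates, over 3–4 independent runs.  The generative model for an
evolved line i (adapted to A) in condition B is

    od = blank + baseline · (1 − cost_i) · (1 + effect(A,B)) · inhib(B, run) · spatial(row, col) + ε

with `effect < 0` encoding collateral sensitivity, `cost_i ∈ [0, cost_max]`
a condition-independent growth deficit, `inhib` the condition strength
(target 0.5, jittered per run, SD 0.05), `spatial` a smooth separable
row×column factor (amplitude 5%), and ε Gaussian with SD 5% of baseline.
Pairs within the selection drug's own class default to cross-resistance
(self +0.5, same class +0.2).  Optional QC failure events mimic the
screen's real failure modes: per-plate cross-contamination (a non-inoculated
well grows), per-condition overdose (inhibition drawn at 92–99%), and
per-run noisy drug-free controls.

Two layout choices matter.  Lines are scattered over the plate by a fixed
seeded re-array, and each line's four replicates sit in the four quadrants
of the sample area.  Without this, a selection group occupying contiguous
grid rows is indistinguishable from a spatial trend, and median-polish
detrending absorbs the biology; scattering (standard re-array practice)
restores identifiability.

What the generator does *not* emulate: correlated noise between replicates,
plate-edge evaporation artifacts, condition-specific noise heteroscedasticity,
carry-over between runs, and any genotype–phenotype mapping.  Passing tests
therefore demonstrate the statistical machinery under the assumed noise
model, not robustness to every artifact of real plate data.

Readings are single-timepoint ODs (the 14-h analogue).  The
`simulate_growth_curves` ensemble documents why a single endpoint suffices:
under capacity-dominated inhibition (carrying capacity log-uniform on
[0.05, 1.0], growth rate narrowly 0.9–1.05 /h) the squared correlation
between the 14-h OD and the area under the logistic growth curve exceeds
0.99, the regime the screen's validation measurements established.  With
widely varying growth rates the equivalence degrades; the ensemble emulates
the validated operating regime.

## Normalization

Three enforced stages; re-applying a stage raises rather than silently
re-running.

1. **Blank correction** — subtract each (run, plate)'s blank-well mean;
   negatives clamp to 0.
2. **Detrending** — iterative Tukey median polish (≤ 20 sweeps, tolerance
   1e−10) on log-transformed positive sample ODs per plate; the fitted row
   and column effects are divided out, zero wells pass through.  The polish
   moves the median of each effect vector into the overall term, so uniform
   plates are unchanged to 1e−9 and a 1×1 plate is a fixed point.
3. **Control scaling** — divide by the run's mean corrected OD of drug-free
   adapted-control wells; summarize each line×condition×run by the median
   over technical replicates.  Whether the original procedure normalized per
   plate or per run-batch is unstated; per-run is used (the drug-free
   controls sit on one plate per run, and detrending already provides
   within-plate comparability).

The exact published normalization lives in supplementary material that is
not reproduced here; blank subtraction → log-scale median polish →
control-ratio scaling is adopted as a faithful, testable stand-in for its
stated goals (within-plate effects removed, cross-plate comparability).

## Quality control

Three filters, applied independently (order-free) to (run, condition) units:

- **contamination**: any non-inoculated well of a plate at blank-corrected
  OD ≥ 0.05 excludes every condition measured on that plate in that run;
- **high CV**: a run whose drug-free control wells have SD/mean > 0.20 is
  excluded entirely;
- **overdose**: a condition whose adapted-control group mean falls below
  10% of the drug-free control mean (> 90% effective concentration) is
  excluded.

Threshold boundary conventions (inclusive ≥ for contamination, strict >
for CV, strict < for overdose) are fixed and unit-tested; the source states
the thresholds but not their inclusivity.  Contamination is judged on
blank-corrected (not detrended) OD because trend correction presupposes
sample wells.  With failure rates contamination 8%/plate, overdose
15%/condition, high-CV 10%/run, four runs typically shrink to ~2–3 retained
per condition, the attrition the original screen reported.

## Interaction inference

Described in the README; numerical details:

- Bootstrap resampling uses one seeded PCG64 stream per ordered pair
  (spawned deterministically from the config seed), shared by the
  sensitivity, resistance and cost tests of that pair, so the matrix is
  reproducible given (data, config).
- The add-one correction keeps Monte-Carlo p-values in (0, 1]; the
  exhaustive mode (all n^n × m^m joint index resamples, feasible to n = 4)
  omits it and can return exactly 0.  Exact zeros entering Fisher's
  combination are floored at 1/(n_bootstrap + 1).
- The 10% criterion is applied to group *means* (medians are available via
  `group_stat="median"`); the per-line summary is always the median of
  technical replicates.
- The cost control resamples each line's drug and drug-free values jointly,
  so per-line costs cancel within a resample; classification requires the
  excess deficit to clear the same 10% threshold at the same α.
- Multiple-testing correction defaults to none (matching the apparent
  original practice); Benjamini–Hochberg across pairs is available
  (`mtc="bh_fdr"`) and can only remove calls.
- Pairs with no QC-retained run (or whose runs lack a retained drug-free
  condition) are reported `untestable`, never `none`.

Operating characteristics under the study conditions (10+10 lines, 4
replicates, 3 runs, replicate SD 0.05): planted effects of −0.5 are
recovered with recall 1.0, and the full 552-pair null campaign produces no
false calls — the threshold-referenced one-sided test is conservative at
effect 0, since its null requires D* ≥ 0.10 by chance.

## Network statistics

Edges are called ordered pairs; weights are effect sizes.  Per-class
weighted out-degree averages, over the antibiotics of a source class, the
number of distinct target classes reached.  The regime-overlap statistic is
intersection-over-union of directed edge sets (intersection-over-smaller
available); "overlap" is not precisely defined in the source, and IoU is the
stricter reading.  Its randomization null redraws each network's edge count
uniformly over ordered non-self pairs (degree-preserving shuffling is
deliberately not the default: the question is whether two screens find the
*same* edges, not the same degree sequence).  Same-class depletion
cross-tabulates unordered testable pairs (same-class × interacting) with
two-sided Fisher's exact p.  Chemogenomic profiles are compared by Jaccard
distance, with interacting vs remaining pairs tested by a rank-sum test —
exact tie-aware enumeration for combined n ≤ 12, tie-corrected normal
approximation otherwise.  Antibiotics without a profile are excluded and
reported.

## Phenotype assays

- **MIC**: cutoff = blank mean + 2·SD (ddof = 1); MIC is the lowest
  concentration whose replicate-mean OD is strictly below the cutoff;
  growth everywhere yields an above-range flag, and a censored numerator
  propagates as a flagged lower bound on the fold change.  Replicates are
  aggregated by the mean (the source states 4 replicates but not the
  aggregation).
- **IC50**: linear interpolation of the replicate-averaged series at 50% of
  the drug-free OD, after a monotonicity check (tolerance 5% of the
  drug-free level); out-of-range crossings are flagged, not extrapolated.
- **Hoechst accumulation**: drop the first 15 kinetic points (75-s cadence),
  smooth OD and fluorescence with a centered moving average (window 5,
  shrinking symmetrically at the edges so straight lines pass through
  exactly), form fluorescence/OD, integrate by trapezoid, and normalize to
  the mean wild-type AUC.  Points with non-positive OD are excluded and
  logged.  The smoothing method is unstated in the source; the window is
  configurable.
- **Membrane potential**: red/green fluorescence ratios relative to the mean
  of ≥ 3 wild-type controls; groups compared by the same exact/asymptotic
  rank-sum machinery.

## Mutation convergence

Site-level convergence counts distinct (gene, position, allele) sites
carried by ≥ 2 clones — allele-aware by default, with a position-only mode,
since "shared at the single nucleotide level" does not pin down allele
identity; both the fraction of distinct sites and the fraction of mutation
records at shared sites are reported, as either denominator is defensible.
Gene-level convergence counts genes mutated in ≥ 2 clones.  The
chemogenomic overlap test is a two-sided Fisher's exact test over a gene
universe that must be supplied explicitly (documented default: 4146
protein-coding genes of the K-12 reference).  Gene-set enrichment is
upper-tail hypergeometric with BH correction.

The synthetic resequencing panel plants the study conditions exactly: 12
escalation clones × 8 mutations + 2 fixed-dose clones × 2 = 100 records
over 44 coding genes; 89 non-synonymous; three identical sites shared by
(3, 2, 2) clones (7% of records at shared sites); 13 genes (29.5%) hit in
≥ 2 clones.  Exact per-clone counts (rather than distributional means) are
used so the bookkeeping identities are deterministic.  The companion
synthetic hit set (850 of 4146 genes, containing 16 of the 44 mutated
genes) is sized so that both the ~36% overlap and its Fisher p ≈ 0.013 are
jointly realizable — the configuration consistent with the reported screen
comparisons.

## Problem sizes and reproducibility

Default analysis sizes: 12–24 antibiotic panels, 10 evolved + 10 control
lines, 4 technical replicates, 3–4 runs, 2,000–10,000 bootstrap resamples,
20,000 overlap randomizations; the full null campaign spans 552 ordered
pairs.  All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning, so every table in `results/` and
every number in `results/acceptance.json` is byte-reproducible given the
seed.

## Known limitations

The cost-control and normalization procedures are reconstructions of
supplementary material unavailable in the source text; they satisfy the
stated goals and are documented above, but are not guaranteed to be
line-for-line identical to the originals.  The evolution simulator is
phenomenological (no mutation spectrum, clonal interference, or
dose-response evolution).  The synthetic screen's noise model is Gaussian
and independent across wells.  Network headline fractions (e.g. the share
of interacting pairs) depend on the planted truth and are not estimates of
the biological network's density.
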