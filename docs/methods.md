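# Methods

## Isotope scale and derivative correction

δ¹³C is defined against the PDB standard ratio 0.01118; all mixing
arithmetic runs in atom fraction F = R/(1+R), the scale on which carbon
mass balance is linear.  Methylation adds one methanol carbon to every
fatty acid, so measured FAME δ values are corrected by carbon-weighted
mass balance in δ space, δ_PLFA = ((n+1)·δ_FAME − δ_MeOH)/n — the
convention of the correction literature.  An exact atom-fraction-space
correction ((n+1)·F_FAME = n·F_PLFA + F_MeOH) is available behind the
`correction_space` switch; at tracer-level enrichment the two differ
negligibly (relative difference < 10⁻³ at δ = 1500 ‰), but the switch
documents the choice.  The methanol δ¹³C has **no default**: it is an
instrument property the laboratory must supply, and a missing value is
a hard error rather than a silent 0 ‰.

## Two-pool mixing and design-aware scaling

For each biomarker the tracer fraction is
f = (F_sample − F_control)/(F_label − F_control), with

* F_control the control-treatment replicate mean per biomarker;
  biomarkers absent from the control fall back to the configured
  natural-abundance atom fraction (default δ = −28 ‰, a C3-dominated
  soil) and are flagged `baseline_imputed`;
* F_label the labelled residue's bulk atom fraction, assumed equal to
  the atom fraction of PLFA synthesized from it (microbes are assumed
  not to discriminate between ¹³C and ¹²C);
* f clipped into [0, 1] with flags `clipped_low` / `clipped_high`;
  excursions beyond ±0.05 additionally log a warning, since small
  negative fractions are ordinary measurement noise but larger ones
  indicate a problem.

Residue-derived C is tracer C / labelled-C fraction in non-mixture
treatments (labelled and unlabelled residue of the same species are
treated as identical substrates) and tracer C directly in mixture
sub-treatments (the labelled species' entire share is labelled).
Primed-SOM-derived C is the mass-balance remainder
C_total − C_baseline − C_plant, with C_baseline the control-treatment
mean concentration per biomarker (which collapses to the control grand
total at the whole-community level).

**Clip propagation.**  Noise can drive the remainder negative.  The
stored pools always sum exactly to the measured total: plant C is
capped at the total, and when total − plant falls below the baseline
the stored baseline is reduced to total − plant (flag `clipped_low`,
shortfall logged).  The rationale is physical — the pre-existing pool
cannot exceed what the residue-derived share leaves room for.

**Mixture assembly.**  A single mixture microcosm only traces its own
labelled species, so mixture-level pools are assembled replicate-wise
across the four sub-treatments: totals (and hence SOM) are averaged,
plant-derived C sums the four tracer contributions, and the control
baseline enters once (attributed ¼ per species in stacked reports).
Per-sample SOM is therefore undefined (NaN) for mixture sub-treatment
rows in the biomarker-level table.

## Mixture effects

The contrast is mixture mean minus the unweighted mean of the four
non-mixture treatment means (equal to the pooled mean in the balanced
design).  Inference uses a sequential (Type I) nested ANOVA — treatment
(mix vs non-mix, 1 df), then crop species nested within treatment (the
four non-mixture species plus the mixture as a fifth level, 3 df) —
against the within-cell residual.  Effects are additive unless the
treatment term is significant at α (default 0.05), then synergistic or
antagonistic by the sign of the difference.  Sums of squares below
10⁻¹² of the response scale are snapped to zero so that
exactly-replicated inputs report a no-variance case (classified
additive) instead of an infinite F from float dust.  No
multiple-testing correction is applied across responses by default; a
flag enables Benjamini–Hochberg.  Fungi:bacteria and G+:G− ratios are
computed per sample and then averaged (mean-of-ratios convention).

**Known limitation — conservative mixture test.**  Because an
assembled mixture replicate pools four microcosms, its measurement
variance is roughly a quarter of a non-mixture replicate's.  The
homoscedastic F test therefore runs conservative for the
mixture-vs-average contrast on partitioned pools: under an additive
truth its realized rejection rate is well below the nominal 5 % (the
expected treatment mean square is about half the residual mean
square).  This is a property of the assembly design, not of the noise
level; synergy calls are correspondingly cautious.  On response-level
data with independent, equal-variance replicates the test is calibrated
(verified at ~5 % over 1000 null layouts).

## Community analysis

Concentration matrices are Hellinger-transformed (square root of
relative abundances; Euclidean distance on the transform equals the
Hellinger distance), dissimilarities are Bray-Curtis, and ordination is
NMDS minimizing Kruskal stress-1.  The optimizer alternates isotonic
regression of embedded distances on the dissimilarities (primary tie
treatment: equal dissimilarities share one fitted value) with a
Guttman-transform step accepted through a backtracking line search, so
stress is monotone non-increasing within a start; the configuration is
renormalized each step because stress-1 is scale-invariant and would
otherwise drift toward collapse (a collapsed configuration is scored as
infinitely bad).  Defaults: k = 2, 20 restarts (the first start is the
principal-coordinates solution, the rest random), 300 iterations,
convergence at stress change < 10⁻⁷; deterministic given the seed.
Final coordinates are centered and scaled so the rms embedded distance
matches the rms dissimilarity.  On random matrices the resulting
stress-1 agrees with R vegan's monoMDS to ~10⁻⁵.

ANOSIM ranks all pairwise dissimilarities and computes
R = (mean between-group rank − mean within-group rank)/(M/2) with
M = n(n−1)/2, so R ∈ [−1, 1] and R = 1 at complete separation.  The
permutation p is upper-tail and includes the observed labelling,
p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm), with 999 permutations by
default — the standard ecology convention, guaranteeing p > 0.

## Synthetic experiments

The generator emulates the reference microcosm design: 13 treatments
(4 pure, 4 non-mix, 4 mix, control) × 4 replicates, 1 mg C g⁻¹ soil
added, labelled residues at 6.7 / 7.8 / 7.8 / 8.0 atom % ¹³C for
buckwheat, clover, radish and sunflower.  Group-level truth (baseline +
residue-derived + primed-SOM-derived C) is allocated to 19 biomarkers
by fixed within-group proportions (an editable table; the defaults are
a conventional soil PLFA panel, with 18:1ω9 assigned to fungi).  Each
biomarker's atom fraction is the C-weighted blend of natural-abundance
carbon and labelled-residue carbon; δ values are back-computed and
derivatized with the configured methanol δ (−40 ‰ in the preset, a
typical petrochemical methanol).  Noise is multiplicative lognormal on
concentrations (unit mean, relative SD 0.05 by default — keeps pools
positive) and additive Gaussian on δ (SD 1 ‰); everything is
deterministic given the seed.

The preset pins the noiseless summaries near the reference magnitudes:
control community 7.50 μg C g⁻¹ (1.80 / 2.20 / 0.74 / 2.36 / 0.40 for
general bacteria, G+, G−, fungi, protozoa — the three published group
values, with the remainder split so G− exceeds protozoa); average
non-mixture residue-derived C 2.73 μg C g⁻¹ with species totals 2.20 /
3.40 / 2.40 / 2.92 (scientist-chosen spread around the published mean);
primed-SOM-derived C 3.82 μg C g⁻¹ under every amendment, distributed
across groups in proportion to baseline biomass; synergy multiplier
6.34/2.73 ≈ 2.32 applied to all species' assimilation in mixtures
(1 = additive truth).  Amended noiseless totals then span 13.5–17.7
μg C g⁻¹.

**What the generator does not emulate:** per-biomarker raw data of any
real soil (the allocation proportions are conventional, not measured),
biomarker-specific isotope fractionation, chromatographic co-elution,
run-to-run IRMS drift, spatial microcosm heterogeneity, and any
time-course (a single 1-day time point, matching the design).  Passing
recovery tests therefore demonstrate correctness of the estimator
chain under the stated noise model, not field-data performance.

## Problem sizes used in tests

Unit and property tests run on toy matrices (3–20 samples) and single
simulated experiments (988 measurement rows).  The distributional
checks use 100 noisy experiments for parameter recovery (median
|relative error| of group-level residue-derived C < 10 %), 1000
full-pipeline simulations for the null classification rate, 1000
response-level layouts for F-test calibration, and 200 random matrices
for the ANOSIM null; exhaustive permutation enumeration is limited to
6-sample problems (720 relabelings).
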