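# Methods

This note documents the statistical models implemented in `proteopanel`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Data model

The central object is a proteins × samples matrix of raw label-free
protein intensities from mucosal biopsy supernatants, with a clinical
group label per sample (HC = healthy control, IBS = irritable bowel
syndrome, UC = ulcerative colitis in remission) and a per-protein protease
annotation flag. Neurophysiology data arrive as per-ganglion recordings:
total imaged neurons, responder count, and one response magnitude per
responder (spike frequency in Hz for voltage-sensitive-dye recordings,
peak ΔF/F for calcium imaging).

## Variance-stabilizing normalization (glog)

Raw label-free intensities follow an additive–multiplicative error model

    x = exp(η)·μ + ε,   η ~ N(0, σ_mult²),  ε ~ N(0, σ_add²),

so the sd of x grows with its mean. The per-sample transform
`h_s(x) = arsinh((x − a_s)/b_s)` renders the variance approximately
constant, and for large arguments differences of `h` converge to natural
log ratios. Calibration parameters `(a_s, b_s)` are estimated by
minimizing the negative profile log-likelihood

    (N/2)·log RSS  +  ½ Σ log(b_s² + (x − a_s)²),

where RSS profiles out per-protein means and the second term is the
Jacobian of the transform (without it, `b → ∞` trivially wins). The fit
is made robust against the differentially expressed minority by least
trimmed squares: after each L-BFGS fit, the 10% of proteins with the
largest residual sums are set aside and the fit repeated on the quietest
90% until the retained set is stable (max 50 rounds).

Numerical choices: scales are parametrized as `log b_s` (positivity by
construction) and box-bounded ±40 nats around their initialization
(`b_s⁰` = per-sample median intensity, `a_s⁰ = 0`) to prevent overflow;
convergence is declared on a *relative* parameter change below 1e-6 —
offsets live on the raw intensity scale (~10⁶ instrument units), so an
absolute tolerance would be instrument-dependent. A constant sample column
is a hard error (its calibration is unidentifiable).

Two deliberately separated properties: the arsinh→log asymptote (a twofold
change reads as ln 2 to <1% once `(x−a)/b > 10`) holds at *fixed*
calibration, while the *fitted* transform absorbs a pure per-sample
dilution factor into `b_s` and aligns the transformed columns — that
absorption is the purpose of the normalization, not a defect.

Downstream, glog values are divided by ln 10 so group contrasts read as
log10 abundance ratios, the unit in which protease tables are printed.

## Moderated differential expression

Per protein, ordinary least squares on the one-way three-group design
gives group means, residual variance `s_g²` and residual df `d = n − 3`.
With ~7 samples per group the variances are noisy, so they are shrunk by
empirical Bayes under a scaled inverse-χ² prior
`σ_g² ~ s0²·d0/χ²_{d0}`:

    s̃_g² = (d0·s0² + d·s_g²) / (d0 + d).

Hyperparameters are estimated by moment-matching the marginal distribution
of `log s_g²`: the mean fixes `s0²` and the excess of the variance over
`ψ′(d/2)` is inverted through the trigamma function (Newton iteration,
relative tolerance 1e-8) to give `d0`, capped at 10⁶. When the observed
scatter of log-variances is at or below pure sampling noise the prior df
is taken as the cap and `s0²` as the geometric mean of the `s_g²`, so
exactly-equal variances shrink to their common value. Zero-variance
proteins are excluded from the moment fit but still receive moderated
values.

Moderated t statistics divide each pairwise contrast by its standard error
computed from `s̃_g²` and refer to a t distribution with `d + d0` df; the
overall three-group effect uses the analogous moderated F on 2 numerator
df. Setting `d0 = 0` reproduces classical ANOVA exactly (verified to
1e-10 against an independent oracle, and against the Bioconductor
reference implementation run through Rscript).

Selection of "differential" proteins applies Benjamini–Hochberg to the
overall-F p-values and thresholds the adjusted values at α = 0.05;
pairwise p-values are reported unadjusted, as in the printed protease
table. Each protein receives an abundance-pattern class determined purely
by the signs and α-level significance of the three contrasts (up in IBS
vs both comparators; up in IBS and in UC vs HC; up in IBS vs HC only; up
in IBS vs UC only; and the mirrored "down" classes; otherwise "other").
The two "up/down vs both" classes take precedence over the single-contrast
classes.

## Panel discovery

Every subset of 2–5 candidate proteases is evaluated as a two-class
linear discriminant classifier. LDA uses the pooled within-class
covariance with equal class priors (the clinical groups are nearly
balanced) and a ridge term λ = 1e-6·trace(Σ)/p for small-sample
stability; score ties classify to the first class in label order.

Accuracy is the proportion of correct held-out predictions over 100
stratified random splits with a 2/3 training fraction (at least 2 training
and 1 test sample per class). **All panels are scored on the same split
sequence** (common random numbers), generated once from the master seed:
this makes panel comparisons paired, so leaderboard differences reflect
the panels rather than split luck, and results are independent of
evaluation order. With independent per-panel split streams, the maximum
over ~200 panels is winner's-curse biased and the ranking is dominated by
noise. Panels are ranked by mean accuracy, ties broken by smaller panel,
then lexicographic ids; the best single replicate accuracy is reported
alongside the mean.

ROC curves sweep thresholds over the unique values of a score (a raw
abundance for single proteins, the full-data-fit LDA discriminant score
for panels); the trapezoid AUC equals the Mann–Whitney pair-counting
statistic exactly, and is invariant under monotone score transforms.
Cross-validated panel scores are available as an option; full-data-fit
scores are the default.

## Neuroindex statistics

Per ganglion, `neuroindex = 100·(responders/neurons)·mean(responder spike
frequency)`, zero exactly when nothing responds; the calcium analogue
divides by the nicotine-responsive cell count instead of the imaged-neuron
count. Patient-level values are medians across the patient's ganglia
(mean available as an option).

Group comparisons: Kruskal–Wallis with tie correction, then Dunn's
all-pairwise z from mean ranks with the tie-corrected rank variance, each
p multiplied by the number of pairwise comparisons (classical
Dunn–Bonferroni). Paired pre/post drug designs use the Wilcoxon
signed-rank test, dropping zero differences, with the exact null
distribution up to 25 untied nonzero differences and the
continuity-corrected normal approximation above; an all-zero difference
vector is returned as a flagged degenerate result with p = 1. Unpaired
two-group contrasts use the Mann–Whitney test (exact for small untied
samples). Protease abundance is related to antagonist-induced percentage
decrease of the neuroindex (`100·(pre − post)/pre`) by Pearson
correlation, with the p-value from the exact t transform of r.

## Synthetic-data generators

The generators define the study conditions under which all recovery
properties are tested; their defaults are fixed and are not tuned per
experiment.

**Proteome cohorts.** 1081 proteins × 22 samples in groups of 7 HC / 8
IBS / 7 UC; 204 differential proteins with |log10 effect| uniform on
0.1–1.6, allocated to the seven pattern classes in the 4/1/3/2/4/2/1
proportions of the published 17-protease partition (largest-remainder
rounding; 204 = 12·17 splits exactly). Each class maps to a (HC, IBS,
UC) shift-multiplier triple; "single-contrast" classes use half-shifts for
the intermediate group. Baseline log10 intensities are N(6.0, 0.8) —
median ~10⁶ instrument units; multiplicative CV 0.35; additive noise floor
sd 10⁴ (~1% of the median intensity), which makes the lowest decile
additive-noise dominated, i.e. exactly the mean–variance structure the
glog transform removes. Raw draws are floored at 1 unit to keep the
matrix positive. An intensity-dependent dropout switch exists but is off
by default (the analysis assumes complete matrices). At these conditions
the BH-5% selection recovers on average ~190 of the 204 planted proteins
with observed FDR ≈ 3–5%.

**Two-class panel cohorts.** For panel-recovery studies the generator
produces 7 + 8 samples over 8 candidate proteases, 3 of them informative
with a +0.63 log10 shift (the printed effect of the strongest single
marker). Two deliberate design features:

* *Exact in-sample planting* — the noise is centered within each class
  before effects are added, so realized class means equal the planted
  values. At 15 samples the standard error of a realized standardized
  group difference is ~0.5, so without centering, "noise" candidates
  routinely carry as much within-cohort signal as planted ones and
  recovery would measure sampling luck rather than the search procedure.
* *Subtype mixture* — the IBS class is a mixture of marker subtypes: each
  IBS sample is elevated in exactly one informative protease (round-robin
  assignment). This encodes the reason multi-marker panels beat single
  markers in a heterogeneous disease: each marker covers one patient
  subset and only the complete informative set covers the class. With
  equal independent shifts instead, any informative pair separates 15
  samples perfectly and the smaller-panel tie-break would rank a pair
  above the planted triple.

The within-class sd defaults to 0.05 log10, placing the top panel's mean
split accuracy at the ~96–98% scale of the printed best panel; residual
errors come mostly from training splits that underrepresent a subtype.

**Neurophysiology.** Ganglia carry 3–15 neurons (uniform; plausible
submucous ganglion sizes — the source data do not state counts), each
responding independently with its group's responder probability (HC 0.10,
IBS 0.81, UC 0.80) and log-normal spike frequencies with group medians
(HC 0.5, IBS 3.8, UC 3.3 Hz; log-sd 0.5 chosen to match the printed
interquartile ranges). Cohort sizes default to 7/14/12 patients with 2
ganglia each. Group neuroindex medians then approach
`100·p·median-frequency` and reproduce the qualitative ordering
IBS ≈ UC ≫ HC. Paired antagonist data draw (abundance, % decrease) from
a bivariate normal with planted correlation (default −0.69, the scale of
the strongest printed protease correlation), decrease mean 55% and sd 18%;
decreases are capped at 100% (a neuroindex cannot drop below zero), and
negative draws (post > pre) occur at the Φ(−55/18) ≈ 0.1% noise rate.

All generators draw from per-operation child streams of one master seed,
so stages can be re-run independently and identical configs yield
byte-identical outputs.

## What passing tests do and do not show

The generators emulate the *statistical structure* the analyses assume —
the mean–variance relation, planted group shifts on the log10 scale,
marker-subtype complementarity, group-wise response distributions — not
real supernatant biology. They contain no peptide-level structure, no
shared-protein correlation (proteins are independent given their group
means), no missing values by default, no batch effects, and no raw
optical traces. Recovery results therefore certify the implementation and
its calibration under the stated conditions; they are not evidence about
clinical performance on real cohorts. The published per-patient
recordings behind the printed neuroindex medians are not publicly
deposited, so those specific numbers are covered by the formula-level and
property-level checks only, and the supplementary-table reproduction
requires the user to supply the published abundance matrix as TSV.

## Problem sizes in the test suite

The default test run uses: 10 full-scale proteome cohorts (1081 × 22) for
differential recovery; 20 panel cohorts (8 candidates, 210 subsets × 100
splits) for panel recovery; 5000 simulated variances for hyperparameter
recovery; 1000 null replicates per nonparametric test for type-I
calibration; 200 datasets of 100 samples for the random-classifier AUC
calibration. The whole suite completes in a few minutes on one CPU.
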