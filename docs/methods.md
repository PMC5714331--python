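# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the design decisions behind `mirpanel`. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Quality control

An assay panel arrives as an assays × samples grid of quantification
cycles (Ct) with an explicit undetected state. Three filters are applied:

* **Melting curve** (`melt_ok` input flag): failure removes the whole
  assay. Melting-curve analysis from raw fluorescence is out of scope;
  the flag is taken as input.
* **Amplification efficiency**: strict `E < 1.6` removes the assay;
  `E = 1.6` is retained. The boundary is deliberately strict-below.
* **Negative control**: a detected Ct with `Ct >= negctrl_ct − margin`
  (margin 5 cycles) is indistinguishable from background. By default this
  removes the offending *cell* (`qc.scope = "cell"`), preserving maximal
  data; `scope = "assay"` removes the whole row on any violation, the
  stricter reading. Assays whose negative control is undetected pass.

Each removed assay records exactly one primary reason, with precedence
melt > efficiency > negative control. QC is monotone: shrinking the margin
or the efficiency cutoff never removes more cells.

"Detected" after QC means a cell that is not undetected; no secondary Ct
ceiling is applied unless the reader is configured with one. The
**co-expressed set** is the assays detected in every sample; it is the
only set on which per-sample summaries are defined without imputation.

**Hemolysis.** ΔCt = Ct(miR-23a-3p) − Ct(miR-451a). miR-451a is released
by erythrocytes, so red-cell lysis lowers its Ct and inflates ΔCt. The
direction of the difference follows the common convention (target minus
marker). Samples with ΔCt > 7.0 cycles are flagged — a literature
convention, configurable. Group differences in ΔCt are tested by
Kruskal–Wallis on the NGT/IGT/T2D axis. ΔCt is invariant to adding a
constant to all Cts of a sample.

**Spike-ins.** The extraction ladder (UniSp2/4/5, 100-fold concentration
steps) should show consecutive spacing of log₂100 ≈ 6.64 cycles at
efficiency 2; deviations beyond a tolerance (default 1 cycle) warn. The
reverse-transcription spike-in (UniSp6) should sit within a band (default
±2 cycles) of the cohort median. Absent spike-ins skip their check with a
log notice.

## Global-mean normalization

Per sample, GM_s is the arithmetic mean Ct over the co-expressed set, and

    NRQ(a, s) = 2^(GM_s − Ct_{a,s}),   log-NRQ stored in base 10.

The exponent base stays 2 (one PCR cycle ≈ one doubling); the reporting
log base is a display choice (log₁₀ default, log₂ available). Undetected
cells stay undefined. Algebraic consequences used as test identities: the
per-sample sum of log₂ NRQ over the co-expressed set is exactly 0, and
NRQ is invariant to adding a constant to all Cts of a sample.

## Normalizer stability

The stability score follows the model-based variance-decomposition idea of
the NormFinder family. On log₂-scale quantities y for k candidate genes
(any per-sample affine shift cancels):

1. The sample effect is estimated as the per-sample mean over the k real
   candidates, β̂_j; residual values z = y − β̂.
2. Per gene i and group g with n_g samples, the naive residual mean square
   s_ig has expectation (1 − 2/k)σ²_ig + Σ_l σ²_lg / k², so the intragroup
   variance is recovered as σ̂²_ig = (s_ig − Σ̂σ²_g/k²)·k/(k − 2) with
   Σ̂σ²_g = Σ_i s_ig · k/(k − 1); negative estimates truncate at 0
   (this needs k ≥ 3, enforced).
3. The intergroup deviation d_ig is the gene-group mean of z centered
   across groups. Its prior variance γ² is estimated by method of moments
   from Σd² over the real candidates, truncated at 0, and d is shrunk by
   γ²/(γ² + σ̂²_ig/n_g).
4. Stability value = mean over groups of |d̃_ig| + sqrt(σ̂²_ig/n_g);
   lower is more stable. The standard-error term uses the *unshrunk*
   sampling variance of the group difference so that intragroup variance
   still ranks candidates when γ̂² truncates to zero (with no group
   effects the shrinkage factor is 0 and a shrunk-SE variant would score
   every candidate 0, losing all resolution).

Ungrouped mode scores sqrt(σ̂²) from the same ensemble decomposition.
Grouped mode over the three diagnostic groups is the default.

The per-sample mean over the co-expressed set enters as the
pseudo-candidate `"global_mean"`; the candidate-set average that defines
the sample effect always excludes it, so single-assay scores are unchanged
by its presence. Note a structural consequence: when the candidate set
*is* the co-expressed set, the pseudo-candidate equals the estimated
sample effect identically, its residuals are zero, and its stability is
exactly 0 — the global mean is then the most stable candidate by
construction, which is precisely the argument for global-mean
normalization on such panels. A candidate that is constant across all
samples (in the model's sense) also scores exactly 0.

## Rank statistics

Average ranks for ties everywhere. Kruskal–Wallis uses the tie-corrected H
with a χ² reference on k − 1 df (all-identical data is a degenerate H = 0,
p = 1, not an error). Dunn's post hoc test uses pooled-rank means,

    z = (R̄_g − R̄_ref) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_g + 1/n_ref)),

two-sided normal p, adjusted over the requested comparison family —
Bonferroni by default (the common reading of "Dunn's multiple comparison
test"), Holm and Šidák available. The reference group is a parameter,
never hard-coded (detection analyses compare vs NGT; correlation-structure
analyses vs IGT). Spearman correlation on a constant vector is undefined:
the kernel returns NaN with an explicit warning rather than silently 0.

Correlation-structure diagnostics operate on raw Ct values within group
(rank-based statistics make the sign convention immaterial up to a global
flip); reversed Ct (negated) is used wherever "quantity" semantics are
reported, e.g. the global-quantity trend against OGTT/HbA1c. Per-miRNA and
pairwise correlations are computed on the co-expressed set — the only set
defined for all samples.

## Differential expression and clustering

Two-sided unpaired t tests on log-NRQ per assay and contrast; pooled-
variance Student t by default (matching the era-typical "unpaired t
test"), Welch optional. Significance categories: p ≥ 0.05 n.s.;
< 0.05 *; < 0.01 **; < 0.001 *** — boundaries exact. No correction across
miRNAs by default; that is a deliberate fidelity choice (the discovery
analysis this package reproduces used raw p < 0.05), and a BH-FDR flag is
provided for modern use, off by default. The IGT umbrella contrast pools
the NP and P subgroups. The signature is the union of assays significant
in at least one contrast.

Group clustering averages log-NRQ per group over the signature miRNAs and
clusters the four group vectors (Euclidean distance, average linkage;
both configurable — the choice is not dictated by the analysis being
reproduced). Signature assays with any undetected cell among the clustered
samples are excluded from the profiles: detection censoring means an
undetected cell is a *low* value, so a mean over the detected subset is
biased upward exactly in the groups where the assay is low, corrupting
group distances. This exclusion measurably stabilizes the recovered
topology on synthetic cohorts (see the decision notes in the test for the
progressor-clustering pattern). The BMI stratification check re-runs the
same t battery with covariate strata as groups.

## Clinical statistics

* **ANOVA from summaries**: SS_between = Σ nᵢ(meanᵢ − grand)²,
  SS_within = Σ(nᵢ−1)sdᵢ²; exactly equivalent to raw-data one-way ANOVA
  when summaries are exact (oracle-tested). Recomputation from a printed
  table is compared at the table's printed precision, since the inputs
  are rounded.
* **Fisher r×c**: complete enumeration of tables with the observed
  margins; p sums multivariate hypergeometric probabilities ≤ that of the
  observed table (ties within 1e-10 relative counted as extreme); no
  mid-p. All-zero margins are dropped first; an internal cap (~5·10⁶
  candidate tables) guards the enumeration.
* **HOMA-IR**: `conventional` = glucose(mg/dL) × insulin(mU/L)/405, the
  standard definition; `paper` = glucose(mg/dL) × insulin/22.5, a variant
  that appears verbatim in some clinical methods sections. They differ by
  exactly the mg/dL→mmol/L factor 18. Synthetic clinical data use the
  conventional form.
* **Test routing** for the summary table: Kruskal–Wallis when any group's
  absolute sample skewness exceeds 1 (a pragmatic quantitative stand-in
  for the qualitative "skewed distribution" criterion), ANOVA otherwise.
* **Correlation map**: Spearman per (signature miRNA, covariate) over all
  samples with both values; by default only miRNAs with ≥ 2 significant
  (p ≤ 0.05) correlations are retained, mirroring the usual reporting
  filter; the filter is configurable.

## Synthetic cohort model

The generator emulates the data structure the analysis assumes, with one
latent factor — the minimal structure that reproduces every qualitative
pattern of interest (global shifts, weakened co-regulation, slope
attenuation). That is a modeling choice, not a claim about biology.

    Ct[a, s] = μ_a + shift_{g(s)} + λ_{a,g(s)}·f_s + δ_{a,g(s)} + ε_{a,s}

* `f_s ~ N(0, 1)`: per-sample global miRNA concentration (cycles).
* `μ_a`: abundance profile — 90 assays Uniform(20, 34) cycles (a clean
  core) and 89 assays Uniform(34.5, 37.5) (borderline at the detection
  limit). The bimodal profile makes the default cohort reproduce the
  realistic detection split: ≈160 of 179 assays detected per sample and a
  co-expressed core of ≈90–110 assays. A single uniform band well below
  the LOD produces no censoring at all and was rejected for that reason.
* `shift_g`: additive per-group Ct shift, default 0 / −0.7 / −0.7 / −0.9
  cycles for NGT / NP-IGT / P-IGT / T2D (negative = more circulating
  miRNA with disease progression).
* `λ_{a,g} ~ N(1, loading_sd_g²)` with loading SDs 0.2 / 0.6 / 0.6 / 0.3:
  the inflated IGT dispersion weakens miRNA–global-mean and miRNA–miRNA
  correlation specifically in IGT. Designated coupling assays (default
  one, `sim-miR-27a-3p`) have λ fixed to per-group values 1.0 / 0.6 / 0.3
  on the NGT/IGT/T2D axis, so the within-group OLS slope of assay Ct on
  global-mean Ct recovers those coefficients.
* `δ_{a,g}`: injected differential effects in cycles; default a 13-assay
  block concentrated in NP-IGT (±0.5–1.5 cycles, 2 up / 7 down), two
  shared IGT effects and two T2D effects.
* `ε ~ N(0, 0.4²)` cycles residual noise; detection ceiling 37 cycles
  (Ct above it becomes undetected); negative controls sit ≥ 6 cycles
  above the ceiling for passing assays. A configurable handful of assays
  fail QC (3 low-efficiency, 2 multi-melt, 2 near-negative-control) so
  the QC stage is exercised by default.
* Group sizes default 9 / 4 / 5 / 9 (NGT / NP-IGT / P-IGT / T2D) and are
  config-driven, never hard-coded, because published splits of the IGT
  subgroups are reported inconsistently across sources.
* Clinical covariates are drawn per group from the scales of a typical
  progression-cohort baseline table; OGTT 2-h glucose and HbA1c are
  additionally linked to f_s (−12 mg/dL and −1.8 mmol/mol per cycle of f,
  i.e. more global miRNA ⇒ higher glycemic burden), so the
  global-quantity trend diagnostic has signal to recover.
  Microalbuminuria is log-normal (strongly skewed) to exercise the
  Kruskal–Wallis routing. HOMA-IR is computed from the drawn glucose and
  insulin with the conventional formula. Hemolysis contamination
  (a −4-cycle miR-451a shift) is off by default and applied to named
  samples when configured.

All randomness flows from a single `numpy` generator seeded by the
config; identical seed + config gives bit-identical cohorts. A
`truth_table` exposes the injected effects, coupling slopes and shifts
for parameter-recovery tests.

**What the generator does not emulate:** inter-plate calibration and batch
structure, assay-specific efficiencies below the doubling ideal in the Ct
model itself, heavy-tailed or correlated residuals, multiple latent
factors, and the identity of real miRNAs (assay names are opaque ids).
Passing recovery tests therefore demonstrates that the pipeline's
machinery recovers the structure this model encodes at realistic sizes and
noise — not that any particular real miRNA list would be reproduced.

## Problem sizes and operating points used in verification

Recovery checks run the full pipeline on the default 179 × 27 cohort.
Replicate counts (25–100 per check) keep the suite and the acceptance
script fast while leaving binomial noise well inside the asserted margins.
Two checks use purpose-built operating points rather than the generator
defaults, both sized by explicit power arguments:

* **Global-shift ordering**: with within-group global-mean SD of 1 cycle
  (the latent factor) and n = 9, the default 0.7/0.9-cycle shifts give
  pairwise z ≈ 1.5 — a per-replicate ordering of group means cannot then
  be demanded at a 95% rate; the package still reports the trend rates
  under defaults. The ordering recovery test injects 1.5/2.0-cycle shifts
  (pairwise z ≈ 3.2).
* **Progressor clustering**: the shared P-IGT/T2D block uses ±2.0-cycle
  effects on 6 assays against a 9-assay NP-IGT block at ±1.5, a scenario
  in which the two profiles are unambiguously close.

## Known limitations

* The stability score is a NormFinder-*style* decomposition as specified
  above, not a bit-compatible reimplementation of any released tool.
* Fisher r×c is exact but enumerative; large tables need the (not
  implemented) network algorithm and raise instead.
* The raw-p signature inflates with panel size by design (no multiplicity
  correction); use the FDR flag when the goal is error control rather
  than fidelity to the reproduced analysis.
* Group-profile clustering drops censoring-affected assays; with extreme
  censoring the signature could shrink to nothing and the stage errors.
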