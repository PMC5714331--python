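# mirpanel

Quality control, global-mean normalization and group statistics for
circulating-miRNA RT-qPCR panels, built for small clinical cohorts profiled
on fixed serum/plasma panels (~180 assays) across diagnostic groups — the
motivating use case is a type-2-diabetes progression cohort with normal
glucose tolerance (NGT), impaired glucose tolerance split into
non-progressors and progressors (NP-IGT / P-IGT), and newly diagnosed
diabetes (T2D).

## What it computes

**QC.** Assays are removed when the melting curve is out of specification,
when amplification efficiency E < 1.6, or when a measured Ct comes within 5
cycles of the assay's negative control. Detection is summarized per sample;
the *co-expressed set* is the assays detected in every sample. Hemolysis is
monitored as ΔCt = Ct(miR-23a-3p) − Ct(miR-451a) (miR-451a is abundant in
erythrocytes); RNA spike-ins check extraction (UniSp2/4/5, a 100-fold ladder
with expected spacing log₂100 ≈ 6.64 cycles) and reverse transcription
(UniSp6).

**Normalization.** Per sample the global mean GM_s is the arithmetic mean Ct
over the co-expressed set, and each assay's normalized relative quantity is

    NRQ(a, s) = 2^(GM_s − Ct_{a,s}),

stored log-transformed (log₁₀ by default). By construction the log₂ NRQ sum
over the co-expressed set is 0 in every sample. The suitability of the
global mean as normalizer is scored with a model-based
variance-decomposition stability value (NormFinder-style: intragroup
variance plus shrunk intergroup bias, lower = more stable), with the global
mean entered as a pseudo-candidate next to every individual assay.

**Co-regulation diagnostics.** Per diagnostic group: Spearman correlation of
each co-expressed miRNA with the global mean, the full pairwise Spearman
map, Kruskal–Wallis with Dunn's post hoc on the per-miRNA correlation
distributions, the Spearman trend of the reversed-Ct global mean against
clinical covariates (OGTT 2-h glucose, HbA1c), and per-group OLS slopes of a
single assay's Ct on the global-mean Ct (the "local vs global" coupling
diagnostic; attenuation of the slope means the assay decouples from the
global miRNA pool).

**Differential expression.** Two-sided unpaired t tests on log-NRQ over the
contrast lattice IGT/NP-IGT/P-IGT/T2D vs NGT plus NP vs P within IGT, star
categories at p < 0.05/0.01/0.001, no multiple-testing correction by default
(an optional BH-FDR flag exists). The union of significant assays forms the
signature used for hierarchical clustering of the four group-mean profiles
(Euclidean, average linkage; both configurable).

**Clinical statistics.** One-way ANOVA reconstructed exactly from printed
group means/SDs/sizes, an exact conditional Fisher test for r×c tables by
complete enumeration, HOMA-IR in two unit conventions, a skewness-routed
ANOVA/Kruskal–Wallis summary table, and the signature-miRNA × clinical
covariate Spearman map.

**Synthetic cohorts.** `mirpanel.simulate` generates full cohorts (Ct
matrix, QC metadata, spike-ins, annotations with Table-1-scale clinical
covariates) from a latent-factor model with group-dependent global shifts,
loading dispersion, injected differential effects, detection-limit
censoring and hemolysis — with a machine-readable ground truth for
parameter-recovery testing. See `docs/methods.md` for the model.

## Worked example

```python
from mirpanel import (
    SyntheticConfig, generate_cohort, apply_assay_qc,
    global_mean, nrq, stability_scores, run_contrasts, select_signature,
)
import pandas as pd

cohort = generate_cohort(SyntheticConfig(seed=1))          # 179 x 27 panel
filtered, report = apply_assay_qc(cohort.ct, cohort.qc_metadata)
print(len(report.coexpressed_set))                          # 95
gm = global_mean(filtered, report.coexpressed_set)
m = nrq(filtered, gm, coexpressed_set=report.coexpressed_set)

idx = [filtered.assay_index(a) for a in report.coexpressed_set]
values = pd.DataFrame(-filtered.ct[idx, :],
                      index=report.coexpressed_set,
                      columns=filtered.sample_ids)
ranked = stability_scores(values, [a.group3 for a in cohort.annotations])
print(ranked[0].candidate_id)                               # 'global_mean'

signature = select_signature(run_contrasts(m, cohort.annotations))
print(len(signature))                                       # 53
```

The same run from a shell:

```bash
mirpanel simulate --out cohort/ --seed 1        # writes ct.tsv, annotations.tsv, ...
mirpanel run --ct cohort/ct.tsv --annotations cohort/annotations.tsv \
    --qc cohort/qc_metadata.tsv --out results/ --seed 1
```

which logs each stage and prints a JSON summary — on this seed: 161.5
assays detected per sample on average, 95 co-expressed assays,
`global_mean` as the most stable normalizer candidate, mean per-miRNA
correlation with the global mean of 0.92 / 0.81 / 0.88 in NGT / IGT / T2D
(the deliberately weakened co-regulation in IGT), and a 53-miRNA signature.
All tables land in `results/` as tab-delimited text plus a Newick group
dendrogram and a `manifest.json` with the fully resolved configuration.

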