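# Methods

## The stratification model

`recurstrat` treats a bulk expression cohort as a mixture of four
transcriptional states along a progression axis: normal brain (Class 1),
a proliferative primary-tumor core (Class 2), a transitional state with
partial loss of lineage identity and emerging immune/ECM signaling
(Class 3), and a recurrence-adapted aggressive state marked by immune–ECM
remodeling and loss of proneural lineage markers (Class 4). The pipeline
does not model these states generatively on real data; it orders samples
along two empirical composite axes and cuts them:

* the **Tumor Score (TS)** — mean z-scored expression of
  tumor-upregulated genes minus that of tumor-downregulated genes, from
  the tumor-vs-normal contrast;
* the **Recurrence Score (RS)** — the analogous composite from the
  recurrent-vs-primary contrast.

Averaging tens of signature genes shrinks per-gene noise by roughly
1/√G, which is what makes the per-sample scores stable enough to cut.
Scores are always computed on z-standardized values; by default the
per-gene mean and standard deviation (n−1 denominator) come from **all**
samples of the scored matrix. A reference-based alternative
(standardize against the normal group only) is exposed via
`zscore_standardize(..., reference_samples=...)`, since the choice is a
genuine degree of freedom: all-sample standardization makes scores
cohort-composition-dependent but needs no trusted reference group. RS is
computed for every sample including normals, but the classifier never
consults RS for a Class-1 assignment.

## Differential expression

Contrasts are two-group comparisons on log2 expression. Fold change is
the difference of group means on the log2 scale (identical to the log of
the ratio of geometric means, so a linear-scale threshold of 1.5
translates to |log2FC| ≥ log2 1.5 ≈ 0.585). A gene is called significant
iff |log2FC| ≥ log2(1.5) (inclusive bound) **and** BH-adjusted q < 0.05
(strict bound); the two boundary conventions are fixed so results are
bit-reproducible.

The default per-gene statistic is the **pooled-variance (Student) t**.
The alternative, Welch's unequal-variance t (`statistic="welch"`), is
preferable when group variances genuinely differ, but with a reference
group of only ~5 samples its Satterthwaite degrees of freedom collapse to
roughly the small group's size (≈4 here), and after multiplicity
correction the power loss is severe — in this design it cuts marker-panel
recovery from ~100% to ~60%. On a common log2 scale after quantile
normalization, approximate homoscedasticity is a reasonable default
assumption, so the pooled test is the default and Welch remains a
selectable option. Genes with zero within-group variance get a variance
floor of 1e-12 (flagged in the output); a gene constant everywhere yields
t = 0, p = 1.

BH adjustment implements the step-up rule directly
(q(i) = min over j ≥ i of p(j)·m/j, capped at 1) rather than delegating,
so its output is bit-identical to the definition; it is cross-checked
against statsmodels in the tests.

## Preprocessing

* **Filtering** keeps genes with across-sample median ≥ 1.0 log2 units
  and sd ≥ 0.1 (both config-exposed; the defaults are deliberately mild —
  they drop only genes that are essentially unexpressed or constant).
  Filtering runs before quantile normalization; running it after is
  possible via the library API and can change results slightly.
* **Quantile normalization** maps every sample onto the mean empirical
  distribution. Tie dialect (fixed because vendors differ): tied values
  within a sample receive the mean of the reference values at the rank
  positions they occupy. The transform is idempotent on tie-free data.
  Array-specific background correction is not implemented.
* **PCA variance fractions** are a QC readout only (samples as
  observations, genes centered but not scaled, since all genes share the
  log2 scale after normalization). They feed no downstream decision.

## Threshold fitting

"Low/high TS" and "low/intermediate/high RS" are operationalized as
data-driven cuts: 2-means on all TS values gives τ_TS (midpoint of the
two centroids); 3-means on the RS values of tumor-like samples gives
c_low and c_high (midpoints of adjacent centroids). The 1-D k-means is
solved **exactly** by dynamic programming over the sorted values
(Ckmeans.1d.dp-style, O(kn²)). This matters: cohorts are heavily
imbalanced (the proliferative class dominates), and Lloyd iterations from
quantile seeds reliably place two centroids inside the majority cluster
and merge the transitional and recurrence-adapted states — a local
optimum the exact solver provably avoids. The DP is deterministic and
permutation-invariant. Boundary ties go to the higher (more
tumor-like / more recurrence-adapted) class, a conservative convention
for a screening framing. Fixed user-supplied thresholds
(`tau_ts`/`c_low`/`c_high` in the config, or CLI flags) bypass fitting
entirely. With fewer than three tumor-like samples the RS cuts fall back
to tertiles, with a warning.

How the original low/intermediate/high boundaries were drawn is not
recoverable; the data-driven rule is this package's own operationalization
and validation is therefore by latent-class recovery on synthetic
cohorts, not by reproducing any published class counts.

## The synthetic cohort generator

The generator emulates the study design, not any particular assay:

    x[g, s] = mu_g + effect(panel(g), class(s)) + eps,  eps ~ N(0, sigma²)

with mu_g ~ N(7, 2²) floored at 0 (log2-intensity-like baselines).
Defaults (all config-exposed, chosen once as plausible for log2 bulk
expression):

| parameter | default | meaning |
|---|---|---|
| n_normal / n_primary / n_recurrent | 5 / 154 / 13 | cohort design |
| n_genes | 5000 | total genes, 250 in panels |
| panel_sizes | 50 each | five marker panels |
| delta_tumor, delta_recurrence | 2.0 | full additive effects, log2 units |
| transitional_fraction_of_effect | 0.5 | Class-3 partial effects |
| sigma | 0.5 | residual noise sd, log2 units |
| primary_state_fractions | 0.7 / 0.2 / 0.1 | Classes 2/3/4 within primary |
| recurrent_state_fractions | 0.2 / 0.8 | Classes 3/4 within recurrent |

Effects by panel: neuronal +Δ_tumor in Class 1 only; proliferative
+Δ_tumor in Classes 2–4; transitional ECM +0.5·Δ_rec in Classes 3–4;
recurrence immune/ECM +0.5·Δ_rec in Class 3 and +Δ_rec in Class 4;
proneural −0.5·Δ_rec in Class 3 and −Δ_rec in Class 4. Panel gene lists
begin with canonical marker symbols (GRIN1, SYN2, … / MYBL2, TOP2A, … /
HAS1, COL6A3 / CCL18, CD209, … / OLIG1, OLIG2, …) and are padded with
synthetic names. Latent classes are apportioned within groups by largest
remainder (deterministic), and recurrent samples are deliberately *not*
all Class 4, so the RS stratification is non-trivial. A fixed seed gives
bit-identical cohorts.

What the generator does **not** emulate: count noise (no negative
binomial), batch effects, within-class continuous gradients,
gene–gene correlation beyond the shared class effect, and realistic
signature sizes (real contrasts yield thousands of genes, the simulation
a few hundred). Passing recovery tests therefore demonstrates that the
pipeline's logic is correct and powerful under its own assumptions — not
that real cohorts will separate this cleanly.

## Evaluation conventions

Latent-class recovery is summarized by the confusion matrix, accuracy,
per-class recall and the adjusted Rand index (permutation-model
expectation correction). Two degenerate conventions are fixed: identical
single-class partitions score ARI 1.0 (the correction's denominator
vanishes there), and in noise-stress sweeps a replicate whose contrasts
yield no significant gene at all — so no signature and no classification
can be built — counts as accuracy 0 rather than being dropped, since
silently excluding failed replicates would overstate robustness.

## Problem sizes

The test suite and the acceptance script run the full default design
(5000 genes × 172 samples); recovery and DE-power summaries use ten
replicate cohorts per condition, which keeps the whole suite under half a
minute while leaving Monte-Carlo standard errors far below the margins
being tested. Marginal-recovery checks of the generator itself enlarge
groups to 100–500 samples so 3-standard-error boxes are tight.

## Known limitations

* The class boundaries are fitted per cohort; scores and classes are not
  transferable across cohorts without refitting (or freezing thresholds).
* With ~5 reference samples, any per-gene test is fragile; the pooled
  test buys power at the price of a homoscedasticity assumption.
* The enrichment universe defaults to the post-filter gene list of the
  analyzed matrix; curated knowledge bases use different (proprietary)
  universes, so p-values are not comparable across tools.
* No survival modeling, network reconstruction or pathway annotation is
  included; the shipped EMT/drug-resistance GMT is a synthetic
  illustration, not curation.
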