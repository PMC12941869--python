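# recurstrat

Expression-based stratification of glioblastoma (GBM) cohorts into four
transcriptional states, with a synthetic-cohort generator for end-to-end
validation.

GBM is an aggressive primary brain tumor with near-universal recurrence,
and recurrent tumors are transcriptionally distinct from the primary
disease. `recurstrat` implements a simple, auditable stratification of
bulk expression cohorts containing normal brain, primary-tumor and
recurrent-tumor samples:

1. **Differential expression.** Two-group contrasts (tumor vs normal,
   recurrent vs normal, recurrent vs primary) on log2 expression, with a
   per-gene two-sample t-test, Benjamini–Hochberg FDR control, and a
   significance call requiring fold change ≥ 1.5 **and** FDR < 0.05.
2. **Signatures.** The up- and down-regulated genes of a contrast form a
   signature (up, down).
3. **Composite scores.** With z-standardized expression z(g, s), the
   **Tumor Score** and **Recurrence Score** of sample *s* are

   ```
   TS(s) = mean_{g ∈ up_TvN}  z(g,s) − mean_{g ∈ down_TvN}  z(g,s)
   RS(s) = mean_{g ∈ up_RvP}  z(g,s) − mean_{g ∈ down_RvP}  z(g,s)
   ```

   built from the tumor-vs-normal (TvN) and recurrent-vs-primary (RvP)
   signatures respectively.
4. **Hierarchical classification.** TS separates **Class 1 (Normal-like)**
   from tumor-like samples; among tumor-like samples, RS distinguishes
   **Class 2 (Primary Tumor—Proliferative Core)**, **Class 3 (Primary
   Tumor—Transitional)** and **Class 4 (Recurrence-Adapted (Aggressive))**.
   Thresholds are fitted by exact one-dimensional k-means (dynamic
   programming), or supplied as fixed cut points.

The package also provides quantile normalization, gene filtering, PCA
variance QC, disjoint Venn-region partitioning of up to five gene sets,
and a right-tailed Fisher (hypergeometric) over-representation test.

Because matched public cohorts with recurrence annotation are small and
heterogeneous, everything is validated against a **synthetic cohort
generator** that emulates the study design (5 normal / 154 primary / 13
recurrent samples by default): five marker panels (neuronal/synaptic,
cell-cycle, transitional ECM, immune/ECM recurrence, proneural) receive
additive class effects on the log2 scale with Gaussian noise, and every
sample carries a latent class label the pipeline tries to recover.

## Worked example

```python
from recurstrat import run_pipeline

result = run_pipeline({"seed": 1})
m = result.model
print(f"tau_ts = {m.tau_ts:.3f}, c_low = {m.c_low:.3f}, c_high = {m.c_high:.3f}")
print(result.report["by_group"])
print("accuracy:", result.recovery.accuracy, " ARI:", result.recovery.ari)
```

prints

```
tau_ts = -3.065, c_low = 0.106, c_high = 2.199
class_id   1    2   3   4
group
normal     5    0   0   0
primary    0  108  31  15
recurrent  0    0   3  10
accuracy: 1.0  ARI: 1.0
```

Reading: the fitted TS threshold (−3.065) cleanly splits the 5 normal
samples (very negative TS) from the 167 tumor samples; the two RS cut
points split the tumor-like samples into proliferative-core (low RS),
transitional (intermediate) and recurrence-adapted (high RS) states. The
cross-tabulation shows the recovered structure: all normals are
Normal-like, primary tumors spread over Classes 2–4, and recurrent tumors
occupy only Classes 3–4. Against the generator's latent labels this run
recovers every sample exactly (accuracy and adjusted Rand index 1.0). The
signatures behind the scores used 52 up / 51 down genes (TS) and
82 up / 50 down genes (RS) in this run.

The same chain is available from the shell:

```bash
recur-strat simulate --out cohort/ --seed 1
recur-strat run --config config.yaml --out results/
```

with a YAML config such as

```yaml
seed: 1
simulation:            # omit and set paths: {expression, annotation} for real data
  sigma: 0.5
thresholds:
  fc_threshold: 1.5
  fdr: 0.05
```

`data/emt_drug_resistance.synthetic.gmt` ships two small *synthetic,
illustrative* gene lists (they are not curated resources) for exercising
the overlap and enrichment commands.

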