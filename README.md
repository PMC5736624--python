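# methstrat

DNA-methylation outcome stratification for juvenile myelomonocytic
leukemia (JMML) cohorts.

JMML is a rare pediatric Ras-pathway-driven myeloproliferative disorder
with sharply divergent outcomes: some patients resolve spontaneously,
others relapse quickly even after stem-cell transplantation. Genome-wide
DNA methylation stratifies such cohorts into **low / intermediate / high**
methylation clusters whose 4-year event-free survival differs strongly,
with the lowest-methylation group behaving most like healthy controls.
`methstrat` implements that entire analysis as a tested, reproducible
pipeline, together with a synthetic-cohort generator so every stage runs
without access to patient data.

## What it computes

Given a probes × samples β-value matrix (β ∈ [0, 1], the fraction
methylated per CpG) the pipeline performs:

1. **Probe filtering** — drop SNP-overlapping, multi-mapping and
   sex-chromosome probes and any probe with detection *p* > 0.01 in at
   least one sample; convert β ↔ M = log₂(β / (1 − β)) for linear-model
   testing.
2. **Cluster discovery** — restrict to probes with across-sample
   SD > 0.25 (or a top-fraction mode), cluster samples with Ward's
   minimum-variance method on Euclidean distances, cut the tree at k = 3
   and order clusters by mean methylation (low → high).
3. **Validation classification** — assign independent samples to the
   discovery clusters by minimum Euclidean distance to the cluster
   centroids (per-probe mean β).
4. **Signature distillation** — rank probes by *typicality*
   (Σ over samples of the squared deviation from the sample's own cluster
   centroid), re-classify the validation cohort with the top-k probes for
   k = 5, 10, …, 200, and count disagreements with the full-signature
   calls as errors.
5. **Outcome statistics** — per-cluster event proportions with exact
   Clopper–Pearson binomial CIs; logistic regression with
   likelihood-ratio tests (univariable and multivariable); 2×2 odds
   ratios with profile-likelihood CIs; Freeman–Halton exact tests for
   r×c tables; Kaplan–Meier curves.
6. **Differential methylation / expression** — empirical-Bayes moderated
   t-tests (variance shrinkage s̃² = (d₀s₀² + d s²)/(d₀ + d)) on M-values
   and on log₂(TPM + 1), with the p < 0.05 & |Δβ| ≥ 0.1 call rule,
   promoter projection (TSS −1.5 kb / +1 kb, strand-aware) and gene-list
   overlap.
7. **Paired-methylome concordance** — bismark-coverage parsing, the
   ≥ 10-read coverage filter, Lin's concordance correlation coefficient
   ρ_c = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²), and variable-site Ward
   clustering for pilot designs with paired CD14⁺ / unselected samples.

## Worked example

```python
from methstrat.synthetic_data import SimConfig, generate_cohort
from methstrat.clustering import fit_cluster_model
from methstrat.outcome_stats import cluster_event_summary, logistic_fit_formula
import pandas as pd

disc = generate_cohort(SimConfig(seed=1))           # 15/11/13 patients + 22 controls
model = fit_cluster_model(disc.patient_beta)         # SD>0.25 probes, Ward, k=3
events = disc.samples.loc[model.labels.index, "event_4yr"]
print(cluster_event_summary(model.labels, events)[["n", "events", "pct",
                                                   "ci_low_pct", "ci_high_pct"]])
tab = pd.DataFrame({"cluster": model.labels, "event": events})
print("cluster LRT p =", logistic_fit_formula(tab, "event", ["cluster"]).lrt_p["cluster"])
```

prints

```
               n  events  pct  ci_low_pct  ci_high_pct
cluster
low           15       1    7           0           32
intermediate  11       5   45          17           77
high          13       8   62          32           86
cluster LRT p = 0.003904856726251217
```

i.e. the three recovered clusters carry event proportions 1/15, 5/11 and
8/13 with their exact 95% binomial intervals, and the cluster factor is
associated with the 4-year event at p ≈ 0.0039 by likelihood-ratio test.

The same workflow runs from the shell:

```bash
methstrat run --outdir run1 --seed 1          # full pipeline + report table
methstrat simulate --outdir sim --seed 1      # just the synthetic inputs
methstrat cluster --beta sim/beta_discovery.tsv --out model.json
methstrat ccc --a s1.cov --b s2.cov --min-reads 10
```

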