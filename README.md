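# lncconsensus

Consensus analysis of long non-coding RNA (lncRNA) expression in bulk
tumour transcriptomes. Bulk RNA-seq of breast cancers shows that lncRNA
expression alone separates tumours into their intrinsic molecular
subtypes (basal-like, luminal A/B, ...), but signatures derived from a
single cohort reproduce poorly across cohorts — partly because each bulk
sample is a mixture of malignant cells with stromal and immune
infiltrate, and lncRNAs expressed by the microenvironment masquerade as
tumour signatures. `lncconsensus` is for computational biologists who
want to run, test or extend that style of analysis: it provides the full
pipeline as a library plus CLI, and a synthetic-cohort generator with
known ground truth so every stage is verifiable.

## What it computes

* **Consensus NMF subtype clustering.** The filtered lncRNA FPKM matrix
  V (genes × samples) is factorized as V ≈ WH with W, H ≥ 0 by
  multiplicative updates for the generalized Kullback–Leibler divergence
  D(V‖WH) = Σ V log(V/WH) − V + WH. Over repeated seeded runs, samples
  co-cluster when they share the argmax component of H; the consensus
  matrix C averages these indicators and assignments come from
  average-linkage clustering of 1 − C. The rank k is chosen over k = 2–6
  by maximizing the gap between cophenetic correlation coefficients of
  the actual and a row-permuted matrix (see `docs/methods.md` for a
  caveat about this rule on cleanly separable data). Meta-genes per
  cluster come from the Kim–Park basis-specificity score on W.
* **Cross-cohort marker consensus.** Meta-gene sets from two cohorts are
  compared per cluster pair by the hypergeometric upper tail
  P(X ≥ x), X ~ Hypergeom(N, |A|, |B|); overlap genes over-expressed in
  the focal subtype in *both* cohorts (log₂FC > 1.00, BH-adjusted
  p < 0.05, limma-trend-style moderated t on log₂(FPKM+1)) become
  consensus markers.
* **Cis-neighbour correlation.** PC genes get "basal plus extension"
  regulatory domains (5 kb up / 1 kb down of the TSS, extended up to
  1 Mb, truncated at neighbouring basal domains); lncRNA–neighbour
  support is the Pearson correlation across samples, the pan-cancer rank
  score 1 − n/N, and subtype-stratified correlations.
* **Microenvironment deconfounding.** Guilt-by-association enrichment of
  strongly co-expressed PC genes (r > 0.60/0.50), single-sample
  rank-based stromal/immune scores with a cosine purity transform, a
  stromal/immune-cell-specific (SIC) lncRNA filter comparing high-purity
  clinical medians against pure-tumour cell-line/PDX panels
  (log₂FC > 0.50 with median panel FPKM < 0.50), and immune cell-type
  attribution by median marker correlation (≥ 4 markers, r = 0.48
  significance line).
* **Synthetic cohorts.** Two clinical-like cohorts with planted subtype
  blocks, cis-correlated lncRNA–PC pairs placed inside regulatory
  domains, Beta-distributed stromal/immune contamination mixed in as
  `observed = (1−φ)·tumour + φ·environment`, plus pure-tumour panels —
  with the full ground truth exported for testing.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from lncconsensus import (SimulationConfig, simulate_cohort,
                          consensus_cluster, hypergeom_tail)
from lncconsensus.data_model import apply_gene_filters
from lncconsensus.cis import (build_regulatory_domains, assign_neighbours,
                              top_neighbour_correlation)

# published meta-gene overlap counts: 9 shared genes between basal
# clusters of 17 and 18 meta-genes in a 588-gene universe
print(hypergeom_tail(588, 17, 18, 9))        # 4.847189017593245e-11

cfg = SimulationConfig(seed=1)               # 3 subtypes x 30 samples
X, ann, truth = simulate_cohort(cfg, "A")    # 920 genes x 90 samples
lnc, pc, report = apply_gene_filters(X, ann)
print(lnc.values.shape)                      # (498, 90) lncRNAs kept

res = consensus_cluster(lnc.values.to_numpy(), k=3, runs=200, seed0=1,
                        sample_ids=lnc.sample_ids)
planted = [truth.subtype[s] for s in lnc.sample_ids]
print(adjusted_rand_score(planted, res.assignments))   # 1.0
print(round(res.cophenetic, 3))                        # 1.0

dom = build_regulatory_domains(ann[ann.biotype == "protein_coding"])
nmap = assign_neighbours(ann[ann.biotype == "lincRNA"], dom)
lnc_id, pc_id, rho = truth.cis_pairs[0]                # planted at rho=0.9
print(top_neighbour_correlation(X, nmap, lnc_id))
# ('PC0061', 0.9108956815153936, 1.373990457836813e-35)
```

The overlap p-value (≈5e-11) is why the two cohorts' basal meta-gene
sets are called concordant; the ARI of 1.0 says the consensus clustering
recovered every planted subtype label; the cis query returns the planted
partner gene with its correlation restored near the target 0.9.

## Command line

```sh
lncconsensus all --seed 1 --outdir runs/demo          # simulate -> report
lncconsensus nmf --config my.yaml --outdir runs/demo  # single stage
```

Stages: `simulate, filter, nmf, de, markers, cis, microenv, report, all`.
Every threshold (filters 1.00/0.10, k range, run counts, r thresholds
0.60/0.50, marker log₂FC 1.00 and q 0.05, purity 0.70, SIC 0.50/0.50,
marker minimum 4) lives in a YAML config overridable by flags; a
manifest records the config hash, and reruns with the same seed are
byte-identical.

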