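# enterolink

**From rumen enterotypes to milk protein yield: a multi-omics inference
pipeline.**

Dairy-cow rumen microbiomes tend to stratify into *enterotypes* — recurrent
community configurations, typically one dominated by *Prevotella* and one
balancing *Prevotella* and *Ruminococcus*. `enterolink` implements, as a
tested and reusable Python package, the full chain of analyses that links
such enterotypes to a lactation phenotype (milk protein yield, MPY, kg/d)
through rumen, serum and milk metabolomes:

1. **Enterotype clustering** — distances are the metric square root of the
   Jensen-Shannon divergence, `D(P,Q) = sqrt(½KL(P‖M) + ½KL(Q‖M))` with
   `M = (P+Q)/2`; samples are clustered by Partitioning Around Medoids (PAM)
   and the cluster count k is chosen by the Calinski-Harabasz index
   `CH = [B/(k−1)]/[W/(n−k)]` on the PCoA embedding. PCoA and between-class
   analysis (BCA) ordinations are included.
2. **Community statistics** — rarefaction, alpha diversity (Shannon,
   Gini-Simpson, Chao1, ACE), ANOSIM with seeded permutations, Mann-Whitney
   U tests with Benjamini-Hochberg FDR, prevalence/abundance filtering, and
   volatile-fatty-acid (VFA) group summaries (TVFA, acetate:propionate).
3. **Co-occurrence networks** — all-pairs Spearman correlations, edges at
   |ρ| > 0.5 and p < 0.05, degree/betweenness centralities, hub
   identification, and comparison against Erdős–Rényi ensembles.
4. **Weighted co-expression modules** (WGCNA-style, from scratch) —
   signed-hybrid adjacency `a_ij = max(cor_ij, 0)^β`, soft power β chosen by
   scale-free fit, topological overlap matrix, average-linkage module
   detection, module eigengenes, eigengene-correlation merging, and
   module–trait correlation with Student-t p-values.
5. **Metabolome differential analysis** — detection/QC-RSD filtering,
   minimum-value imputation, sum normalization, log transform; OPLS-DA with
   a single predictive component, cross-validated Q²Y, and VIP scores
   (mean VIP² = 1); differential metabolites gated on VIP ≥ 1, fold-change
   ratio ≥ 2 or ≤ ½, and BH q ≤ 0.05; Fisher-exact pathway enrichment.
6. **SEM path modelling** — recursive observed-variable path models
   (`y ~ x1 + x2` syntax) fitted by maximum likelihood
   (`F_ML = ln|Σ(θ)| + tr(SΣ⁻¹) − ln|S| − p`), with χ², RMSEA, CFI,
   standardized coefficients and per-equation R²; `chain_search` screens
   every one-module-per-layer chain
   microbiome → rumen → serum → milk → MPY and ranks candidates by fit.

Because the original cohort's per-animal tables are not public, the package
ships a **synthetic cohort generator** (`enterolink.simulate`) that plants
the study design — 4 + 8 animals in two enterotypes, driver genera at the
published abundance profiles, block-correlated metabolome layers of
260/113/94 features, and a standardized causal chain ending at MPY — with
full ground truth, so every stage is testable end to end.

Intended users: microbiome/multi-omics researchers who want a transparent,
scriptable re-implementation of this inference chain, and methodologists who
want planted-truth benchmarks for enterotyping, module detection and path
modelling.

## Worked example

```python
from enterolink import SimConfig, simulate_cohort, select_enterotypes

cohort = simulate_cohort(SimConfig(seed=0))
res = select_enterotypes(cohort["genus"])
print(res.k_best, res.group_sizes())
```

```
2 {1: 4, 2: 8}
```

The CH index selects k = 2 and the 4/8 planted enterotypes are recovered
exactly. The full pipeline runs from one YAML config:

```bash
enterolink run --config pipeline.yaml     # or: python -m enterolink.cli
```

with `pipeline.yaml` like

```yaml
simulate: {}        # or inputs: {genus: genus.tsv, rumen: ..., phenotypes: ...}
seed: 11
outdir: out
```

The consolidated `out/report.md` from that seed includes (abridged, actual
program output):

```
## Community statistics
- ANOSIM R = 0.760, p = 0.0030 (999 permutations)
## SEM chain search
- winning chain: ME4-ME1-ME1-ME2-MPY
- fit: chi2 = 18.045 (df 6), RMSEA = 0.427, CFI = 0.830
```

ANOSIM R ≈ 0.76 says between-enterotype community distances dominate
within-enterotype ones; the SEM section names the module chain (one
eigengene per omics layer) that best carries the microbiome signal through
to milk protein yield, with its fit indices.

Every stage is also exposed as a library function and a CLI subcommand
(`simulate`, `enterotype`, `diversity`, `difftest`, `network`, `wgcna`,
`metabolome`, `sem`, `report`).

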