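# lncnet

Weighted lncRNA–mRNA co-expression network analysis for bulk expression
time courses, built around the study design of liver regeneration after
portal vein ligation (PVL): hepatic lobes that keep their portal blood
supply are profiled at days 0, 1, 7 and 14, and the goal is to find the
gene modules — and the hub mRNAs and lncRNAs inside them — whose
expression tracks the regeneration time course.

The package is a library (`import lncnet`) with a thin `lncnet` command
line on top, plus a synthetic-data generator with *planted* modules so
that every stage of the analysis can be validated against ground truth.

## The method

Starting from a normalized log2 expression matrix (genes × samples):

1. **Differential selection.** For each post-baseline day, probesets are
   tested against day 0 (two-sample t on log2 intensities) and kept when
   *p* < 0.05 and absolute fold change > 2. Passing sets are united
   across comparisons and collapsed to gene symbols.
2. **Weighted network.** Pairwise Pearson correlations *r·ᵢⱼ* are
   soft-thresholded into an unsigned adjacency *aᵢⱼ = |rᵢⱼ|^β*, with β
   chosen as the smallest power whose connectivity distribution fits a
   scale-free form (signed R² ≥ 0.85 over powers 1–30), or set by hand.
3. **Topological overlap and modules.** The adjacency becomes the
   topological overlap matrix
   `TOMᵢⱼ = (lᵢⱼ + aᵢⱼ) / (min(kᵢ, kⱼ) + 1 − aᵢⱼ)` with
   `lᵢⱼ = Σᵤ aᵢᵤ aᵤⱼ`; genes are clustered by average linkage on
   `1 − TOM` and cut into modules with a hybrid tree cut (static branch
   cut, cohesion filter, core trimming, radius-gated assignment).
   Modules are labelled M1..Mk by decreasing size; leftover genes stay
   `unassigned`.
4. **Module–stage relationships.** Each module eigengene (first
   principal component of the standardized module submatrix) is
   correlated with the day vector; the module with the largest |r| is
   the key module. Per gene, GS = |cor(expression, day)| and
   MM = |cor(expression, eigengene)|.
5. **Hub funnel.** Key-module genes with GS > 0.5 and MM > 0.9 are key
   genes. Key mRNAs are ranked by betweenness centrality in a supplied
   protein-interaction graph (top 20 kept); key lncRNAs by smallest GS
   p-value (top 10). A lncRNA–mRNA co-expression network (|r| ≥ 0.9,
   p < 0.05) connects them; key genes with at least one edge are the hub
   mRNAs / hub lncRNAs.
6. **Enrichment.** Module genes are tested against GMT gene sets with
   the hypergeometric upper tail and Benjamini–Hochberg FDR (sets with
   fewer than 5 overlapping genes are dropped).

## Worked example

`examples/04_full_pipeline_hubs.py` runs the whole pipeline on the
default synthetic design (2000 probes, five planted 60-gene modules,
4 stages × 3 replicates, seed 1) and prints:

```
differential probesets: 187 lncRNA, 265 mRNA
network: beta = 10, 4 modules {'M1': 27, 'M2': 24, 'M3': 21, 'M4': 20}
key module M3: stage correlation r = -0.84 (p = 0.00065); GS-MM r = 0.54
key genes after GS > 0.5, MM > 0.9: 11 mRNA, 8 lncRNA
hub mRNAs (11): GENE00072, GENE00044, ...
hub lncRNAs (8): LNC00039, LNC00038, ...
```

Reading this: 452 of 2000 probesets respond to the time course; the
network stage recovers four of the five planted modules among them; the
key module anti-tracks the day axis (r = −0.84), as its planted
trajectory was built to do; and every reported hub gene is a planted
member of that module — the funnel found genuinely central genes. The
other examples exercise each stage separately (`01` generator, `02`
differential expression, `03` network/modules with an adjusted-Rand
check against the planted truth, `05` enrichment).

The same run from the shell:

```bash
lncnet run-all --config config.yaml --seed 1
```

where `config.yaml` holds a `synthetic:` block or paths to expression /
annotation / sample TSVs (plus optional PPI edge list and GMT files).
Individual stages are exposed as `lncnet simulate|de|network|relate|hubs|enrich|ddct`.

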