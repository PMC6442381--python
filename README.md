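# cpgmpra

Design and analysis toolkit for massively parallel reporter assays
(MPRAs) that dissect how **CpG dinucleotide density** shapes mammalian
promoter activity.

Mammalian promoters split into two classes by their normalized CpG
density — the classical observed/expected ratio

```
OE = ( n_CpG / (n_C · n_G) ) · L
```

for a region of length `L`. CpG-island (CGI) promoters (≥ 200 bp,
G+C > 50 %, OE ≥ 0.6) are the transcriptionally active majority, but
density, transcription-factor motifs and methylation are confounded in
native sequence. Barcoded reporter libraries of systematically mutated
promoters, integrated at a single genomic locus, disentangle them:
every construct carries unique barcodes, and the enrichment of a
barcode in the RNA pool over the DNA pool, `n_r/n_d + α` with
pseudocount `α = 0.05`, measures its construct's activity on a log2
scale.

The package covers the full computational arc of such a study:

| module | what it does |
| --- | --- |
| `seqstats` | CpG counting, OE density, GC content, CGI classification |
| `library_design` | five mutagenesis strategies (window combinations, density series, motif mutations, CpG-free tiling, CpG add-back) with motif-aware CpG masking, plus degenerate-pattern barcodes |
| `barcode_assignment` | read-pair → construct matching by mismatch distance with error budget (20 % of sequenced bases), ambiguity margin (3) and barcode purity filter (second/top ratio < 0.3) |
| `activity_quant` | library scaling, DNA-count filtering (> 20 scaled reads), the `n_r/n_d + α` enrichment model, replicate aggregation, relative activities and condition fold changes |
| `stats` | Spearman's ρ with approximate (Monte-Carlo) and exact (exhaustive) permutation significance |
| `binding_pred` | PWM log-odds scanning over both strands, 600-nt window tiling, bound calls (ChIP log2 enrichment > 2.5), the additive logistic predictor `P(bound) = σ(a + b·motif + c·OE)` and precision-recall curves over 100 cutoffs |
| `methylation` | per-CpG bisulfite calls → unweighted per-promoter methylation means |
| `synthetic_data` | seeded generators with recorded ground truth for every stage |

## Worked example

Simulate a 20-promoter density series, quantify it, and ask whether
CpG density drives activity:

```python
import numpy as np
from cpgmpra import (SimulationConfig, Simulator, aggregate_replicates,
                     quantify_replicate, perm_test_approx)

sim = Simulator(SimulationConfig(seed=1, n_promoters=20))
promoters = sim.gen_promoters()                  # OE spread 0.15–1.1
truth = sim.gen_true_activities(promoters)       # known log2 activities
counts, bc_map = sim.gen_counts(truth, n_replicates=3)

reps = {str(r): quantify_replicate(g, bc_map)
        for r, g in counts.groupby("replicate")}
agg = aggregate_replicates(reps).merge(truth, left_on="promoter",
                                       right_on="construct")
res = perm_test_approx(agg.oe.to_numpy(),
                       agg.mean_log2_activity.to_numpy(),
                       n_perm=9999, seed=1)
print(f"rho = {res.rho_observed:.3f}, p = {res.p_value:.2e}")
```

```
rho = 0.973, p = 1.00e-04
```

The rank correlation of ~0.97 says the estimated activities recover the
density-driven ordering almost perfectly; the permutation p-value of
1e-4 (the smallest attainable with 9,999 permutations) says no
permutation of the activities reached that correlation by chance. A
promoter with zero RNA counts across all barcodes sits exactly at the
pseudocount floor `log2(0.05) ≈ −4.32`.

The same API is exposed as a CLI (`cpgmpra simulate`, `seqstats`,
`assign`, `quantify`, `predict-binding`, `corr`, `methylation`); run
`cpgmpra --help`.

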