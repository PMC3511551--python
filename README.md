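# coexnet

Gene association measures, TF coordination networks and Triple-Link
decomposition for coexpression analysis.

## What this is for

Coexpression analysis asks which genes move together across a compendium of
expression profiles — because genes in the same metabolic pathway, or
transcription factors (TFs) steering the same biological process, tend to be
transcribed in concert.  The answer depends heavily on *how* "moving
together" is measured: Pearson correlation sees only linear coupling and is
fragile to outliers, while rank statistics see any monotone coupling and
shrug off spikes.  `coexnet` implements eight association measures behind one
calling convention, the network machinery that consumes them, and the
evaluation tooling to compare them — plus a synthetic-data generator with
planted ground truth so the whole pipeline is testable without any external
download.

The eight measures, for expression vectors x, y of length n:

| id | statistic | p-value |
|---|---|---|
| `pearson` | product-moment r | t = r·√((n−2)/(1−r²)), n−2 df |
| `spearman` | rank correlation ρ (Pearson of average ranks) | same t form on ρ |
| `kendall` | τ (tie-corrected τ-b) | normal, null var 2(2n+5)/(9n(n−1)), tie-corrected |
| `weighted_rank` | r_W = 1 − 6Σd_i²(2n+2−R_i−S_i)/(n⁴+n³−n²−n) | normal, exact permutation-null variance |
| `hoeffding` | D from univariate ranks R, S and bivariate ranks Q | Cantelli bound v_n/(v_n+D²); optional permutation |
| `dcov` | squared distance covariance (double-centered distance matrices) | permutation, +1 corrected |
| `theil_sen` | median of pairwise slopes (y_j−y_i)/(x_j−x_i) | Wilcoxon signed rank on the slope multiset |
| `rank_theil_sen` | Theil-Sen on rank-transformed data | same |

Downstream, each TF is paired with every other gene, lists are sorted by
p-value, and two TFs are linked in the **coordination network** when their
top-100 lists share strictly more than k = 30 genes.  **Triple-Link** then
greedily decomposes the network: seed with the heaviest edge, admit a third
TF with significant links to both seeds, admit later TFs with at least three
significant links (significant = overlap above the matrix mean plus one SD),
emit the cluster, remove its TFs, repeat.  Pathway scoring (S/D/N labels,
slice confusion with the divide-by-9 rescaling, p-threshold fractions),
Shapiro-Wilk normality profiling and the 10-category r-vs-ρ classification
complete the toolkit.

## Worked example

Simulate a compendium with five planted TF groups of eight TFs each, then
recover them through the full pipeline:

```python
import coexnet as cx

cfg = cx.SimulationConfig(seed=7, noise_sd=0.3)
matrix, truth = cx.simulate_tf_coordination(cfg)
tfs = sorted(truth.tf_groups)

ranked = cx.associate_all(matrix, tfs[0], "spearman")
print(ranked.head(3))

lists = {tf: cx.top_n(cx.associate_all(matrix, tf, "spearman"), 100) for tf in tfs}
cm = cx.build_coordination_matrix(lists, k_min=30, n_top=100)
result = cx.decompose(cm)
print(f"threshold: {result.threshold:.2f}")
for cl in result.clusters:
    groups = {truth.tf_groups[t] for t in cl.members}
    print(f"cluster {cl.index}: {len(cl.members)} TFs, seed overlap "
          f"{cl.seed_overlap}, planted groups {groups}")
```

prints

```
  partner  statistic       p_value
0   TF007   0.940761  6.319552e-29
1   TF001   0.926813  2.393937e-26
2   TF004   0.925368  4.135553e-26
threshold: 73.89
cluster 1: 8 TFs, seed overlap 99, planted groups {2}
cluster 2: 8 TFs, seed overlap 98, planted groups {0}
cluster 3: 8 TFs, seed overlap 98, planted groups {1}
cluster 4: 8 TFs, seed overlap 98, planted groups {3}
cluster 5: 8 TFs, seed overlap 98, planted groups {4}
```

TF000's closest partners are its seven co-group TFs (ρ ≈ 0.93–0.94), the
significance threshold (~74) separates within-group overlaps (~98) from the
weak promiscuous background (~50), and every cluster recovers exactly one
planted group — adjusted Rand index 1.0 against the ground truth.

The same pipeline is available from a shell:

```bash
coexnet simulate --kind tf-coordination --seed 7 --out matrix.tsv --truth-out truth.json
coexnet associate --matrix matrix.tsv --query TF000 --method spearman --out ranked.tsv
coexnet network --matrix matrix.tsv --tf-list tfs.txt --out cm.tsv
coexnet decompose --coordination cm.tsv --out clusters.tsv --json-out clusters.json
```

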