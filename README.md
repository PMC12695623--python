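# cmapscreen

Connectivity-Map-style in silico drug screening: match a signed
transcriptomic signature against a compendium of drug-perturbation rank
profiles, and rank compounds by a composite reliability score.

## The problem

Given a transcriptomic state of interest — for example, the expression
shift of neurons in a regeneration-competent state — which drugs push
cells toward (or away from) that state?  Compendia such as the Broad
Connectivity Map profile the transcriptome of cell lines treated with
hundreds to thousands of small molecules; each treatment-vs-control
experiment (an *instance*) is stored as a full ranking of the gene
universe, rank 1 = most up-regulated.  A query is a *signed signature*:
an up-tag list and a down-tag list of genes, built here by thresholding
a differential-expression table (defaults: |log2 fold change| ≥ 1.5,
adjusted p < 0.05).

## The statistic

For a tag list of size *t* in a ranking of *N* genes, with
*V*(1) ≤ … ≤ *V*(t) the ascending rank positions of the tags, the
Kolmogorov–Smirnov enrichment score is

    a  = max_j ( j/t − V(j)/N )
    b  = max_j ( V(j)/N − (j−1)/t )
    ES = a  if a > b,  else  −b

Positive ES means the tags concentrate at the top of the ranking.  An
instance's raw connectivity score is `s = ES_up − ES_down` when the two
have opposite signs, and 0 (*null*) otherwise; raw scores are scaled per
query onto [−1, +1] (positives divided by the run maximum, negatives by
the magnitude of the run minimum), so +1 marks the instance most similar
to the query state and −1 the most dissimilar.

Per compound the screen reports the mean ± s.d. scaled score, a
two-sided permutation p-value (resampling instance scores from the
run-wide pool), Benjamini–Hochberg FDR, instance count, the non-null
ratio (replicate consistency), a specificity score against background
gene-set collections (MSigDB-style GMT), and a **reliability score** —
an equal-weight (configurable) mean of six rescaled components:
|mean score|, 1 − p, 1 − FDR, min(instances/4, 1), non-null ratio,
specificity.  Compounds are ranked by reliability.

## Worked example

```python
import cmapscreen as cs

cfg = cs.SyntheticConfig(n_genes=1000, n_compounds=50, instances_per_compound=3,
                         effect_size=3.0, mimic_fraction=0.1, antimimic_fraction=0.05,
                         signature_sizes=(50, 50), seed=42)
matrix, signature, background, truth = cs.simulate_compendium(cfg)

model = cs.ConnectivityScreen(signature, matrix, background, b_permutations=1000)
results = model.fit(seed=42)
print(results.summary(k=5))
```

```
Connectivity screen results
============================================================
query:            planted
compounds:        50
instances:        150 (63 null)
permutations/cpd: 1000
seed:             42

top 5 compounds by reliability:
 compound        mean+-sd  p_value    fdr  non_null_ratio  specificity  reliability
cmpd_0045 +0.983 +- 0.013   0.0020 0.0167          1.0000       1.0000       0.9524
cmpd_0004 -0.980 +- 0.006   0.0010 0.0167          1.0000       1.0000       0.9520
cmpd_0036 +0.974 +- 0.028   0.0020 0.0167          1.0000       1.0000       0.9508
cmpd_0012 +0.972 +- 0.011   0.0020 0.0167          1.0000       1.0000       0.9506
cmpd_0049 +0.963 +- 0.005   0.0010 0.0167          1.0000       1.0000       0.9493
```

The synthetic compendium planted 5 mimic compounds (instances enriched
for the query's up-tags near the top, down-tags near the bottom) and 2
anti-mimics (the reverse).  The top rows are planted compounds: strongly
positive (or, for the anti-mimic `cmpd_0004`, strongly negative) mean
connectivity, permutation p at the resolution floor, unanimous replicate
sign (non-null ratio 1) and connectivity no background gene set matches
(specificity 1).  `results.compound_table` holds the full ranked table,
`results.instance_table` the per-instance scores, and
`results.plot_ranking()` draws the ranked connectivity /
specificity / reliability figure.  Here
`cs.truth_recovery_report(results.report, truth, k=5)` gives
recall@5 = 0.8 (4 of the 5 mimics in the top 5; the fifth slot is the
anti-mimic, which reliability treats as an equally reliable hit — the
report's `direction` column separates mimicry from reversal,
direction accuracy 1.0).

The same pipeline runs from the shell:

```sh
cmapscreen simulate --n-genes 1000 --n-compounds 50 --seed 42 --out data/
cmapscreen screen --up data/query_up.grp --down data/query_down.grp \
    --matrix data/ranks.tsv --meta data/instances.csv \
    --background data/background.gmt --seed 42 --out out/
cmapscreen recover --report out/compound_report.tsv --truth data/truth.csv -k 5
```

Real compendia are read from GCT 1.2 or headered TSV rank matrices with
an instance metadata CSV; signatures from GRP files or a DE table;
backgrounds from GMT.

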