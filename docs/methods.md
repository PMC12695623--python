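# Methods

## Scoring model

The screen measures whether a drug's transcriptional effect mimics (or
reverses) a query state described by a signed signature: an up-tag list
(size t_up) and a down-tag list (t_down) of genes.  Each compendium
instance is a full ranking of the N-gene universe, rank 1 = most
up-regulated relative to control.  The package assumes this orientation
throughout; readers expose `invert_ranks` for compendia stored the other
way.

For one tag list the enrichment statistic is the classic two-sided KS
running-maximum form.  With V(1) ≤ … ≤ V(t) the ascending tag
positions:

    a  = max_{j=1..t} ( j/t − V(j)/N )
    b  = max_{j=1..t} ( V(j)/N − (j−1)/t )
    ES = a  if a > b  else  −b

On integer ranks the statistic is piecewise-exact in double precision;
no tolerance is applied anywhere in the scoring path.  Ties a = b
resolve to −b (the else-branch as written); note b ≥ V(1)/N > 0, so ES
is never exactly 0.  Attainable extremes are ES = 1 − t/N (tags filling
the top block) and ES = −(1 − (t−1)/N) (bottom block).

The instance-level raw connectivity score is s = ES_up − ES_down when
the two enrichment scores have opposite signs; when they share a sign
the instance is *null* and s = 0 — the compound moved both tag lists the
same way, evidence of neither mimicry nor reversal.  Null instances are
retained: they count toward the instance count and the non-null-ratio
denominator.

Raw scores are scaled onto [−1, +1] **per query across all instances of
the run** (one global axis, not per compound or cell line): positives
divide by the maximum positive raw score, negatives by |minimum
negative|, zeros stay zero.  A sign with no scores skips its branch.

## Compound-level statistics

* **mean_score ± sd_score** — arithmetic mean and n−1 sample s.d. of the
  scaled scores over the compound's instances (s.d. 0 for singletons).
  The spread column is a standard deviation, and is labelled as such.
* **p_value** — two-sided permutation p: B resamples (default 1000) of
  size n (the compound's instance count) drawn without replacement from
  the pool of all instances' scaled scores;
  p = (1 + #{|mean_b| ≥ |observed|}) / (B + 1).  Resampling instance
  scores, rather than re-labelling genes, makes the null respect the
  empirical score distribution of the compendium.  The pseudo-count
  floors p at 1/(B+1) and makes the test slightly conservative (measured
  null exceedance ≈ 0.046 at the 0.05 level over repeated synthetic
  runs).  Each compound draws its own resamples, so p-values are
  independent across compounds given the pool.
* **fdr** — Benjamini–Hochberg step-up across the run's compounds
  (statsmodels implementation behind the package's `bh_fdr` surface).
* **non_null_ratio** — replicate consistency: the majority direction is
  the sign of the summed non-null scaled scores (tie → sign of the mean;
  all-null → 0), and the ratio is (# non-null instances with the
  majority sign) / (all instances).  The all-instances denominator is
  the default; the statistic is deliberately 0 for all-null compounds.
* **specificity** — how unusual the compound's connectivity to the query
  is relative to unsigned background gene sets.  Each background set
  (≥ 5 genes matched to the universe; ≥ 20 usable sets required) is
  shuffled once per run (seeded) and split into pseudo-up/pseudo-down
  halves size-matched to (t_up, t_down) by subsampling when larger.
  Surrogate queries are scored over the compound's instances; their raw
  scores are scaled *jointly* (one scaling across all sets × instances,
  so the background occupies the same [−1, 1] axis — per-set scaling
  would pin every non-null set mean at ±1 with few instances and destroy
  discrimination); specificity = 1 − fraction of sets whose |mean| ≥
  |compound mean|.  An unsigned-|ES| variant was considered and
  rejected: the signed surrogate keeps the background on the same
  statistic as the query.
* **reliability** — weighted mean of six components, each already in
  [0, 1]: |mean_score|, 1 − p, 1 − FDR, min(instance_count/n_cap, 1)
  with n_cap = 4 (evidence saturates after a few replicates),
  non_null_ratio, specificity.  Equal weights by default; weights and
  n_cap are configuration, not code.  The composite is monotone
  non-decreasing in every component.  Reliability is direction-blind
  (|mean|); the report's `direction` column carries the sign.

Ranking sorts by reliability descending, ties by |mean_score|
descending then compound name ascending — a total, deterministic order.
When no background collection is supplied the specificity stage is
skipped and the remaining five weights are renormalised.

## Synthetic compendia

The generator emulates a CMap-like screen with known ground truth.  Per
instance it draws latent gene scores g ~ N(0, 1) i.i.d.; mimic
instances add +λ to the planted up-tags and −λ to the down-tags
(anti-mimics reversed); genes are ranked by descending latent score.
The additive shift on a probit scale gives graded, realistic enrichment:
at the default λ = 3 about 85% of a 50-tag list lands in the top 5% of a
1,000-gene ranking.  A `hard` mode forces tags into the extreme rank
blocks for analytic extreme-case tests.  Background sets are uniform
random draws; overlap with the planted signature is allowed, as in real
collections, and is part of what specificity must tolerate.  Replicates
share the compound's label and λ but draw independent noise — no
replicate correlation model.

Defaults (and the conditions used by the acceptance computations):
1,000 genes, 200 compounds × 3 instances, 10% mimics, 5% anti-mimics,
λ = 3, a 50+50-tag query, 30 background sets of 100 genes.  What the
generator does **not** model: probe-level noise, batch structure,
dose–response, cell-line heterogeneity, correlated gene modules.
Passing recovery tests therefore show the pipeline's statistics behave
correctly under their own assumptions, not that the screen's power on
real compendia matches the synthetic numbers.

## Numerical and design choices

* Gene matching is exact string equality after trimming and
  case-folding; unmatched query tags are dropped with a logged count
  (an empty surviving side is a hard error).  No probe/ortholog mapping.
* Signature construction defaults: |log2FC| ≥ 1.5, adjusted p < 0.05,
  at most 250 tags per side, ties broken by input row order.
* Mixed gene universes across instances are a hard error, never a
  silent intersection; every loaded column is validated as a
  permutation of 1..N.
* One mandatory run seed governs everything stochastic (permutation
  null, surrogate signing, simulation); per-stage child seeds derive
  from it, and identical inputs + seed reproduce byte-identical report
  files.
* Problem sizes in the test suite and acceptance script (N = 1,000,
  200 compounds, B = 500–1,000, five seeds for recovery) were chosen as
  the smallest runs at which the calibration and recovery statistics
  are stable; the whole acceptance computation takes seconds on one
  CPU.

## Known limitations

* The reliability composite is one defensible combination of the six
  named components; alternative weightings change hit ordering near the
  boundary and should be explored via the `weights` option, not code
  edits.
* The permutation null conditions on the realised score pool of the
  run; with very few compounds the pool is small and p-values coarse.
* Weighted (GSEA-style) running sums and LINCS-era tau/WTCS statistics
  are out of scope; the screen is predicated on the classic rank-based
  KS form.
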