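# Methods

## Problem and model

Given an N × l genotype matrix G with additive SNP coding (0/1/2 copies
of the rare allele), the goal is an unsupervised partition of the N
individuals into subpopulations that share allele-frequency profiles.
The pipeline has two stages.

**Base clustering (one run).** A synthetic class of the same size as G
is drawn from the product of G's per-marker empirical marginals; because
the synthetic class has independent markers while structured genotypes
have correlated ones, a random forest trained to discriminate the two
classes (Gini splitting, bootstrap bagging, per-node random feature
subsets of size *mtry*) carves the genotype space along the structure.
The proximity S[i,j] is the fraction of trees in which individuals i and
j land in the same leaf (all N original individuals are passed down
every tree — no out-of-bag restriction, which matches the classical
unsupervised-forest usage and keeps the count exactly a multiple of
1/ntrees). The dissimilarity D = √(1 − S) is embedded by classical
multidimensional scaling — eigendecomposition of −½·J·D²·J with the
centering projector J, retaining eigenvalues above a relative tolerance
— and K-means on the embedding yields one partition into k clusters.

**Consensus.** The base clustering is repeated M times with independent
seeds and per-run k. The co-association matrix CO[i,j] = (runs
co-clustering i and j)/M summarizes the ensemble; Ward's
minimum-variance agglomeration of the distance 1 − CO, cut at the final
cluster count, gives the consensus partition P\*. Over-produced per-run
k (the FixedK scheme, k = ⌈√N⌉) makes members diverse, and the consensus
reliably beats the average member — the package's central empirical
property, asserted by the acceptance tests.

**Baseline.** RFclust averages the proximity matrices of several
independent forests and Ward-clusters √(1 − S̄) directly. It consumes the
same forests but performs consensus at the proximity level rather than
the partition level, making it the natural comparator.

## Parameters

| name | meaning | default | rationale |
|---|---|---|---|
| `ntrees` | trees per forest | 500 | desk-scale; published comparisons used 10 000 (`--paper-defaults`) |
| `max_leaf_nodes` (MN) | hard best-first leaf cap | ⌈√N⌉ | the smallest cap is empirically sufficient and cheapest |
| `mtry` | candidate markers per split | ⌊√l⌋ | canonical classification-forest default; unstated in the source method |
| `n_synth` | synthetic-class size | N | balanced two-class problem; unstated in the source method |
| `n_members` (M) | ensemble size | 10 | desk-scale; published comparisons used 40 |
| `k_scheme` | per-member k | FixedK (⌈√N⌉) | over-producing k maximizes consensus quality; TrueK and RandomK (uniform on [2, ⌈√N⌉]) available |
| `n_clusters` (k_final) | consensus cut | truth K when labels are given | isolates consensus quality from model selection |
| `co_distance` | distance fed to Ward | 1 − CO | the minimal reading of "Ward on the CO matrix"; √(1 − CO) switchable |
| kmeans restarts / max_iter | search effort | 10 / 300 | common library defaults, recorded for reproducibility |

Square roots in k and MN are rounded **up**, so k ≥ 2 whenever N ≥ 2 and
the "overproduced k" intent is preserved (note ⌈√443⌉ = 22).

## Synthetic data

The generator follows the Balding–Nichols model: ancestral frequency
p ~ Uniform(maf_range) per marker (default (0.05, 0.5), avoiding
near-monomorphic markers), per-population frequency
p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with F the divergence knob, genotypes
Binomial(2, p_k). It emulates K well-differentiated island populations
with known truth labels. It does **not** emulate linkage disequilibrium
(markers are independent; a crude duplicate-with-flip-noise knob exists),
admixed individuals, genotyping error, or missingness — so passing tests
show the pipeline recovers clean island structure, not that it handles
admixture clines or LD-induced redundancy. Presets mirror the (N, l, K)
shapes of three published human SNP panels (762/46 256/11,
443/54 794/10, 274/10 805/12) at a reducible scale.

The divergence estimator used in validation is the ratio of
between-population variance (ddof = 1, since the K population
frequencies are a sample from the Beta) to total variance p(1 − p),
computed on the latent frequencies; it recovers the generating F within
±0.03 at l = 5 000.

## Numerical choices

- **Metrics.** NMI uses natural log and the arithmetic-mean
  normalization; 0·log 0 terms are dropped. Two partitions that are both
  single-cluster are identical, so NMI is defined as 1 there; a
  single-cluster vs. structured comparison gives MI = 0 hence NMI = 0.
  ARI returns 1 when the chance-adjustment denominator vanishes (both
  margins degenerate, which forces equality). Accuracy is cluster
  purity — majority-truth-label mapping — matching the verbal
  definition of AC; the alternative error-rate reading is inconsistent
  with purity being a quality score and is not used.
- **MDS tolerance.** Retained eigenvalues must exceed
  max(N·ε·λ_max, 1e−10); an all-zero dissimilarity therefore raises a
  degenerate-input error rather than returning a meaningless embedding.
- **Ward dialect.** scipy's `linkage(..., method="ward")` on the
  condensed 1 − CO distances, i.e. the Lance–Williams recursion on
  squared distances (the "D2" convention). The naive-agglomeration
  oracle in the tests reproduces its merges on tie-free inputs.
- **Tree engine.** scikit-learn's `RandomForestClassifier`, which grows
  trees best-first so `max_leaf_nodes` is a hard cap, bootstraps the
  combined (original + synthetic) training set at full size, and exposes
  per-sample leaf indices via `apply`. Bootstrap sample size equal to
  the training-set size is the classical bagging choice; no other size
  is documented for this method.
- **Seeding.** Every entry point takes one seed. Ensemble member i
  derives its seed from `SeedSequence(master_seed).spawn(M)[i]`, a
  counter-based split, so concurrent (`n_jobs > 1`) and sequential
  execution are bit-identical and adding workers never reorders streams.
- **Empty clusters.** K-means or a consensus cut can return fewer than k
  non-empty clusters; labels are compacted to 1..k′ and k′ reported.

## Validation scale

The end-to-end checks simulate K = 3 populations of 50 individuals with
l = 500 markers at F = 0.2 — small enough for a laptop-minutes test
suite, differentiated enough that recovery is expected. At this scale
the consensus over M = 10 members of 500 trees recovers the generating
populations with median NMI ≥ 0.9 across 20 master seeds and beats the
mean member quality; the directional comparisons (FixedK more diverse
than TrueK; ensemble consensus at least matching proximity averaging)
use the same data with 300-tree forests and 8-member ensembles.
`scripts/acceptance.py` re-runs the pipeline at the 500-tree, M = 10
scale over 5 master seeds and reports the averaged metrics.

## Known limitations

- Missing genotypes are rejected, never imputed.
- No LD model in the generator; results on LD-dense real panels are not
  characterized by the test suite.
- Link-based consensus similarities (CTS/SRS/ASRS) and K-means/spectral
  consensus variants are out of scope; Ward on CO is the only consensus.
- Significance testing between methods is not implemented.
- The final cluster count must be supplied (or taken from truth labels);
  the package does not select K.
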