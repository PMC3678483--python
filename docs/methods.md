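# Methods notes

This note records the models, parameter choices and numerical decisions
behind `rootweb`, in the spirit of a package vignette: what is assumed, what
is tunable, and what a passing test does and does not establish.

## Sequence identity

All identity thresholds (97% within- and among-sample ITS clustering, 99.8%
rbcL clustering, 99.8% host matching, the 0.80 homolog floor) share one
kernel: an end-gap-tolerant global alignment scored with match +1, mismatch
−1, internal gap −2 (linear), terminal gap −0.75, and identity defined as
matches divided by the number of alignment columns between the first and last
aligned pair. Terminal gaps are excluded from the denominator so that a
quality-trimmed read is ~100% identical to its full-length template; the mild
terminal-gap penalty (2 × 0.75 > 1) prevents the aligner from dodging a
mismatch by sliding into free end gaps, which would otherwise inflate
identities of equal-length sequences. IUPAC ambiguity codes never match
(conservative). The kernel is exercised in tests against an independently
written plain-Python dynamic-programming oracle.

Inside greedy clustering an ungapped positional comparison short-circuits the
full alignment when it already reaches the threshold; it is a valid
alignment's identity (a lower bound on the optimum), so membership decisions
are unchanged, and it is exact for the substitution-only error model of the
simulator.

## Clustering and consensus

Greedy abundance-ordered centroid clustering stands in for overlap assembly
at the same identity contract. Sequences are visited in order of decreasing
abundance (ties broken lexicographically, for determinism); each joins the
best centroid at or above the stage threshold or founds a new cluster.
Consensus is the weighted column-majority of members projected onto centroid
coordinates; tied columns receive IUPAC ambiguity codes, and a strict gap
majority drops the column. Members vote only over the region they cover, so
3'-trimmed reads do not erode the consensus tail.

Greedy centroid clustering is not globally optimal for adversarial "chain"
configurations (a–b–c where only b covers both ends); the equivalence test
against a brute-force partition oracle therefore uses well-separated
instances, which is also the regime the identity thresholds are designed for.

## Chimera score

A within-sample cluster is tested against every pair of same-sample clusters
at least twice its abundance. Match profiles are positional (ungapped), which
matches both the simulator's substitution-only errors and the coordinate
structure of a single-crossover chimera; with gapped profiles the crossover
optimum of two unrelated parents rises enough to threaten false positives at
the published 0.1 score threshold. The score is the fractional improvement of
the best two-parent split over the best single parent. Parents themselves are
never flagged by their own chimeras (they are more abundant by construction).

## CLAM habitat test

Each OTU's (root, soil) occurrence counts are tested with two exact one-sided
binomial boundary tests at the supermajority boundary K = 2/3 with
sample-size scaling, per-species alpha = 0.05 and no cross-species
correction. An OTU is "too rare" when neither test is significant and its
total count is below the smallest total at which *both* boundary tests could
ever reach alpha (`max` of the two one-sided minima); below that, a
non-significant result is uninformative rather than evidence of generality.
With 159 root and 38 soil samples this minimum is 27, which cleanly separates
root-only counts of 31 and above (significant) from 18 and below (too rare),
matching the published classification of the common OTUs. The alpha and K are
exposed in `ClamConfig`.

## d' and its extremes

For a node with row counts a_ij, row total A_i and partner availability
q_j = c_j / m, `d = Σ p'_ij ln(p'_ij / q_j)`. The extremes are taken over
integer reallocations of A_i across partners: d_max is attained at a vertex
(all interactions on the rarest partner, because a convex function is
maximized at an extreme point and every vertex is integer-feasible), and
d_min by incremental greedy allocation, which is exactly optimal because the
objective is separable and convex in each cell. Both are verified against
exhaustive enumeration on small matrices. When d_max = d_min (single
available partner) d' is defined as 0. d' is clamped to [0, 1] against
floating-point noise. Note that scaling a matrix by an integer factor changes
the integer-redistribution granularity, so d' is only approximately
scale-invariant.

## vaznull

Null matrices preserve the grand total and the number of links: cells are
selected without replacement with probability ∝ (row total × column total)
under a feasibility rule that keeps enough picks in reserve to cover every
row and column, then the remaining interaction events are distributed
multinomially over the selected cells with the same probabilities. The
permutation p-value for d' uses the add-one estimator
`(1 + #{null ≥ observed}) / (1 + n_perm)` (one-sided, observed ≥ null), which
avoids p = 0. The goodness-of-fit check on the null ensemble treats the mean
replicate matrix as a single multinomial draw of the grand total — a
desk-scale check of bias, not a distributional test of every cell.

## Relaxed LCA

At each rank only homologs carrying the rank are counted (absent annotation
is not conflict). The majority name is accepted when its support is at least
(1 − tolerance) of those homologs, inclusive, with a 1e-9 epsilon so that an
exactly-10% discordant hit set (e.g. 2 of 20) is tolerated despite binary
floating point. Tolerance 0 reproduces the strict LCA exactly, which is
property-tested. The homolog neighborhood (identity window 0.03 below the
best hit, floor 0.80, cap 50) is a configuration choice, not a published
value. The priority merge accepts a rank from a lower-priority source only
when that source's ancestor ranks equal the already-merged prefix; how
ancestor conflicts between tiers should be resolved is not specified
anywhere, and this rule is the package's own (conservative) choice.

## The synthetic world

Defaults state the survey design: 12 plants with one dominant host (45% of
root samples), 40 fungi (14 ectomycorrhizal, 3 arbuscular, 8 endophytes, 15
other), 150 root + 40 soil samples, 106–635 reads per sample (uniform — no
per-sample depth distribution is published, so the shape is a parameter),
0.5% per-base substitution errors, 2% chimeras, and an 8-mer molecular ID.

* **Host preference** is a per-fungus Dirichlet over plants with mean equal
  to plant abundance and concentration as the single knob: ~0.15 for
  ectomycorrhizal fungi (specialists), 20–50 for arbuscular fungi and
  endophytes (generalists), 5 for the rest. Concentration 0 degenerates to a
  one-host specialist; ∞ to exact availability-tracking.
* **Habitat**: root affinity 0.97 for endophytes (root-restricted), 0.60–0.65
  for mycorrhizal fungi (extraradical mycelia reach the soil), 0.50 for the
  rest.
* **Per-sample composition** is a Dirichlet around the host- and
  habitat-conditional weights with concentration 8, so a terminal-root
  fragment is dominated by a handful of OTUs.
* **Quality** follows a QV-38 plateau decaying linearly to ~QV 10 over the
  final quarter of the read with N(0, 2) jitter. The running-mean trimming
  rule cuts where the suffix mean crosses 20, i.e. where the ramp passes
  ~QV 30 — about 18% of the read — so template lengths (220 bp ITS, 560 bp
  rbcL) are chosen to clear the 150/400 bp length filters after trimming.
* **MIDs** keep pairwise Hamming distance ≥ 3, so single substitutions are
  rejected rather than reassigned. Chimeras splice two abundance-weighted
  same-sample parents at a crossover uniform in the middle 60% of the
  template. **Sequences** are i.i.d. uniform nucleotides with no homopolymer
  structure: the generator validates clustering logic at the stated identity
  thresholds, not robustness to 454 flowgram (indel) noise, which is out of
  scope throughout.
* **References**: each OTU receives ~25 database relatives 1–3 substitutions
  away, with annotation depth genus/class/phylum in roughly 80/16/4%
  proportions. The misannotation quota — exactly `round(rate × genus
  records)` — replaces a record's whole lineage with another genus's lineage,
  spread across OTUs by largest remainder so the per-query discordance stays
  near the nominal rate.

A green recovery test therefore establishes that the pipeline's thresholds,
filters and statistics interlock correctly on data that satisfies the stated
error model; it does not establish robustness to indels, chimeras with more
than two parents, PCR amplification bias, or real ITS sequence structure.

## Expected-recovery bookkeeping

"Planted abundant OTUs" are computed from the simulator's provenance table:
non-chimeric ITS reads with an error-free molecular ID and a recognizable
primer (≤ 2 mismatches), counted per (OTU, sample); an OTU is expected when
some sample reaches five such reads. This mirrors the pipeline's own filter
cascade without running it, and the recovery tests require the pipeline's
abundant-OTU count to match it exactly in ≥ 95% of seeds. Read depths in the
20-seed recovery test are 140–220 per sample (below the survey's range) to
keep the run inside a desk-scale time budget; depth only scales the
statistics' sample sizes, not the logic under test.

## Known limitations

* Greedy clustering is order-dependent by design; determinism comes from the
  abundance/lexicographic ordering, not from global optimality.
* The CLAM alpha, the exact "too rare" rule, and the homolog neighborhood
  reproduce the published classifications but are inferences exposed as
  configuration, not published constants.
* d' significance is one-sided (specialization); anti-specialization is not
  tested.
* The accumulation curves use simple random re-ordering (100 shuffles by
  default); no extrapolated richness estimators are provided.
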