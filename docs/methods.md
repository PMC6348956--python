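# Methods

This note documents the statistical conventions the package implements,
the choices made where the methods literature leaves the design open, and
what the synthetic generator does and does not emulate.

## Event logs and bout segmentation

The raw input is a focal-observation event log: one row per behavioural
event with period, focal individual, 15-minute sample start, event type
(grooming, supplant, avoidance, aggression, submission), actor, recipient,
start time and duration (0 for point events).  Times are seconds from an
arbitrary per-period origin; there is no calendar handling.

Grooming episodes of an unordered pair are partitioned into bouts by a
single forward scan: an episode joins the current bout iff its start is no
more than `gap_s` (default 30 s) after the end of the last grooming in the
bout, in either direction.  Conventions, all tested as invariants:

- The boundary is inclusive: a gap of exactly 30 s continues the bout,
  because a bout ends only once *more* than 30 s have passed.
- The gap is measured from the episode *end* (start + duration), not start.
- Simultaneous mutual grooming is legal — mutual grooming is recorded as
  two separate directed episodes which may overlap.  Two overlapping
  episodes in the *same* direction indicate an observation error and the
  log is rejected rather than silently merged.
- The Groomer is the actor of the earliest episode; a bout is reciprocated
  iff both directions occur within it.
- Total grooming seconds are conserved exactly through segmentation and
  every downstream aggregation split (full = reciprocation-excluded +
  mutual-bout portions).

Duplicate records (same period, type, actor, recipient, start — the key
deliberately excludes duration) arise when a dyadic event is seen during
both members' focal samples; identical duplicates collapse to one record
with a logged warning, conflicting durations are an error.  Per-individual
observation time is the count of distinct focal samples times the sample
length.

## Dominance, rank and kinship

The hierarchy is ordered by the average dominance index: for individual
*i*, the mean over opponents *j* with at least one decided interaction of
`wins_ij / (wins_ij + wins_ji)`.  Only opponents actually met enter the
mean, which is what makes the closed form exact: under a fully consistent
hierarchy with all dyads observed, rank *i* of *n* scores `(n−i)/(n−1)`.
Supplants and aggression credit the actor with the win; avoidance and
submission credit the recipient (the individual avoided or submitted to).
All four event types are weighted equally.  Ties in the index are broken
by total wins, then label order, and always flagged.  An individual with
no decided interaction has an undefined index and is rejected so the
caller can exclude her explicitly.

Relatedness comes from the recursive tabular (numerator relationship)
method on the pedigree; unknown parents are unrelated founders.  This
yields the field's standard coefficients — 0.5 for mother × daughter and
full sisters, 0.25 for grandmother × granddaughter and aunt × niece, 0.375
for cousins who are also paternal half-sibs — and is cross-checked in the
tests against an independent coancestry recursion.

## Network metrics

The only combination of conventions consistent with reconstructing the
published centrality tables from partner lists alone is: degree, reach and
betweenness on the *binarised* undirected graph; eigenvector centrality on
the *weighted* affinity matrix.

- Reach centrality is `1 + Σ_j 1/d(i,j)` over reachable others, so an
  isolated individual scores exactly 1.000.  This closed form reproduces
  all thirteen published reach values in both periods; a normalised
  variant is easy to derive but is not what the published tables print.
- Betweenness is the unnormalised geodesic form (endpoints excluded,
  equal splitting across multiple geodesics, unreachable pairs skipped),
  in pair-path units.
- Eigenvector centrality is the principal eigenvector of the weighted
  matrix with non-negative entries and unit *Euclidean* norm — the
  convention identified from the published values' sum of squares.  On
  disconnected graphs it concentrates on the component with the largest
  leading eigenvalue.

Community structure uses Newman's leading-eigenvector bisection on the
weighted modularity matrix `B_ij = A_ij − k_i k_j / 2m`, with greedy
single-vertex refinement and recursion while a split increases Q;
isolated individuals are removed first and reported separately.  Q above
0.30 is flagged as meaningful structure.  On every small graph the
heuristic is verified against an exhaustive search over all partitions,
with equality on the canonical two-triangle fixture (Q = 0.5).

Dendrograms use average linkage on dissimilarities `max(w) − w`; the
cophenetic correlation coefficient is the Pearson correlation between
off-diagonal similarities and the dendrogram's implied cophenetic
similarities, flagged as faithful above 0.80.  Average linkage and
similarity-based CCC are assumptions (the originating software's
defaults), stated here rather than hidden.

Rank-vs-centrality tests invert ranks (lowest = 1) so a positive Spearman
rho means higher-ranking individuals are more central; with four measures
per hypothesis every row carries the Bonferroni-adjusted alpha 0.0125.

## The tau-Kr permutation test

Dyadic matrices violate the independence assumptions of ordinary rank
correlations.  The rowwise Kendall statistic correlates two actor × actor
matrices row by row, `S_i = Σ_{j<k} sign(x_ij − x_ik)·sign(y_ij − y_ik)`
over off-diagonal column pairs, with `Kr = Σ_i S_i` and
`tauKr = Kr / Σ_i D_i`, `D_i` the tie-corrected (tau-b) maximal
concordance of row i.  Rows constant in either matrix contribute nothing
to either sum; cells undefined in either matrix (e.g. gRI of a dyad that
never groomed) are excluded pairwise within rows.

Inference conserves each actor's outgoing value multiset: the off-diagonal
entries of each row of `y` are permuted independently.  Because the
per-row S distributions are independent under this null, the exact null of
Kr is their convolution; the implementation enumerates it whenever the
permutation space has at most 10⁶ arrangements (always for groups of 4)
and samples 10,000 permutations otherwise.  Two-tailed p-values measure
symmetric deviation from the null mean of Kr, which is exactly zero under
within-row permutation — centring on the analytic zero rather than the
sampled mean keeps sampled and enumerated p-values consistent on the
discrete null support.  Measured size on independent-noise matrices
(n = 5, 400 runs): 0.043.

**Reciprocity is a special case.**  Correlating a matrix with its own
transpose means the two matrices share every dyad's values, so permuting
the transpose independently of the original understates the null variance
(the per-row S terms are positively coupled through shared dyads).
Measured on matrices with independent entries — a true no-reciprocity
null — that scheme rejected at 0.10–0.14 instead of 0.05.  The package's
`reciprocity_test` therefore permutes each actor's outgoing row of the
*directed matrix itself* and recomputes given-versus-received on the
permuted matrix.  Under the null that actors allocate grooming across
partners at random, the observed matrix is exchangeable with its row
permutations, making the p-value exact; the two-tailed centre is the mean
over the observed value and all permutations, preserving that
exchangeability.  Measured size: 0.037–0.043 across dense, sparse and
fully simulated nulls (slight conservatism is inherent to discrete
permutation nulls with many ties); power is unaffected (a symmetric
matrix with distinct rows yields p = 1/(B+1)).  The statistic itself is
unchanged — only the null model differs from the generic two-matrix test.
Whole-actor relabeling is available as a non-default sensitivity option.

## Market statistics

- **Partner diversity.**  `H′ = −Σ p_i ln p_i / ln(n−1)` with `p_i` the
  proportion of the groomer's *bout-frequency* directed to partner i
  (an effort-based variant is available) and `n` the number of mature
  females.  The `ln(n−1)` denominator is the log of the number of
  available partners, which makes H′ span exactly [0, 1]: 0 for a single
  partner, 1 for uniform grooming over all n−1 others.
- **gRI.**  `1 − |gAB/(gAB+gBA) − gBA/(gAB+gBA)| = 1 − |gAB−gBA|/(gAB+gBA)`,
  symmetric, scale-invariant, 1 for a perfectly balanced dyad, 0 for a
  unidirectional one, undefined (NaN) where no grooming was traded.
- **Within-bout reciprocity.**  Over immediately reciprocated bouts only:
  weighted least squares of ln(seconds the Reciprocator groomed the
  Groomer) on ln(seconds the Groomer groomed first), natural logs, each
  bout weighted by the inverse of its dyad's reciprocated-bout count so
  every dyad's weights sum to one.  Reported: slope, F(1, m−2), weighted
  residual mean square s², p; a perfect fit is flagged degenerate.
- **Grooming up the hierarchy.**  Expected up-grooming per female is her
  total given grooming times the proportion of females ranked above her;
  observed is her grooming to strictly higher-ranked partners.  The
  observed−expected differences (the alpha female's is structurally zero
  and is dropped with the other zeros) are tested with an exact Wilcoxon
  signed-rank test, separately for effort and frequency; the statistic
  reported is W⁺, the sum of positive-difference ranks.  An exclusion
  list re-runs the computation without named individuals (ranks
  compressed), supporting mother-with-infant sensitivity analyses.
- **GR/GG versus rank.**  The received/given ratio per female against
  inverted rank (positive rho = higher-ranking females receive relatively
  more).  A female who neither gave nor received has an undefined ratio;
  the default excludes her (logged), a "zero" convention keeps her at 0
  for sample-size parity with published analyses.  A female who received
  but never gave scores +inf, which is rank-safe.
- **Family-wise corrections.**  When the reciprocity battery runs on both
  the full and the reciprocation-excluded data, every result carries the
  adjusted alpha 0.025; the rank-vs-centrality family carries 0.0125.

## The synthetic generator

The generator is not a fit to any dataset; it is the minimal mechanism
that makes each market effect switchable by one parameter so that every
downstream test has a ground truth.  Structure:

- **Group.**  n females (default 7) in one matriline: every individual
  descends from a single founder female; all births of a generation share
  a founder sire, which reproduces the standard kinship classes (0.5,
  0.375, 0.25).  Latent ranks are a seeded permutation.  Each female
  prefers k partners (default 2) with Dirichlet-distributed weights.
- **Grooming.**  Bout initiations per directed pair follow a Poisson
  process with rate ∝ preference × exp(β·[recipient ranks higher]),
  normalised so each female initiates `bout_rate_per_h` (default 1.0)
  bouts per clock hour.  Episode durations are lognormal (μ = 3.5,
  σ = 0.8 in ln-seconds, ≈ 45 s median).  With probability r (default
  0.1) the recipient reciprocates within 30 s with duration = initial ×
  `recip_balance` × lognormal noise.  Initiations that would collide with
  an ongoing bout of the same pair are dropped so that 30-s segmentation
  recovers the generated bouts unambiguously.
- **Agonism.**  Per-dyad Poisson events at rate `a0·exp(−γ·ŵ)` with ŵ the
  dyad's normalised grooming affinity — γ > 0 produces the negative
  grooming×agonism (tolerance) coupling.  The higher-ranked female wins
  with probability c (default 0.95); the event is written as a supplant
  by the winner or an avoidance by the loser, equiprobably.
- **Observation model.**  Events live on a continuous clock sliced into
  15-minute focal samples rotating round-robin across individuals.  A
  grooming bout is recorded iff one of its participants is focal when the
  bout starts (the observer follows an interaction to its end — filtering
  per episode would artificially truncate reciprocation at sample
  boundaries); point events are recorded iff a participant is focal when
  they occur.  Dyadic events are therefore observed at roughly 2/n of
  their generated rate.
- **Determinism.**  Every (period, dyad, process) triple draws from its
  own stream derived from the master seed, so adding or silencing a dyad
  never perturbs the others' draws — verified by a test that withdraws a
  female and checks the remaining dyads' events are identical.
- **Demographic changes.**  A maturing female can be inserted at a given
  rank (others' order preserved), an individual can be withdrawn (rates
  zeroed, she remains present — social exclusion), and the
  mother-with-dependent-infant bonus (extra unreciprocated grooming
  directed at the mother by every other female) can be switched off to
  emulate infant independence.

Default rates were chosen once so that a default period resembles the
published descriptive totals (≈200–260 observed bouts, ≈9–13·10³ s of
grooming, ≈400–650 agonistic events per period at 16 observation hours
per female); they were not adjusted afterwards.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no males and no spatial structure; no diurnal or
seasonal rhythm (homogeneous Poisson rates); no behavioural
autocorrelation beyond bout structure; preferences are fixed within a
period (no drift); kinship does not influence preference (the two can be
correlated in real matrilines); observation is error-free apart from the
focal filter.  Conclusions about estimator calibration and recovery
transfer to real logs only insofar as those logs match the model's
independence assumptions.

## Problem sizes in the test suite

Monte-Carlo suites use fixed consecutive seeds.  The reciprocity null
calibration runs 1,000 simulated periods at the default study conditions
(16 obs-hours/female, r = 0, β = 0, n_perm = 2,000) and checks the
rejection rate against the 95% binomial interval around 0.05.  Rank
recovery runs 100 periods at c = 0.95 (each containing well over 300
agonistic events) and requires Kendall tau ≥ 0.9 against the latent order
in at least 95.  Graph-metric oracles run on 40 random graphs of up to 8
nodes against exhaustive path enumeration; modularity is checked against
exhaustive partition search on graphs of up to 8 nodes.  Scaled-down
variants of the generator invariants (20–30 seeds, 4–10 obs-hours) live in
the unit suite for speed; the full-size studies are in the acceptance
suite.

## Known limitations

- The permutation engine materialises sign tensors of shape
  (batch, n, n−1, n−1); fine for groups of tens of individuals, not for
  hundreds.
- Exact Wilcoxon p-values fall back to the normal approximation when
  ties among |differences| prevent exact enumeration.
- The dendrogram cut for the membership matrix uses the modularity
  partition's cluster count; when modularity and average linkage disagree
  about the grouping, the membership matrix follows the dendrogram.
- GR/GG with zero given grooming yields +inf ratios, which Spearman
  handles but summaries print as `inf`.
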