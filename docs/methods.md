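# Methods

## The problem

In laying-hen flocks, aggressive interactions — the usual raw material for
dominance indices such as David's score or Elo ratings — are rare. The
alternative implemented here infers the social hierarchy from *feeding
competition*: hungry hens compete for a feeder that only a few birds can use
at once, and each hen's position relative to the feeder is scored on an
ordinal 0–3 rubric at 30-second intervals (3 = feeding; 2 = within 2–6 cm or
clearly motivated; 1 = displaced or circling for an opening; 0 = disengaged).
The package turns those scores into a within-pen hierarchy and then asks
whether rank predicts feeding behavior, growth, organ development, vigilance,
and the cecal microbiome.

## Rank aggregation (the sorted sum)

For each pen and test, a hen's interval scores are summed (0–60 for a 20-
interval test) and hens are ranked within pen on that sum, rank 1 highest.
The **sorted sum** is the sum of a hen's per-test ranks over all tests; with
6 tests and 10 hens it lies in [6, 60], and smaller values mean higher social
rank. Final ranks R1…R10 are assigned per pen in ascending sorted-sum order;
R1–R2 form the high-ranking (HR) group and R9–R10 the low-ranking (LR) group
(4 pens → n = 8 per group).

Numerical choices:

- **Within-test ties** get average (fractional) ranks by default, preserving
  the rank-sum invariant Σranks = n(n+1)/2 used throughout the tests. An
  ordinal mode (`tie_mode="ordinal"`, first-listed wins) is available when
  integer ranks are required.
- **Final ties** are left tied for reporting (`final_rank` uses average
  ranks). When a tie crosses the HR/LR boundary the assignment is forced
  deterministically: higher total raw score wins, then lexicographically
  smaller hen id. Both steps are order-independent.
- Ranks are computed within pen only; pens are separate social units and are
  compared via group labels, never raw sorted sums.

## The synthetic study generator

The generator emulates the study design end to end so the pipeline is fully
testable offline: 4 pens × 10 hens, 6 tests × 20 intervals, a feeder
admitting 2–4 birds, feeder-log monitoring over days 67–90 of age, and cecal
ASV tables for the 16 HR/LR hens. Each hen has a latent dominance score
θ ~ N(0, 1). All randomness derives from one seed through named child
streams (profiles, competition, feeder, weights, organs, vigilance, asv), so
regenerating one data stream never perturbs another.

**Competition scores.** At each interval the pen is ordered by
θ + N(0, `noise_sd`); the top `feeder_capacity` (default 3) hens score 3, the
next `score2_band` (2) score 2, the next `score1_band` (2) score 1, the rest
score 0. This is the simplest mechanism consistent with the rubric and the
feeder's capacity; band sizes are configurable. We use 20 intervals per
10-minute test (scoring at 0:30 … 10:00); 21 instants would be an equally
defensible reading, so the count is a parameter.

**Rank recovery is measured against the attainable ordering.** With a
deterministic band rule, hens inside one band receive identical sums at
every interval when `noise_sd = 0`, so no aggregation method can separate
them: the finest recoverable structure is the ordered bands with ties inside
(average ranks 2 / 4.5 / 6.5 / 9 for bands of 3/2/2/3). `rank_recovery`
therefore computes Spearman ρ between the recovered final ranks and this
band-coarsened θ ordering. At zero noise the sorted-sum pipeline recovers it
exactly (ρ = 1 in every pen); recovery degrades monotonically over the noise
grid {0, 0.5, 1, 2, 5} (mean ρ ≈ 1.0, 0.96, 0.95, 0.92, 0.80 over 50 seeds).

**Feeder events.** Per hen per day, visit count ~ Poisson with group means
HR 30 / MID 25 / LR 20 visits·d⁻¹ (dominant hens return to the feeder more
often); per-visit intake ~ Gamma(shape 8) with means HR 6 g / MID 7 g /
LR 8 g (subordinate hens eat more per sitting — the compensation strategy);
occupation time = intake × 12 s·g⁻¹ × lognormal(0, 0.1) noise. Visits are
laid out sequentially from 08:00 with exponential waits so one hen's events
never overlap. These rates imply HR > LR in visits/day, intake/day and
occupation/day but LR > HR in intake/visit, the four directional contrasts
the analysis must reproduce; the daily intake difference (≈180 vs 160 g) is
deliberately modest so the contrast is statistical, not trivial.

**Growth and organs.** Body weight starts at N(1000, 50) g on day 67 and
gains N(20, 3) g·d⁻¹ *identically in all groups* — the study found no rank
effect on weight, so the generator encodes none. Organ weights are drawn so
that organ indices (g organ per kg body weight) match the published group
means/SDs: e.g. heart 4.82 ± 0.71 (HR) vs 4.03 ± 0.29 (LR) g/kg.

**Vigilance.** One categorical 0–2 draw per hen: HR probabilities (0, 0, 1)
and LR (0.125, 0.5, 0.375) reproduce the observed score proportions in
expectation. Multiple sessions can be generated; the analysis reduces them
with a modal rule (ties toward the more fearful score), with `max` and
`last` as alternatives, since how the study collapsed its five sessions to
one score per hen is not stated.

**ASV counts.** A Dirichlet-multinomial: base proportions are heavy-tailed
lognormal across `n_taxa` = 300 ASVs; each sample's composition is
Dirichlet(`dm_concentration` × base) with `dm_concentration` = 50 (strong
overdispersion typical of 16S data), and counts are multinomial at depth
~ Poisson(20 000). HR samples have the base proportions of effect taxa
multiplied by exp(log-fold) (defaults mirror the reported directions:
Firmicutes, Succinatimonas, *Eubacterium hallii* group, Anaerostipes up;
Bacteroides, Mucispirillum, Subdoligranulum, Deferribacterota down), and the
15 % rarest ASVs are structurally zeroed in HR samples. Structural zeroing —
rather than abundance shifts — creates the HR richness deficit without
moving evenness, matching a richness-only alpha-diversity difference.
Taxonomy comes from a fixed mock lineage table covering the phyla and genera
the analysis reports, including "unclassified-at-genus" entries
(Barnesiellaceae, Clostridia UCG-014) to exercise parent-labelled
aggregation.

What the generator does **not** emulate: real 16S error profiles and
chimeras, phylogenetic structure (hence ordination uses Bray–Curtis, not
UniFrac), day-to-day behavioral autocorrelation, and any hen-level coupling
between microbiome and behavior beyond the group labels. Passing tests
demonstrate that the analysis recovers structure the generator planted, not
that the biological claims hold in new data.

## Statistics

- **Two-sample comparisons** use the pooled-variance Student t-test with
  df = n₁ + n₂ − 2. The "SEM" reported beside each comparison is the pooled
  standard error of the difference, √(s_p²(1/n₁ + 1/n₂)) — this, and not the
  Welch standard error, reproduces the published tables' SEM column on every
  verifiable row, which is why pooled is the default and Welch sits behind a
  flag. Raw-sample tests optionally screen each group with Shapiro–Wilk
  (α = 0.05) and natural-log transform positive data that fails, logging the
  decision per variable.
- **Wilcoxon rank-sum**: for n₁ + n₂ ≤ 12 the two-sided p is computed by
  full enumeration of all C(n₁+n₂, n₁) label assignments of the pooled
  values — exact under ties — as P(|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|); larger
  samples use the tie-corrected normal approximation.
- **Chi-square**: Pearson X² with no continuity correction (the published
  vigilance X² = 7.27 is the uncorrected value); zero row/column margins are
  rejected, and the pipeline drops score categories observed in no bird
  before testing.
- **Correlation screen**: Spearman ρ per (taxon, trait) pair with two-sided
  p and stars at 0.05/0.01; rows are ordered for display by average-linkage
  clustering of correlation profiles. Constant columns yield a flagged
  undefined coefficient. No multiple-testing correction by default (matching
  the analysis being replicated); Benjamini–Hochberg is available for the
  taxa screen.
- **Reporting** rounds half-up to 2 decimals in the replication layer only;
  all computation is done unrounded.

Cells of the published tables that cannot be recovered from their own
rounded summaries — bursa p, Shannon/Simpson/Pielou p, and the chao1 SEM
(off by 0.01 from re-computation) — are marked *known-excluded* by the
replication harness rather than failed: re-deriving a p-value from
two-decimal means and SDs cannot round back onto those printed values.

## Microbiome conventions

- **Shannon in bits** (log base 2). This is forced by internal consistency
  of the published numbers: evenness 7.58/log₂(774.5) ≈ 0.79 matches the
  printed Pielou value, while the natural-log version would exceed 1, which
  is impossible for an evenness.
- **Simpson** is Gini–Simpson, 1 − Σp² (the published ≈ 0.98 scale).
- **Chao1** uses the bias-guarded form S + F₁(F₁−1)/(2(F₂+1)), defined when
  doubletons are absent.
- Alpha indices are computed on raw counts by default; rarefaction to the
  minimum depth is available (`rarefy`) since whether the original indices
  were rarefied is unstated.
- **Ordination** is classical PCoA (double-centered Gower matrix,
  eigendecomposition) on Bray–Curtis dissimilarities of relative abundances.
  Bray–Curtis replaces weighted UniFrac deliberately: the pipeline has no
  phylogenetic tree, so the ordination is illustrative rather than a
  replication surface. Negative eigenvalues are reported, never clamped;
  coordinates use positive eigenvalues only, and each axis's sign is fixed
  by making its largest-magnitude coordinate positive.
- **Differential abundance** defaults to the Wilcoxon rank-sum on
  proportions (robust at n = 8 per group); a t-test mode exists. The
  permutation type-I rate of this screen is measured in the acceptance
  suite (≈ 0.04 at α = 0.05 — conservative because the U distribution is
  discrete at n = 8 + 8).

## Problem sizes

Defaults run the full emulated design (40 hens, 24 feeder days, 300 ASVs at
~20 000 reads). Some tests use a scaled-down bundle (80 ASVs, ~4 000 reads,
7 feeder days) where only structural properties are asserted; Monte-Carlo
assertions (20–50 seeds, 1000 permutations) always run at the full design
sizes stated above.

## Known limitations

- The band-scoring idealization makes within-band hens indistinguishable at
  zero noise (see rank recovery above); real observation rubrics likely leak
  more information (partial orderings within the feeding group).
- The generator draws vigilance and microbiome data conditionally on the
  group label only; it cannot exhibit hen-level mediation between behavior
  and taxa, so the correlation heatmap on synthetic data shows group-driven
  structure.
- Cross-pen absolute comparisons of sorted sums are meaningless by design.
- No Elo/Bradley–Terry/David's-score alternatives; the sorted sum is the
  method under study.
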