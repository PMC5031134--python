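# Methods

## Model and procedure

`domarch` treats a protein's domain architecture — the N→C ordered sequence of
its domain signature accessions — as a proxy for function, and the equality of
architecture labels as the clustering relation. The pipeline is:

1. **Annotation parsing.** InterProScan 5 tab-separated output is read per
   genome. Only columns 1 (protein accession), 4 (analysis), 5 (signature
   accession), 7 (start) and 8 (stop) are required; coordinates are 1-based
   inclusive and never converted. Hits are filtered by signature database
   (default: Pfam only; TIGRFAM and InterPro-integrated accessions are
   selectable). Duplicate hits are retained — no redundancy pruning anywhere.
   Only proteins with at least one hit participate in any analysis; SB cluster
   sets are restricted to the same annotated universe before comparison.
2. **Ordering and labeling.** Hits of one protein are ordered by start
   position. Alphabetic (lexicographic, on the accession) order applies to two
   tie classes: pairs with identical starts (whether or not they overlap), and
   overlapping pairs whose starts differ by strictly less than 3 amino acids.
   The canonical label joins the ordered accessions with `;`.
3. **Clustering and matrices.** One cluster per distinct label; the cluster id
   *is* the label, so independently computed analyses merge trivially. The
   genome × architecture abundance matrix counts proteins per label per
   genome; the binarized view (count ≥ 1) feeds persistence, Heaps and PCA.
4. **Pan-genome statistics.** Persistence = genomes carrying the cluster ÷
   genomes considered; core = persistence 1; singleton = exactly one protein
   (a one-genome cluster of several paralogs is *not* a singleton). Ratios are
   plain quotients; a half-up 2-decimal rounding is offered because that is
   how such tables are conventionally printed, and the raw quotient is always
   retained.
5. **Openness.** Over random genome orderings, y(j) = number of architectures
   first seen at the j-th genome. The model `y = κ·j^(−α)` is fitted by
   nonlinear least squares (scipy `curve_fit`, bounds κ, α > 0) on the points
   pooled over permutations with j ≥ 2, initialized at κ₀ = mean y at j = 2,
   α₀ = 1. α < 1 ⇒ open, α > 1 ⇒ closed; α = 1 is reported open with a note.
   Orderings are sampled with replacement by a single seeded generator.
6. **Cluster-set comparison.** Directional counterpart counts, the
   {1,…,5,6+} histogram, one-to-one (exact set equality) agreements, and the
   domain-count composition of one-to-one clusters.

## Numerical and design choices

* **Tie-rule transitivity.** The pairwise ordering rule can be intransitive on
  chains (A–B and B–C within the 3-aa overlap window but A–C not). The
  implementation pre-sorts canonically by (start, end, accession) and then
  applies a comparison sort with the literal pairwise comparator: on every
  instance where the rule is transitive — all realistic ones — the result is
  exactly the rule's total order, and on pathological chains the result is
  still deterministic and permutation-invariant, with a logged warning. A
  quantized two-key sort (grouping chained hits and sorting each group fully
  alphabetically) was considered and rejected: it contradicts the literal rule
  on transitive chains (e.g. hits Z@10–100, A@12–50, M@14–120 order A, Z, M
  under the rule but A, M, Z under group-alphabetic sorting).
* **Strictness of the 3-aa window.** "< 3" is implemented as a strict absolute
  difference of starts, applied only to overlapping pairs; non-overlapping
  hits with close starts stay start-ordered.
* **Fit scale.** Least squares on the natural scale, because zero new-cluster
  counts are common and a log transform would need pseudo-counts; a
  log–log regression is available behind `log_scale=True` for sensitivity
  analysis. Pooled points are fitted rather than per-j means (`use_means`
  flag available); the two coincide in expectation.
* **PCA.** Columns are mean-centered but not variance-scaled — the standard
  treatment for presence/absence ordination, where scaling would inflate rare
  architectures. Scores are deterministic up to component sign.
* **Outlier flagging** is advisory: a genome is reported when its PCA-space
  distance to the centroid exceeds 4× (configurable) the median distance.
* **Degenerate inputs.** Identical genomes ⇒ zero-variance PCA (all-zero
  scores, warning) and a "degenerate" openness call with no fit attempted;
  no singletons ⇒ core/singleton ratio reported as an explicit undefined
  marker, never infinity; empty annotation files ⇒ empty annotation plus a
  warning; a protein id on two cluster-file lines ⇒ hard error.
* **Published count tables as inputs.** Hand-entered summary tables
  occasionally violate internal consistency (singletons exceeding the pan
  size in one published SB row); `PangenomeSummary` warns rather than refuses,
  since computed summaries can never trigger the condition.

## The synthetic generator

The generator emulates exactly what the analyzers consume: per-genome
protein → label maps, InterProScan-style TSV files (fabricated non-overlapping
coordinates, starts 120 aa apart so the tie-break path is never triggered
accidentally — dedicated fixtures exercise it deliberately), and paired
DAB/SB clusterings with configured one-to-one, split and merge counts.

Occurrence is i.i.d. per architecture across genomes: core architectures in
every genome, accessory strata by independent coin flips at a stratum
probability, private singletons per genome at a Poisson rate, optional
two-copy paralogs. There is no phylogenetic correlation, no sequence-level
realism, no domain-boundary noise and no database-version drift — so passing
tests demonstrate correctness of the bookkeeping and estimators under the
stated model, not robustness to the annotation noise of real data. Ground
truth is recorded from the *realized* sample (an accessory architecture that
lands in every genome counts as core), which is what makes exact
generator–analyzer agreement a meaningful check.

Default study-condition choices: architecture length distribution decaying as
{1: 0.70, 2: 0.17, 3: 0.07, 4: 0.03, 5: 0.02, 6: 0.01}, mimicking the steep
single-domain dominance seen in real one-to-one composition tables; Heaps
permutation default 5 × 10³ (tests and the acceptance script use 50–500, which
keeps Monte-Carlo spread in α̂ well under 0.05); persistence histograms use 20
equal bins on (0, 1].

For openness-recovery fixtures, `power_law_strata` solves a non-negative
least-squares mixture over an occurrence-probability grid so that the expected
first-discovery curve equals κ·j^(−α) at every j = 1..n: for an architecture
carried with probability p, the chance of first appearing at rank j of a
random ordering is p(1−p)^(j−1). Direct sampling of probabilities from the
asymptotic power-law density was tried first and biased α̂ upward by ~0.14 at
50 genomes (finite-j corrections dominate the small ranks), which the
calibrated mixture removes.

## Problem sizes

Tests and the acceptance script run at desk scale: 10–100 genomes, tens to a
few hundred architectures, 50–500 permutations, 200 random partition pairs of
up to 500 proteins. These sizes give exact agreement checks and stable
estimator recovery (α̂ within ±0.01–0.03 of truth on calibrated fixtures)
while completing in seconds. Full-scale analyses (hundreds of genomes,
~20 000 architectures) use the same code paths; the matrices are plain dense
integer arrays, which at that scale remain well under a gigabyte.

## Known limitations

* Architecture equality is exact: InterPro parent/child hierarchies are not
  collapsed, Pfam clans are not merged, and partial domain hits are not
  pruned. All three would change cluster granularity and are deliberately out
  of scope.
* The Heaps' fit quantifies openness only; it is not a pan-genome size
  estimator, and no binomial-mixture or tree-aware models are provided.
* SB clusterings are consumed, never computed: no Blastp, OrthAgogue or MCL
  is run.
* The i.i.d. occurrence model ignores phylogeny; accumulation curves of real
  taxa with strong population structure will deviate from the synthetic ones.
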