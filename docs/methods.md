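# Methods

This note documents the models, conventions and numerical choices behind
`nlrevo`, what the synthetic-data generators do and do not emulate, and the
known limitations.

## NG86 Ka/Ks estimation

The estimator is the Nei–Gojobori (1986) counting method with Jukes–Cantor
correction, the classical default for gene-family surveys (users comparing
against MEGA should select its NG86 mode; maximum-likelihood codon models
are out of scope).

* **Sites.** Each codon position contributes (synonymous single-nucleotide
  changes at that position)/3 to the synonymous site count; a change that
  creates a stop codon counts as nonsynonymous. Site totals are averaged
  over the two sequences; N = 3·(ungapped codons) − S.
* **Differences.** Codons differing at k positions are scored by averaging
  synonymous/nonsynonymous steps over all k! orderings of the changes;
  orderings passing through a stop codon are excluded (if all are blocked,
  all orderings are used so the count is still defined).
* **Correction.** d = −(3/4)·ln(1 − (4/3)·p) applied to p_s = Sd/S and
  p_n = Nd/N separately. p ≥ 3/4 raises a saturation error and the pair is
  reported as not computable. Note that a single two-fold degenerate codon
  pair (e.g. GAA/GAG) saturates by construction — one synonymous difference
  over a third of a site — so finite Ks values require realistic sequence
  lengths.
* **omega.** Ka/Ks, undefined (excluded from summaries, not infinite) when
  Ks = 0.
* **Gaps.** Pairwise deletion: gap columns are dropped per pair, both for
  Ka/Ks and for Pi.

## Codon alignment

Coding sequences are aligned through their translations: global
Needleman–Wunsch on the proteins (BLOSUM62, affine gaps) threaded back onto
codons, so gaps only open in multiples of three. Gap penalties are stiff —
open −20, extend −2 — because NLR family members rarely carry indels and
cheaper gaps let highly diverged pairs realign spuriously, which inflates
Ks by roughly 0.1 at Ks ≈ 0.8 under neutral protein evolution. With these
penalties the whole estimator-recovery grid (below) is unbiased, and a
genuine codon deletion still aligns as a single 3-nt gap.

## Duplication dating

T = Ks · g / μ with μ = 9.48 × 10⁻⁹ point mutations per site per generation
(the peach rate) and g = 3 years per generation, reported in million years
to two decimals. This deliberately omits the factor of two for two
diverging lineages used in the T = Ks/2r convention: the published ages
this package is benchmarked against (31.65 / 63.29 / 158.23 MY for Ks 0.1 /
0.2 / 0.5) are only reproduced by the undivided form, so that
operationalization is fixed here and users should be aware dates are on
that scale.

## Family clustering

* Kept edges require identity **and** coverage strictly above the level
  (70/80/90); an edge at exactly 70.0 is dropped.
* Coverage denominator is the shorter sequence of the pair — the permissive
  standard choice, applied identically to internally aligned and
  BLAST-derived edges.
* Families are single-linkage connected components; genes without kept
  edges are singletons. Raising the level can only split components, so
  multi-gene counts are non-increasing in stringency (asserted in tests).
* BLAST tabular ingestion keeps the best HSP (highest bitscore) per
  direction and merges reciprocal directions keeping max identity and max
  coverage. HSP tiling is not attempted (documented limitation: coverage
  from a single HSP understates genes whose similarity is split across
  HSPs).
* The internal aligner is local with match +1, mismatch −2, gap open −5,
  gap extend −2 (BLASTN-like) and is used only when no BLAST table is
  supplied. Identity is matches over aligned columns (gaps included);
  coverage is aligned residues of the shorter sequence over its length.
* Family average identity is the mean over edges between members; it is NA
  for singletons and excluded from family-identity means.

## Trees and duplicated-clade calls

* Neighbor joining on Jukes–Cantor-corrected nucleotide distances with
  pairwise deletion; negative branch lengths are clamped to zero. Saturated
  pairs (p ≥ 3/4) receive a fixed large distance (5.0 substitutions/site)
  to keep the matrix finite; distances that large are unresolvable and
  their placement is effectively arbitrary, which the bootstrap then
  reports as low support.
* Bootstrap: columns resampled with replacement, NJ recomputed, support =
  % of replicates containing the original bipartition (canonicalized so
  rooted/unrooted encodings agree). Deterministic given the seed.
* Unrooted inputs are midpoint-rooted before clade calling; supports are
  reattached by bipartition so rerooting cannot migrate them.
* Clade calls: traversing from the root (the root itself is never called),
  a node with support > 50 and ≥ 2 genes is called species-specific when
  its genes are from one species, lineage-specific when it spans ≥ 2
  species **and** contains a within-species duplicate pair. A two-species
  clade with one gene each evidences speciation, not duplication, and is
  not called. Calls are maximal — descendants of a called clade are not
  re-called — so the reported gene counts partition and no gene is counted
  twice.
* Known limitation of maximality: when several unrelated families sit in
  one tree, a deep join between them occasionally attracts chance bootstrap
  support above 50 and absorbs its subtree into a single lineage-specific
  call. The pipeline therefore builds one tree per subclass scope (TNL and
  non-TNL separately), and the planted-event recovery experiment places one
  event of each type per tree. On real data the support threshold provides
  the same protection, since deep internodes of NLR trees are rarely well
  supported.
* External Newick trees are read with internal-node labels as supports;
  all-fractional labels (≤ 1) are scaled to percent with a warning.

## Expression screening

* Screen: |log₂FC| ≥ 2 (inclusive) AND p < 0.05 AND FDR < 0.05 (both
  exclusive), applied to precomputed contrast tables — differential
  expression estimation itself is upstream and out of scope, so the screen
  is contrast-agnostic.
* Time-point clustering: log₂(FPKM+1), distance 1 − Pearson over gene
  profiles, average linkage, two-group cut. Constant gene rows are dropped
  (correlation undefined) with a warning. Correlation distance makes the
  grouping invariant to per-gene scaling and to sample order.
* Early/late contrast: per-gene means over ≤ 12 h and ≥ 24 h samples per
  genotype, with Welch t-tests between genotypes per phase.

## Synthetic data: what it emulates, what it does not

The generators provide every pipeline input with known truth, emulating the
*structure* of a six-genome NLR survey — not its biology.

* **Diverged pairs.** Two copies of a random ancestor accumulate proposed
  single-nucleotide changes, rejected if they create a stop. The proposal
  loop steers the *realized* NG86-measured Ks and Ka directly onto their
  targets using incremental site/difference bookkeeping: nonsynonymous
  divergence is driven first (it perturbs the synonymous count more than
  the converse, via pathway averaging), synonymous divergence is topped up
  second, and any event that would push the other statistic past its own
  target is rolled back. Recovery over the grid Ks ∈ {0.05, 0.1, 0.2, 0.5,
  0.8} × omega ∈ {0.2, 1.0} (500 codons, 200 replicates) holds within
  |ΔKs| ≤ 0.05 and |Δomega| ≤ 0.15. Because the stopping rule uses the
  package's own counting, recovery validates estimator/simulator
  consistency, not the mutation process's biological realism: there is no
  transition/transversion bias, no codon-usage bias, no indels, no rate
  heterogeneity.
* **Family sets.** Each family carries one planted event. Species-specific
  events are recent duplications (pairwise Ks drawn from [0.05, 0.3])
  confined to one species; lineage-specific events are ancient duplications
  (Ks from [0.5, 0.9]) whose two lineages are each carried by two species
  with small post-speciation drift (Ks 0.02 per branch). Event timing is
  encoded purely through Ks magnitude; there is no coalescent process, no
  gene loss, no conversion. Within-family identity stays high and
  between-family sequences are unrelated, so threshold clustering recovers
  families exactly — real families straddle the 70% boundary far more
  ambiguously.
* **Domain tables.** Each gene receives an unambiguous TIR/CC/RPW8/NB-ARC/
  LRR architecture consistent with its planted subclass, with 1-based
  inclusive amino-acid coordinates. Real annotations disagree between
  sources and truncate domains; any LRR source is treated as sufficient.
* **Expression.** log-normal baseline per gene, two genotypes × eight time
  points (0–72 h). Planted responders rise monotonically (≤ 0.5 log₂ units
  drift through 12 h, then a 3.5–4 log₂ plateau from 24 h) in the resistant
  genotype and follow a 24 h-period sine wave in the susceptible one. The
  companion logFC/p/FDR table makes exactly the planted set pass the
  screen, including distractors that fail precisely one criterion. Counts
  (318 genes, 48 responders) mirror a single-species NLR complement.
* **Determinism.** Every generator draws from a named sub-stream of one
  root seed (hash-derived spawn keys), so outputs are byte-identical for a
  fixed config and adding a generator does not disturb the others.

## Problem sizes in the default test and acceptance runs

Chosen as the smallest sizes at which every recovery statement is stable:
200 replicate pairs × 500 codons for Ks recovery; 120 + 80 pairs × 300
codons for the bimodal histogram; 100 seeds × (2 families × 4 genes, 100
bootstrap replicates) for clade recovery; 100 random graphs ≤ 30 nodes for
the clustering oracle; 100 seeds × (318 genes × 16 samples) for the
expression split. The full pipeline demo uses 6 families × 4 genes × 300
codons with 100 bootstrap replicates.

## Other conventions

* Percentages print with two decimals, ties rounded half-up, matching
  survey reporting style.
* Quartiles use linear (type-7) interpolation.
* Welch's t-test everywhere two groups are compared (equal variances are
  never assumed); the degenerate all-equal case reports t = 0, p = 1.
* Ks histograms use half-open bins [k·w, (k+1)·w), default width 0.1 over
  [0, 1); modal bins are local maxima (leftmost bin of a tied plateau).
* Coordinates in domain tables are 1-based inclusive amino-acid positions;
  gene ids follow `<species>|<gene>`.
* Multiple NB-ARC hits: the first (smallest start) anchors the N-terminal
  test. Multiple LRR hits: any suffices.
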