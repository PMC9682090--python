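# Methods

This note records the models, contracts and numerical choices behind
`foramflow`, the reasoning where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate about real data.

## Read preparation

**Merging.** The merger implements the documented contract rather than any
particular tool's scoring: the reverse read is reverse-complemented and
slid against the forward read's 3′ end; every candidate overlap *o* in
[`min_overlap`, `max_overlap`] is scored by its mismatch ratio
(mismatches / *o*); the minimum-ratio overlap wins, ties going to the
longest overlap, and the pair is accepted when the ratio is at most
`max_mismatch_ratio` (defaults 50, 300, 0.2). At disagreeing overlap
positions the base with the higher Phred score is kept (ties keep the
forward base, making the rule symmetric up to that documented tie); the
consensus quality is the maximum of the two. The published combined-quality
formulas of specific mergers are deliberately not reproduced — only the
three parameters above are normative.

**Primer trimming.** The degenerate primers (fwd
`GWGGWGTTAATGCTGGTYGAAC`, rev `RWRCTTCWGGATGWCTAAGARATC`) are matched
IUPAC-aware — a degenerate code matches any base in its set, `N` matches
everything — as a whole-primer prefix (suffix) alignment with unit-cost
edits up to `ceil(0.2 × primer length)`, requiring at least 10 matched
primer bases, mirroring the error-rate semantics of cutadapt-style
trimmers at the level this pipeline needs. Trimmed reads shorter than
10 bases are rejected.

**Quality truncation.** `-fastq_truncqual`-style truncation cuts
immediately *before the first base with Q < 20* (strict `<`): a read whose
scores never drop below 20 is untouched and a read starting at Q10 becomes
empty and falls to the length filter. Whether the original tools used `<`
or `≤` at the boundary is not documented anywhere we could anchor to; the
strict reading matches the usual gloss "bases below a quality score of 20"
and is fixed here as the contract.

**Length filter.** Inclusive on both ends (315 ≤ len ≤ 325): "outside the
range" excludes only strict outsiders, and the 321–323 bp reference
amplicons must survive. Every rejected read is attributed to exactly one
stage (merge, forward primer, reverse primer, post-trim length, quality/
length), and the per-stage counts reconcile with input minus output; the
run manifest asserts this.

## Denoising

Dereplicated uniques are processed in descending abundance (ties broken by
lexicographically smaller sequence, so the procedure is deterministic). A
unique *u* merges into the first accepted centroid *c* with
`size(u)/size(c) ≤ β(d) = 1/2^(αd+1)`, α = 4, where *d* is the unit-cost
edit distance (substitutions and indels); otherwise *u* founds a new
centroid. Uniques below the minimum abundance 8 are excluded before
clustering. Two deliberate choices: the merge target is the *first*
eligible centroid in abundance order (not the nearest — the greedy
published description, and deterministic), and clustering is pooled across
samples into one ASV space with per-sample counts retained, because the
analysis reports a single ASV table. The banded edit-distance shortcut
(skip centroids whose distance bound already makes β too small) provably
never changes the outcome; an exhaustive restatement of the rule serves as
the test oracle on hundreds of random instances. Total reads are conserved
by construction. Chimera removal is not part of the contract and is not
implemented.

The relative-abundance cutoff zeroes counts with
`count / pre-filter sample total ≤ 1e-4`; the `≤` makes exactly 1 read in
10,000 disappear while 2 reads stay, matching the worked example the
parameters came with. Thresholds always use pre-filter totals, which makes
the operation idempotent with frozen totals.

## Pairwise identity and database search

Global identity is defined as **matches / alignment columns of a global
(end-to-end) alignment, gap columns counting in the denominator**.
Minimum-edit alignments are not unique, and co-optimal paths can carry
different match counts (even making a naive implementation asymmetric), so
the definition is pinned down as the *maximum match count over all
minimum-edit-distance alignments*; with unit costs every non-match column
is one edit, hence identity = M/(M+d). This is computed exactly by one
vectorised dynamic programme minimising `d·2^20 − M`, is symmetric by
construction, and agrees with an independent cell-by-cell DP oracle on
random pairs. Including gap columns in the denominator is the conservative
choice and keeps the measure order-independent; which exact identity
definition produced the published 75/80/84/96/99.4 thresholds is unknown,
so those printed values are carried as configuration defaults regardless.

Database search aligns each full query against every reference with free
end gaps on the reference side (the database is tens of sequences, so
exhaustive alignment is exact and still instantaneous; no heuristic
seeding). A hit requires query coverage ≥ 0.90 and identity > 0.75; the
maximum-identity hit assigns taxonomy truncated at the deepest rank whose
threshold the identity *strictly* exceeds (the thresholds are printed as
"> X %"), with genus surviving only inside a species-level call since no
genus threshold exists. Ties at the maximum identity keep all tied labels
and use their deepest common taxon — the same semantics as composite
reference entries.

## Reference building and threshold calibration

Per species, candidate barcodes are ASVs seen in at least two of its
specimens; the candidate with the largest summed abundance wins (ties to
the lexicographically smaller sequence). A shared-by-two candidate always
beats a larger single-specimen ASV — sharing is the authenticity
criterion. Species without a candidate are excluded and reported. Species
whose chosen barcodes are identical merge into a composite entry labelled
`SpA/SpB` whose path is the members' deepest common prefix; composites are
first-class taxa downstream.

The calibration criterion was an open design point: the source material
states thresholds "representing the database best" without a rule. The
rule adopted here: for each rank, entry pairs split into within (sharing
the rank's taxon) and between; a threshold *t* misclassifies a within pair
with identity ≤ *t* or a between pair with identity > *t*; the violation
count is piecewise constant between observed identities, and among
minimising intervals the widest is taken, *t* at its midpoint (for
separable data this is the midpoint of the single error-free gap).
Thresholds are then made non-decreasing with rank depth by
pooled-adjacent-violators averaging (exact ties nudged by 1e-9 to keep the
strict-increase invariant). A rank with no between pairs has no upper
anchor and is reported as undefined rather than guessed. The full
within/between identity distributions and all violating pairs are exported
so the calibration is auditable.

## Detection, validation, rarefaction

Presence is ≥ 1 read after the abundance cutoff — no extra read floor, as
taxa at very low counts are real detections in this assay. A species is
detected at a site when present in strictly more than half of the
successfully amplified replicates (3 of 5 detects; 3 of 6 does not;
replicates that failed to amplify are excluded from the denominator before
the call). Mock communities are scored by four metrics, each as
numerator/denominator: expected species present in all replicates,
expected species detected by the majority rule, replicates containing
every expected species, and replicates containing any species outside the
expected set. Because "erroneous species" could be read as a replicate
count or a species list, the report stores both (the per-replicate count
and the distinct intruding species).

Expected rarefied richness uses the exact hypergeometric form
`E[S_n] = Σ_i (1 − C(N−N_i, n)/C(N, n))`, evaluated with log-gamma for
stability; tests check it against Monte-Carlo subsampling within three
standard errors (with a 1e-3 absolute floor, the resolution of the
Monte-Carlo estimate itself).

## Community statistics

Bray–Curtis: `d(x,y) = 1 − 2·Σ min(x_i,y_i) / Σ (x_i+y_i)` (via scipy);
two all-zero samples make the distance undefined and raise, naming the
pair. ANOSIM ranks all n(n−1)/2 dissimilarities with average ranks on
ties; `R = (mean between-rank − mean within-rank)/(M/2)`. One-way
PermANOVA uses the direct sums
`SS_total = Σ_{i<j} d²_ij/n`, `SS_within = Σ_g Σ_{i<j∈g} d²_ij/n_g`,
pseudo-`F = (SS_between/(a−1))/(SS_within/(n−a))`, `R² = SS_between/
SS_total`; on Euclidean distances this equals the classical MANOVA-trace
F computed from coordinates, which is the cross-check oracle. The
multifactor case is restricted to sequential (Type-I) tests through the
distance-based linear model: Gower-centred inner-product matrix, hat
matrices of the growing design, `SS_term = tr((H_t − H_{t−1}) G)`, each
term's F against the full-model residual. Sample identities are permuted
freely, except that a term declared nested (site within location) permutes
samples only within its parent's levels — a stated, simple exchangeability
unit; full restricted-permutation frameworks are out of scope. A term
fully confounded with earlier terms (zero added rank, e.g. habitat vs its
one-to-one site) reports NaN F and p = 1. All permutation tests use 999
permutations and `p = (1 + #{perm ≥ obs})/(1 + n_perm)`, so the smallest
attainable p is 0.001 — the convention behind every "p = .001" this kind
of study prints.

NMDS is nonmetric SMACOF written here so that the stress trajectory is
observable: per iteration, disparities are the isotonic regression of the
embedded distances onto the observed dissimilarity order (scaled to the
embedded sum of squares), Kruskal stress-1
`sqrt(Σ(θ−δ)²/Σδ²)` is recorded, and a Guttman transform updates the
configuration; iteration stops when stress improves by < 1e-7 or at 300
iterations. Four seeded random starts plus one classical-scaling
(eigendecomposition) start are run and the best stress wins; results are
deterministic under the seed. Monotone non-increase of the stress
trajectory is asserted in tests at the seeds used.

## Synthetic data: what it emulates, and what it does not

The generator plants the exact statistical structure the analysis assumes.
Reference barcodes evolve from one random ~322 bp ancestor down the
six-rank taxonomy by substitutions only, every edge mutating positions
globally disjoint from every other edge's, so each leaf-pair Hamming
distance is exactly the sum of per-edge substitution counts on its path.
Per-edge counts (13/7/17/8/2/3 from phylum to species edges, 0-or-1 for
the two within-species populations) place every lowest-common-rank
identity band strictly between the published thresholds, with margin for
the slight upward drift a minimum-edit alignment shows over Hamming at
large distances; the generator measures the realised alignment-identity
bands after generation and refuses to emit a database whose bands overlap
or fail to bracket the thresholds. Infeasibility (substitution budget
exceeding the amplicon length) is detected before generation. Two
consequences are accepted openly: all sequences in one database share a
single length drawn from the 321–323 range, and at most two sequences per
species are emitted — a third would push a within-species pair below the
99.4 % species band at this amplicon length.

Communities: mocks hold 8 or 9 species (the study design) at equal nominal
abundance — one specimen each — with multiplicative lognormal replicate
noise (σ = 0.15, a small PCR-replicate jitter; the source gives no value,
this is a stated assumption); bulk sites draw log-normally skewed
abundances (σ = 1) over a 12-species subset, since no abundance
distribution for real sediment communities is documented — these defaults
are assumptions, not claims. Reads are 2×300 bp over the amplicon
(concrete realisation of the degenerate primer sites + barcode), counts
multinomial on abundances, substitution errors independent per mate with
Phred 15–25 at error sites and 30–40 elsewhere, so quality truncation is
exercised while the length filter stays deterministic (no indel errors).
Chimeras default off; a two-parent breakpoint model exists for stress
tests. All randomness flows through one seeded generator; fixed seeds give
byte-identical FASTQ.

What passing tests therefore show: the implementation honours its
contracts, recovers planted parameters, and is lossless on clean data.
What they do not show: robustness to PCR bias, gene copy-number variation
(known to decouple read counts from specimen counts in this marker),
quality-score miscalibration, indel sequencing errors, or chimera loads —
none of which the generator emulates.

## Problem sizes

The bundled demo runs 6 mocks × 5 replicates plus 10 bulk sites × 5
replicates at 400–1000 read pairs per replicate over a 21-species
reference (42 sequences with two populations per species) — deliberately
desk-scale so the complete pipeline, the 20-seed calibration-recovery
sweep, and the acceptance checks all run in minutes on one CPU. Depth
matters only through the abundance cutoff (at 10,000 reads per sample the
cutoff removes exactly singletons) and the minimum-abundance prefilter;
both are exercised directly by unit tests at the published magnitudes.

## Known limitations

- The merger assumes the standard convergent pair geometry; staggered
  pairs with adapter read-through are out of scope.
- The identity definition, while exact and symmetric, is one of several
  defensible conventions (e.g. excluding end gaps); calibrated thresholds
  shift slightly between conventions, which is why the threshold defaults
  are configuration, not derived values.
- The multifactor PermANOVA permutes raw sample identities (within parents
  for nested terms); residual-permutation schemes would differ for small
  samples.
- Composite reference labels are single taxa; they can only be split by an
  explicit label-grouping map.
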