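# Methods

## Model and procedure

The package operationalises EDGE prioritization (Evolutionarily Distinct
and Globally Endangered) for a clade with incomplete molecular sampling.
Its inputs are a rooted, time-calibrated, ultrametric phylogeny of the
sequenced species and a species table carrying genus membership, IUCN Red
List category, a sampled flag and region occurrences. The analysis
proceeds in five stages.

1. **Tree handling.** Trees are dendropy objects read from Newick.
   Underscores in unquoted labels are kept literal (species names are join
   keys against the table; silent underscore-to-space conversion would
   break the join). Every non-root edge must carry a non-negative length;
   a length on the root itself is a stem with no fair-proportion owner set
   and is ignored for leaf depths and PD (warned, not erased). Polytomies
   and zero-length edges are allowed throughout. Ultrametricity is
   validated as max−min leaf depth ≤ rel_tol × max depth, default rel_tol
   1e-6 (dating software emits floating-point lengths; exact equality is
   unrealistic). Pruning suppresses unary internal nodes by summing the
   incident edge lengths but keeps a unary root, so retained leaf depths
   never change.

2. **Imputation.** Each species lacking sequence data is grafted into its
   genus. Candidate edges are those strictly inside the genus crown clade;
   when a genus has a single sampled member, that leaf's pendant edge is
   the candidate. The attachment point is one uniform draw over the total
   candidate branch length — so edges are chosen with probability
   proportional to length and the height along the chosen edge is uniform.
   This matches the behaviour of the R function the field uses for this
   step (phytools `add.species.to.genus`, option "random"), which samples
   `runif(1) * sum(edge.length)` over the genus subtree. A rule choosing
   candidate edges uniformly regardless of length was considered and
   rejected: it over-weights the many short deep edges and is not what the
   reference tool does; the difference moved downstream rank recovery only
   slightly. The new pendant edge runs to the tree height, preserving
   ultrametricity. Grafts within a replicate are applied sequentially in
   species-table order, so later congeners can attach to earlier grafts
   and congeners cluster. A genus with no sampled member is a hard error —
   there is no anchor, and a silent fallback would be untestable.
   Replicate r draws from `SeedSequence((seed, r))`, so each replicate is
   a pure function of (tree, seed, r) and replicates are reproducible
   independently.

3. **Distinctiveness.** Fair-proportion ED divides each edge length by its
   descendant leaf count and sums along each root-to-tip path; values are
   computed per replicate and summarised by the per-species median (even
   counts: mean of the two middle order statistics). ED is computed per
   replicate and the median taken — not ED on a consensus tree — so the
   placement uncertainty of grafted species propagates into the summary.
   Σ ED = PD holds to ~1e-15 relative on every tree (it is an algebraic
   identity; the tolerance covers float summation order).

4. **Scoring.** Categories are converted to extinction probabilities under
   two schemes: ISAAC (LC 0.025 doubling to CR 0.4) scored as
   `ln(1+ED) + GE·ln2`, and IUCN50 (LC 0.00005, NT 0.004, VU 0.05,
   EN 0.42, CR 0.97) scored as `ln(1 + ED·p_ext)`, the log expected PD
   loss. The two ISAAC forms are algebraically equivalent
   (GE·ln2 = ln(p/0.025)), which the tests assert to 1e-12. The IUCN50
   formula reproduces the published worked example (ED 315.00, EN →
   4.89) to two decimals; residual ≤0.03 differences on some published CR
   rows are documented upstream and not chased. DD and NE species are
   scored as CR (a deliberate worst-case so unassessed species are not
   overlooked); EW, listed among threatened but given no probability by
   either scheme, is also scored as CR. All rankings use competition
   ("1-2-2-4") ranks with exact-value ties — no rounding before tie
   detection. The threatened-ED ranking (raw VU/EN/CR/DD/NE/EW by
   decreasing median ED) provides a prioritization independent of the
   probability transformation. User-defined schemes can be supplied as
   JSON (name, category→probability map, formula).

5. **Comparison and spatial tests.** Rank deltas are
   `rank_alternative − rank_reference` (reference defaults to IUCN50;
   negative = reference prioritizes), with |Δ| ≤ 10 treated as equivalent.
   Top-k sets include boundary ties (competition ranking makes "top 100"
   ambiguous otherwise; inclusion is deterministic and the set size is
   logged). Per region, the observed number of top-set species is tested
   against Binomial(k_total, richness_r / total_species) with the
   two-sided exact binomial test, method of small p-values (the sum of all
   point probabilities no larger than the observed one) — the conventional
   definition, needed because regions can be flagged for either excess or
   deficit. The null is proportionality to richness; with multi-region
   occurrences the trials are not strictly independent, so the test is an
   approximation, used as a flagging device. No multiple-testing
   correction is applied by default (matching common practice for this
   analysis); Benjamini–Hochberg adjustment is available behind a flag.
   α defaults to 0.05.

## Synthetic data: what it emulates, what it does not

The generator exists so every stage is exercisable end to end without
external data. It emulates: an ultrametric species tree (pure-birth/Yule,
rescaled to a root age of 340 Myr, roughly the crown age of living
gymnosperms); monophyletic genera obtained by cutting the tree at the
shallowest level yielding the requested genus count; Red List categories
drawn i.i.d. at the frequencies of the 1,090 gymnosperm species (LC 416,
NT 167, VU 156, EN 161, CR 80, EW 4, DD 20, NE 86); region occurrences
with phylogenetic signal (a primary region evolving as a uniform-jump
process at 0.01 events/Myr over 20 regions, plus a 10% chance of one extra
region); and a sampling mask of 167/1,090 ≈ 15.3% unsampled species with
every genus keeping at least one sampled member. Defaults: 1,090 species,
80 genera (the real genus count is not published; ~13–14 species per genus
matches the checklist's scale and is configurable).

It does **not** emulate: diversified or clade-correlated extinction risk
(categories are i.i.d., whereas real threat status clusters
phylogenetically and geographically), rate variation or the deep
genus-stem/young-crown structure of the real gymnosperm tree (Yule trees
are "busier" near the present), extinct lineages, realistic biogeography
beyond clustered primary regions, or taxonomic error. Passing tests on
synthetic data therefore demonstrate the machinery — conservation
identities, placement validity, ranking and test correctness,
reproducibility — not that any particular real ranking is correct.

## Numerical choices

* Ultrametricity tolerance 1e-6 relative (validation); simulator output is
  ultrametric to ~1e-15 relative.
* Conservation (Σ ED = PD) asserted at 1e-9 relative; observed ~1e-15.
* Exact binomial p-values delegated to `scipy.stats.binomtest` and checked
  against direct enumeration to 1e-12 absolute for n ≤ 500.
* Percentages in summaries are rounded half-up to one decimal (report
  convention); full precision is kept in CSV outputs.
* Ties in all rankings are exact float equality; tied scores share the
  minimum rank.
* Degenerate inputs: a single-leaf tree is ultrametric by definition and
  its only edge is a root stem (depth 0); zero-length edges contribute 0
  to PD/ED and receive zero attachment probability; an empty threatened
  subset yields an empty ranking; empty inputs to summaries report
  not-applicable percentages.
* Seeds: every stochastic routine takes an explicit seed and derives
  independent substreams via `numpy.random.SeedSequence`; outputs are
  bitwise reproducible.

## Problem sizes used in the checks

The test suite exercises trees up to 200 leaves (oracle comparisons on 100
random trees of ≤ 64 leaves) and the acceptance script runs the synthetic
study at full scale — 1,090 species, 80 genera, 167 grafted species, 100
replicates — plus a parameter-recovery experiment at 200 species × 10
seeds × 10 replicates. These sizes keep a full run in the low minutes on
one CPU while covering the scale the method is used at.

## Known limitations

* ED recovery after masking + imputation is bounded by identifiability:
  the median ED of a grafted species reflects its genus, not its true
  position (measured mean Spearman ρ ≈ 0.88 against true-tree ED at 15%
  missing over all species; ≈ 0.93 among sampled species; ≈ 0 among the
  imputed ones). Rankings of species added without sequence data should be
  read as genus-level, not species-level, statements.
* The hotspot null treats regions independently and ignores multi-region
  occurrence dependence; no pooled all-regions statistic is computed (its
  definition is ambiguous).
* Name matching between tree and table is exact-string by design;
  mismatches are reported, never guessed.
* The ISAAC/IUCN50 probability tables are fixed constants of the published
  transformations; sensitivity to other transformations is supported via
  user-defined schemes but not explored here.
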