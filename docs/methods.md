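# Methods

This note documents the models and procedures implemented by mse-toolkit,
the parameters that matter, what the synthetic corpus does and does not
emulate, and the numerical choices a maintainer should know about. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Community similarity kernel

The pairwise similarity S(a, b) between two relative-abundance profiles is
computed by a single post-order pass over the reference phylogeny. At each
leaf v the shared mass min(aᵥ, bᵥ) is counted as matched; the residuals
aᵥ − min and bᵥ − min propagate to the parent, each discounted by
exp(−λ·l) for its branch length l, and may match again at any internal
node (children of multifurcations are folded jointly; no binarization).
The root's unmatched residual is discarded and the sum is clipped to
[0, 1] against floating-point accumulation.

Properties: S is symmetric to 1e−12 (the reduction uses only `min` and
sums), S(x, x) = 1, and S is non-increasing in λ. As λ→∞ every internal
match vanishes and S collapses to the taxon-overlap score
Σᵥ min(aᵥ, bᵥ) = 1 − ½·L1, available directly as the `taxon-overlap`
mode. The kernel is a stand-in for Meta-Storms-style phylogenetic scoring
and is deliberately pluggable: search and scoring only consume the
similarity values, so a different scorer with the same signature drops in.

**Discount geometry.** A residual that climbs distance *a* on one side and
*b* on the other before matching is discounted by exp(−λ·max(a, b)) — the
min of the two decayed masses — not by the path sum a + b. Consequently
"farther along the tree" in the plain path-length sense does not always
mean "less similar": what is monotone is divergence depth. Moving mass to
leaves that diverge progressively earlier from the reference lineage
(nested ancestors, so both climb distances grow) never increases
similarity, and that is the form the property tests assert.

λ defaults to 1.0 per unit branch length: with the unit-scale branches of
the simulated trees this yields substantial but not saturating ancestral
matching, keeping S(a, b) < 1 for distinct samples.

The implementation compiles the tree once into flat post-order arrays and
evaluates one query against an entire sample matrix with vectorized numpy,
so a query-versus-database comparison costs a single traversal.

## Reference database and sample store

Profiles are row-normalized, aligned to the tree (taxa that are not leaves
are dropped with a logged warning and the rest renormalized — amplicon
tables routinely contain unplaced features), and stamped with study,
habitat, date/year and sequencing-QC metadata. Quality control keeps a
sample iff read count ≥ 500 and (mapping rate absent or ≥ 0.80); both
thresholds are inclusive, and samples lacking a mapping rate pass that
rule. Near-duplicate curation runs a single greedy pass in chronological
order (full date when present, else December 31 of the bare year; ties by
ascending id): a newcomer whose best similarity against the already-kept
set reaches 0.9999 is dropped, so the later-dated member of each duplicate
pair always loses.

On disk, each sample is re-encoded once against the build-time tree as
(post-order leaf ordinal, abundance) pairs, sorted by ordinal, one small
text file per sample; a JSON manifest records the canonical leaf ordering
(stores are self-describing) and the id→file map. Loading any subset of
samples touches only their files, and every load is appended to an access
log so the candidate-only I/O contract is testable. The default index
table is precomputed at save time for the same reason.

## Two-tier search

Tier one aggregates every profile to genus-level "index keys" (the weight
of a key is the summed relative abundance of its members; taxa without the
rank pool into `unclassified`) and selects the c candidates with the
smallest L1 key distance to the query, ties by ascending id. Tier two
scores only those candidates with the exact kernel and returns the top k
(ties by ascending id). Exhaustive mode skips tier one and is exactly
equivalent to sorting the all-pairs similarity row.

Defaults: k = 10, c = max(15·k, ⌈0.05·|db|⌉), index level = genus. The
coarser phylum level was evaluated and rejected as a default: all samples
of one habitat-like cluster share a nearly identical phylum key vector, so
once a cluster outgrows the candidate pool the tier-one distances cannot
separate its members and indexed top-10 recall on the default synthetic
corpus fell to ≈ 0.68. Genus keys restore recall to ≈ 0.99 at the default
pool while still scoring under a fifth of the database. Both the level
and the pool size are configurable; exactness is guaranteed only in
exhaustive mode and the recall property quantifies the heuristic tier.

Plain `search` keeps a self-hit (a database sample queried against the
database ranks itself first); the scorers exclude it explicitly.

## Scores

With top-n similarities S₁ ≥ … ≥ Sₙ against the *eligible* database
(year ≤ birth year − 1 for novelty; novelty is judged only against what
existed strictly before the sample):

    MNS = 1 − Σ_{i=1..n} Sᵢ·(n−i) / Σ_{i=1..n} (n−i),    n = 10.

The weights are (9, 8, …, 1, 0)/45: the n-th match carries weight zero,
and the formula is implemented verbatim, quirk included. Fewer than n
matches are padded with similarity 0 (an empty eligible database gives
MNS = 1 — a first-year sample is maximally novel by construction).
Depths below n = 2 are rejected: at n = 1 the weight sum is zero.

MAS(m) sums S(m, i) over samples i ≠ m such that (a) m is in i's top-n hit
list (i's self-hit excluded; the pool restricted to year ≤ cutoff when a
cutoff is given), (b) S(m, i) ≥ 0.85, and (c) study(i) ≠ study(m). The
same-study rule is read as "same-study samples cannot contribute to
MAS(m)"; the alternative reading (removing them from each observer's
top-n pool before ranking) is available as a config switch, default off.
MFI = MNS × MAS exactly (the same floats, no re-rounding), and the flags
are inclusive: novel ⇔ MNS ≥ 0.15, high attention ⇔ MAS ≥ 14, focus ⇔
both. The 0.15/14 defaults can be replaced by the top-q MAS quantile
(`mas_quantile_threshold`, 'higher' interpolation so at least a fraction q
of samples sit at or above the returned value).

Because an observer's top-n list is finite, a growing database can
displace a sample from lists it used to occupy: MAS is *not* guaranteed
monotone in the database, only typically so. On the default synthetic
corpus the cohort-mean MAS grows with every yearly offset and individual
year-over-year steps are non-decreasing in the large majority of cases;
the tests assert exactly that, not hard monotonicity.

Scoring offers an exhaustive path (top-n lists read off the cached
all-pairs matrix — the default at desk scale) and an indexed path (per-
observer two-tier searches); the two agree to 1e−9 on the test fixtures.

## Temporal analytics

Accumulation curves are cumulative totals and novel counts per calendar
year per category; the novel-sample ratio is their quotient and its trend
is an ordinary-least-squares slope per year (scipy `linregress`, which the
tests pin to the closed form to 1e−12). The normality report fits the
observed score distribution's mean and SD, draws an equal-size seeded
normal sample, and reports (i) the Pearson correlation between observed
and simulated bin frequencies on shared bins (Sturges' rule by default —
the overlay-curve comparison) and (ii) a two-tailed Welch two-sample
t-test p-value. A literal standard N(0, 1) would be incomparable to scores
centred near 0.15, hence the moment matching. Novelty–diversity
association is a Spearman rank correlation between per-sample MNS and the
Shannon index −Σ p ln p (nats) of abundances aggregated to a chosen rank.

## Attention trajectories and the hybrid predictor

For every sample that was novel at birth (year Y), MAS_i is recomputed
with the database restricted to year ≤ Y + i for offsets i = 1..4 (the
horizon default; in training, a cutoff past the newest sample simply
covers the whole database, while in prediction offsets beyond the present
are treated as unobserved). Ratios MAS_i / MAS_max (0/0 ≡ 0) live in
[0, 1]. The fitted model has two parts:

* **Reg_i** — the expected maximum-MAS ratio at offset i from a pooled OLS
  regression of ratio on offset over all training trajectories (all-zero
  trajectories excluded: they carry no shape information), clipped to
  [0.05, 1]. The floor prevents the estimator below from dividing by a
  near-zero early-offset expectation.
* **RF_i** — feature importances of a 500-tree random-forest classifier
  (fixed seed, single-threaded) trained on the four ratio features to
  discriminate focus from nonfocus trajectories, normalized to sum 1.
  Reported accuracy is stratified k-fold cross-validation with
  k = min(5, minority-class size), at least 2.

The maximum future MAS of a sample with observed offsets O is

    MAS_max = Σ_{i∈O} (MAS_i·RF_i / Reg_i) / Σ_{i∈O} RF_i,

an importance-weighted average of per-offset extrapolations; with a single
observed offset it reduces to MAS₁/Reg₁ for any importances. Estimates are
non-negative and scale linearly in the MAS inputs. *Sleeping beauties* are
samples novel at birth, currently below MAS 14, with at least one observed
offset and an estimated maximum ≥ 14. The fitted component follows the
Model/Results convention (`HybridAttentionModel(...).fit()` returns a
results object with `summary()` and JSON round-tripping) because it is the
one genuinely fitted model in an otherwise procedural toolkit.

The classifier trains on max-normalized ratios by default; a raw-MAS mode
exists behind a flag. `discrimination_report` adds a 2-component PCA
projection of the features for plotting.

## Synthetic study conditions

The generator emulates a public 16S repository at desk scale,
apportioning one `numpy` Generator seed across every draw; serialization
uses shortest-round-trip float formatting, so outputs are byte-identical
across runs. Defaults (~840 samples):

| Parameter | Default | Meaning |
| --- | --- | --- |
| `n_leaves` | 200 | OTUs / tree leaves |
| `n_habitats` | 5 | established habitats, sampled every year |
| `years` | 2010–2017 | corpus span |
| `samples_per_habitat_per_year` | 20 | one study per (habitat, year) |
| `dirichlet_concentration` | 50 | within-habitat dispersion |
| `support_fraction` / `overlap_fraction` | 0.30 / 0.10 | archetype sparsity and sharing |
| `rank_abundance_scale` | 2.0 | e-folding of archetype rank abundances |
| `emergent_habitat_year` | 2016 | pioneer cohort's birth year |
| `emergent_cohort_size` | 5 | planted sleeping beauties (one study) |
| `follow_up_per_year`, `follow_up_decay` | 13, 2/13 | tapering follow-up wave |
| `pioneer_concentration_factor` | 1000 | pioneers sit at the archetype centre |
| `follower_concentration_factor` | 4 | followers scatter around it |
| `orphan_cohort_size` | 5 | novel habitat never resampled |
| `n_planted_duplicates` | 5 | perturbed copies (≤ 1e−6), later-dated |
| `qc_fail_fraction` | 0.02 | established samples failing QC |

Trees are forward pure-birth topologies with exponential branch lengths
(mean 0.5); phyla are monophyletic blocks joined on a pure-birth backbone
and genera are ≤ 5-leaf post-order blocks within a phylum. Habitat
archetypes occupy circular windows over the canonical leaf order with
exponentially decaying rank abundances. The e-folding of 2.0 leaves was
calibrated — per the generator's own test contract — so that two draws
from the same archetype at concentration 50 typically exceed the 0.85
connectivity cutoff (median within-habitat similarity ≈ 0.86–0.92) while
cross-habitat similarities stay far below it (< 0.85 everywhere, medians
≈ 0.07).

The emergent habitat models delayed recognition: a 5-sample pioneer study
appears in 2016 on a fresh archetype (novel by construction), and a wave
of 13 independent follow-up studies lands the next year, tapering
geometrically afterwards — mirroring how organically accrued attention in
the established habitats saturates after the first years. Pioneers are
drawn essentially at the archetype centre while followers scatter, so
every follower is closer to each pioneer than to any fellow follower and
ranks all pioneers at the top of its list; planted attention per pioneer
is then ≈ follower count × 0.95, uniform across pioneers and safely
inside the "asleep but predicted to awaken" window. The orphan habitat is
the control: equally novel, never followed, MAS identically zero. Ground
truth records pioneers (expected focus), orphans (never-followed novel),
duplicate pairs and planted QC failures.

What the generator does **not** emulate: sequencing reads and their error
modes, chimeras, primer/region effects, copy-number variation (the
copy-number normalizer is exercised with explicit tables in tests),
uneven yearly deposition, habitat imbalance, or batch effects. Passing
recovery tests therefore demonstrates the *machinery* — curation, search,
scoring and prediction recover what was planted under controlled
conditions — not that real corpora exhibit these dynamics.

## Problem sizes and numerics

The test suite and the acceptance script run the default ~840-sample
corpus, a ~310-sample fixture for search-oracle equivalence, a
~210-sample fixture for attention-oracle equivalence, and a ~180-sample
pipeline for byte-level determinism; these sizes were chosen so every
oracle can be brute-forced honestly while the whole suite stays quick on
a single CPU. Numerical conventions: profile normalization is validated
to 1e−6 and asserted to 1e−9 after renormalization; kernel symmetry to
1e−12; similarity values clipped to [0, 1]; ties everywhere broken by
ascending sample id; all randomness flows from explicit seeds.

## Known limitations

- The kernel is a property-complete stand-in, not a verbatim Meta-Storms
  port; absolute similarity values (and hence absolute MNS/MAS scales)
  will differ from the original engine even though the score machinery is
  identical.
- Indexed search is heuristic; exact results are guaranteed only in
  exhaustive mode.
- MAS computation at repository scale is quadratic in the eligible sample
  count along the exhaustive path; the indexed path trades exactness for
  speed.
- Samples without any timestamp are searchable but excluded from
  year-restricted pools, temporal analyses and trajectories.
- The hybrid model extrapolates within its 4-offset horizon and assumes
  the training cohorts' attention-shape is representative; regime changes
  in deposition behaviour break Reg_i.
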