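# Methods

## Model

`lapp` treats each gene as a binary random variable over a genome panel:
its phylogenetic profile. A logic triplet hypothesis asserts that the
output gene's presence is (approximately) a Boolean function of two input
genes, `c ↔ f(a, b)`, with `f` one of the eight two-input functions that
are non-degenerate in both inputs and biologically interpretable as
pathway structure (types 1–8: AND, NAND, OR, NOR, `a ∧ ¬b`, `¬a ∨ b`, XOR,
XNOR). Types come in complement pairs (1↔2, 3↔4, 5↔6, 7↔8) whose truth
tables are bitwise negations; types 5 and 6 are the only order-sensitive
ones, so three distinct genes span 3 × (6 + 2·2) = 30 ordered hypotheses.

Scoring uses the uncertainty coefficient
`U(c|y) = [H(c) + H(y) − H(c,y)] / H(c)` and
`ΔU = U(c|f(a,b)) − max(U(c|a), U(c|b))`. ΔU is the information the joint
logic explanation adds beyond the best single input; it is ≤ 1, equals
`1 − max(U(c|a), U(c|b))` exactly when `c = f(a,b)` everywhere, and is
near 0 for independent genes. Entropies are in bits; since U is a ratio of
entropies, the base cancels and ΔU is base-independent.

### Balancing

The joint counts `n_ijk` over the eight (a, b, c) scenarios are reweighted
per triplet so that each non-empty ab cell receives equal mass while the
conditional distribution of c within the cell is preserved:
`p′_ijk = (1/M) · n_ijk / n_ij` over the `M` non-empty cells. This is
probability reweighting, never physical resampling; on tables whose cell
sizes divide a common value it is exactly equivalent to replicating
genomes until all cells have equal weight (tested against that
construction). All three U terms of ΔU, and the agreement fraction, use
the same weighting — mixing a balanced `U(c|f)` with raw single-input
terms would make the difference incoherent. The flag is exposed so raw
and balanced variants can be compared.

Consequences worth knowing: under balancing the input marginals are
uniform (`p′(a=1) = p′(b=1) = 0.5`, so H(a) = H(b) = 1 bit), and when the
four cells already hold equal counts, balancing is a no-op and raw and
balanced ΔU coincide.

### Complement disambiguation

Mutual information cannot distinguish `f` from `¬f`, so both members of a
complement pair always share `U(c|f)` and ΔU. A hypothesis is reported
under the member whose truth table agrees with c on more than half of the
weighted mass; at exactly one half both members are suppressed. The
agreement fraction is reported alongside ΔU.

### Filters and significance

Profiles need at least `min_state_count` genomes (default 18) in each
state, and a hypothesis needs at least `min_scenario_count` genomes
(default 18) in each of its input pair's four ab cells — below that the
balanced conditional within a cell is too noisy to be informative. The
filter is evaluated per input pair, so the same three genes can pass for
one output-gene choice and fail for another. ΔU ≥ 0.3 is flagged
significant and ΔU ≥ 0.1 reported, both configurable. These defaults are
the method's published operating point for a 182-genome panel and are kept
as absolute counts, not fractions.

An empirical permutation null is provided (`permutation_null`): the output
profile is shuffled across genomes with a seeded generator and
`p = (1 + #{ΔU_perm ≥ ΔU_obs}) / (n_perm + 1)` (the +1 correction keeps p
positive and finite-sample valid). It is a pragmatic stand-in for an
analytic null of ΔU, which is not available.

## Preprocessing

Genome columns closer than 5% of the row count in Hamming distance
(strict inequality) are deduplicated greedily in input order, removing the
genome with more absences; ties remove the lexicographically greater
identifier so the result is order-independent reproducible. Whether the 5%
threshold is evaluated before or after row clustering is ambiguous in the
original description; it is applied before, matching the stated order of
operations. Genes with identical profiles are collapsed to the
first-encountered representative (the member → representative map is
written as TSV), then low-entropy profiles are dropped. Note the pipeline
as a whole is not idempotent in corner cases: dropping rows can make two
genome columns newly near-identical.

## GO evaluation

A predicted triplet is *putative* when its three genes share at least one
Biological Process term after ancestor expansion, *unannotated* (excluded
from denominators) when any gene has no BP terms. Accuracy is
N_putative / N_all over annotated triplets. Ancestor expansion follows
is_a edges only and keeps ancestors whose depth is at least `min_depth`
(default 4) below the namespace root — "four levels under the root" is
read as suppressing the three most generic levels, since the alternative
(keeping only near-root terms) would make deep, specific terms never
shared. Depth is the minimum path length to the root (a DAG term can have
several path lengths; the minimum is deterministic). part_of edges are
ignored; a different traversal would need only a change in the edge filter
of `read_ontology`. Reporting operations: accuracy per half-open ΔU bin
`[x, x+w)` of width 0.05 labelled by bin centre (a value exactly on an
upper edge belongs to the next bin, with a 1e-9 tie tolerance), and the
cumulative putative fraction along the descending-ΔU ranking.

## Synthetic benchmarks

The generator emulates the three features of real ortholog matrices that
matter to triplet scoring:

- **gene-frequency heterogeneity** — background genes are independent
  Bernoulli rows whose frequencies default to Beta(0.5, 0.5), a U-shaped
  law giving many near-universal and many rare genes;
- **scenario skew** — planted triplets assign genomes to the four ab cells
  by a multinomial over `scenario_weights`;
- **flip noise** — the planted output is `f(a, b)` XOR Bernoulli(ε) per
  genome, ε ∈ [0, 0.5], default 0.02 (a light error rate; 0.5 erases the
  signal entirely). Noise is applied to c only: input noise is equivalent
  to reshaped scenario weights and would not add a distinct degradation
  mode.

Defaults mirror the reference scale (182 genomes). For *skewed* benchmarks
(one cell at 70% mass) the minor cells carry 10% ≈ 18.2 genomes at that
scale — exactly at the scenario filter, so skewed plants would be filtered
almost surely; skewed benchmarks therefore use 400 genomes so minor cells
(~40 genomes) clear the filter with multinomial jitter.

Recovery of a planted hypothesis is judged up to logical equivalence: for
XOR/XNOR plants the constraint fixes the parity `a ⊕ b ⊕ c`, which is
symmetric in all three roles, so any role assignment of the same type is
an equally correct description and the "true" output gene is unidentifiable
in principle. For the other types the output gene, type and (for types
5/6) input order must match.

What passing synthetic tests does **not** show: the generator draws
genomes i.i.d., with no phylogenetic correlation (birth–death on a tree),
no horizontal transfer, and noise that is uniform across scenarios. Under
this model raw and balanced scoring are both consistent and their ranking
performance is nearly tied (balanced wins on per-triplet score separation
for skewed plants; raw pools more genomes and is marginally steadier at
the hypothesis level). The real-data advantage of balancing — driven by
noise and network structure that correlate with genome composition — is
outside what an i.i.d. generator can demonstrate.

## Numerical conventions

- log base 2 throughout; `0·log 0 ≡ 0`.
- Distribution normalisation checked at 1e-9; U clamped to [0, 1] against
  |rounding| ≤ 1e-12, larger excursions raise.
- Target marginals with entropy below 1e-12 bits are treated as degenerate
  (an all-present gene's marginal can round to entropy ~1e-16 rather than
  exactly 0) and the hypothesis is skipped.
- Result ordering: descending ΔU, ties broken lexicographically by
  (gene_a, gene_b, gene_c, type_id). ΔU serialised at 6 decimals.
- Empty ab cells (possible only when the scenario filter is relaxed):
  balance spreads mass 1/M over the M non-empty cells, keeping the
  operation total.

## Problem sizes

Exhaustive search is O(C(n,3) · 30) hypotheses; at the full reference
scale (~10⁴ genes) that is ~10¹² hypotheses and must be bounded by gene
subsets and report thresholds — the implementation streams triples and
holds only reported results. Test and acceptance runs use small matrices
(≤ ~25 genes, 182–400 genomes), 100 seeds for recovery rates and 20 seeds
for balanced-vs-raw comparisons, which keeps the whole suite at a couple
of minutes on one CPU while the Monte-Carlo error on reported rates stays
a few percent.

## Known limitations

- Binary profiles only; no weighted or continuous orthology scores, no
  relationships among more than three genes.
- The permutation null permutes genomes i.i.d. and therefore inherits the
  same independence assumption the generator makes.
- GO evaluation depends on the ontology release used; accuracies computed
  against different releases are not comparable at the third decimal.
- The greedy genome deduplication is order-dependent by design (documented
  traversal), not a globally optimal covering.
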