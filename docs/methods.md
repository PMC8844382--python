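# Methods

## Input model and binarization

The primary input is a host-range matrix: strains × phages, numeric
cells. Quantitative lysis scores (spot intensities, efficiency of
plating) are reduced to a binary lytic / non-lytic view by a threshold:
a cell is lytic when its value is **strictly greater** than the
threshold, default 0 ("any lysis counts"). The raw values are retained
alongside the binarized view, but every downstream statistic uses only
the binary matrix; quantitative weighting of interactions is an explicit
non-goal. The canonical orientation is rows = bacteria; transposed files
are handled by an orientation flag, and the delimiter is auto-detected
among tab, comma and semicolon because published matrices vary.
Duplicate strain or phage labels are an error rather than being merged:
merging would change node degrees and therefore every importance score.

## Infection networks and Expected Importance

The binary matrix defines a directed bipartite network with one edge
phage → bacterium per lytic cell. Expected Importance is a rescaled
degree: EI_p = 100·out_d/|B| per phage (percent of strains lysed,
0–100) and EI_b = −100·(1 − in_d/|P|) per bacterium (0 for a strain
lysed by every phage, −100 for a resistant one). The opposite signs
separate source and target nodes in renderings; both scores are stored
at full floating precision and rendered to one decimal in reports.
Non-infecting phages and resistant bacteria are kept in the network as
flagged isolated nodes — they are part of the experimental dataset —
but the search ignores the former and redundancy statistics exclude the
latter. Fill is the fraction of lytic cells; symmetry is reported as a
three-way category (more bacteria / square / more phages) because the
property that drives combinatorial complexity is squareness, not the
exact ratio.

## Cocktail search

Both searches operate on the phages with out-degree ≥ 1 (a phage with no
hosts can never improve coverage) and target the susceptible strains,
i.e. the union of all host sets.

**Heuristic (network metrics).** Stage 1: every strain with in-degree 1
forces its unique lyser into the cocktail. Stage 2: the remaining phages
are visited in descending EI_p order and added only if they lyse at
least one still-uncovered strain, until all susceptible strains are
covered. Ties on equal EI_p break by input column order; the rule is
arbitrary but deterministic, which testing requires. The greedy always
completes, but has no optimality guarantee.

**Exhaustive.** For k = 1, 2, … all k-subsets are enumerated and the
best coverage per size recorded; the first k achieving full coverage is
the Minimum Cocktail Size. Among equal-coverage subsets of one size the
lexicographically first combination (standard enumeration order) wins —
optimal covers are often non-unique, and any of them yields the same
size, coinfection distribution and redundancy statistics. The size cap
defaults to 12 phages, a practical ceiling for realistic formulations
(published corpora top out around 11); at the cap the best incomplete
subset is returned and flagged. An optional branch-and-bound mode prunes
subtrees whose optimistic bound — current coverage plus the largest
remaining host-set sizes — cannot beat the incumbent. The bound is
admissible and the `>` incumbent update preserves the lexicographic
tie-break, so the pruned search is exact; tests compare it subset-for-
subset against plain enumeration. Host sets are packed into integer
bitmasks, making a subset's coverage a few ORs and a popcount.

## Cocktail networks, efficacy and redundancy variation

The cocktail network restricts the parent to the cocktail phages and all
susceptible strains. Expected cocktail efficacy is 100·|covered|/|B|
over **all** bacteria including resistant ones, so it reaches 100% only
for a complete cocktail on a network without resistance — the "fully
successful" case. Coinfection is the strain's in-degree within the
cocktail (in_dc); its distribution is tabulated as the percentage of
strains lysed by k = 1..MCS phages, pooled per MCS group, each row
summing to 100%.

Redundancy of a strain is the fraction of a network's phages lysing it.
Redundancy variation compares cocktail to parent on a decimal log scale,
rv = log10((in_dc/MCS)/(in_d/|P|)), with bounds rv_min =
log10(|P|/(MCS·in_d)) (exactly one cocktail phage lyses the strain) and
rv_max = log10(|P|/MCS) (in_dc at its ceiling). Two consequences are
asserted as properties: rv_max − rv_min = log10(in_d) for every strain,
and rv = rv_min whenever MCS = 1. Note that the stated upper bound
rv_max ignores the cap in_dc ≤ in_d; for strains with in_d < MCS the
attainable maximum is lower, so rv_max is a valid but not always tight
bound, and for a single-phage cocktail rv equals rv_min while rv_max
coincides with it only when in_d = 1. Negative rv values are possible
(a strain lysed by proportionally fewer cocktail phages than network
phages) and are reported as computed. Resistant strains are excluded
from all redundancy statistics — their ratio is undefined — and
efficacy is the only statistic computed over the full strain set.
Group summaries use the median (midpoint convention for even counts).

## Synthetic generator

The generator exists so every pipeline stage is testable without
external data; it emulates the shape of published host-range corpora,
not any particular study.

- `random`: each cell lytic independently with probability `fill`.
- `nested`: phage j lyses the first k_j strains with k_1 ≥ k_2 ≥ …, a
  linear ramp scaled to the target fill — prefix host sets are totally
  ordered by inclusion by construction. Inclusion ordering was chosen
  over isocline-based nestedness models because it is the property the
  pipeline actually exploits: the broadest phage covers the union, so a
  perfectly nested network always has MCS 1.
- `noisy_nested`: a nested matrix degraded by exchanging a `noise`
  fraction of (lytic, non-lytic) cell pairs; each swap relocates one
  interaction, so fill is held exactly constant while the hierarchy
  erodes.
- `corpus_like_sample`: node counts log-uniform in [10, 900], 80% of
  matrices with more bacteria than phages, fill drawn sparser for larger
  matrices (echoing the weak negative size–fill association in surveys),
  alternating random and noisy-nested structure.

Seeds are mandatory (fixed default constant), and the same seed yields
bit-identical matrices. What passing tests on these matrices do **not**
show: real host-range data carry phylogenetic block structure,
assay-dependent thresholds and quantitative EOP variation that the
generator does not model; results on synthetic batches validate the
algorithms, not biological conclusions.

## Corpus metadata fixture

The packaged 50-row table transcribes the published survey of host-range
studies (dataset, hosts, phages, matrix size). Its defining invariant —
matrix_size = hosts × phages for every row — is enforced at load time
and was used to disambiguate the two counts during transcription; the
split is unique for every row. Aggregates over the table (2,877 hosts,
899 phages, 52,688 cells, 80% of datasets with more bacteria than
phages, node counts 10–906, rounded means 58 hosts and 18 phages per
dataset) are recomputed by `summarize_corpus_metadata`, not stored.
The corpus-level cocktail results themselves (MCS distribution, median
efficacy, estimator correlations) require the 50 raw matrices, which
are not distributable with the package and are out of scope.

## Numerical and testing choices

- Logarithms are base 10 throughout the redundancy analysis.
- Spearman correlations use scipy with average ranks for ties;
  constant descriptors are omitted with a warning because their rank
  correlation is undefined.
- The exhaustive search is cross-validated against an independent
  brute-force set-cover oracle (frozensets, no shared code path) on 200+
  seeded random networks up to 8×8 at fills 0.1–0.9; the greedy is
  simultaneously checked to never beat the optimum. These sizes keep the
  full validation sweep under a minute while 2^8 subsets still exercise
  every branch.
- Batch processing is sequential in sorted path order; unreadable files
  are logged and skipped, and only zero readable inputs is fatal.

## Known limitations

Binary networks discard infection-efficiency information; phage–phage
synergy or antagonism during coinfection is not modeled — the
redundancy statistics quantify opportunity for coinfection, not its
outcome. The exhaustive search is exponential in the number of phages;
beyond a few dozen active phages at the default cap it can become slow
(pruning helps but does not change the worst case). No approximation
guarantee is claimed for the greedy beyond the tested size ≥ MCS
relation, and no ILP formulation is provided.
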