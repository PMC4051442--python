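# Methods

## Statistical model

Each prediction database (MDB) is treated as a fixed bipartite graph between
miRNAs and genes. Enrichment of a candidate molecule against a query set is
an urn draw from that database's own universe: for Gene2miR, the population
is the database's N distinct genes, K of which are the candidate miRNA's
predicted targets; the draw is the n query genes present in the database, and
the observed count k is the overlap. The reported probability is the exact
upper tail P(X ≥ k) of the hypergeometric distribution (scipy's survival
function at k−1; no normal approximation). Each database is tested against
its *own* background rather than a pooled one, so a small, specific database
can still contribute significant support and a huge permissive one does not
drown it out. miR2Gene is the mirror image with the roles of miRNAs and
genes swapped; on a transposed graph the two directions produce identical
statistics, which the suite checks.

Multiple testing is corrected with Benjamini–Hochberg, applied **within each
database across its tested candidates**. Correcting per database keeps the
test family aligned with the background choice: each database answers its
own question, and cross-database agreement is then demanded separately
through the minimum-support requirement. Support = adjusted value ≤ the
p threshold (raw p when FDR is disabled).

A candidate is reportable when it is supported by at least `min_mdbs`
databases (default 2) and its supporting hits cover at least `min_hits`
query members (default 2). Both defaults encode the view that a prediction
backed by a single database or a single gene is noise.

### miRIS

miRIS = ½·(n_support/n_selected) + ½·(n_hits/input_size), the arithmetic
mean of the two fractions — the closed form that gives the two components
the equal contribution the score is defined to have, and that reproduces the
known lower bound: with 2-of-10 database support the score is
0.1 + hits/input > 0.1, with greatest lower bound exactly 0.1 as the input
grows. `input_size` is the *analyzed* count (after mapping and
de-duplication), not the raw line count of the query file. `best_p` is
reported raw (pre-FDR) as the minimum over supporting databases; it colors
the results table but never enters the score, and neither do binding-site
counts (reported in the zoom tables only). Ranking is deterministic:
miRIS descending, then best_p ascending, then candidate id.

## Identifiers and seed families

Gene identifiers are unified into a central RefSeq-like namespace through
static many-to-one snapshot tables. Ambiguous sources (one id, several
central targets) are rejected to the unmapped audit list with a warning —
determinism is worth more than coverage here. When no mapping tables are
supplied, identifiers are assumed central and pass through; when tables are
supplied, an id must be a known source or a known central id, and everything
else is preserved verbatim in the audit list. Every raw occurrence lands in
exactly one bucket, so input = analyzed + duplicates + unmapped always
holds (property-tested).

The canonical seed is the substring at 1-based positions 2–8 of the mature
sequence, case-insensitive, T normalized to U. miRNAs with identical seeds
form one family, keyed by the seed string itself; a miRNA with no available
sequence keeps its own id as a singleton family, so compaction never
discards edges. Compaction is idempotent and leaves the gene set unchanged.
Duplicate (miRNA, gene) rows — whether from the source file or from family
collapse — keep the maximum score and maximum site count: max is monotone
and order-independent, so the result does not depend on row order.

## Context filters

Restricting to a tissue/cell-line removes edges to unexpressed genes
(value > 0 by default; the presence cutoff is configurable) and recomputes
the background N, since enrichment against genes that cannot express in the
context would be anti-conservative. The top-expressed filter keeps
ceil(fraction·|genes|) genes (default fraction 0.30), ties at the cut
admitted in id order. The score filter keeps the top
ceil(fraction·|edges|) edges per database by its native score, fraction in
{0.10, 0.25, 0.50, 1.00}; it operates on edges because per-gene aggregation
of heterogeneous database scores is undefined, and databases without scores
pass through with a warning. All filters are contractions; context and
expression restrictions are idempotent, while an exact-count quantile cut is
deliberately not (reapplying it re-cuts the smaller table) — reproducibility
of a single application, with deterministic ties, is the property that
matters operationally.

## PSI refinement

EV(M, G) = realized edges / (|M|·|G|) ∈ [0, 1], equal to 1 exactly on a
complete biclique. One refinement pass on the mutable side does all
removals first, then all additions; each accepted move must *strictly*
increase EV (ties rejected — this guarantees termination, since EV is
bounded), candidates are scanned in id order and the best improvement wins,
first id on exact ties. Removals of input members stop at the stability
floor (≥ stability·|input| retained; default 0.90, hard floor 0.75);
additions are capped symmetrically at (1−stability)·|input| per pass.
Addition candidates are the molecules sharing at least one edge with the
current fixed side — a bounded pool that cannot admit molecules with no
connection to the working subgraph.

Full modes (miR2miR, Gene2Gene) alternate a half-step inference of the
opposite side — single-database enrichment with the embedded parameters,
support requirement relaxed to 1 since only one database is in play, top
200 candidates kept — with a greedy pass, for `n_iterations` complete
cycles (default 2), stopping early on convergence. Partial modes
(Gene2miR, miR2Gene) run one half-cycle and end on the opposite molecule
type. Everything runs independently per database; the final report keeps
molecules present in at least `min_mdbs` per-database final states (capped
at the number of databases the query actually overlaps). The result carries
the full move log (EV before/after each accepted move, strictly increasing)
and the diff partition retained / removed / added.

Greedy EV maximization is a heuristic; on the shipped small-graph fixture
suite its gap to the exhaustive stability-feasible optimum is zero, which
the acceptance tests verify, and the property suite checks it never exceeds
the optimum on random ≤4×4 graphs.

In the PSI results table the score column is the enrichment miRIS for
partial modes (where the output molecules are enrichment candidates of the
original query); for full modes, where a same-type output molecule has no
enrichment test of its own, the cross-database consensus fraction is
reported instead.

## Synthetic data

The generator emulates the structure of real prediction databases without
their content: a universe of genes (RefSeq-style ids) and miRNAs, `n_mdbs`
databases with i.i.d. Bernoulli background edges, and one planted
miRNA-by-gene module whose cells appear with probability
p_signal·mdb_agreement per database. Defaults — 200 genes, 50 miRNAs,
4 databases, background density 0.02, a 5×20 module at signal 0.9 — keep a
full generate-enrich-refine cycle under 0.1 s while leaving the module
statistically unmistakable, which is what the recovery benchmarks need:
planted regulators must outrank all decoys, and PSI must strip a planted
contaminant, in ≥95 of 100 seeded runs. Scores are uniform noise and site
counts uniform on 1–3; sequences are 22-nt mature miRNAs whose seeds
realize an exact family count by round-robin assignment. Everything is
deterministic under `rng_seed` and the planted truth is serialized as JSON
next to the fixtures.

What the synthetic fixtures do *not* emulate: the heavy-tailed degree
distributions of real predictors, correlated errors between databases built
on the same algorithm, 3′-UTR length biases, or non-canonical seed pairing.
Passing the recovery benchmarks therefore demonstrates the statistical
machinery is correct and well-calibrated on known ground truth, not that any
particular real-data prediction is right.

## Numerical choices and limitations

* Exact hypergeometric tails throughout; verified against full draw
  enumeration for every valid configuration with N ≤ 12 to 1e-12.
* BH-FDR via statsmodels, verified against a hand-written step-up oracle on
  1000 random lists.
* EV strict-improvement tolerance 1e-12; stability arithmetic uses a 1e-9
  guard so that e.g. 10 % of 10 is one move despite floating-point rounding.
* All orderings (edge tables, candidate scans, output files) are fully
  deterministic; identical inputs produce byte-identical outputs.
* Gene isoforms are not resolved; identifier mapping is snapshot-based only.
* The greedy refinement offers no global optimality guarantee beyond the
  verified small-graph suite; stability keeps it from wandering far from
  the input, which is the intended behavior, not a bug to engineer around.
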