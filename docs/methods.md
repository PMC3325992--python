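# Methods

## Model

`atcpred` predicts the 14 first-level ATC classes of a query compound by
nearest-evidence transfer over two pairwise score networks. For each
class, the likelihood is the maximum score between the query and any
training drug holding that class; ranking the 14 likelihoods in
descending order yields an ordered multi-label prediction. The rule rests
on one assumption: compounds that interact, or that are structurally
similar, tend to share therapeutic roles. Nothing is fitted — the
"model" is the training label table plus the score tables — so
leave-one-out evaluation is exact and cheap: removing a drug from
training simply removes its memberships from the per-class maxima.

Two kinds of evidence are supported and deliberately never mixed on one
scale:

* **interaction confidence** — integers, nominal range 1–1000, as in a
  STITCH `chemical_chemical.links` dump; absent pairs score 0;
* **structural similarity** — reals in [0,1] (e.g. Jaccard coefficients
  on maximum common subgraphs); absent pairs score 0.

The **integrated** method is a routing rule: interaction evidence is
consulted first, and only a query whose 14 interaction likelihoods are
all zero (the *trivial outcome* — no interaction record against the
training set) falls back to the similarity table. A second routing
semantic (`fallback="dataset"`) instead routes by score-table coverage:
any query with an interaction record at all stays on the interaction
route, mirroring an a-priori split of a benchmark into drugs with and
without interaction information. `per_query` is the default because it is
the literal trivial-outcome test; the two differ only for drugs whose
interaction records all point outside the training set.

## Ranking, ties and degenerate inputs

Likelihood ties are broken by ascending class index (the fixed A…V
order), making every ranking a deterministic total order — a requirement
for reproducible per-order hit counting. Zero-likelihood classes are
ranked too (trailing, in index order) by default: per-order hit counts on
real benchmarks are nonzero out to order 14, which a truncated ranking
could not produce. `include_zero_classes=False` restores the truncated
reading. A query with no evidence in either table receives the pure
index-order ranking tagged `method_used="none"`, and is counted like any
other prediction (its hits land where the tie-break puts its true
classes); the per-method breakdown in the report makes these visible.
Self-pairs are discarded at score ingest — under leave-one-out a query
can never legitimately be its own evidence — and duplicate pair entries
keep the maximum score (idempotent and order-independent). Queries still
present in the training table are rejected rather than silently handled.

## Evaluation measures

For N jackknifed drugs: `CP_j` counts drugs whose j-th ranked class is
true, `AC_j = CP_j / N`; `AN` is the mean number of true classes of the
*evaluated* subset (equivalently its virtual/structural count ratio);
`m = ceil(AN)` (the smallest integer ≥ AN; at exactly integral AN the
ceiling is used); `L_m` is the fraction of all true memberships recovered
within the first m ranks. The identity `N·AN·L_m = CP_1 + … + CP_m` holds
exactly (both sides count (drug, hit-order) pairs) and is asserted in the
test suite, as is `L_14 = 1` for full-length rankings. The jackknife
driver removes the entire drug record — all class memberships — before
predicting it, never one membership at a time, since sibling memberships
would leak the query's own scores.

## Synthetic benchmark generator

The generator (`atcpred.synthetic`) emulates the structure of a
KEGG/STITCH-derived benchmark of 3,883 drugs so that every predictor and
metric is testable without downloads:

* **multiplicity distribution** — each drug draws its class count T from
  a distribution defaulting to the reference breakdown 3295/370/110/37/
  27/44 for T = 1…6 (expected AN = 4912/3883 ≈ 1.265);
* **class weights** — T distinct classes drawn without replacement with
  probabilities proportional to the reference class sizes (nervous
  system largest at 737/4912);
* **assortative edges** — a pair sharing ≥1 class receives an edge with
  probability `p_within`, otherwise `p_between`; defaults 0.1 / 0.01 give
  a clearly recoverable but imperfect signal. Scores are uniform over
  their ranges (integers in [150, 1000]; similarities in [0.1, 1])
  rather than signal-graded: the predictor uses only per-class maxima, so
  edge *presence* carries the signal and graded magnitudes would add
  nothing testable;
* **coverage** — only a random fraction (default 2144/3883 ≈ 0.552) of
  drugs participates in the interaction network, exercising the
  similarity fallback; the similarity network covers every drug, serving
  as the universal backstop. Because Bernoulli sampling can isolate a
  designated-covered drug, any such drug is given one edge to a random
  covered partner, making the covered set exactly ⌊coverage·n⌋ (the
  same guarantee gives every drug ≥1 similarity edge). Forced edges are
  label-independent and so do not bias the random-guess floor. Degenerate
  case: ⌊coverage·n⌋ = 1 leaves that drug uncovered, as an edge needs two
  endpoints.

Everything is reproducible from a single integer seed.

What the generator does **not** emulate: the score *distributions* of
real STITCH/SIMCOMP data (real confidence scores are heavily skewed, not
uniform), correlated multi-label structure (real co-membership patterns
are far from independent draws), transitivity of real chemical networks,
and identifier-mapping noise. Passing tests on synthetic data therefore
demonstrate the correctness and calibration of the machinery — exact
metric identities, the random-guess floor near 1/14, recovery of strong
assortative signal, correct fallback routing fractions — not the field
accuracy of the method on real drugs.

One consequence of pairwise scores plus multi-label drugs is worth
stating: even at `p_within=1, p_between=0` first-order accuracy does not
reach 100%, because a multi-label neighbour injects its (single) pairwise
score into *every* class it holds, including classes the query lacks, and
the index tie-break can then rank such a class first. Perfect recovery
under full assortativity is provable only for single-label populations or
tie-tolerant hit counting.

## Numerical and design choices

* Interaction scores are kept as exact integers end-to-end (files print
  raw integers; rankings are auditable); similarities round-trip through
  files at full `repr` precision.
* Strict parsing is the default for all readers — malformed rows fail
  with their line number — with a lenient mode that skips and counts.
  Header sniffing on score files treats a non-numeric third field on line
  1 as a header unless it is a missing-value token (NA/NaN/null/none/.),
  which is data and an error.
* Scores above 1000 in interaction files are kept with a warning (the
  1–1000 range is advisory); negative scores and similarities above 1 are
  always rejected.
* Identifier handling is exact string match after whitespace trimming; no
  cross-database (KEGG↔STITCH) identifier mapping is attempted, so inputs
  must be pre-harmonised.
* `AN < 1` and empty subsets are rejected (every drug has ≥1 class).

## Problem sizes

The test suite and acceptance checks run the jackknife at up to 3,883
synthetic drugs (the reference scale) and calibration checks at 2,000–
3,000 drugs; the oracle-equivalence suite uses 220 random instances of up
to 30 drugs against a brute-force double loop. All complete in seconds on
one CPU.

## Known limitations

* The reference benchmark's headline jackknife accuracies were computed
  on external STITCH v2.0 and KEGG similarity dumps that cannot be
  redistributed; this package reproduces the benchmark's *printed
  arithmetic* exactly and validates the method's statistical behaviour on
  synthetic data, but does not regenerate those accuracies from raw data.
* Only ATC level 1 is supported; lower levels would need their own
  benchmarks but no new machinery.
* The likelihood rule is a pure maximum — no k-nearest-neighbour
  smoothing, weighting or probability calibration — by design.
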