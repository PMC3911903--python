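# Methods

## Setting and model

The input is a collection of N predicted signed directed networks over a
common set of genes, typically the high-scoring fraction of a
non-deterministic reverse-engineering run.  An interaction is a triple
(effector, target, sign) with sign ∈ {activating, inhibiting}; the two
signs on one gene pair are distinct interactions everywhere.  By default
a single network may carry only one sign per gene pair (the dynamical
model families these collections come from assign each edge one
regulatory role) and self-loops are rejected; both restrictions are
reader options.

The extraction procedure rests on one structural assumption: if a
functionality required by the data can be realised by alternative edge
sets, each high-scoring network contains one alternative essentially in
full, so the members of an alternative co-occur across networks while
members of competing alternatives exclude each other.  Unspecific
variable edges — interchangeable effector candidates the data cannot
distinguish — occur independently and show neither pattern.

## Step 1 — frequencies and tiers

Each observed interaction i gets its relative frequency f(i) = (networks
containing i)/N, computed over the whole collection.  Tiers:
high-confidence interaction if f > hc_cutoff, high-confidence
non-interaction if f < nc_cutoff, low-confidence otherwise.  Both
comparisons are strict; frequencies exactly at a cutoff stay
low-confidence, keeping borderline edges available for set extraction.
Interactions never observed are non-interactions by convention and never
enter pair enumeration, which keeps pair counting quadratic in the
*observed* edge set (small in practice).  Only low-confidence pairs are
scored further.

## Step 2 — dependency scores and characteristic sets

For an unordered pair {a, b} of low-confidence interactions, with f(a∧b)
the fraction of networks containing both and f(a∧¬b) the fraction
containing a but not b, the scores are min-conjunctions of
association-rule confidences conf(a→b) = f(a∧b)/f(a):

    AND(a,b) = min(f(a∧b)/f(a), f(a∧b)/f(b))
    EX(a,b)  = min(f(a∧¬b)/f(a), f(b∧¬a)/f(b)) = 1 − max(conf(a→b), conf(b→a))

Both lie in [0,1], are symmetric, and sum to at most 1 (equality iff the
two confidences agree), so with score_cutoff > 0.5 — enforced by the
config type — at most one relation can qualify per pair.  The
conjunction is isolated behind a single parameter (`min` default;
`product` and `bounded_product` available) so the sensitivity of
extracted sets to this choice can be probed without touching the
pipeline.

Qualification gates both the score and its evidence frequency, strictly:
AND requires AND(a,b) > score_cutoff and f(a∧b) > joint_cutoff; EX
requires EX(a,b) > score_cutoff and min(f(a∧¬b), f(b∧¬a)) > joint_cutoff.
Gating EX by both exclusive frequencies is the symmetric analogue of the
joint-frequency gate: each relation's supporting observations must be
frequent enough not to be noise artifacts.

Characteristic sets are the connected components (size ≥ 2) of the graph
whose edges are qualifying AND relations; merging is transitive by
construction.  Set ids S1, S2, … are assigned by lexicographically
smallest member, so repeated runs produce byte-identical reports.  Each
set's support is the fraction of networks containing *all* members,
computed against the collection when available (the pairwise relations
alone only bound it; the minimum pairwise joint frequency is used as an
upper-bound surrogate otherwise, and flagged as such in the docstring).
An EX relation between two sets makes them competing; an EX relation
*inside* one AND component is a conflict — reported, never
auto-resolved, and the affected sets are withheld from automatic
grouping unless forced, since no principled tie-break exists.

## Step 3 — grouping and voting

A network's signature is the set of characteristic sets it contains,
with crisp containment (all members present).  Networks containing no
set are excluded from ensemble creation; networks containing two
competing sets simultaneously — impossible under the model, possible
under noise — are flagged as violations and excluded by default
(`keep_violations` retains them under their full signature).  Every
network therefore lands in exactly one group or in the excluded list.
Valid signatures are all non-empty combinations of sets containing no
competing pair; with three sets of which one pair competes this yields
the five combinations the combinatorics demands.

Voting per group uses signed voting: for each gene pair with n₊
activating and n₋ inhibiting votes out of N networks, the net vote
v = (n₊ − n₋)/N assigns weight |v| to the edge with the sign of v, and
no entry when v = 0.  The exact formula of the consensus scheme this
convention follows is config-isolated (`scheme="frequency"` gives plain
per-signed-edge frequency voting, under which both signs of a pair may
carry weight); the net-vote convention is the package's documented
default and is not changed silently.  Within a group, every member of
every signature set has frequency exactly 1, and the high-confidence
backbone rides along near 1 — group-ensembles are sharpened versions of
the full ensemble, not subsets.

## Evaluation

**Entropy.**  H(ensemble) = Σᵢ h(fᵢ) with h the binary entropy in bits
and the sum over the candidate universe (all ordered gene pairs without
self-loops, both signs); edges never predicted contribute 0, so the sum
effectively runs over the stored weights.  The logarithm base is a
parameter; the group-vs-full entropy *ratio* (mean over groups of
H(group)/H(full)) is base-independent, so comparisons of relative
sharpening do not depend on this reconstruction choice.

**AUPRC.**  Edges are ranked by descending weight; at each distinct
positive weight t the prediction set is {weight ≥ t} (ties share one
threshold, making the area invariant under permuting equal-weight
entries), precision = TP/|predictions|, recall = TP/|reference|, with a
true positive requiring an exact signed match — a predicted edge with
the wrong sign is a false positive by default, since signed references
make sign errors real errors.  The area is the rectangular sum
Σ (Rₖ − Rₖ₋₁)·Pₖ with R₀ = 0, no interpolation, hence bit-reproducible
and exactly 1 when all reference edges are strictly top-ranked and
exactly 0 when no reference edge carries weight.

**Set precision** is the fraction of a set's members present in the
reference.  **Interaction validation** simulates one experiment: if the
tested edge is in the reference, all networks lacking it are rejected,
otherwise all networks containing it; the survivors are re-voted.  An
empty survivor set raises rather than returning a degenerate ensemble.

## Synthetic benchmark generator

The generator emulates the *output* of a reverse-engineering run
directly, not the dynamics or the optimiser: per network it draws a
group signature, writes the high-confidence backbone (each edge with
probability `backbone_presence`), all members of the signature's planted
sets, each unspecific variable edge independently, and then flips the
presence of every admissible signed edge with probability `noise_rate`
(an addition whose opposite-signed edge already exists is skipped, so
the one-sign-per-pair invariant survives noise).  Per-network fit scores
are uniform draws from `score_range` — placeholders with no dynamical
meaning, present solely to exercise best-fraction selection and group
scoring.

Defaults, fixed once as the study conditions: 10 genes, 500 networks,
in-degree uniform on [1,3], backbone presence 0.95, two competing planted
3-edge sets at proportions 0.5/0.5 (set P1 drawn from the reference, P2
rewiring the same targets to effectors absent from the reference), four
variable edges at presence 0.4, noise 0.02 (kept below the
non-interaction cutoff so noise alone cannot fake low-confidence
structure), scores uniform on [0.05, 0.15].  At these conditions and the
default cutoffs (0.8/0.1/0.1/0.7), member frequencies sit near 0.5
(LOW), within-set AND confidences near (1−noise)² ≈ 0.96, cross-set EX
scores near 1, and variable-edge confidences near their presence
probability 0.4 — comfortably inside the intended tiers, which is what
makes recovery a meaningful check rather than a knife-edge one.

What the generator does *not* emulate: correlated noise from a shared
optimiser trajectory, fit scores that actually depend on topology,
partial realisation of alternatives, or more than pairwise competition
structure.  Passing the recovery tests therefore shows the extraction
machinery is correct under the stated structural model, not that the
model captures every real reverse-engineering output.

## Numerical and design choices

- All cutoff comparisons strict ("above"/"exceed"); documented once here
  and applied uniformly.
- Deterministic ordering everywhere: sorted members name sets, ensemble
  TSVs sort by descending weight then lexicographic edge, signatures
  enumerate by size then lexicographic ids.
- Frequencies are exact count ratios; pair statistics are derived from
  integer counts so the identities f(a∧¬b) = f(a) − f(a∧b) hold exactly
  in floating point.
- Zero-marginal pairs raise a dedicated error from the score functions;
  the pipeline filters them before scoring.
- Problem sizes in the stochastic test suite: 50 seeds at the default
  500-network generator conditions, chosen to estimate the ≥ 95% / ≥ 90%
  success-rate properties with low variance while keeping the whole
  suite fast.

## Known limitations

- Crisp containment: a network missing one member of a set by noise
  drops out of that group entirely (it is excluded, not misassigned);
  fuzzy membership is deliberately out of scope.
- The signed-voting and entropy formulas follow documented conventions
  chosen here; both are isolated behind parameters, and conclusions
  drawn from ratios are insensitive to the entropy base.
- Conflicted set systems (intra-set EX links) always require manual
  resolution; there is no automatic cutoff re-tuning.
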