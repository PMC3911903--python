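# charnets

Characteristic interaction sets and group-ensemble voting for collections
of predicted gene regulatory networks.

## The problem

Non-deterministic reverse-engineering methods (probabilistic optimisation,
cross-validation resampling) produce hundreds to thousands of candidate
gene regulatory networks that all fit the data comparably well.  Ensemble
voting — scoring each signed edge by its frequency across predictions —
works well when the predictions are similar, but when the collection mixes
distinct topologies the vote blurs them together: edges that strictly
co-occur within one topology become indistinguishable from unspecific
variable edges.

`charnets` extracts that hidden structure in three steps:

1. **Frequencies.** Each signed edge i (effector → target, activating `+`
   or inhibiting `-`) is classified by its relative frequency f(i) across
   all N networks: high-confidence interaction (f > 0.8 by default),
   high-confidence non-interaction (f < 0.1), or low-confidence otherwise.
2. **Mutual dependencies.** For each pair of low-confidence edges a, b the
   co-occurrence and mutual-exclusion scores are min-conjunctions of
   association-rule confidences,

       AND(a,b) = min( f(a∧b)/f(a), f(a∧b)/f(b) )
       EX(a,b)  = min( f(a∧¬b)/f(a), f(b∧¬a)/f(b) )

   so AND(a,b) + EX(a,b) ≤ 1 and with a score cutoff above 0.5 (default
   0.7) at most one relation qualifies.  Connected components of the AND
   graph are the *characteristic sets*; sets linked by an EX relation are
   *competing* — a valid network realizes at most one of them.
3. **Grouping and voting.** Networks are grouped by the exact combination
   of characteristic sets they contain (networks containing none are
   excluded), and signed voting — net weight (n₊ − n₋)/N per gene pair —
   is applied per group.  Each group-ensemble carries its characteristic
   edges at frequency 1, on top of the shared high-confidence backbone.

Evaluation utilities quantify the gain: per-edge binary-entropy of an
ensemble (low entropy = confident, homogeneous ensemble), step-integrated
AUPRC of weight-ranked edges against a signed reference, characteristic-set
precision, and a simulated validation experiment that rejects all networks
inconsistent with one experimentally tested interaction.  A synthetic
generator produces collections with planted competing sets, backbone,
variable edges and noise, plus the ground truth to score recovery against.

## Worked example

```sh
charnets simulate -o sim --n-networks 120 --seed 7
charnets extract sim/collection.tsv -o report.json
# 2 characteristic set(s), 1 competition(s) -> report.json
charnets vote sim/collection.tsv -o vote --per-group
# 2 group ensemble(s) + full ensemble -> vote
charnets evaluate vote/ensemble_full.tsv sim/reference.tsv \
    --group-ensemble vote/ensemble_S1.tsv --group-ensemble vote/ensemble_S2.tsv
```

prints (abridged):

```json
{
  "entropy": 25.208,
  "auprc": 0.9893,
  "entropy_ratio": 0.8231
}
```

The simulated collection planted two competing 3-edge sets; `extract`
recovered both (S1, S2) and their competition.  The full ensemble has
25.2 bits of entropy, much of it from planted edges sitting near
frequency 0.5; grouping reduces the mean group-ensemble entropy to 82%
of that, since each group realizes its own set at frequency 1.  The
AUPRC of 0.989 says the reference edges are almost perfectly
top-ranked.  The same
operations are available as a library:

```python
from charnets import SyntheticSpec, generate_collection, extract_characteristic_sets

collection, truth = generate_collection(SyntheticSpec(seed=7, n_networks=120))
result = extract_characteristic_sets(collection)
print([sorted(map(str, s.members)) for s in result.system.sets])
```

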