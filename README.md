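# thermospot

Analysis pipeline for psychophysical mapping studies of **thermosensitive
skin spots** — the small (~1 mm²) loci where a near-threshold warm or cool
probe reliably evokes a temperature sensation. Given per-spot coordinates
and verbal-report sequences collected over repeated search sessions on a
bounded skin region (e.g. the dorsal forearm), the package answers three
questions:

1. **What did each spot feel like?** Candidate spots are confirmed by up to
   four repeat stimulations (the loop stops at the first positive report)
   and classified into a five-way taxonomy: *cold*, *warm*, *inconsistent*
   (reports disagree with each other, or the spot responds in both the
   cooling and the warming block), *incongruous* (reports agree with each
   other but contradict the stimulus polarity), and *unconfirmed*.
2. **How are spots arranged in space?** Uniformity of the proximodistal
   coordinates is tested with the Anderson–Darling statistic against a
   fully specified uniform law on fixed bounds,

   A² = −n − (1/n) Σᵢ (2i−1) [ln u₍ᵢ₎ + ln(1 − u₍ₙ₊₁₋ᵢ₎)],

   with Monte-Carlo or asymptotic p-values. Aggregation is measured with
   the Clark–Evans index R = r̄_obs / r̄_exp (observed over CSR-expected
   mean nearest-neighbour distance; R < 1 ⇒ aggregation), using the
   Donnelly edge correction for the bounded rectangular region:
   r̄_exp = ½√(A/n) + (0.0514 + 0.0412/√n)·P/n with the matching variance
   for a two-sided z test.
3. **Do spots persist across sessions?** A spot counts as conserved if any
   confirmed spot of the same participant in another session lies strictly
   closer than a threshold (default 6 px ≙ 2 mm). Matched spots form
   chains; the package reports both the component and the
   re-identification counting conventions, chain lengths, and
   category agreement along chains.

A ground-truth **synthetic generator** (Thomas cluster process with an
optional wrist-elevated density gradient, per-lineage session persistence
with positional jitter, and a stochastic report model) makes every stage
testable without access to raw experimental data.

## Worked example

The module `thermospot.studydata` rebuilds a reference table from the
published marginal summaries of a four-session forearm mapping study
(8 participants, 349 candidate spots):

```python
from thermospot.studydata import reference_table, reference_logs
from thermospot.classification import classify_table, summarize_categories

table = classify_table(reference_table(), reference_logs())
s = summarize_categories(table)
print(s.counts)
print(s.percents)
print(round(s.per_participant_mean_sd["cold"][0], 2),
      round(s.unconfirmed_rate_percent, 1))
```

prints

```
{'cold': 112, 'warm': 41, 'inconsistent': 165, 'incongruous': 16, 'unconfirmed': 15}
{'cold': 34, 'warm': 12, 'inconsistent': 49, 'incongruous': 5}
14.0 4.3
```

i.e. 334 of 349 candidates were confirmed (4.3% unconfirmed), 34% of
confirmed spots were cold, 12% warm, and 49% evoked *inconsistent*
sensations, with 14.00 cold spots per participant on average.

The same pipeline runs end to end on simulated data from the command line:

```sh
thermospot run --config cfg.json --out out/ --seed 42
```

with `cfg.json` containing `{"simulate": {"n_participants": 4}}` yields
(abridged):

```
Spot categories
---------------
210 confirmed of 221 candidate spots (5.0% unconfirmed)
  cold            85   40%  per-participant mean 21.25 (SD 5.80)
  ...
Spatial statistics
------------------
  participant P1: AD A2=3.553 p=0.01549 Clark-Evans R=0.25 z=-10.12 p=4.705e-24
  ...
Conservation across sessions
----------------------------
  20 of 210 confirmed spots conserved (9.5%, component convention, threshold 6.0 px)
```

Every R is well below 1 (the generator produces clustered maps), and only a
small fraction of spots recur across sessions, as expected from the
generator's low persistence default. Alongside the text report the run
writes `results.json` and machine-readable TSV tables (`categories.tsv`,
`spatial.tsv`, `conservation.tsv`).

Other subcommands: `thermospot simulate` (write synthetic spot/response/
ground-truth CSVs), `classify`, `spatial`, `conserve` for individual
stages.

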