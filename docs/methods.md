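# Methods

## Model

`trialminim` implements marginal-total minimization for two-arm trials in
the Taves / Pocock–Simon family, with a biased-coin random element.

A trial is configured with an ordered *factor scheme*: factors (gender,
age class, diabetes, aggregated ethnicity by default), each with ordered
levels and per-level weights. The scheme induces a fixed class ordering —
factors in declared order, levels in declared order, and the two outcome
classes (option 1 = control, option 2 = experimental) always in the last
two positions. The default scheme has 10 allocation classes, so vectors
have length 12.

A participant's class vector has exactly one nonzero entry per factor,
equal to that level's weight. Weighting is applied at vector construction,
so the per-arm marginal totals accumulate weighted values and the scores
inherit the weighting with no further machinery: halving a factor's
weights halves its influence on every future score.

The minimization score of an arm is the sum of that arm's marginal totals
at the positions where the new participant's allocation-class value is
nonzero. Equal scores allocate at random with probability ½ per arm
(ties are defined by exact floating-point equality, which is well defined
here because totals are sums of identical weight values); otherwise the
arm with the smaller score is preferred and followed with probability r.

## The randomization element r

r is the probability of following the minimization-preferred arm. The
accepted domain is **[0.5, 1]**: r = 1 is deterministic minimization,
r = 0.8 departs from the preference on 20% of decisions (which supports
allocation concealment), and r = 0.5 ignores the scores entirely — pure
randomization, making the engine usable for a standard randomized trial
with a centralized audit trail. Values below 0.5 would prefer the arm
that *increases* imbalance; they are rejected with an explanatory error
rather than silently accepted. Ties always use probability ½ regardless
of r.

When r = 1 and the scores differ, no random draw is consumed: the
decision is a pure function of its inputs, and the RNG stream is
identical whether or not deterministic branches occur between coin flips.
Every consumed uniform draw is recorded in the decision object for the
audit trail.

One global r applies to the whole trial; per-factor or per-site random
elements are not modeled.

## Randomness and reproducibility

The engine owns a single `numpy` generator, seeded from entropy by
default and overridable via configuration or `--seed`. An identical
configuration, seed and submission stream yields a byte-identical state
file. The simulator derives independent child seeds per replicate from a
`SeedSequence`, pairing streams across strategies so comparisons of r
values are paired comparisons.

## State persistence

The single source of truth is an append-only UTF-8 text file, one line
per allocated participant, fields joined by a configurable delimiter
(default `zz`), no header, Unix newlines. Field order is: participant ID,
date (ISO), weekday name, submitter, then all class values including the
two outcome flags — 16 fields under the default scheme. Class values are
rendered as integers when integral (`1`), otherwise by `repr` (`0.5`),
which round-trips exactly.

Serialization refuses any record whose fields contain the delimiter
(e.g. a participant ID like "Azzam" under the `zz` delimiter) *or* whose
field boundaries would concatenate into the delimiter (an ID ending in
`z` next to `zz`); the check is a split-back verification, so a line is
written only if parsing it reproduces the fields exactly. The delimiter
is configurable per trial for data where collisions are expected.

Every append writes the identical line to the state file (fsynced) and to
an archive mirror that is never read during operation; a missing archive
is recreated with a warning. Parsing rejects lines with a wrong field
count, non-numeric class values, anything but exactly one outcome flag,
or more/fewer than one nonzero class per factor, reporting the line
number. Blank lines are skipped with a warning.

The allocation transaction (load history → decide → append → notify) runs
under an exclusive advisory `flock` on a sidecar lock file, so concurrent
submissions serialize and each decision sees the complete history.
Duplicate participant IDs are refused unless explicitly overridden.

## Notifications and distributed backup

Each allocation composes three messages: submitter, study nurse (an exact
copy) and administrator. The submitter message is a fixed 18-line
template (header, date, weekday, time, ID, submitter, gender, age, age
class, detailed and aggregated ethnicity, the arm display string, running
counts, r, footer); the 18-line count is normative in this package, the
wording is its own. The administrator message contains the same content
plus the newly appended line and the entire state file verbatim between
marker lines; `rebuild_from_backup` extracts that block byte-identically,
so every allocation distributes a complete off-site backup. Message
transport is a pluggable interface (recording and file-outbox
implementations ship; SMTP is deployment plumbing and out of scope), and
transport failure never rolls back an allocation — allocation truth lives
in the state file.

## Intake

The detailed-ethnicity vocabulary maps 17 intake codes onto exactly
{white, black, asian, chinese}; codes A, B, C (White British / Irish /
other White background) map to "white". The shipped table is a synthetic
stand-in modeled on the UK NHS/census code letters — the full assignment
is trial configuration data, overridable per study, and integrity (17
codes, 4 categories, A/B/C → white) is revalidated at config load. Age is
cut at a configurable threshold (default 65) with the boundary inclusive
on the old side (65 → "old"). "Not stated" style responses are ordinary
vocabulary entries, never silently dropped. Validation aggregates all
problems into one report, and a confirmation summary supports the
two-step confirm flow (CLI `--yes` skips it).

## Synthetic population model

`default_population_model` draws factor levels independently per
participant with marginals typical of a small UK chronic-kidney-disease
cohort: 50% male, 71/152 under 65, 39/152 diabetic, and ethnicity
142:5:4:1 white:black:asian:chinese, with n = 152 per trial. Ages and
detailed codes are filled in consistently with the drawn levels so
streams exercise the full intake/reporting stack. The generator models
marginal prevalences only — real arrival streams have correlated factors,
site effects and temporal drift, so passing balance tests demonstrates
the algorithm's behavior under independence, not a guarantee for any
particular clinic population.

`run_trial` replays a stream with incrementally maintained aggregates;
this is equivalent to the engine's full load-from-file transaction (a
dedicated test asserts the equivalence), and keeps the 200-replicate
comparisons fast. Balance is summarised by the per-class
|control − experimental| totals, their maximum, and the arm-size
difference; `compare_strategies` reports means and central 95% ranges
over replicates, paired across r values.

## Problem sizes and tolerances

The shipped simulations use 200 replicates of n = 152 for the
minimization-vs-randomization comparison, 100,000 draws for coin-
frequency checks (3σ binomial band ≈ ±0.4 percentage points at p = 0.2),
and 20,000 draws for tie fairness (±0.011). Score-oracle and round-trip
properties are checked on 1,000 random instances each.

## Limitations

* Two arms only; no Pocock–Simon range/variance imbalance metrics beyond
  the sum-of-marginal-totals score; no stratified or block randomization.
* Factor independence in the generator (see above).
* The advisory lock serializes writers on one host (or a shared
  filesystem honoring `flock`); multi-host deployments need a single
  allocation endpoint in front of the engine.
* No authentication, encryption at rest, or mail delivery — deployment
  concerns deliberately left to the hosting layer.
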