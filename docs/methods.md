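# Methods

## Data model

A **location event** is one sensor read *(resident, timestamp, area)*;
timestamps are naive date-times truncated to whole seconds.  Events are
segmented into **traces**: one per (resident, calendar day).  Within a day,
consecutive same-area reads collapse into a single **visit** whose dwell
runs from the first read of the area to the next area change.  Two
boundary conventions are implemented:

* default: the last visit of a day ends at the day's final read — the
  sensor gives no evidence of presence after the last event, so a
  single-read day has dwell 0;
* `extend_to_midnight=True`: the final stay is carried to 00:00:00, and a
  stay continuing into the next day restarts there at midnight, so a visit
  never crosses a day boundary in either mode.

The day boundary is the local midnight of the timestamps as given (no
timezone conversion is applied; inputs are assumed to be in facility-local
time).

MXML serialization writes one `ProcessInstance` per trace, one `start`
entry per visit, and a closing `complete` entry for the final visit when
its dwell is positive; reading reverses this exactly, so write→read is the
identity on any log derived from an event stream.  Entries with lifecycle
event types other than `start`/`complete` (or with none) are dropped on
read and counted in the log metadata.  Gaps between consecutive visits are
not representable in event form; logs produced by segmentation or
simulation are gap-free.

## Model inference

The inferred automaton is first-order and label-merged: one node per area,
a virtual start node `_START_`, a transition per observed consecutive
visit pair (counted), and a final flag on every area that terminated at
least one trace.  Visit counts and accumulated dwell are exact tallies.
Consequences:

* every training trace replays successfully against its own model, by
  construction;
* counts are additive and order-independent, and adding traces never
  removes structure;
* no noise filtering is applied at inference time (an optional post-hoc
  count threshold exists, default 0 — infrequent behavior is signal here,
  not noise).

Parallel-join discovery (multi-source transitions) is representable in the
data model but never produced: a resident is in one place at a time, so
location streams are strictly sequential.

## Model comparison

**Edit distance.**  Node identity is the area label (virtual start
excluded); transition identity is the (source, target) label pair,
start-transitions included.  Differences of model A vs. model B are the
set differences in both directions; the scalar distance is the weighted
count `WD = w_na·|N_A| + w_nd·|N_D| + w_ta·|T_A| + w_td·|T_D|`.  Counts do
not enter the comparison — it is purely structural; frequencies feed the
heat maps instead.  Default weights are (2, 2, 1, 1): gaining or losing a
whole location is treated as twice the change of a new path between known
locations.  With symmetric weights the distance is symmetric; the
difference lists swap roles when the operands swap.

**Trace replay.**  Replay starts at the virtual start; each visit must
fire a transition from the current state to its area, and the day must end
in a final state.  On failure the replay resumes greedily at the node of
the offending area and records what the model lacks: an unseen area is an
added node plus the added transition reaching it; a known area reached by
an unseen step is an added transition; a known but non-final terminal area
is recorded as a transition to the `_END_` pseudo-target, weighted as a
transition.  A terminal area that is itself an added node contributes no
extra finality difference (adding the node implies marking it final).  The
day's score is the weighted count of these differences — exactly the
edit-distance formula applied to the replay's difference set.

**Drift analyses.**  The daily outlier series trains one model on a
baseline window (a month in the intended use) and scores each later day by
replay distance; peak ties break to the earliest day, and the full series
is always returned so a human judges the peaks.  The weekly curves use
ISO-8601 weeks; partial first/last weeks are included if they contain at
least one trace, and calendar weeks inside the span with no traces are
skipped and listed in the series metadata.

## Heat maps and favorite areas

Node intensity is accumulated dwell divided by the maximum over the model,
transition intensity the analogous count ratio — linear max-normalization,
chosen over log scaling for interpretability (an optional threshold zeroes
everything below it).  If all values are zero (degenerate, e.g. a model of
single-read days) all elements are treated as equal and maximal.
Normalization is per-model; comparing heat maps across periods therefore
shows *relative* allocation, not absolute hours — the favorite-areas table
carries the absolute per-period dwell sums, which are conserved exactly
against the traces.  "Favorite" areas are the top-k (default 7, the number
of stock areas) by total dwell; the table itself is never truncated.

## The simulator

A resident is a semi-Markov chain over areas: a day starts at a fixed
clock time in an area drawn from a start distribution; dwells are drawn
per area from a shifted exponential with a 60 s floor (a faster hand-off
is a read artifact, not a stay; a gamma alternative with shape 2 is
available); the next area follows a row-stochastic matrix with zero
diagonal.  One event is emitted per area entry — exactly what a
change-triggered location logger records.  The stock profiles are:

* `nursing_home_profile` — baseline: seven areas (TV room, dining room,
  own room, library, three courtyards), mean stays 15–90 min, days
  08:00–21:00 (≈ 15 visits/day);
* `winter_profile` — same areas, courtyards abandoned and indoor stays
  lengthened; the target of incremental seasonal drift;
* `sick_day_profile` — an anomalous day kept to the own room, an infirmary
  area absent from the baseline, and short dining-room trips.

Change injection: *sudden* switches profiles from an onset date;
*incremental* advances a convex combination of matrices, dwell means and
start distributions once per simulated week by a fixed rate (convexity
keeps every intermediate matrix row-stochastic, which is asserted daily).
A helper injects a single anomalous day at a known index for ground-truth
outlier experiments.  All randomness flows through one numpy PCG64
generator, so a seed fixes the corpus byte for byte across platforms.

What the simulator does **not** emulate: beacon signal noise and misreads,
multi-resident interaction, night-time movement, weekday/weekend
structure, or physically realistic trajectories.  Passing the simulation
experiments therefore shows the algorithms recover the changes they are
designed for under clean semi-Markov conditions; it does not quantify
robustness to sensor artifacts in real deployments.

## Evaluation protocol and problem sizes

The acceptance evaluation (in `scripts/acceptance.py` and mirrored in the
test suite) uses these scales, chosen to give stable statistics at desk
scale: 200 random model pairs for the metric axioms; 100 simulated logs of
5–50 days for the acceptance guarantee; 50 seeded runs of 30 baseline +
10 evaluation days with one injected anomalous day for sudden-change
recovery (the expected recovery rate is well above 90%; occasional misses
happen when the anomalous day's replay score ties a day with several novel
rare transitions); 20 simulated weeks for the drift curves, drifting at
rate 0.05/week toward the winter profile versus a stationary control
(under the stationary null the trend p-value is uniform, so a single run
is significant at the 5% level one time in twenty); 50 random logs for
MXML round trips.

## Numerical and design notes

* Distances are sums of products of small integers and user weights —
  exact in floating point for all practical weight choices.
* DOT output is deterministic: elements are emitted in sorted label
  order; rendering layout is delegated to external DOT tools.
* The CLI pipeline writes a JSON manifest (inputs, seed, version, stage
  summaries) and removes partial outputs on failure; identical config and
  seed reproduce byte-identical artifacts.
* Replay of an empty trace is an error: day segmentation never produces
  one, so an empty sample indicates an ingestion bug upstream.
* The pipeline configuration schema (YAML): `seed`, `output_dir`, either
  `simulate: {profile, days, start_date, resident, change: {kind, target,
  onset|rate|day_index}}` or `input: <path>`; optional `resident`,
  `model_window: {from, to}`, `eval_window: {from, to}`, `weights: {node,
  transition}`, `weekly_drift`, `favorite_areas`, `period`, `plots`.

## Known limitations

* One area per timestamp: overlapping beacon reads are resolved upstream
  by the location system; the package trusts the stream.
* The inference is first-order: behavior distinguishable only by
  longer-range context (the same room playing different roles at
  different times of day) merges into one node.
* Replay difference reporting is greedy, not an optimal alignment; scores
  upper-bound the minimal edit but the reported elements are the ones a
  clinician sees highlighted, favoring interpretability over minimality.
* Week curves on sparse logs (few traces per week) are dominated by
  sampling noise in which rare transitions happened to occur; the curves
  are meant for expert inspection, not automated change-point testing.
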