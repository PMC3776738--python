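# Methods

## The pipeline in one paragraph

`pacscreen` turns raw real-time-strategy telemetry — one JSON-lines log per
player per game, holding every command, hotkey press, minimap action,
production order and view-screen movement — into a per-player vector of 15
cognitive-motor variables, and then asks *which of those variables help
separate players from two different skill leagues*, for every pair of
leagues two steps apart plus the extreme novice-professional contrast. The
screening decision is made against an injected pure-noise pseudo-variable,
so that "importance" is judged relative to what chance produces under the
identical fitting procedure.

## Points of View and Perception-Action-Cycles

Screen movements in an RTS are functionally similar to saccades: the player
relocates the view to look and act somewhere else. We group them with the
dispersion-threshold identification (I-DT) algorithm familiar from
eye-tracking. Dispersion of a window of screen positions is
`(max x - min x) + (max y - min y)`. Sliding from the earliest move:

1. seed the smallest window whose time span reaches the duration threshold
   (default 20 timestamps ≈ 230 ms);
2. if its dispersion exceeds the threshold (default 6 game coordinates),
   drop the first move and re-seed;
3. otherwise grow the window until the next move would push dispersion over
   the cap;
4. emit a Point of View (PoV): centroid of member coordinates, start at the
   first member's timestamp, end at the violating move's timestamp; resume
   at the violating move.

Conventions the algorithm statement leaves open, fixed here: the PoV
interval is half-open `[start_t, end_t)` for event containment; at end of
stream the PoV ends at the last member's timestamp + 1; ties in timestamp
are processed in input order. Only screen moves drive segmentation — hotkey
selects can relocate the view in the real game interface, but we do not
model them as PoV generators, which is also why they are excluded from every
PAC variable (see below).

A PoV containing at least one qualifying action is a Perception-Action-Cycle
(PAC). Qualifying means any non-screen-move event except hotkey selects.
Action latency — PoV onset to first qualifying action — plays the role of
reaction time in a laboratory trial.

## The 15 per-player variables

| variable | definition | unit |
|---|---|---|
| action_latency_ms | mean over PACs of first-action delay | ms |
| actions_per_pac | mean qualifying actions per PAC | count |
| pacs_per_min | PACs per minute of game time | 1/min |
| gap_between_pacs_s | mean PAC-end to next-PAC-start | s |
| hotkey_selects_per_min, hotkey_assigns_per_min | hotkey usage rates | 1/min |
| unique_hotkeys | distinct hotkey ids used | count (≤10) |
| minimap_attacks_per_min, minimap_rightclicks_per_min | minimap actions | 1/min |
| workers_per_min | worker-production rate | 1/min |
| map_explored_pct | grid cells visited by ≥1 PoV centroid | % |
| unique_units | distinct unit types trained | count |
| complex_units_per_min, complex_abilities_per_min | cognitively demanding production/abilities | 1/min |
| apm | all non-screen-move events per minute | 1/min |

Game length is `max_timestamp × ms_per_timestamp` with 11.5 ms per
timestamp by default (20 timestamps ≈ 230 ms fixes the conversion; the
"25000 timestamps ≈ 5 minutes" inclusion rule implies ~12.0 ms, so the
source material is internally approximate and the value is configurable).
Interpretation choices: APM includes hotkey events (the inclusive count is
the one consistent with a pooled mean near 117); gaps between PACs are
reported in seconds (the only magnitude-consistent unit given ~18 PACs/min);
map exploration uses a 16×16 grid over a 128×128-coordinate map, both
configurable. Players with zero PACs get NaN in the PAC-derived fields and
are dropped per screening task with a logged count.

Inclusion filters mirror the replay-level comparability rules: at least
25000 timestamps of play, at least 100 total inputs, exactly two human
players. Thresholds are inclusive on the accepted side (the source states
only the drop conditions). Survey-style exclusions (identity verification,
game version) are not recomputable from an event log and are out of scope.

## Importance screening

For each league-pair task (defaults: spacing two — Bronze-Gold through
Diamond-Professional — plus Bronze-Professional), 25 repetitions of:
draw 70% of the task's rows without replacement; append a fresh `control`
column of i.i.d. Uniform(0,1) noise; fit a forest (1000 trees, 5 candidate
features per split; tests and the acceptance script use 100 trees to keep
wall-clock budgets sane — the decision rule is unchanged); record each
variable's out-of-bag permutation importance and the forest's out-of-bag
accuracy.

The 95th percentile (linear interpolation) of the control's 25 importance
values is the critical value; a variable is flagged when its *median*
importance exceeds it. This holds each variable's false-flag rate at or
below roughly 5% and deliberately makes no family-wise correction — the
output is a screening shortlist, not a set of confirmatory p-values. The
max-of-control value is reported as a secondary, more conservative
diagnostic. Variables are ranked by descending median importance (ties by
mean, then name), control included, so ranks are a permutation of 1..16.

The forest layer is a bagging ensemble of CART trees
(`sklearn.tree.DecisionTreeClassifier`) with bootstrap row sampling,
out-of-bag accuracy, and per-tree OOB permutation importance (mean decrease
in accuracy). Conditional-inference trees were preferred in the original
setting to avoid split-selection bias toward predictors with many distinct
values; all 16 features here are continuous, where that bias is minimal, so
plain CART trees are used and the layer is pluggable. Subsampling is not
stratified by league and accuracy is OOB-based (both choices undocumented in
the source; stratified and balanced modes are available by flag). The
`balanced_n` mode draws an equal number of rows per class before
subsampling, reproducing the equal-class-size robustness rerun.

Determinism: every repetition derives its seeds from
`SeedSequence(master_seed, spawn_key=(task_index, rep))`, so task order and
repetition count never perturb each other's draws, and a report is
bit-for-bit reproducible from `(table, config, seed)`.

## The synthetic cohort

No deposited replay corpus exists, so the generator *is* the data source
for every end-to-end result here. Per player: game length ~ Normal(8, 1.5)
minutes floored at 5.2; fixation dwells ~ lognormal, inter-fixation gaps ~
gamma; fixation centers follow a reflected random walk that returns to one
of three anchor locations (bases) with probability `home_prob` and
relocates uniformly with probability `far_jump_prob`; consecutive centers
stay ≥16 coordinates apart so every transition clearly violates the
dispersion cap. Within a fixation, screen moves jitter ±0.8 coordinates
around the center; a transition move partway to the next center closes the
PoV 2 timestamps after the true dwell ends. A fraction
`pac_action_fraction` of fixations receives a first action after a gamma
latency and a `1 + Poisson` burst of generic commands; hotkey, minimap and
production events arrive as uniform Poisson background with league-graded
rates, and also count as qualifying actions when they land inside a PoV.

League gradients encode the qualitative skill picture: perception-action
cycle time shrinks geometrically from ~5 s (Bronze) to about half
(Professional), first-action latency strictly decreases with league, every
event rate is non-decreasing, and hotkey/unit pools grow.

League placement is modeled as a *noisy measure of underlying skill*: each
player draws a continuous skill `league + Normal(0, skill_sd)`
(`skill_sd = 1.2` leagues; 0.4 for the more homogeneous professional group)
and their parameters are interpolated log-linearly between league levels at
that skill, with additional mean-preserving lognormal trait jitter
(σ = 0.12) on latency and the event rates. This is what makes adjacent
leagues overlap heavily while leagues two apart remain separable at
realistic (~70–95%) classification rates, and it supplies most of the
pooled between-player spread; without it every player in a league would be
statistically identical and any two-league classifier would be trivially
perfect. The spread values are structural constants of the study
conditions, chosen to place two-league separability in the published range,
not fitted per variable.

The absolute levels are set by `calibrate_params`: an iterative proportional fit that
simulates a scaled-down cohort, runs the *actual* extraction pipeline, and
rescales one mapped knob per off-target pooled mean (latency mean ↔ latency
target, burst size ↔ actions per PAC, cycle time ↔ APM, gap ↔ gap target,
within-fixation move rate ↔ total inputs, home-return probability ↔ map
explored, each event rate ↔ its own rate target) by
`(target/measured)^step` with decreasing steps, judging convergence on the
mean of the last three cohorts because single-cohort means of the rare
event rates (complex units ~0.3/min) are noisier than the 2% tolerance.
The shipped `DEFAULT_LEAGUE_PARAMS` table is one converged run of this
procedure (30% cohort scale) and is frozen as literals.

Two pooled quantities are deliberately *not* calibration targets.
`pacs_per_min` is over-determined: with APM, actions-per-PAC and the event
rates at their published values, the qualifying-action budget forces
PACs/min to ~17.5 rather than the printed 18.4 — the printed pooled
summaries are mutually inconsistent by about 5% under any homogeneous
model, and we keep APM and actions-per-PAC exact instead. The discrete
pool sizes behind `unique_hotkeys` and `unique_units` are set once in the
base table (weighted means ~4.3 and ~6.5 against printed 4.36 and 6.53),
not iterated.

`null_mode` draws each player's generative parameters from the
size-weighted league mixture while keeping the league *label* assignment
fixed, so labels carry no behavioral signal; these cohorts drive the
false-flag-rate checks.

### What the generator does not emulate

Real replays have opponent interaction, economy dynamics, map geography,
strategy-dependent event clustering, within-player variability across games
and non-stationarity within a game (early-game worker focus, late-game
battles). Passing tests therefore show that the *pipeline* measures what it
claims and that the screening procedure is calibrated and powered — they do
not re-establish the original empirical ranking of variables, which would
require the original replays. For the same reason the published per-task
classification rates and the original rank matrix are not reproduction
targets; the null-calibration and power properties stand in for them.

## Numerical and testing choices

* Problem sizes: unit tests run on hand-built logs; the oracle-equivalence
  check uses 1000 random streams of ≤200 moves; null calibration uses 40
  independent 80-player null cohorts at 100 trees; power curves use 10
  seeds × 4 effect sizes (0, 0.5, 1, 2 SD shifts) at 100 trees; the
  cohort-reproduction check simulates the full 3360 players once.
* The I-DT oracle in `tests/_idt_oracle.py` is an independent, naive
  re-statement of the definition (plain lists, full recomputation) kept
  free of package imports.
* Flag-rate bounds use one-sided binomial 99.5% quantiles: the median-vs-
  95th-percentile rule is conservative (its per-variable false-flag rate is
  *at most* ~5%), so only the upper tail is informative.
* Degenerate inputs: empty move streams yield no PoVs; a stream whose span
  never reaches the duration threshold yields none; zero game length is an
  error; a constant column has exactly zero permutation importance.

## Known limitations

* The generator's league gradients are monotone interpolations anchored at
  two qualitative endpoints; real per-league distributions are unknown here.
* Calibration matches pooled means, not SDs or shapes; pooled SDs emerge
  from the league spread plus within-league noise and are not controlled.
* The forest is CART-based bagging, not conditional-inference forests;
  with continuous features the importance rankings agree in our
  simulations, but exact numerical importances differ by construction.
* `ms_per_timestamp` is a single global constant; real game-speed
  variation is assumed filtered out upstream.
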