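# Methods

## Problem and data model

`adherekit` analyses dosing histories from a once-daily medication regimen
monitored through two independent channels:

- a **smart button** the patient presses to self-report "I just took my
  dose" (a press reaches the server through a phone app, so presses can be
  lost in transit), and
- an **electronic medication-event monitor (EMM / MEMS-style) pill cap**
  that timestamps every bottle opening, used as an objective proxy for dose
  taking.

Every event is an absolute instant with a UTC offset, attributed to a
participant and a device uid. All analysis happens in *participant clock
time*: the study calendar is a fixed horizon of `n_days` consecutive local
calendar days (default 52), partitioned into consecutive phases (default
1–14 / 15–45 / 46–52), and the day boundary is participant-local midnight.
We anchor days to the participant's local midnight because adherence is a
daily behavior organized around the patient's own day, not the server's.

### Timezones and travel

A participant's *effective* timezone on a study day is the home timezone
unless a travel-log entry covers that day; overrides apply per whole local
calendar day (no sub-day travel resolution is modelled). Because the travel
log is keyed by study day while the study day depends on the timezone, an
instant near a travel boundary can admit two consistent (day, zone)
readings; a travel-consistent reading wins, so the override zone governs
its entire local day. This rule is deterministic and is exercised by the
simulator's traveler scenario.

Two rendering policies are implemented. `participant_local` is the correct
behavior. `fixed_server` always renders events in the home/server zone,
deliberately reproducing a known failure mode of server-side feedback
systems: a patient who travels five hours ahead and doses exactly at their
(new local) goal time is misclassified as outside the window when the
server applies its own zone. Keeping the broken policy available makes the
mismatch testable rather than anecdotal.

## Dosing window and timing classification

The scheduled dose time is a local clock time (`goal_time`). The on-time
window is `window_fraction × dosing_interval_hours / 2` on either side of
it — with the default 24 h interval and fraction 0.25 this is the ±3 h
window used in practice because taking a drug within 25% of its dosing
interval preserves bioavailability. Classification uses the **minimal
circular distance on a 24 h clock**, so a 23:30 press against a 01:00 goal
is 1.5 h early, not 22.5 h late, and the window wraps across midnight.
The interval is **closed**: a press exactly at `goal ± half-width` is
on time (the permissive reading of "within ±3 hours"); a minute-enumeration
oracle in the tests confirms that a ±3 h window around 01:00 contains
exactly 361 of the 1440 minute marks. `window_fraction` may be 1.0, the
degenerate case in which every clock time is in-window.

## Feedback decision rules

Only button presses trigger feedback; cap openings never do. Presses are
sorted by timestamp before processing (webhook delivery order is not
guaranteed), making replays byte-identical. The rules per press:

1. Resolve the participant from the button uid (the registry is injective;
   unknown uids are logged and skipped, never aborting the stream).
2. Localize the press and find its study day and phase.
3. Phases 1 and 3, repeat presses in phase 2, and presses after the study
   horizon all get the single **standard** acknowledgement.
4. The **first** press of each local study day in phase 2 gets a tailored
   message matching its timing class. The tailored bank holds 30 on-time
   and 30 outside-time messages; the index cycles deterministically,
   `((study_day − first_phase2_day) mod 30) + 1`, so a full phase 2 visits
   every message once and wraps. The bundled bank carries placeholder
   prose; the structure (counts, categories, indices) is the modelled part.

A post-horizon press is reported with `phase = None` and timing
`not_applicable` — participants are known to keep using devices past the
formal study end, and such events are flagged, never dropped.

Messages are emitted to a pluggable transport; the bundled transport is a
dry-run log (no SMS delivery, receipts or retries are modelled).

## Adherence scoring

Taking adherence for a once-daily regimen: a day is adherent if it has at
least one event on that participant-local day (duplicates within a day are
idempotent). A score over a period is
`100 × adherent_days / (period_days − exclusion_days)`, where exclusions
are days the participant reported not using the device; removing them from
the denominator mirrors how such studies adjust for reported non-use.
Scores are rounded **half-up to integer percent**; completeness
(`100 × recorded / expected`) is reported to **one decimal** — each
matching the precision conventionally printed for that statistic. Cap
openings are treated as dose-taking proxies; no timing-weighted index or
multi-dose regimen is implemented.

## Two-channel concordance

Within each participant-local study day, button and cap events are paired
one-to-one by the matching that **minimizes the total absolute time
difference** (Hungarian assignment on the |Δ|-seconds matrix). A greedy
closest-first rule is not equivalent: with presses at 08:00 and 08:03
against openings at 08:02 and 08:04, greedy commits to (08:03, 08:02) and
is forced into (08:00, 08:04), a worse total than the optimum. The exact
assignment is deterministic and matches the intuitive "corresponding
event" reading; a tiny concave perturbation (`1e-6·√seconds`) breaks
equal-total ties toward matchings containing exact pairs, keeping the
statistics invariant under swapping the channel labels.

Deltas are computed on absolute instants and reported at whole-minute
granularity (floor of seconds, signed as button − cap). A pair is
*button-first* when the press precedes the opening by ≥1 min, *cap-first*
in the opposite case, *identical* when the instants agree to the minute.
A day is concordant if it has ≥1 pair; the concordance percentage is over
monitored days (horizon minus reported non-use days), and the ±5 min
agreement percentage — inclusive, `|Δ| ≤ 5` — is over pairs. Days with an
event on exactly one channel count toward that channel's day count and
against concordance.

## Behavioral simulator

The simulator generates *measurement* data, not intervention response: it
emulates the data-collection design (daily dose, cap opening, optional
button press), so passing tests demonstrate the pipeline's arithmetic, not
behavioral claims about real patients. Per non-excluded day, independently:

| parameter | meaning | default |
|---|---|---|
| `p_dose` | probability the dose is taken | 0.762 |
| `jitter_sd_minutes` | SD of Gaussian timing noise around the goal | 45 |
| `late_shift_minutes` | mean timing shift | 0 |
| `p_press_given_dose` | probability the button is pressed | 0.80 |
| `p_press_received` | probability a press reaches the server | 0.599 |
| `press_lag` | press delay after the opening | mixture, below |
| `nonuse_days` | reported device non-use days | ∅ |
| `travel` | whole-day timezone overrides | ∅ |

The defaults are calibrated to the completeness rates of a 5 × 52-day
once-daily feasibility deployment: `p_dose = 0.762` reproduces 76.2% cap
completeness, and the joint press-through `0.80 × 0.599 ≈ 0.479` reproduces
36.5% button completeness (0.762 × 0.479). The split of 0.479 between
pressing and transmission is not identifiable from those aggregates; 0.80 /
0.599 was fixed once as a plausible division in which transmission loss
(the app being closed) dominates. The jitter SD of 45 min is a realistic
spread for a daily routine; no distributional information beyond summary
extremes exists to fit it, so it is a stand-in, not an estimate.

The press lag is a mixture: with probability 0.7 uniform on 0–2 min,
otherwise exponential with mean 60 min, negated with probability 0.25
(press before opening). The heavy tail reproduces the qualitative extremes
seen in practice (delays of many hours when a patient is interrupted and
presses later); the weights are configuration, not fitted values. Dose
instants are truncated to stay within the local day (the daily data model
needs one local-day assignment); button presses may cross midnight.

Ground truth (`dose_taken`, `press_attempted`, `press_received` per day)
is returned alongside the event streams, enforcing
`received ⇒ attempted ⇒ taken`, and supports parameter-recovery tests: cap
adherence/100 estimates `p_dose`, and button-days/cap-days estimates the
joint press-through rate.

A bundled 5-participant scenario mirrors the qualitative heterogeneity of
a small feasibility cohort: a near-perfect taker, a low-adherence taker, a
high taker with zero received presses, a traveler (days 20–27, +5 h zone),
and a participant who stops using the devices on day 48. Seeding is
explicit throughout (`numpy` `SeedSequence` spawning per participant);
equal seeds give byte-identical fixtures.

What the simulator does **not** model: habit formation or any effect of
the feedback messages on behavior, day-to-day dependence (each day is
independent), device clock drift, and sub-minute timing structure.
Conclusions about real-data performance are limited accordingly.

## Numerical and formatting choices

- Rounding: half-up (decimal, not banker's) to integer percent for
  adherence; one decimal for completeness and concordance percentages;
  whole minutes for deltas.
- Degenerate inputs raise typed errors rather than returning NaN: empty
  scoreable period (`UndefinedScoreError`), zero monitored days
  (`UndefinedPercentageError`), zero expected events, empty cohorts.
- Event CSV parsing collects malformed rows with line numbers and fails
  once at the end; missing columns fail fast.
- Every CLI run can write a manifest (input SHA-256 digests, config
  snapshot, seed, version); manifests equal up to the wall-clock timestamp
  imply byte-identical outputs.

## Problem sizes used in the checks

The statistical checks run at sizes chosen to make Monte-Carlo error small
relative to the tolerances: 200 replicate cohorts (52,000 participant-days)
for the completeness calibration, judged at ±3 standard errors of the
binomial mean; 500 participant-studies (26,000 days) for parameter
recovery, also at ±3 SE; and 1,000 random small instances (≤3 events per
channel per day) for the pairing-versus-brute-force equivalence.

## Known limitations

- Once-daily regimens only; one expected dose per day is hard-wired into
  scoring and simulation.
- Travel resolution is whole-day; a dose taken mid-flight between zones is
  attributed to whichever zone's reading is travel-consistent.
- Daylight-saving behavior is whatever the IANA database provides; no
  additional modelling.
- The pooled concordance summary cannot recover per-order medians from
  per-participant summaries (medians are not poolable); recompute from
  pooled pairs when exact pooled medians matter.
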