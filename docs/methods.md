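# Methods

## The problem

ICU glycemic management leaves two intertwined traces in an electronic
medical record: blood-glucose readings (bedside fingerstick glucometer and
central laboratory analyzer) and insulin administrations (subcutaneous
boluses, intravenous pushes, and continuous infusions charted as rate
intervals). Neither stream is analysis-ready: charting is delayed, values
are ceiling-coded or fat-fingered, lab results are double-charted, and —
crucially — the record does not say *which* glucose reading a given insulin
dose was a response to. `glupair` implements (1) a criterion-by-criterion
curation of both streams, (2) a rule-based alignment of each insulin event
to its plausible trigger, (3) validation assays of the result, and (4) a
synthetic-EHR generator that makes all of it testable against a known
ground truth.

## Curation criteria

Glucose readings, in order (each step is a row in the `CurationReport`, so
counts always chain):

| step | action |
|------|--------|
| A | drop rows whose ERROR flag is 1 |
| B | drop zero values |
| C | drop null values |
| D | keep only patients with at least one insulin event |
| E | collapse identical (subject, timestamp, value) readings charted in both CHARTEVENTS and LABEVENTS |
| F | drop lab-analyzer values ≥ 1000 mg/dL and fingerstick values ≥ 500 mg/dL (meters ceiling-code higher readings as "500"); resolve the measurement time as STORETIME when it precedes CHARTTIME (delayed charting), else CHARTTIME |

Insulin events: G drop rewritten (never-delivered) entries; H drop events
with no ICU-stay ID; I impute missing infusion rates from ORIGINALRATE,
then keep infusions with 0 < rate ≤ 29.8 U/hr; J keep short-acting boluses
with 0 < dose < 18.0 U; K keep other boluses with dose > 0.

Numerical boundary choices: the bolus cap is exclusive and the infusion cap
inclusive, so the retained extrema are exactly 17.0-class doses and
29.8 U/hr — the caps are 99th-percentile values, and the published
post-curation maxima sit at 17.0 and 29.8. Both caps are configuration, and
`recompute_caps` re-estimates them as a percentile of the data at hand.
The 18 U cap applies only to short-acting boluses; basal products
legitimately reach 180 U and are filtered only for non-positive values.
Criterion D keys on `subject_id` ("patients", not admissions), and the
packaged pipeline feeds *curated* insulin events into it, which makes the
curated glucose population and insulin population coincide. Criterion E
keeps the LAB-origin row of a duplicate group (the laboratory record is
authoritative) with deterministic tie-breaks (lowest row id), and matches
on the pre-resolution chart time because E runs before F.

## Alignment rules

Within each ICU stay (events or readings outside `[in_time, out_time]` are
excluded — criterion L), every curated insulin event is linked to at most
one glucose reading:

1. the latest reading preceding the event by ≤ 90 min;
2. otherwise the earliest reading following it by ≤ 90 min;
3. when both exist, the higher value wins;
4. a short-acting bolus and a short-acting infusion event starting within
   15 min of each other are one clinical action ("bolus, then start the
   drip"): both receive the same reading, selected as in rules 1–3
   relative to the earlier member's start time;
5. readings below 90 mg/dL are never paired — no clinician treats
   hypoglycemia with regular insulin.

Parameters (all in `PairingParams`): window 90 min (inclusive at the
boundary — "up to 90 minutes"), floor 90 mg/dL, bundle gap 15 min. The
bundle gap quantifies "very close" for rule 4; it is deliberately
configurable because no canonical value exists.

Deterministic tie-breaks, needed for reproducibility and for oracle
testing: an equal-value straddle resolves to the *preceding* reading
(trigger-precedes-treatment semantics); among readings at the identical
timestamp the higher value wins, then LAB origin, then the lowest row id;
bundle matching scans boluses chronologically, each taking the nearest
free short-acting infusion within the gap. The floor applies to following
candidates as well as preceding ones: every published paired-glucose
minimum is exactly 90.0, implying a global floor. Because rule 4 windows
the shared reading at the bundle's earlier member, the later member's own
gap may exceed the window by at most the bundle gap; the file writer
permits exactly that slack on rule-4 rows and is strict elsewhere.

A reading may trigger several administrations; its row in the paired file
carries `Repeated = True` when it was aligned to at least one insulin row
(the value is repeated in that row's `GLC_AL`).

## Validation assays

- **Distribution moments** per measurement method: n, mean, SD, median,
  excess kurtosis, Fisher-Pearson skewness, min, max. Zero-variance
  samples report skewness 0 and undefined kurtosis.
- **Method agreement**: the first fingerstick of each stay is paired with
  the temporally closest lab result; Bland-Altman bias, SD and limits of
  agreement bias ± k·SD (k = 1.96 by default, configurable) are computed
  per time-gap (Δθ) bin, with a Wilcoxon signed-rank test of zero median
  difference and a LOWESS smooth of Δ against the pair mean (any standard
  local-regression smoother satisfies this contract; statsmodels' LOWESS
  is used). Δ glucose is oriented fingerstick − lab. Δθ bin edges default
  to 0/30/60/90/120 min with an open last bin and are configuration.
- **Scenario comparison**: per stay, the first short-acting bolus is
  paired under A (full rules, 90 min), B (full rules, 60 min) and C (no
  rules: nearest preceding reading, unbounded, no floor). Differences
  (scenario − C) are binned by the gap to the scenario-C reading and
  tested with a two-sided paired signed-rank test at 0.05; zero
  differences are dropped (classical Wilcoxon convention) and counted
  separately; a bin with no non-zero difference reports p = 1. Scenarios
  A/B use the full rule set — with only a preceding-readings definition,
  every instance in the > 90-min gap bins would be excluded as A-unpaired,
  which contradicts how those bins behave; the rules may instead attach a
  following reading there, which is exactly what the large median
  differences in those bins measure.

Pair counts are nested by construction: C pairs whenever any reading
precedes the bolus, A whenever C's choice (or a within-window neighbour)
qualifies, B under a stricter window — so paired(C) ≥ paired(A) ≥
paired(B).

## The synthetic generator

What it emulates: per-stay lognormal lengths of stay; a mean-reverting
AR(1) latent glucose (setpoint 140 mg/dL, autocorrelation 0.8, innovation
SD 25) with exponential meal excursions and a dose-proportional insulin
response; fingerstick observation noise (bias +2, SD 7 mg/dL) against lab
noise (SD 3); fingersticks roughly 4-hourly and lab glucose roughly
12-hourly, jittered; a sliding-scale protocol (modal 2–4 U boluses for
140–165 mg/dL, 2–4 U/hr infusion rates from 115 mg/dL, nothing below the
protocol floor), infusion-managed stays, bolus+infusion bundles at
infusion starts, and a once-daily basal dose adjusted to the morning
reading. Every administration records its triggering reading, the protocol
band and the true reading-to-dose gap in a ledger.

Artefacts are injected on top of the clean tables, each on a distinct row,
each itemised with whether curation can recover it: delayed charting
(8.4% of chart rows, lognormal delay with median 25 min; CHARTTIME slips
late while STORETIME keeps the true check time — recoverable by criterion
F), cross-table duplicates of lab rows (recoverable: the clean row
survives deduplication), missing infusion rates with ORIGINALRATE intact
(recoverable by imputation), and the unrecoverable classes: error flags,
zeros, nulls, ceiling-coded "500" fingersticks, rewritten insulin entries
and outlier doses/rates above the caps. Expected post-curation tables
therefore follow from the ledger in closed form, and the test suite checks
them by exact set comparison.

One structural choice deserves emphasis: consecutive charted readings in a
stay are at least 185 min apart (fingersticks are 4-hourly; lab draws that
would land closer to a bedside check than that are suppressed, as a unit
clerk batching draws would). Because 185 > 2 × 90, whenever a treatment
follows its trigger within the 90-min window the trigger is the unique
latest eligible preceding reading and no following reading can compete —
so alignment provably recovers every ledger link via rule 1 (or 4), and a
link can be missed only when its true gap exceeds the window. This makes
the recovery guarantees consequences of the schedule, not of tuning.
Treatment delay (reading → administration) is lognormal with median 10 min,
capped at 30 min by default; lifting the cap and raising the median/sigma
(e.g. median 25, σ = 1) produces the heavy-tailed regime in which recovery
degrades, and degrades only on links with gap > 90 min.

What the generator does **not** emulate, hence what passing tests do not
show about real data: pharmacokinetic insulin-glucose dynamics (the
response is a one-step drop), inter-site protocol variation, multiple ICU
stays per admission, CareVue-era records, free-text or unit errors, and
correlated artefacts (e.g. a sick patient charted worse). Realism of the
glucose trajectory is explicitly not a goal; schema, timing and artefact
structure are.

## Numerical and degenerate-input conventions

Timestamps are minute-resolution ISO-8601; window comparisons are
inclusive; all randomness flows from a single `numpy` generator seeded in
`SimConfig`, so identical configs produce byte-identical files. Empty
inputs produce empty (header-only) outputs everywhere. The file writers
validate the published invariants (16/21-column layouts, exactly one
stream populated per row, TIMER consistency, per-stay chronological order,
floor and window bounds) and refuse to write violating rows.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence runs 1,000 random micro-instances of ≤ 20 events;
recovery assays use 200-stay cohorts (≈ 2,300 ledger links); curation
accounting uses a 120-stay corrupted cohort; the Bland-Altman assay uses a
4,454-pair Monte-Carlo sample with Δ ~ Normal(2, 10). These sizes give
binomial/Monte-Carlo error well inside the asserted tolerances while
keeping the whole suite fast on one CPU.

## Known limitations

- Rule 4's "very close" threshold and the no-rules scenario's unbounded
  lookback are conventions; both are parameters.
- Criterion E collapses a duplicate group to a single representative even
  when one table contains the same value twice at one timestamp.
- The scenario assay bins on the scenario-C gap; instances where a
  scenario pairs nothing are excluded from its signed-rank test and
  reported separately, so bins are not identically sized across scenarios.
- On real MIMIC-III extracts the item-ID maps must match the local
  itemid vocabulary; they are configuration, not constants.
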