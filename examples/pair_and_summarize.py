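"""Align insulin events to their triggering glucose readings.

Runs the full pipeline on a synthetic cohort and prints which alignment
rule fired how often, the per-administration-type pairing rates, and a
check of the alignment against the generator's ground-truth ledger.
"""

import tempfile

from glupair import (SimConfig, build_paired_timeline, curate_glucose,
                     curate_insulin, pair_events, pairing_recovery,
                     read_glucose_tables, read_icustays, read_insulin_table,
                     simulate_cohort)

with tempfile.TemporaryDirectory() as d:
    tables = simulate_cohort(SimConfig(n_stays=40, seed=15), out_dir=d)
    readings = read_glucose_tables(f"{d}/CHARTEVENTS.csv",
                                   f"{d}/LABEVENTS.csv")
    events = read_insulin_table(f"{d}/INPUTEVENTS_MV.csv")
    stays = read_icustays(f"{d}/ICUSTAYS.csv")

events, _ = curate_insulin(events)
readings, _ = curate_glucose(readings, events)
pairs, summary = pair_events(events, readings, stays)

print(f"{summary.n_paired} of {summary.n_events_in_icu} in-ICU insulin "
      f"events paired ({summary.paired_pct:.1f}%); "
      f"{summary.n_events_excluded} events fell outside their ICU stay.")
print("rule frequencies (1 = preceding, 2 = following, 3 = straddle/higher, "
      "4 = bolus+infusion bundle):")
for rule, n in sorted(summary.rule_counts.items()):
    print(f"  rule {rule}: {n}")
print(summary.by_group.to_string(index=False))

recovery = pairing_recovery(pairs, tables.links)
print(f"\nground truth: {100 * recovery['recovered'].mean():.1f}% of the "
      f"{len(recovery)} generator links were re-identified; misses happen "
      "when the trigger was destroyed by an injected artefact or the true "
      "reading-to-dose gap exceeds the 90-min window.")

paired_file = build_paired_timeline(readings, events, stays, pairs)
print(f"paired timeline has {len(paired_file)} rows and "
      f"{len(paired_file.columns)} columns "
      "(the glucose_insulin_pair layout).")
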