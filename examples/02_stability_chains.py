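"""Track place-field consistency across days.

Runs the detection pipeline on a 3-day experiment, builds consistency
chains (a cell keeps its field within +/-30 cm of its first-day
location on every consecutive day), classifies transient vs sustained
cells, counts past vs new place cells per day, and compares the past-PC
total with the memoryless-random expectation.
"""

from placedyn import stability
from placedyn.pipeline import run_pipeline

tables = run_pipeline(
    {
        "generator": {"n_cells": 80, "n_days": 3, "laps_per_session": 36, "seed": 7},
        "analysis": {"n_shuffles": 200},
        "models": {"n_replicates": 5},
    }
)

chains = tables["chains"]
print("chain-length distribution (days a field stayed consistent):")
print(chains["length"].value_counts().sort_index().to_string())
print("\nclassification (counts convention: sustained = >2 days):")
print(chains["class_counts"].value_counts().to_string())

print("\npast vs new place cells per day (past + new = total):")
print(tables["past_new"].to_string(index=False))

per_day, total = stability.expected_random_past_pcs()
print(f"\nmemoryless-random expectation at full study scale "
      f"(2,511 neurons, P(PC)=0.3, 60/180 jitter): {total:.0f} past PCs "
      "over days 2-7 -- the observed study count (2,284) is ~4.7x larger, "
      "the signature of history-dependent reactivation.")
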