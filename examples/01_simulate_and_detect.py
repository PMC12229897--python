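"""Generate a small synthetic session and detect its place fields.

Builds one day of a 60-cell experiment on the 180-cm belt, runs the
dF/F -> transient -> spatial-map -> four-criteria detection chain, and
compares the detected fields with the generator's ground truth.
"""

import numpy as np

from placedyn.pipeline import analyze_session
from placedyn.synth import GeneratorConfig, generate_experiment

cfg = GeneratorConfig(n_cells=60, n_days=1, laps_per_session=36, seed=42)
sessions, truth = generate_experiment(cfg)
session = sessions[0]
print(f"session: {session.n_cells} cells, {session.n_laps} laps, "
      f"{session.n_frames} frames at {session.frame_rate:.0f} Hz")

smap, pf_table, _ = analyze_session(session, n_shuffles=300,
                                    rng=np.random.default_rng(0))
t1 = truth.events
merged = pf_table.merge(t1, on=["cell", "condition"])
err = np.abs(((merged.pf_location_cm - merged.centre_cm + 90) % 180) - 90)

print(f"ground-truth fields: {len(t1)}; detected: {len(pf_table)}; "
      f"matched: {len(merged)}")
print(f"median location error: {err.median():.2f} cm "
      "(the backward COM drift puts the detected peak slightly behind "
      "the induction centre)")
print(pf_table.head(5).to_string(index=False))
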