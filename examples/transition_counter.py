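"""Molecular transition counter: counting nutrient switches in chemistry.

Simulates the eight-component mass-action circuit under alternating
glucose/galactose doses (switches at t = 50, 100, 150) and reads out how
many directed transitions each memory species recorded.
"""

from metachange import (
    build_transition_counter,
    calibrate_increment,
    count_transitions,
    simulate_circuit,
)
from metachange.circuit import alternating_dose_schedule

model = build_transition_counter()
schedule = alternating_dose_schedule(pulse_len=50.0, n_pulses=4)
traj = simulate_circuit(model, schedule)

for column, direction in (
    ("GluToGal_Counter", "GluToGal"),
    ("GalToGlu_Counter", "GalToGlu"),
):
    inc = calibrate_increment(model, direction)
    res = count_transitions(traj["t"].values, traj[column].values, inc)
    print(
        f"{direction}: final level {res.final_level:.2f} a.u., "
        f"single-switch increment {res.increment:.2f} -> count = {res.count}, "
        f"spikes at t = {[round(s) for s in res.spike_times]}"
    )
print(
    "\n-> the circuit's stable memory species retain that the environment"
    "\n   switched Glu->Gal twice and Gal->Glu once — the sufficient"
    "\n   statistics a cell would need for collapsed Bayesian inference."
)
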