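"""Simulate one drinking-task trial and segment it into its phases.

Builds a synthetic IMU recording of the instrumented glass (contact
impulse, sagittal tilt to the mouth, return, table contact), runs the
event chain A–E, and prints the detected instants next to the
generator's ground truth.
"""

from graspkin import TrialConfig, segment_trial, synth_trial

cfg = TrialConfig(seed=7)                 # default: 0.34/1.10/1.11 s phases
trace, truth = synth_trial(cfg)
events, phases = segment_trial(trace)

print("event   detected   truth   (s)")
for name, got, want in [("A", events.t_a, truth.events.t_a),
                        ("B", events.t_b, truth.events.t_b),
                        ("C", events.t_c, truth.events.t_c),
                        ("D", events.t_d, truth.events.t_d),
                        ("E", events.t_e, truth.events.t_e)]:
    print(f"  {name}     {got:7.3f}   {want:7.3f}")
print(f"trial closed by: {events.criterion_end}")
print(f"phases: accommodation {phases.accommodation_pct:.1f}% | "
      f"transport {phases.transport_pct:.1f}% | "
      f"return {phases.return_pct:.1f}%  (total {phases.total_s:.2f} s)")
# A is the grasp contact (first resultant-acceleration peak), B the
# movement onset on the sagittal tilt, C the apex at the mouth, D the
# table contact that ends the return phase.
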