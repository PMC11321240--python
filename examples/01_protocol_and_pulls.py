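"""Build a session schedule and the actuator commands each condition issues.

Prints the randomized condition order, the block structure, and the pull
command generated for a trigger 2.00 s after the cue under each condition.
"""

from emdassist import make_condition_specs, make_pull_command, schedule_session

plan = schedule_session(include_passive=True, seed=4, participant_id="P01")
print(f"session for {plan.participant_id}: {len(plan)} trials")
print("condition order:", " -> ".join(plan.condition_order))
frame = plan.to_frame()
print(frame.groupby(["block_index", "condition", "phase"], sort=False).size().head(9))

print("\npull commands for a trigger at t = 2.00 s after the cue:")
for spec in make_condition_specs():
    cmd = make_pull_command(spec, 2.00)
    if cmd is None:
        print(f"  {spec.name:16s} no pull (control)")
    else:
        print(
            f"  {spec.name:16s} start {cmd.start_time:.3f} s, duration {cmd.duration:.2f} s, "
            f"direction {cmd.direction:+d}, rope speed {cmd.rope_speed:.2f} m/s"
        )

# The delayed conditions start 40 ms later than the rapid ones; assistance
# pulls (direction +1) last 0.31 s, perturbations (-1) 0.1 s, and every pull
# retracts the rope at 40 rad/s x drum radius = 0.79 m/s.
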