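"""From a realistic synthetic recording to per-cycle features and CVs.

Simulates one ten-cycle recording with per-cycle jitter and sensor noise
(the generator's defaults), analyzes it, and prints the per-recording
summary: the mean of each parameter over the seven retained cycles and the
coefficient of variation (CV), the intra-trial variability index used to
quantify motor precision.
"""

from ellipsekin import RecordingSpec, analyze_recording, generate_recording

spec = RecordingSpec(n_cycles=10, jitter_cv=0.035, noise_sd=0.02)
traj = generate_recording(spec, seed=42, subject_id="demo", hand="D", speed="N")
features, summary = analyze_recording(traj)

print(f"recording {traj.label()}: {summary.n_cycles} retained cycles")
print(f"{'parameter':<14}{'mean':>10}{'sd':>10}{'cv':>8}")
for row in summary.table.itertuples(index=False):
    cv = f"{row.cv:.3f}" if row.cv == row.cv else "  -"
    print(f"{row.parameter:<14}{row.mean:>10.3f}{row.sd:>10.4f}{cv:>8}")
print("\nCV of duration < 0.05 marks the strong cycle-to-cycle temporal")
print("consistency typical of spontaneous-pace elliptical drawing.")
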