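"""Simulate one 600 s infant resting-state recording and recover section FC.

Builds the default synthetic scenario (correlated slow hemodynamics, systemic
global signal, cardiac pulsation, three motion events), runs the full
pipeline (QC → OD → filters → GSR → GVTD censoring → MBLL → section FC), and
compares the recovered Fisher z against the ground-truth section series.
"""

import numpy as np

from infantfc import RecordingScenario, RunConfig, load_probe_fixture, run_subject, simulate_recording
from infantfc.pipeline import preprocess_recording

probe, smap = load_probe_fixture()
scenario = RecordingScenario(seed=1)
recording, truth = simulate_recording(probe, smap, scenario)
result = run_subject(recording)

print(f"included: {result.included}; valid data: {result.valid_seconds:.1f} s "
      f"of {scenario.duration_s:.0f} s; channels excluded by QC: "
      f"{len(result.qc.excluded_channels)}")

hb, _ = preprocess_recording(recording, probe, smap, RunConfig(), result.qc)
iu = np.triu_indices(6, 1)
z_true = np.arctanh(np.clip(truth.realized_corr(hb.mask)[iu], -1 + 1e-7, 1 - 1e-7))
fc = result.fc["HbO2"]
z_hat = fc.z[iu]

print(f"mean |z_hat - z_true| over the 15 section pairs: "
      f"{np.mean(np.abs(z_hat - z_true)):.3f}")
print("\nconnection                         class                       z_hat   z_true")
for k, conn in enumerate(fc.connections):
    print(f"{conn.label:34s} {conn.klass:27s} {z_hat[k]:+.3f}  {z_true[k]:+.3f}")
print("\nPositive z = correlated section hemodynamics; the recovered values "
      "track the generating ground truth to within sampling precision.")
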