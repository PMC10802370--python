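"""Score optode–scalp coupling and prune bad channels.

Simulates a recording in which 8 of the 34 channels have zero cardiac
coupling (poor optode contact), scores every channel in 3 s windows with the
scalp coupling index (SCI) and peak spectral power (PSP), and applies the
both-below-threshold pruning rule.
"""

import numpy as np

from infantfc import channel_quality, load_probe_fixture, simulate_recording
from infantfc.simulate import qc_benchmark_scenario

probe, smap = load_probe_fixture()
scenario = qc_benchmark_scenario(seed=0, duration_s=300.0)
recording, truth = simulate_recording(probe, smap, scenario)
report = channel_quality(recording.intensity, recording.fs)

decoupled = {int(c) for c in np.flatnonzero(~truth.coupled) + 1}
print(f"windows per channel: {report.sci.shape[1]}")
print(f"truly decoupled channels: {sorted(decoupled)}")
print(f"excluded by SCI/PSP rule: {sorted(report.excluded_channels)}")
print(f"recording excluded (>40% bad channels): {report.recording_excluded}")
print("\nchannel  mean SCI  mean PSP  fail fraction")
for c in [1, 2, 5, 6]:
    print(f"{c:7d}  {np.nanmean(report.sci[c-1]):8.3f}  "
          f"{np.nanmean(report.psp[c-1]):8.3f}  {report.fail_fraction[c-1]:12.2f}")
print("\nA well-coupled channel records the cardiac pulse at both wavelengths "
      "(SCI near 1, PSP above 0.1); a decoupled channel fails both scores in "
      "most windows and is pruned.")
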