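"""Generate one labeled synthetic EEG session and inspect its structure.

Builds a 23-channel, 256 Hz session with a seizure at minute 20 and prints
the state timeline plus the Welch spectral peak of the preictal segment —
which should sit near the configured 5 Hz preictal center frequency.
"""

import numpy as np
from scipy.signal import welch

from preictal import SynthConfig, generate_session

config = SynthConfig(session_minutes=22, onset_minute=20, preictal_minutes=10, seed=7)
recording, annotation = generate_session(config)

print(f"recording: {recording.n_channels} channels x {recording.n_times} samples "
      f"at {recording.fs:g} Hz ({recording.duration_s / 60:.0f} min)")
for start, end, label in annotation.intervals:
    print(f"  {start:7.1f} - {end:7.1f} s  {label}")

pre_start, pre_end = annotation.intervals_for("preictal")[0]
i0, i1 = int(pre_start * recording.fs), int(pre_end * recording.fs)
focus_channel = recording.n_channels // 3  # where the preictal source is focal
f, pxx = welch(recording.samples[focus_channel, i0:i1], fs=recording.fs, nperseg=1024)
band = (f >= 1) & (f <= 30)
print(f"preictal Welch peak on channel {focus_channel}: "
      f"{f[band][np.argmax(pxx[band])]:.2f} Hz (configured center: "
      f"{config.state_spectra['preictal'].center_hz:g} Hz)")
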