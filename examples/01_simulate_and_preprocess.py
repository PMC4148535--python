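"""Generate a synthetic recording and extract EMG envelopes.

Builds a 20 s, 8-channel surface-EMG recording whose amplitude is driven
by smooth sub-2 Hz finger-movement drives, then runs the standard
envelope chain (rectify, MVC-normalize, 4 Hz zero-phase low-pass,
decimate to 200 Hz) and reports how closely the recovered envelope
matches the generative ground truth.
"""

import numpy as np

from emgkin import SimulationConfig, make_dataset, preprocess_emg

ds = make_dataset(SimulationConfig(duration=20.0, seed=0))
print(f"raw EMG: {ds.emg.samples.shape[0]} channels x {ds.emg.samples.shape[1]} "
      f"samples at {ds.emg.fs:.0f} Hz")

env = preprocess_emg(ds.emg, ds.mvc)
print(f"envelope: {env.values.shape[0]} x {env.values.shape[1]} at {env.fs:.0f} Hz")

core = slice(200, -200)  # skip filter start-up transients
rms = np.sqrt(np.mean((env.values[:, core] - ds.envelope.values[:, core]) ** 2))
print(f"envelope vs ground truth RMS error: {rms:.4f}")
print("values are on the normalized [0, 1] MVC scale; an RMS error of ~0.01 "
      "means the chain recovers the generative envelope to about 1 % of MVC.")
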