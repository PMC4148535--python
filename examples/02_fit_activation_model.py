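"""Fit the EMG-to-muscle-activation dynamics, recovering the EMD.

The synthetic kinematics are driven by activation dynamics with a known
electromechanical delay (EMD) of 45 ms, poles gamma1 = gamma2 = -0.9539
and shaping factor A = -3.  Constrained optimization of the kinematic
reconstruction error should recover those values from the raw data alone.
Takes about half a minute.
"""

from emgkin import (
    SimulationConfig,
    make_dataset,
    normalize_angles,
    optimize_params,
    preprocess_emg,
)
from emgkin.preprocess import preprocess_angles

ds = make_dataset(SimulationConfig(duration=60.0, seed=0))
env = preprocess_emg(ds.emg, ds.mvc)
theta = normalize_angles(preprocess_angles(ds.angles))

params, diag = optimize_params(env, theta, seed=0)
t = ds.config.true_params
print(f"true:      d = {1000 * t.d:.1f} ms, A = {t.A:.2f}, "
      f"gamma = ({t.gamma1:.4f}, {t.gamma2:.4f})")
print(f"recovered: d = {1000 * params.d:.1f} ms, A = {params.A:.2f}, "
      f"gamma = ({params.gamma1:.4f}, {params.gamma2:.4f})")
print(f"cost {diag.cost:.3e} after {diag.n_evaluations} evaluations")
print("d is the EMD in milliseconds (delay between EMG onset and joint "
      "motion); recovery within 5 ms (one sample at 200 Hz) shows the "
      "delay is identifiable from the data.")
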