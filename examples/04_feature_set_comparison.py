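"""Compare input representations: plain envelopes vs delay-aware activations.

Because the synthetic kinematics lag the EMG by a genuine 45 ms
electromechanical delay, inputs that model the delay should reconstruct
the angles with lower error than the raw (no-delay) envelopes, under
identical folds and the same regressor.
"""

from emgkin import (
    SimulationConfig,
    compare_feature_sets,
    emg_to_activation,
    make_dataset,
    normalize_angles,
    preprocess_emg,
)
from emgkin.preprocess import preprocess_angles

ds = make_dataset(SimulationConfig(duration=60.0, seed=2))
env = preprocess_emg(ds.emg, ds.mvc)
theta = normalize_angles(preprocess_angles(ds.angles))
act = emg_to_activation(env, ds.config.true_params)

reports = compare_feature_sets(
    {"envelope": env.values.T, "activation": act.v.T},
    theta.values.T, theta.dof_labels, regressor="ridge", seed=2,
)
for name, rep in reports.items():
    print(f"{name:12s} mean R = {rep.mean_r:.3f}   "
          f"mean NRMSE = {100 * rep.mean_nrmse:.2f} %")
d = 100 * (reports["envelope"].mean_nrmse - reports["activation"].mean_nrmse)
print(f"activation inputs reduce NRMSE by {d:.2f} percentage points — the "
      "gain from modelling the electromechanical delay instead of ignoring it.")
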