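"""Sample efficiency: GP versus neural network as training data shrinks.

Trains both regressors on progressively smaller fixed-interval subsamples
of the training pool and evaluates on a fixed held-out test block.  The
GP's nonparametric posterior typically needs far fewer samples than the
network needs to fit its weights.  Takes a few minutes.
"""

from emgkin import (
    SimulationConfig,
    emg_to_activation,
    learning_curve,
    make_dataset,
    normalize_angles,
    preprocess_emg,
)
from emgkin.preprocess import preprocess_angles

ds = make_dataset(SimulationConfig(duration=60.0, seed=3))
env = preprocess_emg(ds.emg, ds.mvc)
theta = normalize_angles(preprocess_angles(ds.angles))
act = emg_to_activation(env, ds.config.true_params)
X, Y = act.v.T, theta.values.T

rows = learning_curve(X, Y, sizes=[250, 1000, 1800], regressors=("gp",),
                      seed=3, dof_labels=theta.dof_labels,
                      gp_max_n=1800, gp_restarts=2)
rows += learning_curve(X, Y, sizes=[250, 1000, 1800], regressors=("nn",),
                       seed=3, dof_labels=theta.dof_labels,
                       hidden_grid=(25, 100), max_iter=400)
print(f"{'regressor':10s} {'train size':>10s} {'test NRMSE %':>12s}")
for r in rows:
    print(f"{r['regressor']:10s} {r['size']:>10d} {100 * r['mean_nrmse']:>12.2f}")
print("lower is better; compare the GP at 250 samples with the NN at 1800 "
      "to see the sample-efficiency gap.")
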