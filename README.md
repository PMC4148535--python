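# emgkin

Continuous, simultaneous estimation of 15 finger-joint angles from
multi-channel surface EMG, built around an EMG-to-muscle-activation model
that parameterizes the electromechanical delay (EMD).

## The problem

Surface EMG from the forearm reflects the drive to the extrinsic finger
muscles, but the mechanical response of the joints lags the electrical
signal by tens of milliseconds. Proportional myoelectric control — driving
a prosthetic hand or exoskeleton continuously, not by discrete gestures —
needs a regressor from EMG to joint angles that accounts for that lag
without exploding the input dimension with tapped delay lines.

`emgkin` implements a compact alternative: a second-order recursive
activation filter whose four parameters include the EMD itself,

    u_j(t) = α e_j(t − d) − β1 u_j(t−1) − β2 u_j(t−2)
    β1 = γ1 + γ2,   β2 = γ1 γ2,   α − β1 − β2 = 1,   |γ| < 1
    v_j = (e^{A u_j} − 1) / (e^A − 1),   −3 ≤ A ≤ 0

where e_j is the normalized 4 Hz EMG envelope of muscle j, d the EMD and
A the activation nonlinearity. (γ1, γ2, d, A) are fitted by constrained
optimization of the joint-angle reconstruction error. The muscle
activations v feed either a multi-output feedforward neural network or a
bank of 15 exact-inference Gaussian-process regressors (zero mean,
squared-exponential kernel, hyperparameters by marginal-likelihood
maximization), scored per DOF with Pearson's R and the NRMSE of the 0–1
normalized angles under block five-fold cross-validation.

A synthetic-data generator produces raw EMG (amplitude-modulated 20–450 Hz
broadband carrier), joint angles driven by the true activation dynamics,
and optional planar marker trajectories — with full ground truth — so the
entire pipeline, including EMD recovery, is testable without any
recordings. See `docs/methods.md` for the model details and design
choices.

## Worked example

Fit the activation model on a synthetic recording whose ground-truth EMD
is 45 ms (`examples/02_fit_activation_model.py`):

```
true:      d = 45.0 ms, A = -3.00, gamma = (-0.9539, -0.9539)
recovered: d = 45.0 ms, A = -2.96, gamma = (-0.9559, -0.9519)
cost 1.834e-05 after 9676 evaluations
```

The optimizer recovers the delay to the sample and the shaping factor to
a few percent from the raw EMG and angles alone. Comparing input
representations under identical folds and regressor
(`examples/04_feature_set_comparison.py`):

```
envelope     mean R = 0.232   mean NRMSE = 6.68 %
activation   mean R = 0.996   mean NRMSE = 0.65 %
```

— the delay-aware activation inputs cut the reconstruction error by a
factor of ten relative to no-delay envelopes, because the synthetic
kinematics genuinely lag the EMG. The other examples cover envelope
calibration, GP-bank cross-validation, and NN-vs-GP learning curves; each
prints a short interpretation of its numbers.

A thin CLI mirrors the library for shell use:

```bash
emgkin simulate --out sim/ --seed 1 --duration 20
emgkin preprocess --emg sim/emg.csv --out sim/envelope.csv
emgkin optimize --emg sim/envelope.csv --angles sim/angles.csv --out sim/params.yaml
emgkin evaluate --emg sim/envelope.csv --angles sim/angles.csv --method gp --out sim/scores.csv
```

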