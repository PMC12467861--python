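# Methods

This note records the modelling choices behind `gaitintent`: what the
synthetic data emulate, how each stage is parameterized, which design
questions were genuinely open, and what the test suite does and does not
establish about real recordings.

## Synthetic gait model

The generator stands in for human multimodal gait recordings, which are
not redistributable. It reproduces the *statistical structure the
pipeline assumes*, not subject-specific biomechanics.

**sEMG.** Each channel is an amplitude-modulated stochastic process
s(t) = e(t)·c(t) + artifacts, where the carrier c(t) is unit-variance
Gaussian noise band-shaped to 20–250 Hz (the physiological sEMG band)
and the envelope e(t) is a per-mode, per-muscle template: a tonic
activation level plus Gaussian bursts parameterized by (center % of
gait cycle, width %, amplitude in mV). Burst placements for the five
steady gaits are hand-set to caricature rectus femoris / tibialis
anterior / soleus timing (left leg = right leg shifted half a cycle);
tonic levels are fixed draws from U(0.15, 0.55) mV. Artifacts: a 50 Hz
powerline sinusoid (0.05 mV, random phase per trial), a slow random-walk
baseline drift (0.08 mV RMS), and optional AWGN at a target SNR.

**IMU.** Each of 18 axes is a sum of ≤ 4 gait-cadence harmonics with
mode-specific amplitudes and phases, a mode-specific DC term, and white
artifact noise. The DC term models the gravity projection / mean angular
rate of a segment whose orientation differs across terrains (stairs vs
ramp vs level); without it, 100 ms windows sampled at different gait
phases are not separable by any phase-blind classifier, and with it the
simulator meets its design bound (below). Accelerometer amplitudes are
O(2.5 m/s²), gyro O(45 °/s).

**Transitions.** A transition mode A→B is a *partial* linear cross-fade:
within each gait cycle the envelope is (1−u)·A + u·B with u ramping
0.2 → 0.8, plus a small transition-specific tonic boost (preparatory
co-contraction) and posture offset. The partial fade keeps the class
distinct from its endpoints (a full 0 → 1 fade makes edge windows
numerically identical to A or B, and the 13 classes cannot be told
apart even in principle) while leaving RD ↔ RD-LW-style confusability in
place. The per-window oracle used to validate separability — window
means of the noise-free envelopes plus mean/RMS of the noise-free
kinematic templates — supports a nearest-centroid accuracy of ~94%,
against a design bound of 90%.

**Defaults** (all configurable): 6 sEMG channels at 1000 Hz, 3 six-axis
IMUs at 200 Hz, cadence 1 Hz, 2 s steady trials, transition trials of
0.5 s pad + 1 cycle transition + 0.5 s pad, 100 ms windows. A dataset of
10 trials/mode is 130 trials and 2600 windows.

**What the simulator does not model:** electrode shift, inter-subject
variability, muscle crosstalk, fatigue-induced spectral compression over
time, cadence variability within a trial, or biomechanically consistent
joint kinematics. Accuracies near 100% on clean synthetic data therefore
demonstrate pipeline correctness and protocol validity, not expected
field performance.

## Preprocessing

Butterworth designs use bilinear-transform digital prototypes
(`scipy.signal.butter`): bandpass 20–250 Hz of order 4, IMU low-pass
6 Hz of order 4; the notch is a second-order IIR at 50 Hz with Q = 30,
chosen narrow to spare the adjacent sEMG band. All filters are applied
forward–backward (`filtfilt`, odd-reflection padding), so the net phase
is zero; pole stability is asserted at design time. Windows are cut
rectangular and non-overlapping; the Hamming taper named alongside the
windowing is applied **only** in spectral estimation, because tapering
in the time domain would bias MAV/RMS/VAR — both behaviors are available
via the `taper` flag.

## Features

MF is defined as the smallest frequency at which cumulative periodogram
power reaches half the total (ties resolve to the first such bin); the
common printed shorthand "MF = ½Σp" is a power, not a frequency, and is
interpreted as this half-power crossing. The PSD estimator is the
minimal defensible one at 100-sample windows: a single Hamming-tapered,
mean-removed, one-sided periodogram. Silent (all-zero) windows report
MF = MPF = 0 rather than NaN. Feature columns are z-scored before any
kernel method, with statistics fitted on training data only — RBF
kernels are scale-sensitive and the raw columns span four orders of
magnitude.

## Kernel PCA

The kernel matrix must be double-centered (K − 1K − K1 + 1K1) before
eigendecomposition: the feature-space maps are not zero-mean, and
omitting the centering biases every component toward the data mean.
Out-of-sample projection centers the cross-kernel against stored
training statistics. Eigenvalues below −10⁻⁸·λ₁ abort with an error;
small negative ones clamp to zero. Component count defaults to 95%
cumulative contribution; σ defaults to the median pairwise distance of
≤ 500 training rows (the median heuristic) and is *not* tuned by the
optimizer — tuning (C, g, σ) jointly triples the search dimension for
marginal benefit on this feature set. A `kernel="linear"` path exists
only as a cross-check: it must reproduce ordinary PCA scores up to sign,
and does so to < 10⁻⁶ in the tests.

## Sparrow search

Both the baseline (SSA) and improved (ISSA) optimizers maximize fitness
(classification accuracy); benchmark functions enter negated. Roles per
iteration: the top PD = 20% by fitness are explorers (multiplicative
shrink X·exp(−i/(βT)) while the risk draw R < ST = 0.8, additive normal
jump otherwise), the rest followers, and a fresh random 10–20% sample
become scouts (retreat toward the global best if worse than it,
otherwise step away from the worst, gap-normalized with ε = 10⁻¹²).
The improved variant adds:

1. **Chaotic opposition-based initialization** — candidates from the
   sinusoidal-perturbation chaotic map x_{k+1} = mod(x_k + 0.2 −
   (0.5/2π)·sin 2πx_k, 1), mapped affinely into the box, paired with
   their opposites a + b − x; the fitter half of the 2n pool survives.
   The map's near-fixed points {0, 0.5} are excluded as chaos seeds.
2. **Adaptive follower weight** ψ(t) = sin(π/2 (1 − e^{t/T−1})),
   decreasing from ≈ 0.838 to 0: followers move along X + ψ(X − X_p)
   (dispersing from the best explorer early, freezing late).
3. **Hybrid mutation of the incumbent best**, two evaluations per
   iteration: a Gaussian refinement step whose scale follows a
   success rule (×1.5 after an improving step, ×0.7 otherwise, in the
   spirit of Rechenberg's 1/5 rule, floor 10⁻¹⁶), and a Cauchy hop on
   one random coordinate at 0.1× the coordinate range. When the best
   fitness has not improved by more than 10⁻⁸ (relative) for 10
   iterations, the refinement trial is spent on a second hop, and an
   accepted hop restarts the refinement scale at 0.05·σ₀. This design —
   rather than a pre-scheduled annealed σ(t) — is what lets a fixed
   2-evaluation budget deliver both machine-precision convergence on
   unimodal landscapes and basin escape on multimodal ones.

Evaluation accounting is exact: 2n (opposition init) + n per iteration +
2 mutation trials, never exceeding 2n + T(n+2).

**Benchmark registry.** Sphere, Rastrigin and Ackley ship for testing,
with the optimum placed off-center *and off-diagonal* (at fractions
(0.30, −0.21, …) of each half-width, cycled over dimensions). This
follows CEC benchmarking practice and matters here specifically: the
standard SSA explorer rule contracts positions multiplicatively toward
the coordinate origin, and its alarm/follower moves act along the
all-ones direction, so origin-centered or diagonally-shifted optima
reward those structural biases rather than search quality. On the
shifted suite, ISSA dominates the budget-matched SSA baseline on all
three functions (Wilcoxon one-sided p ≤ 0.0007 over 20 paired seeds);
convergence is reported as the squared distance to the known optimum.

## SVM and tuning

The soft-margin dual is solved by libsvm (via scikit-learn) with the
kernel written as exp(−g‖x₁−x₂‖²); a brute-force SLSQP solve of the
same dual serves as an independent oracle in the tests (decision values
agree to 5·10⁻³, dual coefficients within [0, C]). Multiclass is
one-vs-one (78 machines for 13 classes) with deterministic vote
tie-breaking by class order. The tuning fitness is mean stratified
5-fold CV accuracy, made order-invariant by canonical row sorting, on a
stratified subsample of at most 390 windows (≈ 30/class) — the
hyperparameter landscape is estimated cheaply, then the final machine is
refitted on all training windows. Search bounds log₁₀C ∈ [−2, 3],
log₁₀g ∈ [−4, 2]. The pipeline's internal ISSA budget defaults to
population 10 × 15 iterations (≈ 200 fitness evaluations); the
grid-search baselines evaluate the 42 integer-exponent grid points of
the same box.

## Evaluation protocols

The bootstrap splits at **trial** level (stratified by each trial's
primary mode, 80/20, without replacement by default) — window-level
splitting would place temporally adjacent windows of the same trial on
both sides and leak. A `with_replacement` flag provides the literal
draw-with-replacement reading, holding out never-drawn trials.
Standardizer, KPCA, hyperparameter tuning and the final SVM are all
fitted inside each iteration's training portion. Reported: median
accuracy, nonparametric 95% CI (2.5th/97.5th percentiles), pooled
row-normalized 13×13 confusion matrix. SNR robustness trains on clean
signals and injects channel-scaled AWGN into held-out sEMG only.
Streaming prediction conditions the signal with the same zero-phase
filters (forward–backward filtering is acausal; it is applied per
acquisition buffer — here the recording) and then classifies windows
strictly in arrival order; its labels must equal batch prediction
exactly, and per-window inference latency is ~5 ms against the 100 ms
real-time budget.

Problem sizes in the shipped tests and acceptance script — 10 trials per
mode, 10 bootstrap iterations, 3 ablation iterations, 20 optimizer
seeds — are the package's desk-scale defaults; all are configuration
parameters.

## Known limitations

- Simulator realism as listed above; synthetic accuracies saturate near
  100% on clean data by design (separability is a construction goal).
- The KPCA model stores the full training matrix; transform cost is
  O(n_train · n_new · d). No Nyström or incremental variant.
- The ISSA follower rule as adopted freezes followers late in the run;
  exploitation then rests on explorers, scouts and the best-point
  mutation. Alternative readings of the follower update exist but were
  not adopted.
- ε-regularized scout division can still produce large steps when the
  best-worst fitness gap is tiny; box clipping bounds the damage.
- No probability calibration, class weighting, or additional sEMG
  features (zero crossings, slope sign changes, waveform length,
  wavelet energies).
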