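# Methods

## The model

`sixmm` simulates a dimensionality-reduced, one-dimensional six-mass model
(6MM) of vocal-fold (VF) oscillation.  Each fold is a mesh of 3
longitudinal sections (posterior P, medial M, anterior A) x 2 vertical
levels (lower, upper) of point masses; because the dominant VF motion is
medio-lateral, every mass has a single lateral degree of freedom.  State
tensors are laid out `(side 2, section 3, vertical 2)` with the left fold
at negative lateral positions and the right fold positive.

Five force families act laterally on every mass `m` at position `x`:

- **Anchor** `F_a = -k_a (x - x_r)(1 + eta (x - x_r)^2) - r_a x_dot`: a
  damped spring to the rest position `x_r` with a cubic stiffening term
  (`eta = 100 cm^-2`), the classical nonlinear extension of the two-mass
  model (2MM) spring.
- **Vertical coupling** between the lower and upper mass of a pair and
  **longitudinal coupling** along the chain
  `fixed_P - P - M - A - fixed_A`: springs that span a fixed transverse
  distance `ell` (2 mm vertical, 5 mm longitudinal), whose entire
  elongation force `k (sqrt(dx^2 + ell^2) - ell)` is applied laterally,
  restoring the relative lateral deflection `dx`.  The restoring
  direction is the sign of `dx`, smoothed as `2 sigmoid(dx/eps) - 1`
  (i.e. `tanh(dx/2 eps)`); the magnitude vanishes quadratically at
  `dx = 0`, so the force is continuous for any `eps`.  Longitudinal
  stiffness is `xi_l = 0.2` times the summed adjacent anchor
  stiffnesses; the fixed chain ends sit at +-0.05 mm (posterior) and
  0 mm (anterior) laterally and are assigned their neighbouring mass's
  anchor stiffness.
- **Collision**: when a left/right pair overlaps (`x_left > x_right` at
  the same section and level), a zero-free-length spring of stiffness
  `k_c = 3 xi_c k_a` (the undivided fold-level anchor stiffness times the
  proportionality `xi_c = 1`) pushes the sides apart symmetrically with
  penetration depth `max(0, x_left - x_right)/2` per side.
- **Bernoulli driving force**: subglottal pressure `P_S` loads the lower
  plate of every open glottal column over its area (column width
  `vf_length/3` x plate thickness `ell_v`), with pressure
  `P1 = P_S [1 - theta(g_min)(g_min/g_low)^2] theta(g_low)` where
  `g_low`, `g_up` are the gap widths at the two levels and `g_min` their
  minimum.  The jet separates at the minimal section: a divergent column
  (minimum at the entry) carries no pressure, a column closed above
  feels the full `P_S`, and nothing ever acts above the minimal section.
  This is the canonical Steinecke-Herzel form applied per column.

Lateral motion integrates `m x_ddot = F_a + F_v + F_c + F_d + F_l` with
classical fourth-order Runge-Kutta at `dt = 0.25 ms` in double precision;
1000 steps give a 250 ms record.  Lower masses start deflected 1 mm
outward from rest, upper masses at rest, velocities zero.

A model instance is defined by 14 positive scaling factors `q`: six
reciprocal mass factors (per vertical pair; a factor 2 halves the pair's
mass), six anchor stiffness factors, one subglottal pressure factor and
one collision proportionality factor.  `q = 1` reproduces the defaults
(bottom mass 0.125/3 g, top 0.025/3 g; bottom anchor 80/3 N/m, top
8/3 N/m; `P_S` = 800 Pa).

**Trajectories** are what a high-speed camera would see from above: per
side and section, the signed lateral position (mm) of whichever pair
member is closer to the glottal midline (ties go to the lower mass, whose
edge controls the flow).  Rows are ordered (left, right) x (P, M, A).

### Parameter-value readings

Two printed constants were adopted in their classical-2MM form rather
than at face value, because the face-value readings leave the model
unable to phonate at all:

- `r_a = 0.02/3 Ns/m` (anchor damping; damping ratio ~0.1 for the lower
  masses, the standard 2MM value).  A hundredfold smaller damping gives a
  decay time of 1.25 s, under which *every* sampled configuration passes
  the oscillation filter and the documented 23-30% exclusion rate cannot
  occur.
- `k_v = 10 N/m` (vertical coupling).  At 0.1 N/m the upper masses are
  dynamically decoupled, the glottis cannot alternate between convergent
  and divergent shapes, and the pressure force can do no net work per
  cycle — self-sustained oscillation is then impossible for the default
  configuration.

The sign-smoothing length defaults to `eps = 0.1 mm`: small against
typical deflections, so essentially the entire coupling force acts
laterally.  Measured on the default configuration, phonation onset
requires `eps <= 0.25 mm`; at `eps = 1 mm` the smoothing weakens the
vertical coupling below the oscillation threshold.  `eps` is exposed in
`PhysicalConfig` for sensitivity studies.

`k_v` appears once elsewhere with a length unit ("1 mm"), an apparent
typo; only the stiffness reading is used.

## Synthetic data generation

Scaling vectors are sampled i.i.d. log-uniformly on `[1/5, 5]`
(density `1/(q log 25)`): the median is 1 (the default model), the mean
`(q_max - q_min)/log(q_max/q_min) ~ 1.49`, and scaling up by less than
any factor is exactly as likely as scaling down by less than its
reciprocal.

Rest positions follow shifted-gamma marginals `Gamma(alpha, beta) + c`
per longitudinal section, fitted to time-averaged experimental
trajectories (alpha = 5.59 / 23.8 / 1450, beta = 7.96e-3 / 1.70e-3 /
2.05e-4, c = -1.66e-4 / -1.11e-2 / -2.76e-1 for P/M/A).  These fit
parameters are stated in cm and converted to mm at the interface: the
resulting means (0.44 / 0.29 / 0.21 mm) match the ~0.5 mm scale of
observed fold-edge deflections, whereas an mm reading would make rest
gaps ten times smaller than the reported oscillation amplitudes.
Skewness decreases P -> A as the shape parameter grows.  The anterior
law's negative shift places ~0.3% of its mass across the midline; such
draws are kept (the marginals stay exact) and read as pre-phonatory
contact, which the collision force resolves.

The six marginals are joined by a normal copula whose correlation matrix
is blended toward independence, `rho_tilde = d I + (1 - d) rho`, with
`d = 0.5`.  The published matrix exists only as a figure, so the shipped
default is synthetic: it reproduces the printed anchors (medial to
same-side neighbours 0.31-0.63; opposite-side anticorrelation -0.8
posterior to -0.2 anterior; the left-anterior anomaly: +0.46 to the
opposite posterior, -0.39 to its own posterior) and fills the remaining
entries with moderate values keeping the matrix positive definite.
`estimate_rho` recomputes the matrix from any user-supplied trajectory
means.

Each sample is simulated for 250 ms and kept only if it oscillates: the
per-row standard deviation over the post-75 ms window, expressed in the
model's cm working unit, averaged over the six rows, must reach `1e-3`
(i.e. 0.01 mm).  Filtered datasets store trajectories single precision;
labels and rest positions double.  Generation is fully reproducible from
one seed.

Under these defaults about 88-89% of samples survive the filter, above
the reported 70-77%.  The two faithful readings of the
coupling-direction smoothing bracket that band (~0.61 at `eps = 1 mm`,
~0.89 at `eps = 0.1 mm`), but only the sharp reading phonates at the
default configuration, which the model must do; the residual gap
presumably traces to details of the original driving-force formulation
that the available description does not pin down.

## The inverse surrogate

Preprocessing drops the 75 ms transient, cuts a 512-step (128 ms)
window — uniformly random per sample and re-rolled every training epoch,
the first eligible window in evaluation — adds Gaussian noise with
per-trajectory standard deviation equal to 10% of that trajectory's own
std (training only), and zero-truncates so left rows stay <= 0 and right
rows >= 0.  The per-window trajectory means are computed before the
noise and fed to the network as side information.

The network is a convolutional-recurrent regressor.  One shared sub-CNN
per trajectory row (conv kernel 3 stride 3, 10 channels; max-pool 2;
conv kernel 3 stride 2, 5 channels; max-pool 2) compresses 512 steps to
a 21 x (5*6) sequence.  A two-layer bidirectional GRU (hidden 256)
iterates the sequence; its initial hidden state for all layers and
directions is the trajectory means through one FC + ReLU.  An attention
branch applies a per-step FC to width 16 over the 21 compressed steps
(giving 16 x 21; a "16 x 30" variant exists in the source description
but is inconsistent with its own convolution arithmetic), flattens, and
maps to width 16; the top layer's final hidden state maps to width 16;
both merge through FC(32) + ReLU + FC(14).  The output head is
element-wise exponential — a log-space regression head that guarantees
positive predictions.  A literal softmax head (which would constrain the
14 outputs to sum to one) and a softplus head are selectable for
comparison.  Sub-CNN weight sharing across rows is the default and can
be disabled.

Training minimizes RMSLE, `sqrt(mean (log q - log q_hat)^2)` — the
natural scale-invariant loss for positive multiplicative targets — with
Adam, initial learning rate 5e-3 decaying by 0.9 per epoch, batch size
512, a seeded 90/10 train/validation split, and early stopping after 5
epochs without validation improvement.  A constant identity prediction
scores RMSLE `2 log 5 / sqrt(12) ~ 0.93` under the sampling law, the
floor any learning must beat.

The network and its gradients are implemented on a small reverse-mode
autodiff engine over numpy (`sixmm.autodiff`), verified op-by-op against
central finite differences.  The network path runs single precision; the
ODE path stays double.

## Evaluation

`evaluate_surrogate` judges predictions twice.  In parameter space:
per-parameter MAE and MAPE, with subglottal pressure also in Pa
(x 800 Pa; e.g. a unitless MAE of 0.185 is 148 Pa).  In observable
space: the predicted parameters are re-simulated — with rest positions
taken from the time averages of the *observed* trajectories, the same
identity that makes the procedure applicable to recordings whose true
rest positions are unknown — and fundamental frequency and amplitude of
re-simulated vs observed trajectories are compared.  `f0` is the argmax
over f > 50 Hz of the reciprocally weighted spectrum `|X(f)|/f`
(overtone suppression; `1/f^2` optional), resolution `fs/n`; constant
signals have no defined `f0`.  Amplitude is the maximum of the
positively oriented trajectory.  Gross `f0` mispredictions are kept in
the means (a median absolute error is reported alongside).  Re-simulation
blow-ups are excluded from observable averages and counted.

The floor for any constant guess is the closed-form expected absolute
error `[b + a + u log(u^2/ab) - 2u]/log(b/a)`, minimized at the median
`sqrt(ab)`; at the default bounds the optimum is ~0.994, identical for
all 14 i.i.d. components.  When several training runs are compared, runs
whose validation loss exceeds the best by more than 10% are excluded as
subperformant.

## Problem sizes in the test suite

The test suite runs desk-scale versions of every claim: the survival
fraction is estimated from 2 000 samples (the acceptance script uses
10 000), and the parameter-recovery check trains on 3 000 generated
samples with GRU hidden size 64, batch size 128 and at most 40 epochs —
batch 128 keeps the updates-per-epoch of the scaled dataset comparable
to the full-scale setting, where batch 512 meets tens of thousands of
samples.  At this reduced scale the surrogate reaches a validation MAE
for the pressure scaling of ~0.46 (bound 0.994), pressure is the
best-learned of the 14 parameters, and the collision proportionality
stays near the guessing bound — the qualitative learnability ordering of
the full-scale study.  Full-scale training (>= 10 000 samples, hidden
256, five-fold) is supported by the same functions but takes hours on a
CPU and is not part of the default suite.

## What the synthetic data do and do not show

The generator emulates the statistical structure of segmented high-speed
video trajectories: gamma-skewed rest geometry with realistic
inter-position dependence, 250 ms records at 4 kHz, amplitude-
proportional noise.  It does not emulate camera calibration error,
non-orthogonal viewing angles, segmentation dropouts, non-steady
phonation, or vocal-tract acoustic loading (absent from the model
itself).  Passing tests therefore demonstrate that the inverse pipeline
recovers parameters of the model that generated the data — the
model-reality gap of real recordings is outside what this package can
certify.

## Numerical choices and degenerate inputs

- SI units internally (m, kg, s, Pa); mm/g/ms at every interface.
- RK4 with fixed `dt`; instability (non-finite state) is flagged with
  its first bad step; in batch generation such samples count as
  excluded, in single simulation they raise.
- The undamped, undriven, collision-free system conserves the sum of
  kinetic and integrated elastic potentials exactly in the continuum
  limit; at `dt = 0.25 ms` the stiffest mode has `omega dt ~ 0.3` and
  RK4's dissipative truncation error dominates the energy budget
  (~3e-3 relative over 50 ms, fourth-order in `dt`).
- Trajectory tie-break: equal |x| in a pair selects the lower mass.
- The oscillation filter treats its threshold inclusively
  (`std == threshold` passes) and aggregates row stds by mean
  (min available).
- Gamma fitting uses scipy's maximum likelihood with the shift as the
  location parameter and rejects fits failing a 1% KS check on the
  fitting data; constant inputs are rejected.
- The copula sampler requires the blended correlation to be positive
  definite and reports failure otherwise.
- `compressed_length` and the instantiated network agree by
  construction; both reject inputs too short for the conv stack.

## Known limitations

- The oscillation-filter survival fraction (~0.89) exceeds the reported
  0.70-0.77 band; see the calibration discussion above.
- Synthetic fundamental frequencies concentrate around 60-110 Hz,
  at the low end of porcine phonation; amplitudes around 0.4-1.5 mm.
- The statistical-guess bound assumes the log-uniform sampling law;
  it is not a bound for differently distributed real parameters.
- Experimental-recording evaluation (pressure sensor ground truth) is
  supported through the trajectory-CSV interface but no recordings ship
  with the package.
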