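# Methods

This note records the models, conventions and design choices behind
`orientinv`, in the order data flows through the package.

## Conventions

* **Earth frame** `E`: North-East-Down. `z_E` points toward the Earth's
  centre; `x_E` along the horizontal component of the magnetic field
  (magnetic North); `y_E` East.
* **Acquired acceleration** of a unit at rest points Earth-down (the
  gravity-reaction convention common to commercial IMUs).  The simulator
  emits data under the same convention, so the filter and the data cannot
  disagree silently.
* **Quaternions** are scalar-first Hamilton quaternions; `R = rotmat(q)`
  maps sensor-frame vectors to the Earth frame.  All conversions force the
  scalar component to be non-negative, removing the double-cover ambiguity
  from any quaternion time series.  The rotation-matrix-to-quaternion
  conversion uses `q1 = sqrt(1 + trace)/2` with the vector part
  `(d32-d23, d13-d31, d21-d12)/(4 q1)`; when the trace approaches -1
  (rotation near 180 degrees, never the case for between-sample
  differential rotations) the standard largest-diagonal branch takes over.
* **Euler triples** `(theta, phi, psi)` compose as
  `Rx(theta) @ Ry(phi) @ Rz(psi)`; random re-orientations draw each angle
  independently and uniformly from `[-pi, pi)`.

## Orientation filter

Per sample, two orientation estimates are fused:

1. **Short-term**: the first-order quaternion kinematic update
   `q <- normalize(q + (dt/2) q (x) (0, omega))`.  The filter feeds it the
   trapezoidal average of the two gyro samples bracketing the step, which
   removes most of the phase lag of the rectangle rule on oscillatory
   motion while keeping the update itself first-order.
2. **Long-term**: a damped Gauss–Newton descent on the 4-component residual
   `[R(q) a_hat - (0,0,1); (R(q) m_hat)_y]` — the measured acceleration
   should map to Earth-down and the rotated magnetic field should have no
   East component.  Using only the East component of the field means the
   magnetic dip never enters the cost, so a wrong dip assumption cannot
   tilt the estimate.  The Jacobian is computed by forward differences on
   the four quaternion components (the residual normalizes internally, so
   the radial direction is null and a 1e-9 Tikhonov term keeps the normal
   equations well posed).  Step halving on cost increase makes the cost
   non-increasing; iteration stops at `gn_step_tol = 1e-8` or after
   `gn_max_iter = 10` rounds.

The fused estimate is the normalized, sign-aligned weighted average
`normalize(mu q_gyro + (1-mu) q_gn)` with `mu = 0.95` by default.  Two
further details matter in practice:

* **Initialization** is algebraic (TRIAD: down = normalized acceleration,
  east = down x field, north = east x down), so a static reference-aligned
  stream produces the identity orientation from the first sample.  A 1-s
  prefix with zero angular rate and the first sample's acc/mag held
  constant is prepended and its outputs dropped, letting the filter settle
  before the data of interest.
* **Dynamic-motion weighting**: the accelerometer rows of the residual are
  scaled by `exp(-((|a| - g)/(0.15 g))^2)`.  When the specific-force
  magnitude deviates from gravity the direction of the measured vector no
  longer indicates down, and trusting it tilts the estimate; the weight is
  exactly 1 at rest.  Setting `acc_weight_scale = 0` disables it.

With these defaults the filter recovers noiseless simulated trajectories of
the default activity set with a mean per-sample error of about 1 degree
after the first second (high-acceleration classes are the hardest; purely
rotational motion is recovered to a few hundredths of a degree).  All
constants live in `FilterConfig`.

`mu -> 1` reduces the filter to pure gyro integration from the TRIAD start;
`mu -> 0` tracks the per-sample Gauss–Newton solution.  Both limits are
asserted in the tests, as is equivariance: re-wearing the unit with a
constant rotation `P` (data pre-multiplied by `P^{-1}`) changes the
estimates to `R P` within filter tolerance — the property the differential
rotations rely on.

## Transforms

Per unit and 5-s segment (all channels length N = 125 at 25 Hz):

| technique | channels/unit | invariance |
|-----------|---------------|------------|
| reference | 9  | none (fixed-orientation baseline) |
| random    | 9  | none (reference after random re-orientation) |
| norm      | 3  | exact |
| gravity   | 6  | exact |
| svd       | 9  | exact after sign fixing |
| earth     | 9  | up to orientation-estimation error |
| proposed  | 13 | up to orientation-estimation error |

Choices the underlying ideas leave open:

* **gravity**: the along-gravity channel is the *signed* projection onto
  the normalized time-mean of the acceleration (a projection, not a
  magnitude); the perpendicular channel is a norm.  Segments whose mean
  acceleration is (near) zero have no defined gravity direction and are
  rejected (`DegenerateSegmentError`) rather than silently zeroed.
* **svd**: the principal axes come from the unit's *joint* 3 x 3N data
  matrix (all three sensor types concatenated sample-wise), keeping the
  three streams in one common frame.  Singular-vector signs are fixed by
  making the largest-magnitude projection of the data onto each axis
  positive, ties broken toward the earlier sample — determinism is what
  turns the mathematical invariance into a numerical one (verified to
  ~1e-14).
* **differential rotations**: `D_n = R_{n+1} R_n^T` (the between-sample
  rotation `C_n = R_n^T R_{n+1}` conjugated into the Earth frame).  The
  N-1 element sequence is padded by repeating the final value so every
  channel has length N.  `q_diff` scalar components are forced >= 0; for
  real between-sample rotations `q_diff` stays near `(1, 0, 0, 0)`.

## Features, normalization, PCA

26 features per channel, fixed order: min, max, mean, population variance,
skewness, kurtosis (non-excess, i.e. 3 for a Gaussian), biased
autocorrelation at lags 5, 10, ..., 50 normalized by the lag-0 value
(defined as 0 for constant channels — no NaN ever leaves the extractor),
and the five largest peaks of the one-sided DFT magnitude spectrum
(DC excluded) with their frequencies in Hz.  Peaks are local maxima
selected greedily by magnitude with a minimum pairwise separation of 11
bins; missing peaks are reported as (0, 0), and magnitudes below
`1e-12 * sum|x|` are treated as round-off, not peaks.  Frequencies are
reported in Hz (`bin * rate / N`) rather than bin indices.

Feature vectors are min–max scaled to [0, 1] per subject over all of that
subject's vectors (the test subject's own range is used, which matches a
per-subject calibration step and is the default; train-derived scaling is
a one-line change).  PCA keeps the top F = 30 eigenvectors of the feature
covariance (eigen-decomposition, not data SVD).  It is fit on the training
folds only and applied to the held-out subject — the leakage-safe variant;
fitting globally instead is a `rotate`/`n_components`-style switch away in
the library but not the default.

## Classifiers

Fixed hyperparameters: SVM (RBF kernel, one-vs-one, C = 5, gamma = 0.1;
the two-level grid-search utility that produced these values is exposed as
`svm_coarse_grid`/`svm_fine_grid`), k-NN (k = 7, Euclidean), random forest
(100 trees), OMP (residual tolerance 1e-3).  The ANN is a three-layer
sigmoid network: hidden width = nearest integer to the mean of `log2(2K)`
and `2K - 1` (21 for K = 19 classes), weights initialized uniformly in
[0, 0.2], on-line back-propagation with learning rate 0.3, stopping when
the epoch-error reduction relative to the mean of the previous 10 epochs
falls below 0.01 (safety cap: 1000 epochs).  BDM fits one Gaussian per
class (ML mean and sample covariance, equal priors); LDC shares the
*unweighted average* of the per-class covariances, which makes its
decision boundaries hyperplanes and makes it coincide with BDM when all
classes genuinely share one covariance.  Singular covariances are
ridge-regularized with a logged epsilon.

The sparse-representation classifier stores the training vectors as a
unit-norm column dictionary and codes each (unit-normalized) test vector by
orthogonal matching pursuit until the residual norm is <= 1e-3.  Class
residuals then use the class's members of the *selected support*
(least-squares refit; classes absent from the support score the full test
norm).  The alternative `class_dict` mode computes the least-squares
residual over each class's complete dictionary — note this is only
informative when class dictionaries are undercomplete (feature dimension
exceeds the per-class training count); with overcomplete class
dictionaries every class can represent the test vector exactly and the
mode degenerates, which is why `support` is the default.

The random forest uses scikit-learn's entropy criterion (information gain)
with sqrt(D) feature subsampling; a gain-*ratio* splitting rule is not
available there and the difference is immaterial for the equal-count,
all-continuous feature matrices this pipeline produces.

## Evaluation protocol

Leave-one-subject-out: one fold per subject, the fold's test set being
exactly that subject's vectors.  Overall accuracy pools correct counts over
all folds; the per-fold spread is reported as the population standard
deviation of fold accuracies.  Group accuracies (stationary = the four
posture classes, non-stationary = the rest) are unweighted means of the
per-class accuracies inside each group, so a rare class counts as much as
a common one.  Confusion matrices are counts with rows = true class.

## Synthetic data

Each activity class is a `MotionSpec`: a fixed body posture plus
sinusoidal body-frame angular velocity and sinusoidal Earth-frame linear
acceleration.  This deliberately tests the signal-processing claims, not
human biomechanics: the point is that the streams are *exactly consistent*
with a known orientation trajectory, so invariance and recovery can be
checked against ground truth.

* Orientation integrates the specified angular rate with six sub-steps of
  the exact quaternion exponential per 25-Hz sample; the emitted gyro
  signal is the angular rate at the sample instants, the accelerometer
  reads `R^T (g_E + a_E)` and the magnetometer `R^T m_E` with a 55-degree
  dip.  Gravity is 9.81 m/s^2.
* The default set has 19 classes: four stationary postures (sitting,
  standing, two lying poses — distinguishable only through orientation
  information, which is exactly what the invariant transforms discard) and
  15 motion classes with distinct frequency/amplitude/posture signatures.
  Three motion pairs differ *only* by swapping the x and y components of
  both signatures: their per-sample vector norms are identical, so
  norm-based pre-processing cannot separate them while Earth-frame
  representations can — this builds the qualitative advantage of the
  Earth-frame methods into the benchmark in a controlled way.
* Five units carry fixed placement postures (torso, wrists, knees
  stand-ins).  Inter-subject variability: per-subject/class amplitude
  (sigma 8%) and frequency (sigma 4%) scalings; every segment draws fresh
  phases and a ~2-degree posture wobble.  Sensor noise defaults: 0.05
  m/s^2 (acc), 0.005 rad/s (gyro), 1% relative (mag).
* Angular-rate amplitudes stay below ~1.5 rad/s and oscillation
  frequencies below ~7 Hz, comfortably inside the 12.5-Hz Nyquist limit
  (violations raise).

What the simulator does **not** emulate: realistic gait or limb kinematics,
magnetic disturbances, gyro bias and scale errors, inter-unit timing skew.
Passing tests therefore demonstrate the correctness and the *relative*
behaviour of the transforms under controlled orientation nuisance, not the
absolute accuracies achievable on real recordings — those are the business
of the `replicate` CLI command run against real data.

## Benchmark scale

The shipped benchmark uses 8 subjects x 19 classes x 1 minute per pair
(12 five-second segments, 1824 feature vectors, five units) and five seeds,
with the SVM classifier — enough for stable technique orderings while one
run stays around a minute and a half on a single CPU.  The full-scale
shape (5 minutes per pair, 9120 segments, 1140 test vectors per fold) is
available by passing `minutes=5`.

## Known limitations

* The filter's Gauss–Newton stage assumes exactly one dominant local
  minimum near the prediction; heading flips (field horizontal component
  pointing South) are outside its basin but unreachable when tracking from
  a gyro prediction at realistic rates.
* Units whose acceleration and magnetic measurements are (anti)parallel
  have an unobservable heading; the filter freezes such samples at the
  prediction and warns.
* Accuracies on synthetic benchmarks are optimistic in absolute terms
  (clean class structure, stationary noise); orderings, invariances and
  error bounds are the quantities the package stands behind.
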