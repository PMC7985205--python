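# Methods

## Overview

`tissueoptics` estimates the optical properties of a homogeneous tissue
slab — refractive index $n$, reduced scattering coefficient
$\mu_s' = (1-g)\,\mu_s$, and absorption coefficient $\mu_a$ — by inverting
a time-resolved Monte Carlo simulation of photon transport. The forward
model produces the slab's spatio-temporal impulse response in reflection;
each response is compressed into 21 statistical moments; a small fully
connected network learns the map from moments back to
$(n, \mu_s', \mu_a)$ from a large set of simulated slabs with known
properties.

## Forward model: weighted-photon random walk

Photons are launched at $t=0$ at the origin of the illuminated face
($z=0$), travelling along $+z$ into a slab of thickness $L$ (default
10 mm) that is unbounded transversely. Units are mm, ps and mm⁻¹
throughout; time advances by $d\,n/c$ per geometric path $d$ (phase
velocity; dispersion ignored).

* **Free paths.** Step lengths are drawn from the exponential scattering
  density $\rho(d) = \mu_s e^{-\mu_s d}$ by inverse CDF,
  $d = -\ln(u)/\mu_s$. Steps are sampled with $\mu_s$ alone — not the
  $\mu_t = \mu_s + \mu_a$ convention of classic MCML — and absorption is
  instead applied continuously (next point). Both schemes are unbiased
  estimators of the same transport physics.
* **Absorption.** The photon's statistical weight decays by the
  Beer–Lambert factor $e^{-\mu_a \ell}$ over every traversed segment
  $\ell$, including partial segments cut short by a boundary. The kernel
  tracks $\log w$ additively, so the hot loop performs no exponentials;
  the absorbed-weight tally follows exactly from the per-photon budget
  (launched + roulette boosts = exited + lost + absorbed), which is an
  identity here because continuous absorption is the only deposition
  channel.
* **Scattering.** Deflection cosines follow the Henyey–Greenstein phase
  function with anisotropy $g = \langle\cos\theta\rangle$, sampled by its
  closed-form inverse CDF ($2u-1$ when $g=0$). Azimuths are uniform on
  $[0, 2\pi)$; inside the compiled kernel they are realized by rejection
  sampling a point in the unit disc (no trig calls, same distribution).
  The local-frame rotation is the standard one; directions within
  $10^{-6}$ of the polar axis use the axial special case. The kernel does
  not renormalize directions per step — the update preserves unit norm
  analytically and float drift stays below ~$10^{-13}$ over $10^5$ steps.
* **Boundaries.** A step that reaches a face is truncated at the face;
  the unpolarized Fresnel reflectance $R = \tfrac12 (R_s + R_p)$ (with
  Snell refraction, $R=1$ beyond the critical angle) decides
  stochastically between internal reflection and transmission. After an
  internal reflection the remaining step is re-sampled, which the
  memoryless exponential renders statistically identical to carrying the
  residual optical depth. Transmitted photons leave with the
  Snell-refracted direction and are logged (side, $x$, $y$, direction,
  weight, arrival time); exit through $z=0$ is "reflection", through
  $z=L$ "transmission".
* **Specular deduction.** The normal-incidence entry reflection
  $R_{sp} = ((n_{amb}-n)/(n_{amb}+n))^2$ is deducted deterministically:
  every photon launches with weight $1 - R_{sp}$ and the aggregate
  specular weight is logged once at $r=0$, $t=0$ with direction
  $(0,0,-1)$. Ambient index defaults to air (1.0) on both faces.
* **Roulette.** When a photon's weight falls below $10^{-6}$ it survives
  with probability $1/m$ (default $m=10$) and is boosted to $m w$,
  otherwise it dies; the expectation of the returned weight is unchanged.
  A per-photon event cap (default $10^6$) guarantees termination; capped
  weight is tallied as lost and a warning fires when total lost weight
  exceeds $10^{-3}$ of the launch.

**Randomness and determinism.** Every photon owns a counter-based
splitmix64 substream keyed on (run seed, photon index). Results are
therefore bit-identical across repeated runs, independent of batching, and
single-photon traces reproduce exactly what the same photon does inside a
batched run. The per-run seeds of a dataset derive from the master seed
through `numpy.random.SeedSequence`, so any record can be regenerated in
isolation.

## Moment featurization

Rotational symmetry reduces the exit distribution to $I(r, t)$. A
detector side is summarized by the total weight $W=\sum_i w_i$, the
weighted means $\langle r\rangle, \langle t\rangle$, and the weighted
central cross-moments

$$\langle r^\alpha t^\beta\rangle = \frac{\sum_i w_i\,(r_i - \langle
r\rangle)^\alpha (t_i - \langle t\rangle)^\beta}{W}$$

for all $2 \le \alpha+\beta \le 5$, giving $(5+1)(5+2)/2 = 21$ numbers.
The canonical ordering is ascending total order, descending $\alpha$
within an order. Two conventions deserve note:

* The central-moment formula applies to every slot of total order ≥ 2,
  including the mixed and pure second-order moments $(2,0)$, $(1,1)$,
  $(0,2)$ — the stricter reading "$\alpha>1$ and $\beta>1$" cannot
  produce a 21-element basis and is not used.
* The specular record is included by default (it carries most of the
  direct Fresnel information about $n$); `include_specular=False`
  restricts the moments to the diffuse cloud.

Summation runs in a fixed (time, $r$) sort order, so the features are
bitwise independent of input ordering. An empty detector yields a vector
flagged invalid, never silent zeros.

## Training-set construction

Each record draws four independent uniform deviates: $n$ and $g$ map
linearly onto $[1.3, 1.6]$ and $[0.5, 0.95]$; $\mu_s$ and $\mu_a$ map
log-uniformly onto $[0.1, 100]$ and $[0.01, 10]$ mm⁻¹ (they span decades;
linear sampling would starve the low end). These ranges cover reported
values for human tissue. $g$ and $\mu_s$ enter training only through
$\mu_s' = (1-g)\mu_s$, since diffusive transport depends on them almost
exclusively through that combination; the network deliberately predicts
$\mu_s'$ rather than the pair.

Records whose reflection detector caught zero weight are dropped and
counted. With the specular record included this cannot happen over the
default ranges (index-mismatched slabs always reflect specularly); it
protects matched-index configurations.

## Inverse model

Architecture [21, $x$, $x$, $x$, 3] with ReLU hidden layers and linear
output; default $x = 150$. Targets are $n$, $\log_{10}\mu_s'$,
$\log_{10}\mu_a$, each min-max normalized to $[0,1]$ over the training
split. The input moments span many decades and change sign, so they are
compressed by the sign-preserving transform
$\mathrm{sgn}(x)\log_{10}(1+|x|)$ before per-feature min-max scaling over
the training split; raw min-max scaling alone (available via
`signed_log_features=False`) squashes most samples against the low end of
each feature's range and measurably degrades $\mu_s'$ and $\mu_a$
recovery. Training
minimizes MSE with Adam (learning rate $10^{-3}$, batch 256), runs the
full epoch budget with no early stopping, and is reproducible given the
seed. Activation, optimizer, learning rate and batch size are the minimal
standard regression choices; accuracy is insensitive to the hidden width
over a broad band (tested 50–300), which is evidence the problem is being
generalized rather than memorized. An L-BFGS option exists for driving
tiny datasets to memorization in tests.

Numerical conventions worth pinning:

* Prediction evaluates the stored network row by row, so batched and
  record-by-record predictions are bitwise identical, and a model saved
  to its JSON document (architecture, weights, scalers, loss history)
  reproduces predictions exactly after loading.
* A constant target column is widened by a narrow ±0.01 band during
  scaler fitting (maps to 0.5) so a degenerate fit still recovers the
  constant closely; constant feature columns use a wider ±0.5 band so
  unseen inputs cannot explode after scaling. Directly constructing a
  scaler with min ≥ max is an error.
* Outputs are not clipped to the training range; $\mu_s'$ and $\mu_a$ are
  strictly positive by construction ($10^{(\cdot)}$), $n$ is reported
  as-is.

## Error metrics

Per record and parameter, the percent standard error
$E = 100\,|X_{truth} - X_{pred}|/X_{truth}$, always on the linear scale
even though training used log targets. The headline per-parameter figure
is the 95% confidence level: the error value below which 95% of the test
records fall, computed as the 95th percentile with linear interpolation
between order statistics (the convention is pinned because nearest-rank
differs at small $n$). Reports also carry median and mean errors and
per-record tables keyed by truth for prediction-versus-truth and
error-versus-truth plots.

Accuracy is intrinsically non-uniform over the parameter space: at low
$\mu_s'$ or low $\mu_a$ the reflected response barely depends on the
coefficient, and at high $\mu_a$ little light survives to the detector —
in those regimes large errors reflect the physics of the inverse problem,
not the estimator. $n$ is recovered best across the whole space because
Fresnel reflections imprint it directly on the response.

## Problem sizes

A production-quality training set (hundreds of thousands of runs at
2.5×10⁵ photons, 5000-epoch training) is a multi-day batch job. The
package's test suite and acceptance script instead run a desk-scale study
chosen as the package's standard verification size: 5,000 runs of 10⁴
photons over the full parameter ranges, a [21, 150, 150, 150, 3] network
trained 500 epochs, evaluated on 1,000 held-out records. At this scale a
typical study measures median errors below 1% in $n$ and 95% levels of
roughly 2% ($n$), ~10% ($\mu_a$) and ~35% ($\mu_s'$) — the same ordering
a production-scale study exhibits, with the figures limited by the
reduced photon budget (moment noise) and training-set size. The full
production configuration validates and runs through the same pipeline
unchanged.

## What the synthetic data does and does not emulate

The generator *is* the study design: an instantaneous pencil-beam
impulse, a single homogeneous layer, an ideal noiseless detector that
logs every exiting photon with perfect spatial and temporal resolution.
Passing tests therefore demonstrate the self-consistency of the
inversion — that the moments determine the properties and the network
extracts them — not robustness to experimental reality. Real measurements
add detector response and laser pulse width (a convolution deliberately
not modelled), noise floors, finite fields of view, time-zero
uncertainty, and tissue heterogeneity (multi-layer structure,
polarization, fluorescence are all out of scope).

## Known limitations

* Single homogeneous slab only; no layered or laterally varying media.
* The moment features at high orders are noisy at small photon budgets,
  which limits desk-scale $\mu_s'$ accuracy.
* Roulette makes energy conservation exact only in expectation; with
  roulette disabled the budget closes to better than $10^{-9}$.
* The event cap truncates pathological walks (high $\mu_s$, negligible
  $\mu_a$, matched boundaries); capped weight is reported, and the
  default cap of $10^6$ events is far beyond anything the default ranges
  produce.
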