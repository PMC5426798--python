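# Methods

## Model

The study object is a recurrent network of `N = 100` leaky integrate-and-fire
neurons (80 excitatory, 20 inhibitory) with conductance-based synapses.  In
scaled voltage units (rest 0, threshold near 1) the membrane equation of
cell *i* is

    tau_m dv_i/dt = -v_i - g_E,i(t) (v_i - E_E) - g_I,i(t) (v_i - E_I)
                    + sigma_i sqrt(tau_m) xi_i(t),

with independent white background noise xi_i, reversal potentials
E_E = 6.5, E_I = -0.5, and tau_m = 20 ms.  When v_i reaches its threshold
theta_i a spike is emitted, the voltage is held at the reset (0) for
tau_ref = 2 ms, and every postsynaptic conductance receives a pulse: each
conductance is a second-order alpha filter

    tau_d,X dg/dt  = -g + g1
    tau_r,X dg1/dt = -g1 + tau_r,X * alpha_hat * sum_k delta(t - t_k),

so a presynaptic spike makes g1 jump by exactly `alpha_hat` (the tau_r
prefactor cancels when the delta is integrated — the jump is implemented as a
jump, not a dt-dependent kernel).  `alpha_hat = alpha_X W_YX / N_YX`: a raw
weight per (target type Y, source type X) divided by the in-degree, times a
per-source-type pulse amplitude.  Rise/decay times are 1/5 ms (E) and
2/10 ms (I); alpha_E = 1, alpha_I = 2.

Connectivity is fixed in-degree by default: every E cell receives exactly 32
E and 7 I inputs, every I cell 16 E and 8 I (40/35/20/40 % connection
probabilities), drawn uniformly without replacement, no autapses.  An
Erdős–Rényi option draws each edge independently with the same
probabilities; there the weight divisor is the *expected* in-degree, which
keeps the synaptic scale identical across cells (the alternative — dividing
by the realized degree — would make the pulse size degree-dependent).

Two regimes differ only in recurrent excitation: the *asynchronous* regime
(W_EE = 0.5, W_IE = 5) and the *strong asynchronous* regime (W_EE = 9,
W_IE = 8); W_EI = 10 and W_II = 5 throughout.  Heterogeneity enters through
thresholds: log(theta) ~ Normal(-s^2/2, s^2) with s = 0.2, truncated to
[0.7, 1.4] (rejection sampling; acceptance rate is reported).  The
homogeneous control sets theta = 1.

### The background-noise magnitudes

The source table for sigma_E / sigma_I prints fractions with a
typographically ambiguous denominator.  Both candidate readings (x/sqrt(2)
and the literal x/2) are kept in `eicorr.network.SIGMA_CANDIDATES` and are
selectable in the config.  The presets default to the sqrt(2) reading
(sigma_E = 2/sqrt 2, sigma_I = 3/sqrt 2 asynchronous; 1.5/sqrt 2,
2.5/sqrt 2 strong asynchronous) because it reproduces the published
population-averaged rates (about 10.6 Hz excitatory / 44.3 Hz inhibitory,
heterogeneous asynchronous) while the literal reading yields roughly 4 Hz /
24 Hz.

## Monte-Carlo simulation

Euler–Maruyama at dt = 0.01 ms (two orders of magnitude below the fastest
synaptic time scale; the config warns if dt exceeds 1 % of min tau_r).
Threshold crossings are detected at step boundaries and the spike recorded
at the end of the crossing step; the refractory period is a hold-then-reset
(voltage pinned, conductances keep evolving).  Each realization starts from
rest, simulates a discarded 1000 ms equilibration (the network correlation
time is well under a second), and stores spike counts in 1 ms bins; every
larger counting window is a sum of bins.  Noise is generated by a
PCG64-seeded generator in chunks; identical (network, seed) pairs give
bitwise-identical spike trains.

Windowed statistics (rate, Fano factor Var_T/mean_T, pairwise Pearson
correlation rho_T) pool counting windows across realizations.  A
zero-variance cell yields NaN correlations — reported missing, never zero.
Population power spectra are averaged (Welch) periodograms of the
population-summed, mean-subtracted count, with a stated segment length
(default 1024 ms), normalized to the maximum and shown in dB.

## Threshold integration (Fokker–Planck solver)

Summarizing each cell's synaptic input by the mean and variance of its
conductances (Poisson input into the double-exponential filter gives
mean = alpha_hat nu tau_r and variance = alpha_hat^2 nu tau_r^2 /
(2 (tau_r + tau_d)), by Campbell's theorem) turns the single cell into a
one-dimensional diffusion with drift a(v) = [-v - gE (v-E_E) - gI (v-E_I)]
/ tau_m and voltage-dependent (Ito) diffusion coefficient

    D(v) = [sE2 (v-E_E)^2 + sI2 (v-E_I)^2 + sigma^2 tau_m] / (2 tau_m^2).

Stationary rate, spike-train power spectrum and the susceptibilities to
small modulations of <gE>, <gI>, sE2, sI2 (and of an effective current mu)
are solutions of first-order boundary-value problems in voltage, integrated
from threshold downward.  Numerical choices:

* Uniform grid with nodes exactly at the reset and the threshold
  (n_v = 2048 by default); the scaled density q = D P obeys
  dq/dv = (a/D) q - J and is advanced with an integrating-factor step using
  the midpoint a/D, so the stationary problem is solved essentially exactly
  and frequency-domain problems are first-order with the stiff part
  integrated exactly.  Doubling n_v moves rates, A(0) and C0(0) by well
  under 0.5 %.
* The lower (reflecting) boundary is placed adaptively at mu - 8 standard
  deviations of the quasi-stationary voltage (capped at -1 from above).  A
  fixed shallow bound visibly biases rates because the multiplicative-noise
  density extends far below reset.
* Diffusion modulations are handled without numerically differentiating
  delta-D P0: substituting u = D P1 + deltaD P0 absorbs the derivative term
  into the sweep's source.
* omega = 0 is solved as its own stationary-perturbation problem, closed by
  probability conservation (integral of the perturbed density plus
  A tau_ref = 0) rather than as a numerical omega -> 0 limit; A(0) matches
  centered finite differences of the stationary rate to better than 1 %.
* The power spectrum uses the renewal identity
  C0(f) = nu0 (1-|F|^2)/|1-F|^2 with F the Fourier transform of the
  interspike-interval density (first-passage solve, times the refractory
  delay factor e^{-2 pi i f tau_ref}); C0(0) = nu0 CV^2 comes from the
  first two first-passage moments, solved as backward ODEs on the same
  grid.  In the additive-noise limit the stationary rate agrees with the
  classical first-passage (Siegert) formula to < 0.5 %.

The effective current-based reduction (g0 = 1 + <gE> + <gI>,
mu = (<gE> E_E + <gI> E_I)/g0, tau_eff = tau_m/g0, sigma_eff) is kept as a
cross-check mode and for the current-susceptibility comparison; the spectral
problems themselves are solved on the full multiplicative form.

## Network linear response

The self-consistent rates solve nu_i = f_i(conductance moments generated by
cell i's actual presynaptic partners) by damped Picard iteration
(gamma = 0.5, relative tolerance 1e-6, at most 500 iterations, seeded from
the uncoupled rates; the solution is independent of initialization in the
convergent regime).  Input-rate bookkeeping is per-edge, not mean-field.

With per-cell susceptibilities A(f) and baseline spectra C0(f), the
interaction matrix for an edge j -> i of source type X is

    K_ij(f) = A_<gX>,i(f) J_ij(f) + A_sX2,i(f) L_ij(f),
    J_ij(f) = alpha_hat_ij tau_r,X F_X(f),
    L_ij(f) = J_ij(f) (alpha_hat_ij / 2) tau_r,X / (tau_r,X + tau_d,X),

with F_X the unit-area synaptic kernel transform
1/((1 + 2 pi i f tau_r)(1 + 2 pi i f tau_d)).  The scale factors of J and L
are exactly the derivatives of the conductance mean and variance with
respect to the input rate, so the ansatz is consistent with the diffusion
mapping at f = 0.  Inhibition enters through the sign of A_<gI> (negative),
not through signed weights.  The cross-spectral matrix is
C(f) = (I-K)^{-1} C0 (I-K)^{-H}, Hermitian and PSD by construction; the
spectral radius of K stays well below 1 in both regimes (about 0.39 / 0.44
at f = 0).

All transforms use the e^{-2 pi i f t} convention with f in cycles/ms
internally (Hz at API boundaries).  Per-cell solver quantities are computed
at 0 plus 64 log-spaced frequencies (0.1 Hz – 1 kHz) and interpolated
(monotone cubic, separately in real and imaginary part) onto the uniform
quadrature grid used for windowed statistics.  Spike-count covariances come
from Cov_T = integral C(f) T^2 sinc^2(fT) df with the exact Poisson diagonal
nu T split off first; the quadrature range and spacing adapt to T (up to
1.5 kHz, spacing min(0.25 Hz, 1/(40 T))), and Cov_T / T at T = 10^4 ms
reproduces C(0) to about a percent.  Nonpositive predicted variances raise
an error; nothing is clipped silently.

## Motif decomposition

Expanding (I-K)^{-1} C0 (I-K*)^{-1} in powers of K yields order-n
contributions P^n = sum_l K^{n-l} C0 (K*)^l, computed by a three-term
recursion and normalized by the total autospectra
(R^n = Lambda^{-1/2} P^n Lambda^{-1/2}); the R^n sum converges to the
long-window correlation matrix at the geometric rate rho(K)^n (verified
against the direct inverse to 1e-6).  Second order is partitioned exactly by
the intermediate cell's type into E/I chains (both directions summed — the
chain terms are attributed to the pair symmetrically) and E/I common input.
Statistics are computed over distinct E-E pairs only; regressions are
ordinary least squares with intercept, reporting R^2.  The fraction-of-total
measure drops pairs with nonpositive total when they are rare (at most 1 %,
the strong-asynchronous situation) and is refused when they are pervasive
(the asynchronous regime, where signed contributions cancel).  Default
truncation order is 6.

## Correlation susceptibility

The pair susceptibility S_ij = A_i(0) A_j(0)/sqrt(C_ii(0) C_jj(0)) is
evaluated with the network-predicted autospectra; under the Poisson-variance
assumption C_ii(0) = nu_i it factorizes exactly into single-cell terms
S_i = A_<gI>,i(0)/nu_i (times sqrt(nu_i nu_j) for the pair).  Population
averages for the reduced variants are taken over excitatory cells, the
population whose pairs are analyzed.  The d/d<gI> derivative is the
solver's A_<gI>(0) (finite-difference cross-checked).  The fixed-theta sweep
spans mean inhibitory conductances bracketing those realized in the network,
recorded in the analysis output.

## Low-rank approximation

For a symmetric PSD correlation matrix with eigenvalues lambda_1 >= ... the
shift lambda = lambda_1 - sum_{j>1}(lambda_1-lambda_j)^2 /
sum_{j>1}(lambda_1-lambda_j) maximizes the Frobenius fraction captured by
the leading singular direction (verified against a brute-force grid search);
the approximation is lambda I + (sigma_1-lambda) u_1 u_1^T on the E-E block
with unit diagonal.  Eigenvalues are sorted descending, ties broken by
original index, eigenvalues below 1e-12 relative excluded from the rank; the
sign of u_1 is fixed so its rate-weighted mean entry is nonnegative.  Both
the Monte-Carlo and the linear-response correlation matrices can be
analyzed, and are labelled accordingly.

## Estimating regression R^2 at a reduced Monte-Carlo budget

The published correlation-rate regressions rest on an effectively noiseless
10^5-second Monte-Carlo estimate of every rho_ij.  At the desk-scale budget
used here (hundreds to a thousand simulated seconds) the per-pair estimation
noise (SE about 1/sqrt(N_windows)) is comparable to the true across-pair
spread and attenuates the raw R^2 by roughly half.  `eicorr.regression`
therefore also reports the classical split-half disattenuation: the run is
split into two halves, correlations are estimated in each, and the
across-pair covariance of the two half-estimates — in which the independent
noise cancels — replaces the noise-inflated variance in the R^2 denominator.
The estimator is validated on a doubly-stochastic Poisson model with
closed-form correlations; raw values are always reported alongside.

## Problem sizes and what the synthetic data does not cover

Simulated durations are package choices balancing estimator noise against
desk-scale runtimes: the acceptance script uses 600 s (heterogeneous
asynchronous), 400 s (homogeneous control) and 1000 s (strong asynchronous);
the test suite averages three network seeds at 150–300 s each.  Rates are
then precise to well under a percent and the disattenuated R^2 to a few
percent (seed-to-seed network scatter dominates both).

The generator emulates exactly the study conditions — fixed in-degree or
Erdős–Rényi topology, lognormal-threshold heterogeneity, type-dependent
background noise — and nothing else: no synaptic delays, distance-dependent
connectivity, plasticity, adaptation currents, or external stimulus drive.
Conclusions validated here therefore speak to recurrent networks whose rate
diversity comes from excitability, not to stimulus-driven or spatially
structured circuits.

One further honest discrepancy: the published Fano-factor range is
[0.9, 1.1], while this model (sqrt(2) noise reading, several seeds) produces
per-cell Fano factors up to about 1.15–1.22 at T = 100 ms in the strong
asynchronous regime.  The linear-response prediction of Var_T/mean agrees
with the Monte-Carlo values, so this is a property of the model at these
parameters rather than estimator noise, and it is reported as measured.
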