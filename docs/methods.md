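# Methods

## Model and assumptions

The package models the glioma microenvironment as three well-mixed,
continuous populations — tumor cells `C`, activated CD3⁺ T cells `T`, and
monocytic MDSCs `M` — with mass-action/saturating interaction terms (see
README for the equations). Assumptions baked into the formulation:

* logistic tumor growth with a hard carrying capacity `C_max`;
* the free PD-L1 level is proportional to `T + ε_C C` and the inhibitory
  PD-L1–PD-1 complex to `T(T + ε_C C)` (only T cells express PD-1), so the
  checkpoint enters as the factor `1/(1 + ρ T(T + ε_C C))` on T-cell gain;
* MDSC recruitment is linear in tumor load (chemokine secretion scales with
  tumor cells) plus a saturating expansion term `α C/(q + C)`;
* no spatial structure, no treatment terms, time in days, populations in
  cells (the continuum limit of counts).

All 13 parameters are strictly positive; `C_max ≥ 1` and `q ≥ 1` cell.
The package's nominal parameter set is the posterior mode of each marginal
from the ABC analysis; literature ranges and the shipped prior boxes live
in `glioimmune.params`.

One deliberate ambiguity is preserved: the checkpoint strength `ρ` has
literature support around `1e-13…3e-5 cell⁻²` while the posterior analysis
operates on an `O(0.01…1)` scale. The package treats `ρ`'s scale purely as
configuration (prior bounds and nominal value are data, not hard-coded
logic) and does not resolve the unit discrepancy.

## Numerics

`simulate` integrates with LSODA (analytic Jacobian supplied) at
`rtol=1e-8`, `atol=1e-6` cells, falling back to Radau and then to relaxed
tolerances on failure — populations span ~10 orders of magnitude and some
prior draws are very stiff. Two guards keep the flow consistent with the
positivity theory:

* the vector field is evaluated on populations clipped at 0, because an
  undershoot below zero would otherwise be amplified by the logistic term
  (for `C < 0`, `dC/dt < 0` is a runaway) and destroy the solve;
* after solving, undershoots up to `max(atol, 1e-6·max|y|)` are clamped to
  0; anything more negative marks the trajectory failed. Callers (ABC,
  eFAST, envelopes) score failed solves as infinite error / impute them.

The inner loops (ABC, eFAST, envelopes) use a faster path (`odeint`,
`rtol=1e-6`, `atol=1e-3` cells, outputs only at the requested days): those
stages compare trajectories against noisy data at a handful of time
points, so full tolerance would be wasted. The adaptive solution is
validated against an independent fixed-step RK4 oracle at `h = 1e-3` day
to relative error `1e-4` in the test suite.

The tumor-free level `T₀*` is computed from the cubic's Cardano form with
the second radical rationalized (`u − w = −p³/(u + w)`), which avoids the
catastrophic cancellation when `a_T/(2 d_T ρ)` is large, plus a Newton
polish; every call cross-checks against a bracketed Brent solve on
`[0, a_T/d_T + 1]` (Descartes' rule guarantees exactly one positive root).
Tumorous equilibria are found numerically: the C- and M-nullclines reduce
the fixed-point system to one scalar equation in `C*`, scanned on 2,000
log-spaced points over `(1e-3, C_max]` with sign-change bracketing; the
screen `C_max ε_C η / λ_C < 1` is reported as a diagnostic flag only and
never used to skip the search. The Jacobian is hand-differentiated and
verified against central differences.

## ABC rejection

Draws are i.i.d. uniform over per-parameter boxes, generated as one matrix
from a counter-based Philox stream keyed by the seed (reproducible and
cheap to parallelize). Each draw is simulated from `(35 000, 0, 0)` and
scored by the per-population mean relative error against the per-day data
summary (mean by default; min/max as alternate trials); acceptance
requires `E_C ≤ 0.75`, `E_T ≤ 0.72`, `E_M ≤ 0.78` jointly. The working
posterior is the smallest 25% of accepted draws by `E_total` (ceiling
size, ties by draw index).

**The prior boxes are the analysis' biggest free choice.** The study that
motivated this pipeline sampled "the bounds of the horizontal axes" of a
figure whose axes are not printed; the shipped defaults take the three
uniforms the posterior table reports verbatim (`s_T ∈ [1e2, 1e7]`,
`s_M ∈ [0, 0.1]`, `q ∈ [1e9, 1e11]`) and, for the rest, literature ranges
widened to cover the reported posterior supports. Every bound is
overridable (`PriorSpec` / the `priors:` config section), and quantities
that depend on the joint prior volume — the acceptance rate above all —
are sensitive to this choice.

Posterior summaries: mean/median/SD are standard; the mode is the argmax
of a Gaussian KDE (Silverman bandwidth), computed on the log scale for
samples spanning ≥ 2 decades (with the Jacobian back-transform
`f_X(x) = f_Y(ln x)/x`), since several marginals are strongly
right-skewed.

Family fitting minimizes the 1-Wasserstein distance between the empirical
and parametric quantile functions on 2,048 equi-probable levels
(method-of-moments start, Nelder–Mead refinement) over gamma, logistic,
Weibull, exponential, uniform, and normal. Parameterizations are named
explicitly: gamma(shape, scale), logistic(loc, scale),
weibull(scale, shape), exponential(mean), uniform(lo, hi),
normal(mean, sd). Families within one Monte-Carlo quantile-noise width
(`sd/√n`) of the best distance are treated as ties and the
fewest-parameter family wins; without this parsimony rule the exponential
family (nested in Weibull and gamma at shape 1) could never be selected.
Zero-variance samples return a point-mass report.

## Posterior-predictive envelope

10,000 parameter sets (configurable) are sampled either from the fitted
marginal families (default, with rejection of non-physical values such as
negative rates from the unbounded logistic/normal tails — i.e. truncation
to the physical domain) or by resampling accepted posterior draws. Each is
simulated from `(35 000, 0, 0)`; hourly means and SDs are accumulated in
running sums, and every data point is classified by
`|count − mean(day)| / SD(day)` into the σ/4, σ/2, 3σ/4, σ bands. More
than 5% failed solves aborts with diagnostics. Family sampling treats the
marginals as independent; the joint posterior correlations (e.g. the
inverse relationships among the immunosuppression parameters) are not
preserved by construction.

## Bifurcation sweeps

One parameter at a time over a log-spaced grid (default 100 points,
factor-100 span about the nominal value): integrate to 2,000 days and
record the componentwise min/max over the last half of the trajectory
(transient fraction 0.5; both configurable). Long horizons are needed
because approach to equilibrium is slow at small rates; min/max over the
post-transient window distinguishes fixed points (min = max) from cycles.
Solver failures leave NaN markers and the sweep continues.

## eFAST

Built from scratch on the classical search-curve construction. For a
design of size `NS` (odd) with `M = 4` harmonics, the parameter of
interest gets the frequency `ω_max = (NS − 1)/(2M)` — the largest integer
obeying the Nyquist condition — and the complementary parameters get
integer frequencies evenly spread over `[1, ω_max/(2M)]`, so that `M`
harmonics of any complementary frequency stay below `ω_max/2`. Per
resampling, phases are drawn uniformly on `[0, 2π)` and the phase variable
takes `NS` points `s_k = −π + π(2k+1)/NS`.

Two transformations map the sinusoid to the unit interval: the arcsine
curve `x = 1/2 + arcsin(sin(ωs + φ))/π` (uniform sampling) and the
exponential curve `x = n exp(v sin(ωs + φ))`, `v = ln(1/n)`, anchored at a
nominal `n ∈ (0,1)` and spanning `[n², 1]`. In the model analysis the six
right-skewed parameters (`λ_C, C_max, η, ρ, ε_C, r`) use the exponential
curve with `n` the posterior mode normalized into the sampling range
(clamped into `(ε, 1−ε)` with a warning if outside); the remaining seven
use the arcsine curve. Because the exponential curve skews harder than the
posteriors justify, an all-uniform variant is exposed behind the
`curves="uniform"` flag and the truth is bracketed between the two.

Indices come from the one-sided FFT power spectrum of the output along the
curve: `S_i` sums the spectrum at `ω_max` and its `M` harmonics over the
total variance; `S_Ti = 1 − V_c/V` with `V_c` the spectrum summed over all
frequencies up to `ω_max/2` (the whole complementary band, fundamentals
plus harmonics — the standard cutoff, validated here against closed-form
Sobol indices of linear-additive and Ishigami test functions to 0.05).
Estimates are averaged over `NR` resamplings and reported with their SEM.
Outputs with variance below `1e-12·mean²` get zero indices and a warning.
Failed model solves inside a curve are imputed with the per-curve median
(warned); above 5% the analysis aborts. Note the estimator's error
plateaus at the `M`-harmonic truncation bias once `NS` resolves the
spectrum; raising `NS` further does not reduce it.

## Synthetic data generator

`generate(GeneratorSpec(...))` emulates the structure of the murine
experiment: 35,000 glioma cells implanted at day 0; counts of the three
populations at days 7, 13, 20, 24, 27, 34; 1–4 mice per day (drawn from
the seed unless given). Each count is the ground-truth trajectory value
times a unit-mean lognormal multiplier with coefficient of variation
`noise_cv` (default 0.2) — counts are positive and right-skewed, but the
*true* within-day variance structure of the murine data is unknown, so
`noise_cv` is a knob, not an estimate. Two consequences for interpreting
green tests: the synthetic data is exactly model-consistent (its truth is
a model trajectory), so recovery and coverage results demonstrate
*pipeline self-consistency*, not fidelity to the real dataset; and
quantities that depend on the real data's dispersion — the ABC acceptance
rate, envelope coverage counts, minimal fitting errors — land at
different values than the murine study reports.

## Problem sizes

The test suite and `scripts/acceptance.py` run the pipeline at desk scale,
chosen so a full run takes minutes on one core: ABC campaigns of 30–50k
draws (the headline analysis used 1M), envelopes of 2–10k draws, eFAST at
`NS = 257, NR = 5` for the model (design arithmetic is still checked at
the full `NS = 2049`). Scaling up is a matter of the corresponding
`n_samples`/`NS`/`n_draws` arguments.

## Known limitations

* Tumorous equilibria are handled numerically only; no closed-form
  uniqueness/stability certificates are attempted, and the existence
  screen is a flag, not a filter.
* The printed Jacobian off-diagonal entry for the tumor-free state
  (`∂Ṫ/∂C`) in the source analysis lacks a square in one denominator; the
  package uses its own hand-derived Jacobian (difference has no effect on
  the eigenvalues, which come from the other entries).
* Family-sampled envelopes ignore posterior correlations (see above).
* The ABC prior boxes are a documented reconstruction, not a published
  artifact; acceptance-rate-type quantities inherit that uncertainty.
* The global-stability condition `λ_C < η β` is extremely conservative:
  at the nominal parameters `β ≈ 3.5e-24` cells, so the condition only
  activates for astronomically large kill rates. It is a certificate, not
  a realistic operating regime.
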