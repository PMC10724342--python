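# glioimmune

Modelling and inference for glioblastoma–immune dynamics: a three-population
ODE model of the glioma microenvironment with equilibrium/stability
diagnostics, bifurcation sweeps, ABC-rejection parameter inference against
longitudinal cell-count data, posterior-predictive envelopes, and a
from-scratch eFAST global sensitivity analysis.

## Who this is for

Mathematical oncologists and systems biologists studying how two forms of
immunosuppression — the PD-L1–PD-1 immune checkpoint and myeloid-derived
suppressor cells (MDSCs) — shape glioblastoma progression, and which rate
parameters are worth targeting therapeutically.

## The model

With `C` tumor cells, `T` activated (CD3⁺) T cells and `M` MDSCs:

    dC/dt = λ_C C (1 − C/C_max) − η T C
    dT/dt = (a_T + s_T T C) / (1 + ρ T (T + ε_C C)) − r T M − d_T T
    dM/dt = s_M C + α C/(q + C) − d_M M

Tumor cells grow logistically and are killed by T cells at rate `η`.
T cells are activated at constant rate `a_T`, stimulated by tumor contact
(`s_T`), inhibited by the PD-L1–PD-1 complex — represented by
`T(T + ε_C C)` since only T cells carry PD-1 — suppressed by MDSCs (`r`),
and die (`d_T`). MDSCs are recruited by the tumor-secreted chemokines
CCL2/CCL7 (`s_M`), expand saturably (`α`, `q`), and die (`d_M`).

Key analytic structure (implemented in `glioimmune.equilibria`):

* a unique tumor-free equilibrium `(0, T₀*, 0)`, with `T₀*` the single
  positive root of `d_T ρ T³ + d_T T − a_T = 0` (stable Cardano form plus
  Newton polish, verified against bracketed root-finding);
* eigenvalues there in closed form — locally stable iff `λ_C < η T₀*`,
  saddle otherwise;
* a sufficient global-stability condition `λ_C < η β` built from analytic
  population bounds;
* tumorous equilibria `(C*, T*, M*)` found numerically from the nullcline
  reduction, classified by the Jacobian.

## Worked example

```python
>>> from glioimmune import (default_parameters, simulate,
...                         tumor_free_equilibrium, tumorous_equilibria)
>>> p = default_parameters()          # posterior-mode parameter set
>>> eq = tumor_free_equilibrium(p)
>>> round(eq.T0_star, 2), eq.classification
(339.98, 'saddle')
```

The tumor-free state supports only ~340 activated T cells (constant
activation balanced by PD-1 self-inhibition and death), and since
`λ_C = 0.174 > η T₀* ≈ 1.4e-5` it is a saddle: any implanted tumor escapes.
Where it escapes to:

```python
>>> pts = tumorous_equilibria(p).points
>>> [(round(q.C), round(q.T), round(q.M), q.classification) for q in pts]
[(127331, 4186409, 8213, 'stable')]
```

a stable tumorous state with ~1.3e5 tumor cells held below carrying
capacity by ~4.2e6 T cells. Simulating the experimental protocol (35,000
implanted cells) approaches it:

```python
>>> traj = simulate(p, init=(35_000, 0, 0), t_end=40)
>>> round(traj.C[-1]), round(traj.T[-1]), round(traj.M[-1])
(119815, 4072397, 7619)
```

Inference against data (here a synthetic dataset with the murine study's
structure — counts at days 7, 13, 20, 24, 27, 34) follows the
model/results pattern:

```python
>>> from glioimmune import AbcRejection, GeneratorSpec, generate
>>> data = generate(GeneratorSpec(noise_cv=0.2, seed=42))
>>> res = AbcRejection(data).fit(n_samples=50_000, seed=7)
>>> print(res.summary())           # doctest: +SKIP
ABC rejection results
======================================================================
draws sampled:   50000
accepted:        312 (rate 0.0062)
thresholds:      R_C=0.75, R_T=0.72, R_M=0.78
posterior size:  78 (smallest 25% by E_total)
...
```

`res.summaries()` gives mean/median/mode/SD per parameter,
`res.fit_families()` the best parametric family per marginal
(1-Wasserstein), and `posterior_predictive_envelope(res, data)` the hourly
mean ± SD envelope with data-coverage counts.

A CLI mirrors the library: `glioimmune simulate | equilibria | bifurcate |
abc | efast | envelope | synthdata | all` (see `glioimmune --help`).

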