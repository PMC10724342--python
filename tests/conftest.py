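import numpy as np
import pytest

from glioimmune import AbcRejection, GeneratorSpec, default_parameters, generate
from glioimmune.params import DEFAULT_PRIOR_BOUNDS, PARAM_NAMES, ParameterSet


@pytest.fixture(scope="session")
def modes():
    """Posterior-mode parameter set used as the nominal model."""
    return default_parameters()


@pytest.fixture(scope="session")
def synth_data():
    """Default synthetic dataset: 6 days x 2 mice x 3 populations (36 points)."""
    return generate(GeneratorSpec(noise_cv=0.2, seed=42,
                                  mice_per_day=[2, 2, 2, 2, 2, 2]))


@pytest.fixture(scope="session")
def abc_run(synth_data):
    """One shared rejection-sampling campaign (50k draws) reused by the
    recovery, robustness, acceptance-rate, and best-fit tests."""
    return AbcRejection(synth_data).fit(n_samples=50_000, seed=7)


def random_parameter_sets(rng, n, log_uniform_over_priors=True):
    """Random valid parameter sets, log-uniform over the default prior box."""
    out = []
    for _ in range(n):
        vals = {}
        for name in PARAM_NAMES:
            lo, hi = DEFAULT_PRIOR_BOUNDS[name]
            lo = max(lo, 1e-6 if name == "s_M" else 1e-8)
            vals[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        out.append(ParameterSet.from_dict(vals))
    return out


def perturbed_parameter_sets(rng, n, base=None, factor=3.0):
    """Parameter sets near the nominal modes (each scaled by up to x/÷ factor)."""
    base = default_parameters() if base is None else base
    out = []
    for _ in range(n):
        vals = {k: v * float(np.exp(rng.uniform(-np.log(factor), np.log(factor))))
                for k, v in base.to_dict().items()}
        vals["C_max"] = max(vals["C_max"], 1.0)
        vals["q"] = max(vals["q"], 1.0)
        out.append(ParameterSet.from_dict(vals))
    return out
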