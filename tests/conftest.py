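import numpy as np
import pytest

from dsdpower import (
    FactorSpec,
    FittedModel,
    ModelTerm,
    cc1_like_scenario,
    simulate_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cc1_study():
    """One seeded inflated-noise chromatography-like study."""
    scenario = cc1_like_scenario()
    response, sp = simulate_study(scenario, seed=1)
    return scenario, response, sp


def make_model(factors, term_coefs, intercept=0.0, residuals=None, n=8):
    """Hand-built FittedModel for threshold/worst-case tests.

    ``term_coefs``: list of (term_name, coef); p-values and fit diagnostics
    are placeholders.
    """
    terms = []
    coefs = []
    for name, coef in term_coefs:
        if ":" in name:
            a, b = name.split(":")
            terms.append(ModelTerm("interaction", (a, b)))
        elif name.endswith("^2"):
            terms.append(ModelTerm("quadratic", (name[:-2],)))
        else:
            terms.append(ModelTerm("main", (name,)))
        coefs.append(coef)
    res = np.zeros(n) if residuals is None else np.asarray(residuals, float)
    return FittedModel(
        factors=tuple(factors),
        terms=tuple(terms),
        intercept=intercept,
        coefs=np.asarray(coefs, float),
        pvalues=np.full(len(terms), 0.01),
        residuals=res,
        fitted=np.zeros_like(res),
    )
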