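"""Shared fixtures: operators, small synthetic cohorts, and the fitted
60-gene RSS matrix (session-scoped; it is the expensive piece reused by the
discrimination and cluster-recovery tests)."""

from __future__ import annotations

import numpy as np
import pytest

import txkinetics as tk
from txkinetics.config import AnalysisConfig
from txkinetics.pairfit import rss_matrix
from txkinetics.synthetic import GeneratorConfig, simulate_dataset

#: One fixed seed for every stochastic fixture in the suite.
SEED = 1


@pytest.fixture(scope="session")
def expr_op() -> tk.DerivativeOperator:
    return tk.build_derivative_operator(tk.EXPRESSION_GRID)


@pytest.fixture(scope="session")
def exact_cohort():
    """Noise-free, model-exact dataset: pair fits can reach zero residual."""
    gen = GeneratorConfig(model_exact=True, noise_cv=0.0)
    return simulate_dataset(gen, SEED)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default study conditions: 60/30/30 genes, 10% multiplicative noise."""
    return simulate_dataset(GeneratorConfig(), SEED)


@pytest.fixture(scope="session")
def fitted_rss(noisy_cohort, expr_op):
    """RSS matrix over the planted up-regulated set (the heavy computation)."""
    expr, deg, truth = noisy_cohort
    cfg = AnalysisConfig(seed=SEED)
    up_ids = sorted(truth[truth.kind == "up"].index)
    return rss_matrix(expr, deg, expr_op, cfg, gene_ids=up_ids), truth
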