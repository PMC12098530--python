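"""Shared fixtures: small seeded cohorts built from the package's own generator."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

from lpp_select.synthetic_data import BinaryDataset


def make_cohort(
    betas,
    prevalences,
    n: int = 2000,
    intercept: float = -2.0,
    seed: int = 0,
    names=None,
) -> BinaryDataset:
    """Direct logistic-model cohort draw used as an independent construction
    in tests (bypasses GeneratorConfig on purpose)."""
    betas = np.asarray(betas, dtype=float)
    prevalences = np.asarray(prevalences, dtype=float)
    rng = np.random.default_rng(seed)
    X = (rng.random((n, betas.size)) < prevalences).astype(np.int8)
    y = (rng.random(n) < expit(intercept + X @ betas)).astype(np.int8)
    if names is None:
        names = [f"x{i}" for i in range(betas.size)]
    return BinaryDataset(X=X, y=y, names=list(names))


@pytest.fixture
def strong_noise_cohort() -> BinaryDataset:
    """One strong predictor (OR = 6) and one pure-noise predictor, n = 5000."""
    return make_cohort(
        betas=[np.log(6.0), 0.0],
        prevalences=[0.3, 0.3],
        n=5000,
        intercept=-2.0,
        seed=42,
        names=["strong", "noise"],
    )
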