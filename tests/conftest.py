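"""Shared fixtures: small seeded synthetic studies with known structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import devcoex as dx


@pytest.fixture(scope="session")
def small_study():
    """300-gene study with 3 strong planted modules and a planted DDR1."""
    cfg = dx.SynthConfig(
        n_genes=300,
        n_samples=60,
        module_sizes=(100, 80, 50),
        noise_sd=0.5,
        loading_range=(0.8, 0.95),
        marker_spec={1: 20, 2: 15},
        risk_spec=(1, 25, 1.0),
        trait_spec=(("glia_score", 1, 0.7),),
        goi_name="DDR1",
        goi_module=1,
        seed=123,
    )
    matrix, samples, truth = dx.generate_dataset(cfg)
    return cfg, matrix, samples, truth


@pytest.fixture()
def balanced_ages():
    """Age assigner spreading samples evenly over the four default intervals."""

    def assign(samples: pd.DataFrame) -> pd.DataFrame:
        out = samples.copy()
        n = len(out)
        values = np.tile([20.0, 3.0, 20.0, 50.0], n // 4 + 1)[:n]
        units = np.tile(
            ["weeks_postconception", "years", "years", "years"], n // 4 + 1
        )[:n]
        out["age_value"] = values
        out["age_unit"] = units
        return out

    return assign
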