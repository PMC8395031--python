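"""Shared fixtures.

The expensive end-to-end phantom experiments (used by the signal-recovery,
null-calibration and monotonicity tests) run once per session and are shared
across test modules.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

from dwirad.features import BankConfig
from dwirad.phantom import PhantomConfig
from dwirad.pipeline import RunConfig, run_experiment

# Desk-scale study conditions for the end-to-end experiments: cohorts of 112
# phantoms (3:1 split, study positive fraction), the texture-carrying feature
# families (shape + first-order + Laws), and the default selection pipeline.
E2E_PHANTOM = PhantomConfig(
    n_cases=112, positive_fraction=97 / 223, train_fraction=0.75
)
E2E_BANK = BankConfig(categories=("shape", "firstorder", "laws"))

N_SEEDS_SIGNAL = 10
N_SEEDS_NULL = 10
EFFECTS = (0.0, 0.5, 1.0)  # null, small, large texture effect


def _run_one(effect: float, seed: int) -> dict:
    cfg = RunConfig(
        phantom=replace(E2E_PHANTOM, texture_effect=effect),
        bank=E2E_BANK,
        n_icc=0,
        n_bootstrap=50,
        make_plots=False,
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_experiment(cfg)
    out = {}
    for name in ("intra_rad_score", "peri_rad_score", "com_rad_score"):
        out[name] = {
            "training": res.reports[(name, "training")].auc,
            "validation": res.reports[(name, "validation")].auc,
        }
    return out


@pytest.fixture(scope="session")
def e2e_auc_grid():
    """AUCs of the three rad-scores per (texture_effect, seed).

    Returns {effect: [run_dict, ...]} with ``N_SEEDS_SIGNAL`` seeds per
    effect level (seeds are fixed, shared across effect levels).
    """
    grid = {}
    for effect in EFFECTS:
        n = N_SEEDS_NULL if effect == 0.0 else N_SEEDS_SIGNAL
        grid[effect] = [_run_one(effect, seed) for seed in range(1, n + 1)]
    return grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
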