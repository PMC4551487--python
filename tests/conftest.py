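"""Shared fixtures: simulated populations at several scales.

Session-scoped so the expensive default-calibration replicates are built
once and shared between the module tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ricegs.popsim import (SimulationConfig, SubpopSpec, build_trait,
                           sample_architecture, simulate_population)


@pytest.fixture(scope="session")
def default_populations():
    """Five replicate populations at the full default calibration."""
    return [simulate_population(SimulationConfig(), seed=s) for s in range(1, 6)]


@pytest.fixture(scope="session")
def small_population():
    """One mid-sized population (~1k panel SNPs) for marker/predictor tests."""
    cfg = SimulationConfig(n_loci_per_chromosome=150)
    return simulate_population(cfg, seed=11)


def make_tiny_population(seed, n_loci_per_chromosome=60, n_lines=40):
    """Fast 4-subpopulation population for cross-validation tests."""
    cfg = SimulationConfig(
        n_loci_per_chromosome=n_loci_per_chromosome,
        n_cycles=50,
        subpops=tuple(SubpopSpec(f"SP{i}", n_lines, 20, 2) for i in range(1, 5)),
    )
    return simulate_population(cfg, seed=seed)


@pytest.fixture(scope="session")
def tiny_population():
    return make_tiny_population(seed=13)


def trait_blups(population, h2, n_qtl=60, seed=0, name="T"):
    """A simulated trait plus noisy line values standing in for trial BLUPs
    (TBV + Gaussian noise at the requested heritability)."""
    rng = np.random.default_rng(seed)
    arch = sample_architecture(name, population, n_qtl, h2, rng)
    tbv = build_trait(arch, population)
    vg = float(np.var(tbv))
    noise_sd = np.sqrt(vg * (1 - h2) / h2) if h2 > 0 else np.sqrt(max(vg, 1.0) * 100)
    y = tbv + rng.normal(0.0, noise_sd, population.n_lines)
    return arch, pd.Series(y, index=population.line_ids, name=name)
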