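"""Shared fixtures: small, fully seeded synthetic inputs."""

import numpy as np
import pytest

from octphen.simulate import (
    BlockSpec,
    CausalSpec,
    OutcomeSpec,
    ScanGeometry,
    SimConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_geometry():
    return ScanGeometry(n_slices=24, n_rows=96, n_cols=64)


@pytest.fixture(scope="session")
def noiseless_cohort(small_geometry):
    """Six subjects with noise-free volumes and known thickness fields."""
    cfg = SimConfig(
        geometry=small_geometry, noise_sd=0.0, texture_bumps=8, texture_amp=2.0
    )
    return simulate_cohort(6, 40, seed=101, config=cfg)


@pytest.fixture(scope="session")
def noisy_cohort(small_geometry):
    """Speckled volumes for segmentation robustness checks."""
    cfg = SimConfig(
        geometry=small_geometry, noise_sd=0.05, texture_bumps=8, texture_amp=2.0
    )
    return simulate_cohort(6, 40, seed=202, config=cfg)


@pytest.fixture(scope="session")
def genetics_cohort():
    """Morphology-only cohort (no volumes) with planted effects of each mode."""
    cfg = SimConfig(
        geometry=ScanGeometry(n_slices=16, n_rows=96, n_cols=64),
        noise_sd=0.0,
        texture_bumps=0,
        texture_amp=0.0,
        blocks=[
            BlockSpec(20, maf=0.3, ld_decay=0.4, chromosome="1", start=1_000_000),
            BlockSpec(20, maf=0.25, ld_decay=0.4, chromosome="2", start=5_000_000),
            BlockSpec(20, maf=0.4, ld_decay=0.4, chromosome="3", start=9_000_000),
        ],
        causal_map=[
            CausalSpec(2, "mean_thickness", 5.0, "additive"),
            CausalSpec(25, "mean_thickness", 6.0, "dominant"),
            CausalSpec(45, "pit_depth", 4.0, "recessive"),
        ],
        outcomes=[OutcomeSpec("H40", 2e-4, {"mean_thickness": 0.6})],
    )
    return simulate_cohort(1200, 60, seed=303, config=cfg, render_volumes=False)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
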