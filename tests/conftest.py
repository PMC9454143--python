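"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from phasikit import synthetic_data as sd
from phasikit.benchmark import RecoveryResult, run_recovery


@pytest.fixture(scope="session")
def recovery_seed1() -> RecoveryResult:
    """Full pipeline run on the default synthetic layout, seed 1."""
    return run_recovery(1)


@pytest.fixture(scope="session")
def synthetic_seed1() -> sd.SyntheticGenome:
    return sd.generate_genome(sd.SyntheticGenomeSpec(seed=1))


@pytest.fixture()
def small_genome() -> dict[str, str]:
    """A deterministic 400-nt two-chromosome toy genome."""
    import numpy as np

    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return {
        "c1": "".join(rng.choice(bases, 300)),
        "c2": "".join(rng.choice(bases, 100)),
    }
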