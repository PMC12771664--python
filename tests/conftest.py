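"""Shared fixtures: simulated genomes are expensive, so condition pairs
are built once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from senhic import matrix as mx
from senhic import simulate as sim


@pytest.fixture(scope="session")
def comp_pair():
    """Compartment genome (60 Mb @ 100 kb, c = 0.6) with a half-amplitude
    perturbed condition, balanced, plus tracks and truth."""
    cfg = sim.compartment_config(
        seed=1, perturbation=sim.Perturbation(amplitude_scale=0.5)
    )
    cm_a, gt = sim.simulate_matrix(cfg, "baseline")
    cm_b, _ = sim.simulate_matrix(cfg, "perturbed")
    bal_a = mx.ice_balance(cm_a, mask_fraction=0.0)
    bal_b = mx.ice_balance(cm_b, mask_fraction=0.0)
    tracks = sim.simulate_tracks(cfg)
    return {
        "config": cfg, "truth": gt, "tracks": tracks,
        "raw_a": cm_a, "raw_b": cm_b, "bal_a": bal_a, "bal_b": bal_b,
    }


@pytest.fixture(scope="session")
def domain_sim():
    """TAD genome (20 Mb @ 10 kb, 8 TADs with loops), balanced."""
    cfg = sim.domain_config(seed=1)
    cm, gt = sim.simulate_matrix(cfg)
    bal = mx.ice_balance(cm, mask_fraction=0.0)
    return {"config": cfg, "truth": gt, "raw": cm, "bal": bal}


@pytest.fixture(scope="session")
def loop_sim():
    """TAD genome at loop-calling depth (30M contacts), balanced."""
    cfg = sim.loop_config(seed=1)
    cm, gt = sim.simulate_matrix(cfg)
    bal = mx.ice_balance(cm, mask_fraction=0.0)
    return {"config": cfg, "truth": gt, "raw": cm, "bal": bal}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
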