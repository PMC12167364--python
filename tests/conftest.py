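"""Shared fixtures: small seeded synthetic cohorts reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from liverprog.synthetic import (
    SimulationConfig,
    default_config,
    simulate_cohort,
)
import liverprog.synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """20 patients with rendered phantoms at edge 32 (default conditions)."""
    cfg = default_config(n_patients=20, seed=101)
    return simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def tabular_survival():
    """Helper factory: latent covariates + survival times, no phantom images."""

    def make(config: SimulationConfig, n: int, seed: int):
        lats, os_l, pfs_l = [], [], []
        for i in range(n):
            lat = syn._draw_latents(syn._stream(seed, i, "clinical"), config)
            lp = syn._linear_predictor(lat, config.hazard_coefficients)
            o, p, *_ = syn.simulate_survival(lp, config, syn._stream(seed, i, "survival"))
            lat["lp"] = lp
            lats.append(lat)
            os_l.append(o)
            pfs_l.append(p)
        lp = np.array([l["lp"] for l in lats])
        t = np.array([o.time for o in os_l])
        e = np.array([o.event for o in os_l])
        return lats, lp, t, e, os_l, pfs_l

    return make
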