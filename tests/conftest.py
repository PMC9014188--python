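"""Shared fixtures: small populations and split pairs built once per session."""

import numpy as np
import pytest

from polyport import SimConfig, burn_in_to_equilibrium
from polyport.simulate import locus_table, marker_table, split_trajectory


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_selected_pop():
    """Equilibrated population under w=5 stabilizing selection (N=200)."""
    cfg = SimConfig(N=200, w=5.0, U=0.02, burn_in=400, init="stationary",
                    split_time=40, neutral_loci=60, seed=101)
    pop = burn_in_to_equilibrium(cfg)
    return cfg, pop


@pytest.fixture(scope="session")
def neutral_pair():
    """A neutral split pair with its LocusTable and marker table (N=200)."""
    cfg = SimConfig(N=200, w=None, U=0.02, burn_in=40, init="stationary",
                    split_time=40, neutral_loci=80, seed=202)
    anc = burn_in_to_equilibrium(cfg)
    rng = np.random.default_rng(303)
    g, pop_A, pop_B, anc_eff, anc_frq = next(
        split_trajectory(anc, cfg, rng, [cfg.split_time]))
    loci = locus_table(anc_eff, anc_frq, pop_A, pop_B)
    markers = marker_table(pop_A, pop_B)
    return cfg, pop_A, pop_B, loci, markers


@pytest.fixture(scope="session")
def selected_pair(small_selected_pop):
    """Split pair descending from the selected ancestor."""
    cfg, anc = small_selected_pop
    rng = np.random.default_rng(404)
    g, pop_A, pop_B, anc_eff, anc_frq = next(
        split_trajectory(anc, cfg, rng, [cfg.split_time]))
    loci = locus_table(anc_eff, anc_frq, pop_A, pop_B)
    markers = marker_table(pop_A, pop_B)
    return cfg, pop_A, pop_B, loci, markers
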