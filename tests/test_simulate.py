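"""Forward-simulator unit tests: fitness, transmission moments, bookkeeping."""

import numpy as np
import pytest

from polyport import (SimConfig, advance_generation, burn_in_to_equilibrium,
                      gaussian_fitness, initialize_population, summarize_state)
from polyport.simulate import Population, split_trajectory, locus_table


def _single_locus_pop(N, p, a, rng):
    geno = rng.binomial(2, p, size=(N, 1)).astype(np.uint8)
    return Population(
        N=N, geno=geno, effects=np.array([a]),
        locus_id=np.array([0], dtype=np.int64),
        marker_geno=np.zeros((N, 0), dtype=np.uint8),
        marker_id=np.zeros(0, dtype=np.int64))


class TestGaussianFitness:
    def test_peak_identity_and_symmetry(self):
        assert gaussian_fitness(2.0, 2.0, 5.0) == 1.0
        assert gaussian_fitness(2.3, 2.0, 5.0) == gaussian_fitness(1.7, 2.0, 5.0)

    def test_one_sd_displacement(self):
        # displacement equal to the peak width -> exp(-1/2)
        assert gaussian_fitness(5.0, 0.0, 5.0) == pytest.approx(
            np.exp(-0.5), rel=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            gaussian_fitness(np.nan, 0.0, 5.0)
        with pytest.raises(ValueError):
            gaussian_fitness(1.0, 0.0, np.inf)


def test_neutral_single_locus_wf_moments():
    """Conditional on the parents, offspring frequency is Binomial(2N, p).

    A fully heterozygous parent population fixes p = 1/2 exactly, so the
    offspring frequency must be unbiased with variance p(1-p)/2N.
    """
    N, p0 = 100, 0.5
    cfg = SimConfig(N=N, w=None, U=0.0, burn_in=0, init="cold")
    rng = np.random.default_rng(5)
    freqs = []
    for _ in range(600):
        pop = Population(
            N=N, geno=np.ones((N, 1), dtype=np.uint8),
            effects=np.array([0.1]), locus_id=np.array([0], dtype=np.int64),
            marker_geno=np.zeros((N, 0), dtype=np.uint8),
            marker_id=np.zeros(0, dtype=np.int64))
        advance_generation(pop, cfg, rng)
        if pop.n_loci:
            freqs.append(pop.frequencies()[0])
        else:
            freqs.append(pop.absorbed[0][2])
    freqs = np.asarray(freqs)
    se_mean = np.sqrt(p0 * (1 - p0) / (2 * N) / len(freqs))
    assert abs(freqs.mean() - p0) < 4 * se_mean
    assert np.var(freqs) == pytest.approx(p0 * (1 - p0) / (2 * N), rel=0.25)


def test_no_mutation_monomorphic_population_is_static():
    N = 50
    cfg = SimConfig(N=N, w=5.0, U=0.0, burn_in=0, init="cold")
    rng = np.random.default_rng(1)
    pop = initialize_population(cfg, rng)
    m0 = pop.mean_genetic_value()
    advance_generation(pop, cfg, rng)
    assert pop.n_loci == 0
    assert pop.mean_genetic_value() == m0


def test_negative_mutation_rate_rejected():
    with pytest.raises(ValueError):
        SimConfig(U=-0.1)


def test_substitution_bookkeeping_exact():
    """Sum of 2a over fixed loci equals the accumulated substitution offset.

    The warm start seeds a reference offset, so only fixations after
    initialization are compared; no locus may be both live and absorbed.
    """
    rng = np.random.default_rng(0)
    cfg = SimConfig(N=100, w=5.0, U=0.1, burn_in=0, init="stationary", seed=3)
    p2 = initialize_population(cfg, rng)
    off0 = p2.substitution_offset
    for _ in range(150):
        advance_generation(p2, cfg, rng)
    fixed = sum(2.0 * eff for _, eff, b in p2.absorbed if b == 1.0)
    assert p2.substitution_offset - off0 == pytest.approx(fixed, abs=1e-9)
    live = set(int(i) for i in p2.locus_id)
    assert live.isdisjoint({lid for lid, _, _ in p2.absorbed})


class TestSummarizeState:
    def test_single_locus_genic_variance(self, rng):
        pop = _single_locus_pop(4000, 0.5, 0.1, np.random.default_rng(8))
        s = summarize_state(pop)
        assert s.V_a == pytest.approx(2 * 0.5 * 0.5 * 0.01, rel=0.05)
        assert s.V_P == s.V_A

    def test_monomorphic_zero_variance(self):
        pop = Population(
            N=30, geno=np.zeros((30, 0), dtype=np.uint8),
            effects=np.zeros(0), locus_id=np.zeros(0, dtype=np.int64),
            marker_geno=np.zeros((30, 0), dtype=np.uint8),
            marker_id=np.zeros(0, dtype=np.int64))
        s = summarize_state(pop)
        assert s.V_a == 0.0 and s.V_A == 0.0

    def test_ld_term_small_at_equilibrium(self, small_selected_pop):
        """Unlinked loci: time-averaged LD contribution is a small fraction of V_a."""
        cfg, pop = small_selected_pop
        rng = np.random.default_rng(77)
        work = pop.copy()
        lds, vas = [], []
        for _ in range(120):
            advance_generation(work, cfg, rng)
            s = summarize_state(work, cfg.env_sd)
            lds.append(s.ld_term)
            vas.append(s.V_a)
        assert abs(np.mean(lds)) < 0.25 * np.mean(vas)


def test_equilibrium_va_positive_and_flagged(small_selected_pop):
    _, pop = small_selected_pop
    assert pop.equilibrated
    assert pop.equilibrium_va > 0


def test_zero_mutation_burn_in_flags_nonstationary():
    cfg = SimConfig(N=50, w=5.0, U=0.0, burn_in=30, init="cold", seed=4)
    pop = burn_in_to_equilibrium(cfg)
    assert pop.equilibrated is False


def test_selection_reduces_equilibrium_variance():
    """w=5 equilibrium V_a sits below the neutral level at identical U."""
    common = dict(N=200, U=0.02, burn_in=400, init="stationary")
    neutral = np.mean([
        burn_in_to_equilibrium(SimConfig(w=None, seed=s, **common)).equilibrium_va
        for s in range(4)])
    selected = np.mean([
        burn_in_to_equilibrium(SimConfig(w=5.0, seed=s, **common)).equilibrium_va
        for s in range(4)])
    assert selected < 0.6 * neutral


def test_phenotype_variance_small_relative_to_peak(small_selected_pop):
    cfg, pop = small_selected_pop
    s = summarize_state(pop, cfg.env_sd)
    assert s.V_P / cfg.w**2 < 0.15


class TestSplit:
    def test_split_at_zero_is_identity(self, small_selected_pop):
        cfg, anc = small_selected_pop
        rng = np.random.default_rng(12)
        g, pop_A, pop_B, anc_eff, anc_frq = next(
            split_trajectory(anc, cfg, rng, [0]))
        loci = locus_table(anc_eff, anc_frq, pop_A, pop_B)
        assert (loci["origin"] == "ancestral").all()
        assert np.allclose(loci["p_A"], loci["p_anc"])
        assert np.allclose(loci["p_B"], loci["p_anc"])

    def test_snapshot_beyond_split_time_rejected(self, small_selected_pop):
        cfg, anc = small_selected_pop
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            list(split_trajectory(anc, cfg, rng, [cfg.split_time + 1]))

    def test_private_loci_tracked_per_population(self, neutral_pair):
        _, pop_A, pop_B, loci, _ = neutral_pair
        priv_A = loci[loci["origin"] == "private_A"]
        priv_B = loci[loci["origin"] == "private_B"]
        assert len(priv_A) > 0 and len(priv_B) > 0
        assert (priv_A["p_B"] == 0.0).all()
        assert (priv_B["p_A"] == 0.0).all()

def test_selection_removes_shared_loci_faster():
    """Fewer ancestral loci survive in both descendants under selection."""
    def surviving_fraction(w, seed):
        cfg = SimConfig(N=200, w=w, U=0.02, burn_in=300, init="stationary",
                        split_time=80, neutral_loci=10, seed=seed)
        anc = burn_in_to_equilibrium(cfg)
        rng = np.random.default_rng(seed + 1000)
        g, pA, pB, ae, af = next(
            split_trajectory(anc, cfg, rng, [cfg.split_time]))
        loci = locus_table(ae, af, pA, pB)
        anc_rows = loci[loci["origin"] == "ancestral"]
        both = ((anc_rows["status_A"] == "segregating")
                & (anc_rows["status_B"] == "segregating"))
        return both.mean()

    neutral = np.mean([surviving_fraction(None, s) for s in range(3)])
    selected = np.mean([surviving_fraction(4.0, s) for s in range(3)])
    assert selected < neutral
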