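"""Configuration objects shared by the simulator and the theory layer.

Effect sizes are always expressed in phenotype units at the reference
population size ``REFERENCE_N`` (the scale at which mutation-effect
standard deviations such as 0.1 are quoted).  When a simulation is run at
a smaller census size the effects are multiplied by
``sqrt(REFERENCE_N / N)`` so that the population-scaled selection
coefficient ``S = 2 N a^2 / w^2`` of every allele is preserved, and
divergence times are interpreted in units of ``t / 2N``.  This makes
desk-scale runs statistically exchangeable with full-scale ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

#: Population size at which effect-size standard deviations are quoted.
REFERENCE_N = 10_000


@dataclass(frozen=True)
class EffectDistribution:
    """Symmetric, mean-zero mutation effect-size distribution.

    A single ``(1.0, sd)`` component is a Gaussian; several components
    form a mixture of mean-zero normals, which is how heavy tails are
    produced (a minority component with a much larger sd).
    """

    components: tuple[tuple[float, float], ...] = ((1.0, 0.1),)

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.components)
        if not math.isclose(w, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        if any(c[1] <= 0 for c in self.components):
            raise ValueError("component sds must be positive")
        if any(c[0] < 0 for c in self.components):
            raise ValueError("component weights must be non-negative")

    @property
    def kind(self) -> str:
        return "gaussian" if len(self.components) == 1 else "mixture"

    def sample(self, n: int, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
        """Draw ``n`` mutation effects, optionally rescaled by ``scale``."""
        weights = np.array([c[0] for c in self.components])
        sds = np.array([c[1] for c in self.components])
        which = rng.choice(len(sds), size=n, p=weights)
        return rng.normal(0.0, sds[which] * scale)

    def pdf(self, a: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """Mixture density evaluated at effects ``a``."""
        a = np.asarray(a, dtype=float)
        out = np.zeros_like(a)
        for w, sd in self.components:
            s = sd * scale
            out += w * np.exp(-0.5 * (a / s) ** 2) / (s * math.sqrt(2 * math.pi))
        return out

    def variance(self, scale: float = 1.0) -> float:
        return sum(w * (sd * scale) ** 2 for w, sd in self.components)

    def quantile_grid(self, n: int, scale: float = 1.0, half: bool = True) -> np.ndarray:
        """Grid of effect sizes covering the distribution's mass.

        With ``half=True`` only positive effects are returned (every
        quantity downstream is symmetric under ``a -> -a``).
        """
        sd_max = max(sd for _, sd in self.components) * scale
        # union of log spacing (resolves the near-zero region) and linear
        # spacing (resolves the bulk) up to ~5 sd of the widest component
        lo = 1e-3 * sd_max
        hi = 5.0 * sd_max
        grid = np.unique(np.concatenate([
            np.geomspace(lo, hi, n // 2),
            np.linspace(lo, hi, n - n // 2),
        ]))
        if half:
            return grid
        return np.concatenate([-grid[::-1], grid])


#: Heavy-tailed default: a nearly neutral bulk plus a minority component
#: with fifteen-fold sd.  The strongly selected tail then carries an
#: appreciable share of the equilibrium variance, producing the steep
#: early decay of ancestral variance that flattens toward the neutral
#: rate once the tail's contribution has been purged.
HEAVY_TAIL = EffectDistribution(components=((0.8, 0.02), (0.2, 0.3)))
GAUSSIAN_01 = EffectDistribution(components=((1.0, 0.1),))
GAUSSIAN_005 = EffectDistribution(components=((1.0, 0.05),))


@dataclass
class SimConfig:
    """All forward-simulation parameters.

    Parameters
    ----------
    N
        Diploid census (= effective) size.
    w
        Width of the Gaussian fitness peak in phenotype units
        (``w**2`` is the usual stabilizing-selection variance ``V_S``);
        ``None`` or ``inf`` means neutral evolution.
    U
        Expected number of new trait mutations per diploid genome per
        generation.  The default keeps the equilibrium number of
        segregating trait loci in the low thousands at ``N = 1000``.
    env_sd
        Environmental noise sd added to the genetic value when forming
        the phenotype.  0 by default so that ``V_P = V_A`` and the
        genetic mechanism is isolated.
    effect_dist
        Mutation effect-size distribution, quoted at ``REFERENCE_N``.
    scale_effects
        If true (default), multiply sampled effects by
        ``sqrt(REFERENCE_N / N)`` so S is preserved at desk scale.
    burn_in
        Generations of equilibration; ``None`` means ``10 * N``.
    split_time
        Generations each descendant evolves after the split.
    optimum_schedule
        Sorted ``(generation, optimum)`` pairs applied from the split
        onward (generation 0 = split).  Empty means optimum 0 always.
    init
        ``"cold"`` starts from a monomorphic population; ``"stationary"``
        samples allele frequencies from the single-locus
        mutation-selection-drift stationary density (with genotypes in
        Hardy-Weinberg proportions), which drastically shortens the
        burn-in needed.
    neutral_loci
        Count of unlinked neutral markers tracked for F_ST estimation.
    """

    N: int = 1000
    w: float | None = 5.0
    U: float = 0.02
    env_sd: float = 0.0
    effect_dist: EffectDistribution = field(default_factory=lambda: GAUSSIAN_01)
    scale_effects: bool = True
    burn_in: int | None = None
    split_time: int = 100
    optimum_schedule: tuple[tuple[int, float], ...] = ()
    init: str = "cold"
    neutral_loci: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.w is not None and not (self.w > 0):
            raise ValueError("w must be positive (or None for neutrality)")
        if self.U < 0:
            raise ValueError("U must be non-negative")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        gens = [g for g, _ in self.optimum_schedule]
        if gens != sorted(gens):
            raise ValueError("optimum_schedule generations must be non-decreasing")

    @property
    def neutral(self) -> bool:
        return self.w is None or math.isinf(self.w)

    @property
    def effect_scale(self) -> float:
        return math.sqrt(REFERENCE_N / self.N) if self.scale_effects else 1.0

    @property
    def burn_in_generations(self) -> int:
        return 10 * self.N if self.burn_in is None else self.burn_in

    def optimum_at(self, generation: int) -> float:
        """Optimum value in force at ``generation`` (post-split clock)."""
        opt = 0.0
        for g, val in self.optimum_schedule:
            if generation >= g:
                opt = val
            else:
                break
        return opt

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_dist"] = {"components": [list(c) for c in self.effect_dist.components]}
        d["optimum_schedule"] = [list(p) for p in self.optimum_schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "effect_dist" in d and not isinstance(d["effect_dist"], EffectDistribution):
            comps = tuple(tuple(c) for c in d["effect_dist"]["components"])
            d["effect_dist"] = EffectDistribution(components=comps)
        if "optimum_schedule" in d:
            d["optimum_schedule"] = tuple(tuple(p) for p in d["optimum_schedule"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class TheoryConfig:
    """Parameters for the analytic layer (no genotypes involved)."""

    N: int = REFERENCE_N
    w: float | None = 5.0
    U: float = 0.02
    V_P: float = 0.0
    effect_dist: EffectDistribution = field(default_factory=lambda: GAUSSIAN_01)
    scale_effects: bool = False
    n_freq: int = 400    # Chebyshev-type frequency grid resolution
    n_effect: int = 96   # effect-size quadrature points

    def __post_init__(self) -> None:
        if self.n_freq < 16 or self.n_effect < 4:
            raise ValueError("grid resolutions too coarse")
        if self.w is not None and not (self.w > 0):
            raise ValueError("w must be positive (or None for neutrality)")

    @property
    def neutral(self) -> bool:
        return self.w is None or math.isinf(self.w)

    @property
    def effect_scale(self) -> float:
        return math.sqrt(REFERENCE_N / self.N) if self.scale_effects else 1.0

    @classmethod
    def from_sim(cls, sim: SimConfig, **kw) -> "TheoryConfig":
        return cls(
            N=sim.N, w=sim.w, U=sim.U,
            effect_dist=sim.effect_dist, scale_effects=sim.scale_effects, **kw,
        )
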