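"""Polygenic scores, additive genetic values, and prediction-accuracy ratios.

With perfectly estimated effects, an individual's polygenic score is the
part of their additive genetic value contributed by ascertained loci, so
the within-population prediction-accuracy reduction is simply
``Var(S) / Var(G)`` -- the share of heritable variance the score
captures.  The ratio of that share in an unrepresented population B to
the represented population A is the portability of the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Population

__all__ = [
    "ScoreSet",
    "additive_values",
    "polygenic_scores",
    "accuracy_reduction",
    "relative_accuracy",
    "score_population",
]


def additive_values(pop: Population) -> np.ndarray:
    """Per-individual additive genetic values over segregating loci.

    Deviations are interpreted relative to the population mean; the
    constant substitution offset is deliberately excluded (it shifts the
    mean, not any individual's deviation).
    """
    return pop.genetic_values()


def polygenic_scores(pop: Population, loci: pd.DataFrame) -> np.ndarray:
    """Per-individual scores over the ascertained loci (true effects).

    Ascertained loci absent from this population's segregating set (lost
    or fixed here) contribute a constant -- 2a per fixed locus -- and
    hence nothing to the score's variance; they are genotyped all the
    same, which is how a portable score behaves.
    """
    asc = loci[loci["ascertained"]]
    if len(asc) == 0:
        return np.zeros(pop.N)
    wanted = dict(zip(asc["locus_id"].to_numpy(), asc["effect"].to_numpy()))
    cols = [i for i, lid in enumerate(pop.locus_id) if int(lid) in wanted]
    scores = np.zeros(pop.N)
    if cols:
        sub = pop.geno[:, cols].astype(np.float64)
        scores = sub @ pop.effects[cols]
    # constant contribution of ascertained loci fixed in this population
    fixed_const = 0.0
    present = {int(pop.locus_id[i]) for i in cols}
    for lid, eff, b in pop.absorbed:
        if lid in wanted and b == 1.0:
            fixed_const += 2.0 * eff
    return scores + fixed_const


@dataclass(frozen=True)
class ScoreSet:
    """Scores and genetic values for one population, with their variances."""

    population: str
    scores: np.ndarray
    values: np.ndarray

    @property
    def var_S(self) -> float:
        return float(np.var(self.scores))

    @property
    def var_G(self) -> float:
        return float(np.var(self.values))

    @property
    def accuracy_ratio(self) -> float | None:
        return accuracy_reduction(self)


def accuracy_reduction(scores: ScoreSet) -> float | None:
    """Proportion of additive genetic variance captured: ``Var(S)/Var(G)``.

    Scores and values are centred within the evaluated population (a
    variance is computed, so centring is implicit).  ``None`` when the
    population carries no genetic variance.
    """
    if scores.var_G == 0.0:
        return None
    return scores.var_S / scores.var_G


def relative_accuracy(ratio_B: float, ratio_A: float) -> float:
    """Portability: accuracy share in B relative to the GWAS population A."""
    if not ratio_A > 0:
        raise ValueError("ratio_A must be positive")
    return ratio_B / ratio_A


def score_population(pop: Population, loci: pd.DataFrame,
                     label: str | None = None) -> ScoreSet:
    """Convenience: build the ScoreSet of one population from a LocusTable."""
    return ScoreSet(
        population=label or pop.label,
        scores=polygenic_scores(pop, loci),
        values=additive_values(pop),
    )
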