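"""Population-level differentiation statistics: F_ST, Q_ST and Q_X.

The mean polygenic score of a population is twice the sum of its allele
frequencies weighted by effect sizes.  For two populations that split
``t`` generations ago, the neutral expectation is that the squared
difference in mean scores is ``4 V_a F_ST``, which standardizes into

    Q_X = (Z_A - Z_B)^2 / (4 V_a F_ST)  ~  chi^2 with 1 df under neutrality.

A trait under stabilizing selection toward a shared optimum is
under-dispersed (Q_X stochastically below chi^2_1) when scored from all
loci, but incomplete one-population ascertainment removes the
compensating loci and can push Q_X back up to -- or beyond -- neutral
levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "QxResult",
    "mean_polygenic_score",
    "fst_hudson",
    "qx",
    "qst",
    "partition_mean_difference",
    "qx_from_tables",
]


def mean_polygenic_score(freqs, effects, flags=None) -> float:
    """Population mean score ``Z = 2 sum p_l a_l`` over flagged loci.

    Frequencies must include boundary values (0 for lost, 1 for fixed)
    so that substitutions since the reference epoch stay in the score.
    """
    freqs = np.asarray(freqs, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must be in [0, 1]")
    if flags is not None:
        flags = np.asarray(flags, dtype=bool)
        freqs, effects = freqs[flags], effects[flags]
    return float(2.0 * np.sum(freqs * effects))


def fst_hudson(p_A, p_B) -> float:
    """Hudson-type ratio-of-averages F_ST from population frequencies.

    ``sum (p_A - p_B)^2 / sum [p_A (1 - p_B) + p_B (1 - p_A)]`` over
    markers; monomorphic-in-both markers contribute nothing to either
    sum and an all-monomorphic panel is undefined (NaN with a warning).
    """
    p_A = np.asarray(p_A, dtype=float)
    p_B = np.asarray(p_B, dtype=float)
    num = np.sum((p_A - p_B) ** 2)
    den = np.sum(p_A * (1.0 - p_B) + p_B * (1.0 - p_A))
    if den == 0.0:
        warnings.warn("all markers monomorphic: F_ST undefined")
        return float("nan")
    return float(num / den)


def qx(Z_A: float, Z_B: float, V_a: float, F_ST: float) -> tuple[float, float]:
    """The two-population Q_X statistic and its chi-square(1 df) p-value."""
    if not V_a > 0:
        raise ValueError("V_a must be positive")
    if not F_ST > 0:
        raise ValueError("F_ST must be positive (estimate it from markers first)")
    stat = (Z_A - Z_B) ** 2 / (4.0 * V_a * F_ST)
    return float(stat), float(chi2.sf(stat, df=1))


def qst(values_A, values_B) -> tuple[float, float, float]:
    """Q_ST for two populations from true additive genetic values.

    Returns ``(Q_ST, between, within)`` where ``between`` is the squared
    difference of population means, ``within`` the average
    within-population variance, and
    ``Q_ST = between / (between + 2 * within)``.  For a neutral additive
    trait ``E[between] = 4 V_A F_ST`` so ``E[Q_ST] ~ 2 F_ST`` when
    ``F_ST`` is small.  Values must include any substitution offsets so
    that fixed differences count toward the between component.
    """
    values_A = np.asarray(values_A, dtype=float)
    values_B = np.asarray(values_B, dtype=float)
    within = (np.var(values_A) + np.var(values_B)) / 2.0
    between = (values_A.mean() - values_B.mean()) ** 2
    if within == 0.0:
        raise ValueError("zero within-population variance: Q_ST undefined")
    return float(between / (between + 2.0 * within)), float(between), float(within)


def partition_mean_difference(loci: pd.DataFrame) -> tuple[float, float]:
    """Split ``Z_A - Z_B`` into ascertained and non-ascertained parts.

    The two parts sum to the full mean additive-genetic-value difference
    exactly; under stabilizing selection with top-fraction ascertainment
    they scatter near the line of exactly opposing effects.
    """
    asc = loci["ascertained"].to_numpy(dtype=bool)
    diff = 2.0 * (loci["p_A"].to_numpy() - loci["p_B"].to_numpy()) \
        * loci["effect"].to_numpy()
    return float(diff[asc].sum()), float(diff[~asc].sum())


@dataclass(frozen=True)
class QxResult:
    """Q_X and companions for one replicate at one time point."""

    Z_A: float
    Z_B: float
    V_a: float
    F_ST: float
    Q_X: float
    p_value: float
    std_diff: float                 # |Z_A - Z_B| / sqrt(V_a); equals sqrt(4 Q_X F_ST)
    delta_ascertained: float
    delta_non_ascertained: float

    def to_dict(self) -> dict:
        return asdict(self)


def qx_from_tables(loci: pd.DataFrame, markers: pd.DataFrame,
                   va_mode: str = "mean", fst_mode: str = "estimated",
                   expected_fst: float | None = None) -> QxResult:
    """Assemble a :class:`QxResult` from LocusTable + marker frequencies.

    ``va_mode='mean'`` (default) computes the standardizing genic
    variance from frequencies averaged across the two populations,
    ``2 pbar (1 - pbar) a^2`` per ascertained locus, which is symmetric
    in A and B and reduces to the usual V_a when they coincide;
    ``va_mode='A'`` uses population-A frequencies instead.  ``fst_mode``
    selects the Hudson estimate from the marker panel or the expected
    ``t/2N`` passed as ``expected_fst``.
    """
    asc = loci["ascertained"].to_numpy(dtype=bool)
    eff = loci["effect"].to_numpy()
    Z_A = mean_polygenic_score(loci["p_A"].to_numpy(), eff, asc)
    Z_B = mean_polygenic_score(loci["p_B"].to_numpy(), eff, asc)
    if va_mode == "mean":
        pbar = (loci["p_A"].to_numpy() + loci["p_B"].to_numpy()) / 2.0
    elif va_mode == "A":
        pbar = loci["p_A"].to_numpy()
    else:
        raise ValueError(f"unknown va_mode {va_mode!r}")
    V_a = float(np.sum(2.0 * pbar[asc] * (1.0 - pbar[asc]) * eff[asc] ** 2))
    if fst_mode == "estimated":
        F = fst_hudson(markers["p_A"].to_numpy(), markers["p_B"].to_numpy())
    elif fst_mode == "expected":
        if expected_fst is None:
            raise ValueError("expected_fst required with fst_mode='expected'")
        F = expected_fst
    else:
        raise ValueError(f"unknown fst_mode {fst_mode!r}")
    stat, p = qx(Z_A, Z_B, V_a, F)
    d_asc, d_non = partition_mean_difference(loci)
    return QxResult(
        Z_A=Z_A, Z_B=Z_B, V_a=V_a, F_ST=F, Q_X=stat, p_value=p,
        std_diff=abs(Z_A - Z_B) / np.sqrt(V_a),
        delta_ascertained=d_asc, delta_non_ascertained=d_non,
    )
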