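"""Idealized GWAS discovery: which causal loci enter the polygenic score.

Effects are known exactly; discovery is purely a function of the locus's
frequency in the source population.  Three schemes: every segregating
locus, the top fraction ``q`` of loci ranked by contributed genic
variance (a proxy for power-based significance thresholds), or all loci
whose minor-allele frequency exceeds ``m``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AscertainmentScheme", "per_locus_variance", "ascertain"]


@dataclass(frozen=True)
class AscertainmentScheme:
    """Rule deciding which loci are flagged for the polygenic score."""

    kind: str = "all"            # all | top_variance_fraction | maf_threshold
    q: float = 0.05              # fraction kept under top_variance_fraction
    m: float = 0.01              # MAF cutoff under maf_threshold
    source_population: str = "A"

    def __post_init__(self):
        if self.kind not in ("all", "top_variance_fraction", "maf_threshold"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if not 0.0 < self.q <= 1.0:
            raise ValueError("q must be in (0, 1]")
        if not 0.0 <= self.m < 0.5:
            raise ValueError("m must be in [0, 0.5)")
        if self.source_population not in ("A", "B", "both"):
            raise ValueError("source_population must be A, B or both")

    @property
    def label(self) -> str:
        if self.kind == "top_variance_fraction":
            return f"top{self.q:g}"
        if self.kind == "maf_threshold":
            return f"maf>{self.m:g}"
        return "all"


def per_locus_variance(p, a):
    """Genic variance ``2 p (1-p) a^2`` contributed by one locus."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    out = 2.0 * p * (1.0 - p) * a**2
    return out if out.ndim else float(out)


def _segregating(loci: pd.DataFrame, pop: str) -> pd.Series:
    return loci[f"status_{pop}"] == "segregating"


def ascertain(loci: pd.DataFrame, scheme: AscertainmentScheme) -> pd.DataFrame:
    """Return a copy of the LocusTable with ``ascertained`` flags set.

    Discovery happens in the scheme's source population at the present
    generation; loci not segregating there can never be flagged, which is
    what makes scores non-portable.  Ranking ties break by ascending
    locus id so the flag set is deterministic given the table.
    """
    loci = loci.copy()
    loci["ascertained"] = False
    pops = ["A", "B"] if scheme.source_population == "both" else [scheme.source_population]

    flags = np.zeros(len(loci), dtype=bool)
    for pop in pops:
        seg = _segregating(loci, pop).to_numpy()
        if scheme.kind == "all":
            flags |= seg
        elif scheme.kind == "maf_threshold":
            p = loci[f"p_{pop}"].to_numpy()
            maf = np.minimum(p, 1.0 - p)
            flags |= seg & (maf > scheme.m)
        else:  # top_variance_fraction
            p = loci[f"p_{pop}"].to_numpy()
            v = per_locus_variance(p, loci["effect"].to_numpy())
            idx = np.nonzero(seg)[0]
            if len(idx) > 0:
                k = int(np.ceil(scheme.q * len(idx)))
                sub = loci.iloc[idx]
                order = np.lexsort((sub["locus_id"].to_numpy(), -v[idx]))
                flags[idx[order[:k]]] = True
    loci["ascertained"] = flags
    if not flags.any():
        warnings.warn("empty ascertained set: downstream scores have zero variance")
    return loci
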