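"""Plain-text interchange: LocusTable / marker / summary readers and writers."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

LOCUS_COLUMNS = ["locus_id", "effect", "p_anc", "p_A", "p_B",
                 "origin", "status_A", "status_B", "ascertained"]


def write_loci(loci: pd.DataFrame, path) -> None:
    loci.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_loci(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(LOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"locus table missing columns: {sorted(missing)}")
    df["ascertained"] = df["ascertained"].astype(bool)
    return df


def write_markers(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_markers(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes(geno, locus_ids, path) -> None:
    """Individuals x loci copy counts, one column per locus id."""
    pd.DataFrame(geno, columns=[f"L{int(i)}" for i in locus_ids]).to_csv(
        path, sep="\t", index=False)


def write_state_summary(records: list[dict], path) -> None:
    Path(path).write_text(json.dumps(records, indent=2))
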