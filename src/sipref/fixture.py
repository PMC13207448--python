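"""Curated reference dataset of active, isotope-labeled OTUs.

The packaged table holds the per-OTU results of a bicarbonate DNA-SIP
experiment on biological soil crusts (BSC) and their underlying soils (US)
on the Qinghai-Tibetan Plateau, across a resuscitation phase (RP, days
0-7 after wetting) and a sustained hydration phase (SHP, days 7-14): for
each active OTU, its heavy-pool and whole-community relative abundances
(percent, as reported, 2 decimals) and its fixer/transformer class. The
table carries 23 rows over 17 unique OTUs (six OTUs recur across
compartment x phase groups) and is the desk-scale ground truth for the
summary statistics the pipeline computes.

Two reported BSC fixer community fractions do not equal the sum of the
listed per-OTU abundances (input rounding, and possibly an unlisted
contributing OTU for SHP): recomputation gives 5.72 (RP) and 9.62 (SHP)
versus the reported 5.71 and 9.71. Both are exposed; every other summary
reproduces exactly after 2-decimal rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from . import ref_core

EXPECTED_ROWS = 23
EXPECTED_UNIQUE_OTUS = 17

#: BSC fixer community fractions as reported by the source study; the sums
#: of the packaged per-OTU abundances are 5.72 (RP) and 9.62 (SHP).
REPORTED_BSC_FIXER_COMMUNITY_PCT = {"RP": 5.71, "SHP": 9.71}


@dataclass(frozen=True)
class FixtureRow:
    """One active OTU in one compartment x phase group."""

    otu_id: str
    best_hit: str
    phylum: str
    compartment: str
    phase: str
    heavy_ra_pct: float
    community_ra_pct: float
    trophic_class: str


def _data_path():
    return resources.files("sipref").joinpath("data/labeled_otus.tsv")


def fixture_frame() -> pd.DataFrame:
    """The validated reference table as a DataFrame."""
    with resources.as_file(_data_path()) as path:
        table = pd.read_csv(path, sep="\t")
    _validate(table)
    return table


def _validate(table: pd.DataFrame) -> None:
    if len(table) != EXPECTED_ROWS:
        raise ValueError(
            f"reference table has {len(table)} rows, expected {EXPECTED_ROWS}"
        )
    n_unique = table["otu_id"].nunique()
    if n_unique != EXPECTED_UNIQUE_OTUS:
        raise ValueError(
            f"reference table has {n_unique} unique OTUs, expected {EXPECTED_UNIQUE_OTUS}"
        )
    if table.duplicated(["otu_id", "compartment", "phase"]).any():
        raise ValueError("duplicate OTU within a compartment x phase group")
    bad_comp = set(table["compartment"]) - {"BSC", "US"}
    bad_phase = set(table["phase"]) - {"RP", "SHP"}
    if bad_comp or bad_phase:
        raise ValueError(f"unknown group labels: {bad_comp | bad_phase}")
    bad_class = set(table["trophic_class"]) - {"fixer", "transformer"}
    if bad_class:
        raise ValueError(f"unknown trophic classes: {bad_class}")
    for col in ("heavy_ra_pct", "community_ra_pct"):
        if not table[col].between(0, 100).all():
            raise ValueError(f"{col} outside [0, 100]")
    inconsistent = table.groupby("otu_id")["trophic_class"].nunique()
    if (inconsistent > 1).any():
        raise ValueError(
            f"trophic class differs across groups for {inconsistent[inconsistent > 1].index.tolist()}"
        )


def load_fixture() -> list[FixtureRow]:
    """All rows of the reference table, validated on load."""
    return [FixtureRow(**row) for row in fixture_frame().to_dict(orient="records")]


def results_frame() -> pd.DataFrame:
    """The reference table in the pipeline's results-table schema.

    Every fixture OTU was called active in its group; community abundances
    are converted from percent back to fractions of 1.
    """
    table = fixture_frame()
    return pd.DataFrame(
        {
            "taxon_id": table["otu_id"],
            "compartment": table["compartment"],
            "phase": table["phase"],
            "heavy_ra": table["heavy_ra_pct"] / 100.0,
            "community_ra": table["community_ra_pct"] / 100.0,
            "trophic_class": table["trophic_class"],
            "active": True,
        }
    )


def reproduce_summaries() -> dict:
    """Recompute every summary statistic from the packaged per-OTU table."""
    return ref_core.summarize(results_frame())
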