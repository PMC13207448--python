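"""Relative enrichment factor (REF) scoring and community summaries.

For each OTU the REF compares its partitioning between heavy and light DNA
in the labeled incubation against the unlabeled control::

    REF = (13C-heavy / 13C-light) / (12C-heavy / 12C-light)

where the four terms are the OTU's relative abundances in the pooled
heavy/light profiles of the two treatments. REF > 1 indicates isotope
incorporation; an OTU is called *active* when, in addition, its
whole-community (unfractionated) relative abundance exceeds 1%. Both
inequalities are strict. Labeled OTUs are then classed as fixers
(independent evidence of autotrophic carbon fixation, by exact lineage
lookup or the nearest annotated lineage rank) or, conservatively, as
transformers (heterotrophs presumed to acquire the label through
cross-feeding).

Zero handling: a zero in 13C-light, 12C-heavy or 12C-light makes REF
undefined (NaN) and the OTU inactive. No pseudocounts are applied by
default; an optional pseudo-abundance is available for exploratory use
because it changes rankings and must be an explicit choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fractionation import natural_key, PooledProfile

TROPHIC_CLASSES = ("fixer", "transformer", "unknown")

DEFAULT_REF_THRESHOLD = 1.0
DEFAULT_RA_THRESHOLD = 0.01


def round2(x: float) -> float:
    """Round to 2 decimals, ties away from zero (presentation only)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compute_ref(profile: PooledProfile, taxon_id: str, pseudo: float = 0.0) -> float:
    """REF for one taxon; NaN when the ratio is undefined.

    ``pseudo`` (default 0 = off) is added to each of the four abundances
    before forming the ratio; with the default the denominator-zero policy
    of the module docstring applies.
    """
    try:
        h13, l13, h12, l12 = profile.abundances(taxon_id)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    if pseudo > 0:
        h13, l13, h12, l12 = (v + pseudo for v in (h13, l13, h12, l12))
    if l13 <= 0 or h12 <= 0 or l12 <= 0:
        return math.nan
    return (h13 / l13) / (h12 / l12)


@dataclass(frozen=True)
class TrophicReference:
    """Lineage -> trophic class lookup with a nearest-ancestor fallback.

    ``mapping`` keys are lineage names at any rank (e.g. a species binomial,
    a genus, or a phylum). With ``neighbor_rule='nearest_annotated_lineage'``
    an unmatched lineage is walked from its most to least resolved rank and
    the first annotated rank wins; otherwise ``default_class`` applies.
    """

    mapping: Mapping[str, str]
    neighbor_rule: str = "nearest_annotated_lineage"
    default_class: str = "transformer"

    def __post_init__(self) -> None:
        if self.neighbor_rule not in ("nearest_annotated_lineage", "none"):
            raise ValueError("neighbor_rule must be 'nearest_annotated_lineage' or 'none'")
        if self.default_class not in ("transformer", "unknown"):
            raise ValueError("default_class must be 'transformer' or 'unknown'")
        bad = {v for v in self.mapping.values()} - {"fixer", "transformer"}
        if bad:
            raise ValueError(f"reference classes must be fixer/transformer, got {bad}")

    @staticmethod
    def from_csv(path, **kwargs) -> "TrophicReference":
        """Read a (lineage, trophic_class[, evidence]) CSV."""
        table = pd.read_csv(path)
        required = {"lineage", "trophic_class"}
        if not required.issubset(table.columns):
            raise ValueError(f"{path}: trophic reference needs columns {sorted(required)}")
        if table["lineage"].duplicated().any():
            dupes = table.loc[table["lineage"].duplicated(), "lineage"].tolist()
            raise ValueError(f"{path}: duplicate reference lineages {dupes}")
        mapping = dict(zip(table["lineage"].str.strip(), table["trophic_class"].str.strip()))
        return TrophicReference(mapping=mapping, **kwargs)


def _lineage_ranks(lineage: str | Sequence[str]) -> list[str]:
    if isinstance(lineage, str):
        ranks = [r.strip() for r in lineage.split(";")]
    else:
        ranks = [str(r).strip() for r in lineage]
    ranks = [r for r in ranks if r and not r.endswith("__")]
    return ranks


def classify_trophic(lineage: str | Sequence[str], reference: TrophicReference) -> str:
    """Classify a lineage as fixer/transformer/unknown against the reference."""
    ranks = _lineage_ranks(lineage)
    if not ranks:
        raise ValueError("classify_trophic: empty lineage")
    full = ";".join(ranks)
    if full in reference.mapping:
        return reference.mapping[full]
    if reference.neighbor_rule == "nearest_annotated_lineage":
        for rank in reversed(ranks):
            if rank in reference.mapping:
                return reference.mapping[rank]
    elif ranks[-1] in reference.mapping:
        return reference.mapping[ranks[-1]]
    return reference.default_class


@dataclass
class RefResult:
    """Per-taxon outcome of REF scoring."""

    taxon_id: str
    ref_value: float  # NaN when undefined
    heavy_ra: float
    community_ra: float
    active: bool
    trophic_class: str = "unknown"


def score_taxa(
    profile: PooledProfile,
    community_ra: Mapping[str, float] | pd.Series,
    *,
    taxonomy: Mapping[str, str] | None = None,
    trophic_reference: TrophicReference | None = None,
    ref_threshold: float = DEFAULT_REF_THRESHOLD,
    ra_threshold: float = DEFAULT_RA_THRESHOLD,
    pseudo: float = 0.0,
) -> pd.DataFrame:
    """Score every taxon of a profile; returns the REF results table.

    ``community_ra`` maps taxon -> whole-community relative abundance
    (fractions of 1, from unfractionated sequencing) and must cover every
    profile taxon. Rows are ordered by descending REF (undefined last),
    ties broken by taxon id.
    """
    community_ra = pd.Series(community_ra, dtype=float)
    missing = [t for t in profile.taxa if t not in community_ra.index]
    if missing:
        raise ValueError(f"community_ra missing taxa: {missing[:5]}")
    rows = []
    for taxon in profile.taxa:
        h13, _, _, _ = profile.abundances(taxon)
        ref = compute_ref(profile, taxon, pseudo=pseudo)
        ra = float(community_ra[taxon])
        active = (not math.isnan(ref)) and ref > ref_threshold and ra > ra_threshold
        trophic = "unknown"
        if trophic_reference is not None and taxonomy is not None and taxon in taxonomy:
            trophic = classify_trophic(taxonomy[taxon], trophic_reference)
        rows.append(
            {
                "taxon_id": taxon,
                "ref_value": ref,
                "heavy_ra": h13,
                "community_ra": ra,
                "active": active,
                "trophic_class": trophic,
            }
        )
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(table)),
        key=lambda i: (
            math.isnan(table.at[i, "ref_value"]),
            -(table.at[i, "ref_value"] if not math.isnan(table.at[i, "ref_value"]) else 0),
            natural_key(table.at[i, "taxon_id"]),
        ),
    )
    return table.iloc[order].reset_index(drop=True)


def call_active(
    ref_table: pd.DataFrame,
    ref_threshold: float = DEFAULT_REF_THRESHOLD,
    ra_threshold: float = DEFAULT_RA_THRESHOLD,
) -> list[str]:
    """Active taxon ids under strict dual thresholds, deterministic order.

    Order: descending REF, ties by taxon id. Undefined REF is never active.
    """
    required = {"taxon_id", "ref_value", "community_ra"}
    if not required.issubset(ref_table.columns):
        raise ValueError(f"ref_table needs columns {sorted(required)}")
    mask = (
        ref_table["ref_value"].notna()
        & (ref_table["ref_value"] > ref_threshold)
        & (ref_table["community_ra"] > ra_threshold)
    )
    hits = ref_table.loc[mask, ["taxon_id", "ref_value"]]
    ordered = sorted(
        hits.itertuples(index=False), key=lambda r: (-r.ref_value, natural_key(r.taxon_id))
    )
    return [r.taxon_id for r in ordered]


def relative_biomass(ra: float, dna_conc: float) -> float:
    """Relative biomass = RA x C (same units as ``dna_conc``, ug DNA per g soil)."""
    if not 0.0 <= ra <= 1.0:
        raise ValueError(f"relative abundance {ra} outside [0, 1]")
    if dna_conc < 0:
        raise ValueError("dna_conc must be non-negative")
    return ra * dna_conc


def fixer_community_fraction(
    active_fixers: Iterable[str], community_ra: Mapping[str, float] | pd.Series
) -> float:
    """Percent of the whole community held by the active fixers (unrounded)."""
    community_ra = pd.Series(community_ra, dtype=float)
    total = 0.0
    for taxon in active_fixers:
        if taxon not in community_ra.index:
            raise ValueError(f"no community abundance for active fixer {taxon!r}")
        total += float(community_ra[taxon])
    return 100.0 * total


def fixer_share_of_labeled(trophic_classes: Mapping[str, str]) -> float:
    """Percent of unique labeled taxa classed as fixers; NaN when none labeled."""
    if not trophic_classes:
        return math.nan
    fixers = sum(1 for c in trophic_classes.values() if c == "fixer")
    return 100.0 * fixers / len(trophic_classes)


def count_active(records: pd.DataFrame, grouping: str = "union") -> int | dict:
    """Unique active-taxon counts by 'phase', 'compartment' or 'union'.

    ``records`` needs columns taxon_id, compartment, phase (active rows only).
    """
    required = {"taxon_id", "compartment", "phase"}
    if not required.issubset(records.columns):
        raise ValueError(f"records needs columns {sorted(required)}")
    if grouping == "union":
        return int(records["taxon_id"].nunique())
    if grouping in ("phase", "compartment"):
        return {
            key: int(g["taxon_id"].nunique())
            for key, g in records.groupby(grouping, sort=True)
        }
    raise ValueError(f"unknown grouping {grouping!r}; expected phase/compartment/union")


@dataclass(frozen=True)
class SummaryStats:
    """Per compartment x phase summary of the active community."""

    compartment: str
    phase: str
    n_active: int
    fixer_community_pct: float
    fixer_share_of_labeled_pct: float  # per compartment, union over phases
    relative_biomass: float | None = None  # ug DNA per g soil, if C is known

    def __post_init__(self) -> None:
        if self.n_active < 0:
            raise ValueError("n_active must be >= 0")
        for pct in (self.fixer_community_pct,):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"percentage {pct} outside [0, 100]")


def summarize(
    results: pd.DataFrame,
    dna_conc: Mapping[tuple[str, str], float] | None = None,
) -> dict:
    """All printed-style summaries from a results table, as a JSON-ready dict.

    ``results`` needs columns taxon_id, compartment, phase, community_ra
    (fraction of 1), trophic_class, active. Only active rows contribute.
    Percentages are rounded to 2 decimals here, at the presentation layer;
    everything upstream is unrounded.
    """
    required = {"taxon_id", "compartment", "phase", "community_ra", "trophic_class", "active"}
    if not required.issubset(results.columns):
        raise ValueError(f"results needs columns {sorted(required)}")
    active = results[results["active"]]
    out: dict = {"groups": {}, "compartments": {}, "phases": {}, "n_active_total": 0}
    for (comp, phase), g in active.groupby(["compartment", "phase"], sort=True):
        fixers = g[g["trophic_class"] == "fixer"]
        entry = {
            "n_active": int(g["taxon_id"].nunique()),
            "fixer_community_pct": round2(
                fixer_community_fraction(
                    fixers["taxon_id"], g.set_index("taxon_id")["community_ra"]
                )
            ),
        }
        if dna_conc is not None and (comp, phase) in dna_conc:
            conc = dna_conc[(comp, phase)]
            entry["fixer_relative_biomass_ug_per_g"] = round2(
                sum(relative_biomass(ra, conc) for ra in fixers["community_ra"])
            )
        out["groups"][f"{comp}_{phase}"] = entry
    for comp, g in active.groupby("compartment", sort=True):
        classes = (
            g.drop_duplicates("taxon_id").set_index("taxon_id")["trophic_class"].to_dict()
        )
        share = fixer_share_of_labeled(classes)
        out["compartments"][comp] = {
            "n_labeled": len(classes),
            "fixer_share_of_labeled_pct": None if math.isnan(share) else round2(share),
        }
    out["phases"] = {
        phase: count for phase, count in count_active(active, "phase").items()
    }
    out["n_active_total"] = count_active(active, "union")
    return out


def summary_stats(
    results: pd.DataFrame,
    dna_conc: Mapping[tuple[str, str], float] | None = None,
) -> list[SummaryStats]:
    """The same summaries as :func:`summarize`, as typed records."""
    d = summarize(results, dna_conc)
    stats = []
    for key, entry in d["groups"].items():
        comp, phase = key.rsplit("_", 1)
        stats.append(
            SummaryStats(
                compartment=comp,
                phase=phase,
                n_active=entry["n_active"],
                fixer_community_pct=entry["fixer_community_pct"],
                fixer_share_of_labeled_pct=d["compartments"][comp][
                    "fixer_share_of_labeled_pct"
                ],
                relative_biomass=entry.get("fixer_relative_biomass_ug_per_g"),
            )
        )
    return stats
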