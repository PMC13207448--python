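"""Light/heavy stratification and pooling of density-gradient fractions.

An isopycnic CsCl run yields ~12 fractions per treatment, each with a
measured buoyant density (BD, g/mL), a DNA yield and per-OTU counts.
Relative-enrichment scoring consumes four pooled relative-abundance
profiles per paired treatment: the heavy and light pools of the
:sup:`13`\\ C incubation and of the :sup:`12`\\ C control. Fractions are
assigned to the light or heavy pool by comparing their BD against a
threshold (default 1.7274 g/mL); pooled per-taxon abundance is a weighted
mean of within-fraction relative abundances, weighted by default by each
fraction's DNA yield to emulate physical pooling of the DNA before
sequencing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

ISOTOPES = ("12C", "13C")
COMPARTMENTS = ("BSC", "US")
PHASES = ("OS", "RP", "SHP")
WEIGHTINGS = ("dna_quantity", "counts", "equal")

#: BD (g/mL) separating light from heavy DNA.
DEFAULT_BD_THRESHOLD = 1.7274

PROFILE_COLUMNS = ("heavy_13C", "light_13C", "heavy_12C", "light_12C")


def natural_key(taxon_id: str) -> tuple:
    """Sort key placing OTU_2 before OTU_12."""
    return tuple(
        int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", taxon_id)
    )


class Treatment(NamedTuple):
    """Isotope x compartment x phase label of one microcosm."""

    isotope: str
    compartment: str = "BSC"
    phase: str = "RP"

    def validate(self) -> "Treatment":
        if self.isotope not in ISOTOPES:
            raise ValueError(f"unknown isotope {self.isotope!r}; expected one of {ISOTOPES}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}"
            )
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        return self


@dataclass
class FractionRecord:
    """One gradient fraction: identity, BD, DNA yield and OTU counts."""

    sample_id: str
    treatment: Treatment
    fraction_index: int
    buoyant_density: float
    dna_quantity: float
    counts: pd.Series

    def __post_init__(self) -> None:
        self.treatment = Treatment(*self.treatment).validate()
        if not np.isfinite(self.buoyant_density) or not 1.5 < self.buoyant_density < 1.9:
            raise ValueError(
                f"{self.sample_id}: buoyant density {self.buoyant_density} g/mL outside "
                "the plausible CsCl range (1.5, 1.9)"
            )
        if self.fraction_index < 1:
            raise ValueError(f"{self.sample_id}: fraction_index must be >= 1")
        if self.dna_quantity < 0:
            raise ValueError(f"{self.sample_id}: negative dna_quantity")
        if not isinstance(self.counts, pd.Series):
            self.counts = pd.Series(self.counts, dtype=float)
        if (self.counts < 0).any() or not np.isfinite(self.counts).all():
            raise ValueError(f"{self.sample_id}: counts must be finite and non-negative")

    @property
    def total_reads(self) -> float:
        return float(self.counts.sum())

    def relative_abundance(self) -> pd.Series:
        """Within-fraction relative abundance (zeros if the fraction is empty)."""
        total = self.total_reads
        if total == 0:
            return self.counts.astype(float)
        return self.counts / total


@dataclass(frozen=True)
class StratifyConfig:
    """Light/heavy assignment rule.

    ``equality_rule`` resolves a fraction sitting exactly at the threshold;
    the default assigns it to the heavy pool, matching heavy-pool BD ranges
    that start at the threshold value itself.
    """

    bd_threshold: float = DEFAULT_BD_THRESHOLD
    equality_rule: str = "heavy"

    def __post_init__(self) -> None:
        if not 1.5 < self.bd_threshold < 1.9:
            raise ValueError("bd_threshold outside the plausible CsCl BD range")
        if self.equality_rule not in ("heavy", "light"):
            raise ValueError("equality_rule must be 'heavy' or 'light'")


def stratify(
    fractions: Sequence[FractionRecord], config: StratifyConfig | None = None
) -> tuple[list[FractionRecord], list[FractionRecord]]:
    """Partition fractions into (light, heavy) pools by buoyant density.

    The partition is exhaustive and disjoint. An entirely one-sided result
    is legal (it happens when a gradient is poorly centred) and only warns.
    """
    config = config or StratifyConfig()
    fractions = list(fractions)
    if not fractions:
        raise ValueError("stratify: no fractions supplied")
    light: list[FractionRecord] = []
    heavy: list[FractionRecord] = []
    for frac in fractions:
        bd = frac.buoyant_density
        if bd > config.bd_threshold:
            heavy.append(frac)
        elif bd < config.bd_threshold:
            light.append(frac)
        elif config.equality_rule == "heavy":
            heavy.append(frac)
        else:
            light.append(frac)
    if not light or not heavy:
        side = "heavy" if not light else "light"
        warnings.warn(
            f"stratify: every fraction fell on the {side} side of "
            f"{config.bd_threshold} g/mL",
            stacklevel=2,
        )
    return light, heavy


def _union_index(fractions: Iterable[FractionRecord]) -> pd.Index:
    taxa: set[str] = set()
    for frac in fractions:
        taxa.update(frac.counts.index)
    return pd.Index(sorted(taxa, key=natural_key))


def pool_counts(
    fractions: Sequence[FractionRecord], weighting: str = "dna_quantity"
) -> pd.Series:
    """Pool fractions of one treatment into a single relative-abundance vector.

    Pooled abundance of taxon t is sum_f w_f * share(t in f) with normalized
    weights w_f taken from the fraction DNA yields (``dna_quantity``,
    emulating physical pooling of DNA before sequencing), the fraction read
    totals (``counts``, the algebraic equivalent of summing raw counts), or
    uniform (``equal``).
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}; expected one of {WEIGHTINGS}")
    fractions = list(fractions)
    if not fractions:
        raise ValueError("pool_counts: empty fraction set")
    if len({f.treatment for f in fractions}) > 1:
        raise ValueError("pool_counts: fractions must come from a single treatment")
    index = _union_index(fractions)
    if weighting == "dna_quantity":
        weights = np.array([f.dna_quantity for f in fractions], dtype=float)
    elif weighting == "counts":
        weights = np.array([f.total_reads for f in fractions], dtype=float)
    else:
        weights = np.ones(len(fractions))
    total_weight = weights.sum()
    if total_weight <= 0:
        raise ValueError("pool_counts: zero total weight")
    weights = weights / total_weight
    pooled = pd.Series(0.0, index=index)
    for w, frac in zip(weights, fractions):
        pooled = pooled.add(w * frac.relative_abundance().reindex(index, fill_value=0.0))
    # empty fractions contribute no share; renormalize their lost weight
    s = pooled.sum()
    if s > 0:
        pooled = pooled / s
    return pooled


@dataclass
class PooledProfile:
    """The four pooled relative-abundance vectors of a 12C/13C pair.

    ``data`` is indexed by taxon over the union taxon set of the pair and has
    columns heavy_13C, light_13C, heavy_12C, light_12C; absent taxa carry 0.
    """

    pair_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROFILE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"profile missing columns {missing}")
        self.data = self.data[list(PROFILE_COLUMNS)].astype(float)
        self.data.index.name = "taxon_id"
        if (self.data.values < 0).any():
            raise ValueError("profile abundances must be non-negative")
        for col in PROFILE_COLUMNS:
            s = self.data[col].sum()
            if len(self.data) and s > 0 and abs(s - 1.0) > 1e-9:
                raise ValueError(f"profile column {col} sums to {s}, expected 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def abundances(self, taxon_id: str) -> tuple[float, float, float, float]:
        """(heavy_13C, light_13C, heavy_12C, light_12C) for one taxon."""
        if taxon_id not in self.data.index:
            raise KeyError(f"unknown taxon {taxon_id!r} in profile {self.pair_id}")
        row = self.data.loc[taxon_id]
        return tuple(float(row[c]) for c in PROFILE_COLUMNS)  # type: ignore[return-value]

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")

    @staticmethod
    def from_tsv(path, pair_id: str | None = None) -> "PooledProfile":
        data = pd.read_csv(path, sep="\t", index_col=0)
        return PooledProfile(pair_id or str(path), data)


def build_profiles(
    fractions_12c: Sequence[FractionRecord],
    fractions_13c: Sequence[FractionRecord],
    config: StratifyConfig | None = None,
    weighting: str = "dna_quantity",
) -> PooledProfile:
    """Stratify and pool a paired 12C/13C treatment into a PooledProfile."""
    config = config or StratifyConfig()
    if not fractions_12c or not fractions_13c:
        missing = "12C" if not fractions_12c else "13C"
        raise ValueError(f"build_profiles: missing {missing} isotope partner")
    for expected, fracs in (("12C", fractions_12c), ("13C", fractions_13c)):
        bad = {f.treatment.isotope for f in fracs} - {expected}
        if bad:
            raise ValueError(f"build_profiles: {expected} run contains isotopes {bad}")
    groups = {(f.treatment.compartment, f.treatment.phase) for f in fractions_12c} | {
        (f.treatment.compartment, f.treatment.phase) for f in fractions_13c
    }
    if len(groups) > 1:
        raise ValueError(f"build_profiles: mixed compartment/phase groups {groups}")
    compartment, phase = next(iter(groups))

    pools: dict[str, pd.Series] = {}
    for label, fracs in (("12C", fractions_12c), ("13C", fractions_13c)):
        light, heavy = stratify(fracs, config)
        for side, members in (("light", light), ("heavy", heavy)):
            key = f"{side}_{label}"
            pools[key] = (
                pool_counts(members, weighting) if members else pd.Series(dtype=float)
            )
    index = pd.Index(
        sorted(set().union(*(p.index for p in pools.values())), key=natural_key)
    )
    data = pd.DataFrame(
        {col: pools[col].reindex(index, fill_value=0.0) for col in PROFILE_COLUMNS},
        index=index,
    )
    return PooledProfile(f"{compartment}_{phase}", data)
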