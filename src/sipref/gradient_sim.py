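"""Synthetic CsCl-gradient stable-isotope-probing experiments.

Generates paired :sup:`12`\\ C/:sup:`13`\\ C microcosm runs as fraction-level
OTU count tables with known ground truth, so the whole enrichment-scoring
chain can be exercised without sequencing data.

The physical model: each taxon's DNA takes a normal buoyant-density (BD)
distribution on the gradient. The unlabeled mean follows the Schildkraut
GC-density relation (intercept 1.660 g/mL, slope 0.098 g/mL per GC
fraction) and heavy-isotope incorporation shifts it linearly by 0.036 g/mL
per unit atom-fraction excess (AFE, full labeling ~ +0.036). The gradient
is cut into equal-width BD bins ("fractions", numbered densest-first);
per-taxon DNA mass per fraction is the normal integral over the bin,
renormalized to the gradient range so mass is conserved. A small uniform
background (``smear_fraction``) distributes a trace of every taxon across
all fractions — the diffusive tailing and collection carryover that, in
real gradients, make even unlabeled heavy fractions sequenceable; without
it a fully labeled taxon would have strictly zero light-side reads and its
enrichment ratio would be undefined. Sequencing is a per-fraction
multinomial draw with probabilities proportional to per-taxon mass in the
fraction.

The paired :sup:`12`\\ C control shares the community and the random stream
(common random numbers), so with no labeled taxa the two runs are
byte-identical and every downstream enrichment factor is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fractionation import FractionRecord, Treatment

TROPHIC_TRUTHS = ("fixer", "transformer", "inert")


class GradientRangeError(ValueError):
    """A taxon's BD distribution lies entirely outside the gradient."""


@dataclass(frozen=True)
class SimTaxon:
    """Ground-truth description of one simulated OTU."""

    taxon_id: str
    gc_content: float
    baseline_abundance: float
    atom_fraction_excess: float = 0.0
    trophic_truth: str = "inert"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError(f"{self.taxon_id}: gc_content must be in [0, 1]")
        if not 0.0 <= self.baseline_abundance <= 1.0:
            raise ValueError(f"{self.taxon_id}: baseline_abundance must be in [0, 1]")
        if not 0.0 <= self.atom_fraction_excess <= 1.0:
            raise ValueError(f"{self.taxon_id}: atom_fraction_excess must be in [0, 1]")
        if self.trophic_truth not in TROPHIC_TRUTHS:
            raise ValueError(
                f"{self.taxon_id}: trophic_truth must be one of {TROPHIC_TRUTHS}"
            )


@dataclass(frozen=True)
class GradientConfig:
    """Physics and sampling parameters of a simulated gradient.

    Units: densities in g/mL; ``shift_per_afe`` in g/mL per unit AFE;
    ``dna_total`` in arbitrary mass units (about 5 ug loaded per tube);
    ``depth_per_fraction`` in reads. ``smear_fraction`` is the share of each
    taxon's DNA spread uniformly over all fractions (tailing/carryover).
    """

    n_fractions: int = 12
    bd_min: float = 1.690
    bd_max: float = 1.775
    density_sd: float = 0.004
    shift_per_afe: float = 0.036
    schildkraut_intercept: float = 1.660
    schildkraut_slope: float = 0.098
    depth_per_fraction: int = 50_000
    dna_total: float = 5.0
    smear_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        if not 0 < self.bd_min < self.bd_max:
            raise ValueError("need 0 < bd_min < bd_max")
        if self.density_sd <= 0:
            raise ValueError("density_sd must be positive")
        if self.depth_per_fraction < 1:
            raise ValueError("depth_per_fraction must be >= 1")
        if self.dna_total <= 0:
            raise ValueError("dna_total must be positive")
        if not 0.0 <= self.smear_fraction < 1.0:
            raise ValueError("smear_fraction must be in [0, 1)")


def unlabeled_bd(gc_content: float, config: GradientConfig | None = None) -> float:
    """Buoyant density (g/mL) of unlabeled DNA at the given GC fraction."""
    config = config or GradientConfig()
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError(f"gc_content {gc_content} outside [0, 1]")
    return config.schildkraut_intercept + config.schildkraut_slope * gc_content


def labeled_bd(
    bd_unlabeled: float, afe: float, config: GradientConfig | None = None
) -> float:
    """BD after isotope incorporation: linear shift by atom-fraction excess."""
    config = config or GradientConfig()
    if not 0.0 <= afe <= 1.0:
        raise ValueError(f"atom_fraction_excess {afe} outside [0, 1]")
    return bd_unlabeled + config.shift_per_afe * afe


def bin_edges(config: GradientConfig) -> np.ndarray:
    """Equal-width fraction bin edges, ascending in BD (n_fractions + 1 values)."""
    return np.linspace(config.bd_min, config.bd_max, config.n_fractions + 1)


def fraction_midpoints(config: GradientConfig) -> np.ndarray:
    """Bin-midpoint BDs in *fraction order* (fraction 1 = densest bin)."""
    edges = bin_edges(config)
    mids = (edges[:-1] + edges[1:]) / 2.0
    return mids[::-1]


def fraction_mass_matrix(
    community: Sequence[SimTaxon], config: GradientConfig
) -> np.ndarray:
    """Per-taxon DNA mass per fraction, shape (n_taxa, n_fractions).

    Columns follow fraction numbering (densest first). Each taxon's total
    mass is ``dna_total * baseline_abundance``, split as
    ``(1 - smear) * truncated-normal bin integral + smear / n_fractions``;
    bins are half-open [low, high) with the densest bin closed, which the
    continuous CDF-difference integration realizes exactly.
    """
    if not community:
        raise ValueError("community must be non-empty")
    edges = bin_edges(config)
    n = config.n_fractions
    masses = np.empty((len(community), n))
    for i, taxon in enumerate(community):
        mu = labeled_bd(
            unlabeled_bd(taxon.gc_content, config), taxon.atom_fraction_excess, config
        )
        core = np.diff(norm.cdf(edges, loc=mu, scale=config.density_sd))
        inside = core.sum()
        if inside < 1e-9:
            raise GradientRangeError(
                f"taxon {taxon.taxon_id}: DNA peak at {mu:.4f} g/mL lies outside the "
                f"gradient range [{config.bd_min}, {config.bd_max}] g/mL"
            )
        shape = (1.0 - config.smear_fraction) * core / inside + config.smear_fraction / n
        total = config.dna_total * taxon.baseline_abundance
        masses[i] = (total * shape)[::-1]  # ascending BD -> fraction order
    return masses


def _check_community(community: Sequence[SimTaxon]) -> None:
    if not community:
        raise ValueError("community must be non-empty")
    ids = [t.taxon_id for t in community]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon_id in community")
    total = sum(t.baseline_abundance for t in community)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"baseline abundances sum to {total}, expected 1")


def simulate_gradient(
    community: Sequence[SimTaxon],
    config: GradientConfig,
    *,
    treatment: Treatment | None = None,
    rng: np.random.Generator | None = None,
) -> list[FractionRecord]:
    """Simulate one ultracentrifugation run as a list of FractionRecord.

    Fractions are returned densest-first (fraction_index 1 = highest BD).
    Per-fraction read counts are multinomial with probabilities proportional
    to per-taxon mass in the fraction; each record carries the bin-midpoint
    BD and the total DNA mass recovered in the bin.
    """
    _check_community(community)
    treatment = (treatment or Treatment("13C")).validate()
    if treatment.isotope == "12C" and any(t.atom_fraction_excess > 0 for t in community):
        raise ValueError("a 12C treatment cannot contain labeled taxa (afe > 0)")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    masses = fraction_mass_matrix(community, config)
    mids = fraction_midpoints(config)
    taxa = pd.Index([t.taxon_id for t in community])
    records = []
    for j in range(config.n_fractions):
        col = masses[:, j]
        mass = col.sum()
        if mass > 0:
            counts = rng.multinomial(config.depth_per_fraction, col / mass)
        else:
            counts = np.zeros(len(taxa), dtype=int)
        records.append(
            FractionRecord(
                sample_id=(
                    f"{treatment.isotope}_{treatment.compartment}_"
                    f"{treatment.phase}_F{j + 1:02d}"
                ),
                treatment=treatment,
                fraction_index=j + 1,
                buoyant_density=float(mids[j]),
                dna_quantity=float(mass),
                counts=pd.Series(counts, index=taxa, dtype=float),
            )
        )
    return records


@dataclass
class SimExperiment:
    """A paired 12C/13C run plus ground truth."""

    fractions_13c: list[FractionRecord]
    fractions_12c: list[FractionRecord]
    community: list[SimTaxon]
    community_counts: pd.Series
    labeled_taxa: tuple[str, ...]
    config: GradientConfig
    compartment: str = "BSC"
    phase: str = "RP"


def simulate_experiment(
    community: Sequence[SimTaxon],
    config: GradientConfig,
    *,
    compartment: str = "BSC",
    phase: str = "RP",
    community_depth: int | None = None,
) -> SimExperiment:
    """Simulate the paired experiment: a 13C run and its 12C control.

    The control uses the same community with every atom_fraction_excess
    forced to 0 and shares the random stream with the labeled run (common
    random numbers), so the pair differs only through the isotope-induced
    density shifts. An unfractionated whole-community library is drawn from
    the baseline abundances with an independently derived stream.
    """
    _check_community(community)
    community = list(community)
    control = [replace(t, atom_fraction_excess=0.0) for t in community]
    run13 = simulate_gradient(
        community,
        config,
        treatment=Treatment("13C", compartment, phase),
        rng=np.random.default_rng(config.seed),
    )
    run12 = simulate_gradient(
        control,
        config,
        treatment=Treatment("12C", compartment, phase),
        rng=np.random.default_rng(config.seed),
    )
    depth = community_depth or config.depth_per_fraction
    rng_c = np.random.default_rng((config.seed, 1))
    baseline = np.array([t.baseline_abundance for t in community])
    community_counts = pd.Series(
        rng_c.multinomial(depth, baseline / baseline.sum()),
        index=[t.taxon_id for t in community],
        dtype=float,
    )
    labeled = tuple(t.taxon_id for t in community if t.atom_fraction_excess > 0)
    return SimExperiment(
        fractions_13c=run13,
        fractions_12c=run12,
        community=community,
        community_counts=community_counts,
        labeled_taxa=labeled,
        config=config,
        compartment=compartment,
        phase=phase,
    )


def random_community(
    n_taxa: int = 50,
    n_labeled: int = 5,
    afe: float = 0.9,
    seed: int = 0,
    *,
    gc_range: tuple[float, float] = (0.55, 0.70),
    labeled_baseline_range: tuple[float, float] = (0.02, 0.04),
    labeled_trophic: str = "fixer",
) -> list[SimTaxon]:
    """Draw a realistic soil-like community with a known labeled subset.

    GC contents are uniform on ``gc_range`` (soil Actinobacteria and
    Proteobacteria mostly fall at 55-70% GC, placing unlabeled peaks around
    1.714-1.729 g/mL, consistent with an unlabeled-DNA maximum near 1.72).
    Unlabeled baseline abundances are lognormal; labeled taxa get baselines
    drawn from ``labeled_baseline_range`` so they clear a 1% community-
    abundance screen when recovered.
    """
    if not 0 <= n_labeled <= n_taxa:
        raise ValueError("need 0 <= n_labeled <= n_taxa")
    rng = np.random.default_rng(seed)
    gc = rng.uniform(*gc_range, size=n_taxa)
    labeled_idx = set(rng.choice(n_taxa, size=n_labeled, replace=False).tolist())
    labeled_baselines = rng.uniform(*labeled_baseline_range, size=n_labeled)
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=n_taxa)
    remainder = 1.0 - labeled_baselines.sum()
    if remainder <= 0:
        raise ValueError("labeled baselines exceed the whole community")
    unlabeled_idx = [i for i in range(n_taxa) if i not in labeled_idx]
    unlabeled_raw = raw[unlabeled_idx]
    baselines = np.empty(n_taxa)
    for k, i in enumerate(sorted(labeled_idx)):
        baselines[i] = labeled_baselines[k]
    baselines[unlabeled_idx] = remainder * unlabeled_raw / unlabeled_raw.sum()
    community = []
    for i in range(n_taxa):
        is_labeled = i in labeled_idx
        community.append(
            SimTaxon(
                taxon_id=f"TAX_{i + 1:03d}",
                gc_content=float(gc[i]),
                baseline_abundance=float(baselines[i]),
                atom_fraction_excess=afe if is_labeled else 0.0,
                trophic_truth=labeled_trophic if is_labeled else "inert",
            )
        )
    return community
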