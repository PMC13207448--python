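"""End-to-end run: tables in, REF results and summaries out.

Ties the readers, stratification/pooling and REF scoring together behind a
single config. Every run logs the thresholds, weighting and equality rule
actually used — these choices are the scientific crux of REF calling.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__, io, ref_core
from .fractionation import StratifyConfig, build_profiles

log = logging.getLogger("sipref")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    fraction_table: Path
    metadata: Path
    community_table: Path | None = None
    taxonomy: Path | None = None
    trophic_reference: Path | None = None
    outdir: Path = Path("sipref_out")
    bd_threshold: float = 1.7274
    equality_rule: str = "heavy"
    weighting: str = "dna_quantity"
    ref_threshold: float = 1.0
    ra_threshold: float = 0.01
    pseudo: float = 0.0
    default_trophic: str = "transformer"

    def __post_init__(self) -> None:
        if self.ref_threshold <= 0 or self.ra_threshold <= 0:
            raise ValueError("thresholds must be positive")
        for attr in ("fraction_table", "metadata", "community_table", "taxonomy",
                     "trophic_reference", "outdir"):
            value = getattr(self, attr)
            if value is not None:
                setattr(self, attr, Path(value))


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns paths of the written artifacts."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    log_path = config.outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("sipref %s", __version__)
        log.info(
            "bd_threshold=%s equality_rule=%s weighting=%s ref_threshold=%s "
            "ra_threshold=%s pseudo=%s",
            config.bd_threshold,
            config.equality_rule,
            config.weighting,
            config.ref_threshold,
            config.ra_threshold,
            config.pseudo,
        )
        with _stage("read"):
            counts = io.read_otu_table(config.fraction_table)
            meta = io.read_metadata(config.metadata)
            records = io.records_from_tables(counts, meta)
            community = (
                io.read_otu_table(config.community_table)
                if config.community_table
                else None
            )
            taxonomy = io.read_taxonomy(config.taxonomy) if config.taxonomy else None
            trophic = (
                ref_core.TrophicReference.from_csv(
                    config.trophic_reference, default_class=config.default_trophic
                )
                if config.trophic_reference
                else None
            )

        strat = StratifyConfig(config.bd_threshold, config.equality_rule)
        groups: dict[tuple[str, str], dict[str, list]] = {}
        for rec in records:
            t = rec.treatment
            if t.phase == "OS":
                # original samples describe the community but carry no
                # isotope pair; they never enter REF calling
                continue
            groups.setdefault((t.compartment, t.phase), {"12C": [], "13C": []})[
                t.isotope
            ].append(rec)

        results = []
        for (comp, phase), pair in sorted(groups.items()):
            with _stage(f"profiles {comp}/{phase}"):
                profile = build_profiles(
                    pair["12C"], pair["13C"], strat, config.weighting
                )
            with _stage(f"score {comp}/{phase}"):
                community_ra = _community_ra(community, comp, phase, profile.taxa)
                scored = ref_core.score_taxa(
                    profile,
                    community_ra,
                    taxonomy=taxonomy,
                    trophic_reference=trophic,
                    ref_threshold=config.ref_threshold,
                    ra_threshold=config.ra_threshold,
                    pseudo=config.pseudo,
                )
                scored.insert(1, "compartment", comp)
                scored.insert(2, "phase", phase)
                results.append(scored)
                log.info(
                    "%s/%s: %d taxa scored, %d active",
                    comp,
                    phase,
                    len(scored),
                    int(scored["active"].sum()),
                )
        if not results:
            raise PipelineError("stage 'group': no 12C/13C treatment pairs found")
        table = pd.concat(results, ignore_index=True)

        with _stage("write"):
            paths = {
                "ref_results": config.outdir / "ref_results.tsv",
                "summary": config.outdir / "summary.json",
                "log": log_path,
            }
            table.to_csv(paths["ref_results"], sep="\t", index=False)
            summary = ref_core.summarize(table)
            paths["summary"].write_text(json.dumps(summary, indent=2) + "\n")
            log.info("wrote %s and %s", paths["ref_results"], paths["summary"])
        return paths
    finally:
        log.removeHandler(handler)
        handler.close()


def _community_ra(
    community: pd.DataFrame | None, comp: str, phase: str, taxa
) -> pd.Series:
    """Whole-community relative abundance for one group, reindexed to ``taxa``."""
    if community is None:
        raise PipelineError(
            "stage 'score': a whole-community table is required for the "
            "relative-abundance screen"
        )
    col = f"{comp}_{phase}"
    if col in community.columns:
        series = community[col]
    elif community.shape[1] == 1:
        series = community.iloc[:, 0]
    else:
        raise PipelineError(
            f"stage 'score': community table has no column {col!r} and is not "
            "single-column"
        )
    total = series.sum()
    if total <= 0:
        raise PipelineError("stage 'score': community table column sums to zero")
    ra = (series / total).reindex(taxa)
    if ra.isna().any():
        missing = ra[ra.isna()].index.tolist()
        log.warning(
            "community table lacks %d profile taxa (e.g. %s); treating as 0",
            len(missing),
            missing[:3],
        )
        ra = ra.fillna(0.0)
    return ra


def config_from_yaml(path) -> RunConfig:
    """Build a RunConfig from a YAML mapping of the dataclass fields."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
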