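"""Plain-text readers and writers for the pipeline's table formats.

Conventions: TSV for OTU matrices (rows = taxa, columns = samples), CSV for
fraction metadata, JSON for ground truth and summaries; UTF-8, Unix
newlines, '.' decimal separator.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fractionation import (
    COMPARTMENTS,
    FractionRecord,
    ISOTOPES,
    PHASES,
    Treatment,
)
from .gradient_sim import SimExperiment

METADATA_COLUMNS = [
    "sample_id",
    "isotope",
    "compartment",
    "phase",
    "fraction_index",
    "buoyant_density_g_per_ml",
    "dna_quantity",
]


class TableFormatError(ValueError):
    """A table failed structural validation."""


def read_otu_table(path) -> pd.DataFrame:
    """Read a taxa x samples TSV matrix; header = sample ids, col 1 = taxon ids.

    Rejects duplicate taxon ids, ragged rows and negative or non-numeric
    values, reporting the offending line.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise TableFormatError(f"{path}: duplicate taxon ids {dupes}")
    numeric = table.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~table.isna()
    if bad.values.any() or table.isna().values.any():
        mask = numeric.isna()
        i, j = (int(v) for v in np.argwhere(mask.values)[0])
        raise TableFormatError(
            f"{path}: non-numeric or missing value at line {i + 2}, "
            f"column {mask.columns[j]!r}"
        )
    if (numeric.values < 0).any():
        i, j = (int(v) for v in np.argwhere(numeric.values < 0)[0])
        raise TableFormatError(
            f"{path}: negative value at line {i + 2}, column {numeric.columns[j]!r}"
        )
    numeric.index.name = "taxon_id"
    return numeric


def write_otu_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a fraction-metadata CSV (one row per fraction)."""
    path = Path(path)
    meta = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise TableFormatError(f"{path}: missing metadata columns {missing}")
    enums = {"isotope": ISOTOPES, "compartment": COMPARTMENTS, "phase": PHASES}
    for col, allowed in enums.items():
        bad = ~meta[col].isin(allowed)
        if bad.any():
            i = int(np.flatnonzero(bad.values)[0])
            raise TableFormatError(
                f"{path}: row {i + 2}, column {col!r}: {meta[col].iloc[i]!r} "
                f"is not one of {allowed}"
            )
    for col, check in (
        ("fraction_index", lambda s: (s >= 1) & (s == s.astype(int))),
        ("buoyant_density_g_per_ml", lambda s: np.isfinite(s)),
        ("dna_quantity", lambda s: s >= 0),
    ):
        values = pd.to_numeric(meta[col], errors="coerce")
        bad = values.isna() | ~check(values.fillna(-1))
        if bad.any():
            i = int(np.flatnonzero(bad.values)[0])
            raise TableFormatError(
                f"{path}: row {i + 2}, column {col!r}: invalid value {meta[col].iloc[i]!r}"
            )
    if meta["sample_id"].duplicated().any():
        raise TableFormatError(f"{path}: duplicate sample_id values")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def records_from_tables(
    counts: pd.DataFrame, meta: pd.DataFrame
) -> list[FractionRecord]:
    """Assemble FractionRecords by joining a count matrix with its metadata."""
    records = []
    seen: set[tuple[Treatment, int]] = set()
    for row in meta.itertuples(index=False):
        if row.sample_id not in counts.columns:
            raise TableFormatError(
                f"metadata sample {row.sample_id!r} absent from the count table"
            )
        treatment = Treatment(row.isotope, row.compartment, row.phase)
        key = (treatment, int(row.fraction_index))
        if key in seen:
            raise TableFormatError(
                f"duplicate fraction_index {row.fraction_index} within treatment {treatment}"
            )
        seen.add(key)
        records.append(
            FractionRecord(
                sample_id=row.sample_id,
                treatment=treatment,
                fraction_index=int(row.fraction_index),
                buoyant_density=float(row.buoyant_density_g_per_ml),
                dna_quantity=float(row.dna_quantity),
                counts=counts[row.sample_id].astype(float),
            )
        )
    return records


def experiment_tables(exp: SimExperiment) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(count matrix, metadata) tables of a simulated experiment."""
    fractions = list(exp.fractions_13c) + list(exp.fractions_12c)
    counts = pd.DataFrame({f.sample_id: f.counts.astype(int) for f in fractions})
    counts.index.name = "taxon_id"
    meta = pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "isotope": f.treatment.isotope,
                "compartment": f.treatment.compartment,
                "phase": f.treatment.phase,
                "fraction_index": f.fraction_index,
                "buoyant_density_g_per_ml": f.buoyant_density,
                "dna_quantity": f.dna_quantity,
            }
            for f in fractions
        ]
    )
    return counts, meta


def write_experiment(exp: SimExperiment, outdir) -> dict[str, Path]:
    """Write a simulated experiment: counts TSV, metadata CSV, community TSV,
    ground-truth JSON. Returns the paths keyed by artifact name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, meta = experiment_tables(exp)
    paths = {
        "fraction_counts": outdir / "fraction_counts.tsv",
        "metadata": outdir / "fractions.csv",
        "community": outdir / "community.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_otu_table(counts, paths["fraction_counts"])
    write_metadata(meta, paths["metadata"])
    community = pd.DataFrame(
        {f"{exp.compartment}_{exp.phase}": exp.community_counts.astype(int)}
    )
    write_otu_table(community, paths["community"])
    truth = {
        "labeled_taxa": list(exp.labeled_taxa),
        "fraction_order": "fraction 1 = densest (highest BD); indices increase toward lighter DNA",
        "taxa": {
            t.taxon_id: {
                "gc_content": t.gc_content,
                "baseline_abundance": t.baseline_abundance,
                "atom_fraction_excess": t.atom_fraction_excess,
                "trophic_truth": t.trophic_truth,
            }
            for t in exp.community
        },
        "config": dataclasses.asdict(exp.config),
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def read_taxonomy(path) -> dict[str, str]:
    """Read a 2-column TSV (taxon_id, semicolon-delimited lineage)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", header=0)
    if table.shape[1] < 2:
        raise TableFormatError(f"{path}: taxonomy needs taxon_id + lineage columns")
    ids = table.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise TableFormatError(f"{path}: duplicate taxon ids in taxonomy")
    return dict(zip(ids, table.iloc[:, 1].astype(str)))
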