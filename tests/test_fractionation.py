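"""Stratification and pooling: threshold semantics, weighting, invariance."""

import csv
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sipref import (
    FractionRecord,
    PooledProfile,
    StratifyConfig,
    Treatment,
    build_profiles,
    pool_counts,
    stratify,
)
from sipref import io


def frac(bd, counts, *, isotope="13C", index=1, dna=1.0, sample=None):
    return FractionRecord(
        sample_id=sample or f"{isotope}_F{index:02d}",
        treatment=Treatment(isotope),
        fraction_index=index,
        buoyant_density=bd,
        dna_quantity=dna,
        counts=pd.Series(counts, dtype=float),
    )


@pytest.mark.parametrize(
    "bd, side",
    [(1.7186, "light"), (1.7371, "heavy"), (1.7274, "heavy")],
)
def test_stratify_threshold_semantics(bd, side):
    """BD values around the 1.7274 g/mL threshold land on the documented side."""
    with pytest.warns(UserWarning):  # single fraction is necessarily one-sided
        light, heavy = stratify([frac(bd, {"a": 1})])
    pool = heavy if side == "heavy" else light
    assert len(pool) == 1 and len(light) + len(heavy) == 1


def test_stratify_equality_rule_light():
    with pytest.warns(UserWarning):
        light, heavy = stratify(
            [frac(1.7274, {"a": 1})], StratifyConfig(equality_rule="light")
        )
    assert len(light) == 1 and not heavy


def test_stratify_empty_input_errors():
    with pytest.raises(ValueError):
        stratify([])


def test_stratify_one_sided_warns_not_errors():
    with pytest.warns(UserWarning):
        light, heavy = stratify([frac(1.70, {"a": 1}), frac(1.71, {"a": 1}, index=2)])
    assert len(light) == 2 and not heavy


@given(
    st.lists(
        st.floats(min_value=1.691, max_value=1.774),
        min_size=1,
        max_size=12,
    )
)
def test_stratify_partition_is_exhaustive_and_disjoint(bds):
    import warnings as _warnings

    fractions = [frac(bd, {"a": 1}, index=i + 1) for i, bd in enumerate(bds)]
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        light, heavy = stratify(fractions)
    assert len(light) + len(heavy) == len(fractions)
    assert {id(f) for f in light}.isdisjoint({id(f) for f in heavy})


@pytest.mark.parametrize("weighting", ["dna_quantity", "counts", "equal"])
def test_pool_identical_fractions_returns_their_profile(weighting):
    counts = {"a": 30, "b": 60, "c": 10}
    pooled = pool_counts(
        [frac(1.70, counts, dna=2.0), frac(1.71, counts, index=2, dna=5.0)],
        weighting,
    )
    expected = pd.Series(counts, dtype=float) / 100.0
    assert np.allclose(pooled.sort_index(), expected.sort_index())


def test_pool_counts_weighting_equals_summed_raw_counts():
    f1 = frac(1.70, {"a": 10, "b": 90}, dna=1.0)
    f2 = frac(1.71, {"a": 300, "b": 100}, index=2, dna=9.0)
    pooled = pool_counts([f1, f2], "counts")
    total = 10 + 90 + 300 + 100
    assert pooled["a"] == pytest.approx(310 / total, abs=1e-15)
    assert pooled["b"] == pytest.approx(190 / total, abs=1e-15)
    # read conservation: pooled proportions times total reads reproduce sums
    assert pooled["a"] * total == pytest.approx(310, abs=1e-9)


def test_pool_zero_total_weight_errors():
    with pytest.raises(ValueError, match="weight"):
        pool_counts([frac(1.70, {"a": 1}, dna=0.0)], "dna_quantity")


def test_pool_mixed_treatments_rejected():
    with pytest.raises(ValueError, match="single treatment"):
        pool_counts(
            [frac(1.70, {"a": 1}), frac(1.71, {"a": 1}, isotope="12C", index=2)]
        )


def test_dna_weighted_pooling_matches_spreadsheet_oracle(
    default_experiment, tmp_path
):
    """Hand-rolled weighted mean computed straight from the emitted TSV/CSV."""
    paths = io.write_experiment(default_experiment, tmp_path)
    with open(paths["fraction_counts"]) as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    header, body = rows[0], rows[1:]
    with open(paths["metadata"]) as fh:
        meta = list(csv.DictReader(fh))
    heavy = [
        m for m in meta
        if m["isotope"] == "13C" and float(m["buoyant_density_g_per_ml"]) >= 1.7274
    ]
    weights = {m["sample_id"]: float(m["dna_quantity"]) for m in heavy}
    wtot = sum(weights.values())
    expected = {}
    for row in body:
        taxon = row[0]
        acc = 0.0
        for m in heavy:
            j = header.index(m["sample_id"])
            column_total = sum(float(r[j]) for r in body)
            acc += (weights[m["sample_id"]] / wtot) * (float(row[j]) / column_total)
        expected[taxon] = acc

    records = io.records_from_tables(
        io.read_otu_table(paths["fraction_counts"]),
        io.read_metadata(paths["metadata"]),
    )
    heavy_records = [
        r
        for r in records
        if r.treatment.isotope == "13C" and r.buoyant_density >= 1.7274
    ]
    pooled = pool_counts(heavy_records, "dna_quantity")
    norm = sum(expected.values())
    for taxon, value in expected.items():
        assert abs(pooled[taxon] - value / norm) < 1e-12


def test_build_profiles_identical_tables_collapse():
    base = [
        frac(1.70, {"a": 5, "b": 5}, isotope="12C", index=2, dna=3.0),
        frac(1.74, {"a": 8, "b": 2}, isotope="12C", index=1, dna=1.0),
    ]
    mirror = [
        frac(1.70, {"a": 5, "b": 5}, isotope="13C", index=2, dna=3.0),
        frac(1.74, {"a": 8, "b": 2}, isotope="13C", index=1, dna=1.0),
    ]
    profile = build_profiles(base, mirror)
    pd.testing.assert_series_equal(
        profile.data["heavy_13C"], profile.data["heavy_12C"], check_names=False
    )
    pd.testing.assert_series_equal(
        profile.data["light_13C"], profile.data["light_12C"], check_names=False
    )


def test_build_profiles_absent_taxon_is_zero_not_missing():
    f12 = [
        frac(1.70, {"a": 5}, isotope="12C", index=2),
        frac(1.74, {"a": 5}, isotope="12C", index=1),
    ]
    f13 = [
        frac(1.70, {"a": 5}, isotope="13C", index=2),
        frac(1.74, {"a": 3, "only13heavy": 7}, isotope="13C", index=1),
    ]
    profile = build_profiles(f12, f13)
    row = profile.data.loc["only13heavy"]
    assert row["heavy_13C"] > 0
    assert row["light_13C"] == 0 and row["heavy_12C"] == 0 and row["light_12C"] == 0


def test_build_profiles_vectors_sum_to_one(default_profile):
    for col in ("heavy_13C", "light_13C", "heavy_12C", "light_12C"):
        assert default_profile.data[col].sum() == pytest.approx(1.0, abs=1e-9)


def test_build_profiles_input_order_invariant(default_experiment):
    f12 = list(default_experiment.fractions_12c)
    f13 = list(default_experiment.fractions_13c)
    reference = build_profiles(f12, f13)
    rng = random.Random(0)
    rng.shuffle(f12)
    rng.shuffle(f13)
    shuffled = build_profiles(f12, f13)
    pd.testing.assert_frame_equal(reference.data, shuffled.data)


def test_build_profiles_missing_partner_errors(default_experiment):
    with pytest.raises(ValueError, match="12C"):
        build_profiles([], default_experiment.fractions_13c)


def test_profile_tsv_round_trip(default_profile, tmp_path):
    path = tmp_path / "profile.tsv"
    default_profile.to_tsv(path)
    back = PooledProfile.from_tsv(path, default_profile.pair_id)
    pd.testing.assert_frame_equal(default_profile.data, back.data)
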