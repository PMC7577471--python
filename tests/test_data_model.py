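"""Detection-history I/O, covariate preparation, and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msom
from msom.data_model import _vif


# ---------------------------------------------------------------------------
# detection records
# ---------------------------------------------------------------------------


def test_read_detection_records_direct_encoding(tmp_path):
    path = tmp_path / "records.csv"
    path.write_text(
        "species,site,occasion,detected\nspA,s1,1,0\nspA,s1,2,1\n"
    )
    data = msom.read_detection_records(path)
    assert data.x.tolist() == [[[0, 1]]]
    assert data.observed_mask.tolist() == [[1, 1]]


def test_occasion_missing_when_absent_from_manifest(tmp_path):
    rec = tmp_path / "records.csv"
    man = tmp_path / "manifest.csv"
    rec.write_text(
        "species,site,occasion,detected\n"
        "spA,s1,1,1\nspA,s1,2,0\nspA,s1,3,1\n"
    )
    man.write_text("site,occasion\ns1,1\ns1,2\n")
    data = msom.read_detection_records(rec, man)
    k3 = data.occasion_ids.index("3")
    assert data.observed_mask[0, k3] == 0
    assert data.x[0, 0, k3] == 0  # the detection at the unlisted occasion is ignored
    # absent row at a surveyed occasion means non-detection
    assert data.x[0, 0, data.occasion_ids.index("2")] == 0


def test_manifest_marks_nondetection_for_absent_rows(tmp_path):
    rec = tmp_path / "records.csv"
    man = tmp_path / "manifest.csv"
    rec.write_text("species,site,occasion,detected\nspA,s1,1,1\n")
    man.write_text("site,occasion\ns1,1\ns1,2\ns2,1\ns2,2\n")
    data = msom.read_detection_records(rec, man)
    assert data.observed_mask.sum() == 4
    assert data.x.sum() == 1


@pytest.mark.parametrize(
    "body",
    [
        "species,site,occasion,detected\nspA,s1,1,1\nspA,s1,1,0\n",  # conflict
        "species,site,occasion,detected\nspA,s1,1,2\n",  # non-binary
    ],
)
def test_invalid_records_rejected(tmp_path, body):
    path = tmp_path / "bad.csv"
    path.write_text(body)
    with pytest.raises(ValueError):
        msom.read_detection_records(path)


def test_roundtrip_preserves_arrays_and_mask(tmp_path, tiny_data):
    rec = tmp_path / "records.csv"
    man = tmp_path / "manifest.csv"
    msom.write_detection_records(tiny_data, rec, man)
    back = msom.read_detection_records(rec, man)
    assert back.species_ids == tiny_data.species_ids
    assert back.site_ids == tiny_data.site_ids
    np.testing.assert_array_equal(back.x, tiny_data.x)
    np.testing.assert_array_equal(back.observed_mask, tiny_data.observed_mask)
    assert (
        msom.detection_counts(back)["n_detections"].tolist()
        == msom.detection_counts(tiny_data)["n_detections"].tolist()
    )


def test_supplementary_workbook_shim_roundtrips(tmp_path, tiny_data):
    """A workbook in the documented long layout loads to the same history."""
    df = tiny_data.to_dataframe().rename(columns={"species": "Species", "site": "Grid"})
    xlsx = tmp_path / "synthetic_supplementary.xlsx"
    df.to_excel(xlsx, index=False)
    back = msom.read_supplementary_workbook(xlsx)
    np.testing.assert_array_equal(back.x, tiny_data.x)


def test_detection_on_unsurveyed_occasion_rejected():
    x = np.ones((1, 1, 1), dtype=np.int8)
    with pytest.raises(ValueError, match="unsurveyed"):
        msom.DetectionData(["a"], ["s"], ["o"], x, np.zeros((1, 1), dtype=np.int8))


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def _site_table(values, names=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    names = names or [f"c{i}" for i in range(values.shape[1])]
    return msom.CovariateTable(names=names, level="site", values=values)


def test_standardize_three_point_example():
    out = msom.standardize(_site_table([1.0, 2.0, 3.0]))
    np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])  # sample sd (n-1)


def test_standardize_idempotent_and_invertible():
    raw = _site_table([10.0, 20.0, 30.0, 40.0])
    std = msom.standardize(raw)
    assert abs(std.values.mean()) < 1e-9 and abs(std.values.std(ddof=1) - 1) < 1e-9
    again = msom.standardize(std)
    np.testing.assert_allclose(again.values, std.values, atol=1e-9)
    back = msom.unstandardize(std)
    np.testing.assert_allclose(back.values[:, 0], [10.0, 20.0, 30.0, 40.0])


def test_constant_covariate_rejected_by_name():
    with pytest.raises(ValueError, match="flatline"):
        msom.standardize(_site_table([2.0, 2.0, 2.0], names=["flatline"]))


@settings(max_examples=25, derandomize=True)
@given(
    st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40).filter(
        lambda v: np.std(v, ddof=1) > 1e-6
    )
)
def test_standardize_roundtrip_property(values):
    std = msom.standardize(_site_table(values))
    back = msom.unstandardize(std)
    np.testing.assert_allclose(back.values[:, 0], values, rtol=1e-9, atol=1e-6)


def test_standardize_like_uses_reference_scaling():
    ref = msom.standardize(_site_table([0.0, 10.0, 20.0], names=["elev"]))
    grid = _site_table([10.0], names=["elev"])
    out = msom.standardize_like(grid, ref)
    np.testing.assert_allclose(out.values[:, 0], [0.0], atol=1e-12)


# ---------------------------------------------------------------------------
# collinearity screening
# ---------------------------------------------------------------------------


def test_orthogonal_covariates_both_retained():
    tbl = _site_table(np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], float), ["a", "b"])
    rep = msom.screen_collinearity(tbl)
    assert rep.retained == ["a", "b"] and rep.dropped == []
    np.testing.assert_allclose(rep.vif.to_numpy(), [1.0, 1.0])


def test_duplicated_covariate_dropped_by_r_rule():
    rng = np.random.default_rng(0)
    a = rng.normal(size=30)
    tbl = msom.CovariateTable(
        names=["a", "a_copy", "b"],
        level="site",
        values=np.column_stack([a, a, rng.normal(size=30)]),
    )
    rep = msom.screen_collinearity(tbl)
    assert len(rep.retained) == 2 and "b" in rep.retained
    assert rep.dropped[0][1] == "r-rule"
    # retained set satisfies both thresholds
    r = rep.pairwise_r.loc[rep.retained, rep.retained].to_numpy()
    np.fill_diagonal(r, 0)
    assert np.abs(r).max() <= 0.60


def test_vif_matches_statsmodels_oracle():
    rng = np.random.default_rng(42)
    c1 = rng.normal(size=50)
    c2 = rng.normal(size=50)
    c3 = 0.9 * c1 + 0.1 * rng.normal(size=50)
    X = np.column_stack([c1, c2, c3])
    ours = _vif(X, ["c1", "c2", "c3"])
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    design = np.column_stack([np.ones(50), X])
    for m in range(3):
        assert ours.iloc[m] == pytest.approx(
            variance_inflation_factor(design, m + 1), abs=1e-8
        )


def test_screening_shape_guards():
    with pytest.raises(ValueError):
        msom.screen_collinearity(
            msom.CovariateTable(["a", "b", "c"], "site", np.eye(3)[:2])
        )  # fewer rows than covariates


# ---------------------------------------------------------------------------
# habitat pooling
# ---------------------------------------------------------------------------


def _seven_table(rows):
    return msom.CovariateTable(
        names=list(msom.data_model.SEVEN_COVER_CLASSES),
        level="site",
        values=np.asarray(rows, dtype=float),
        site_ids=[f"s{i}" for i in range(len(rows))],
    )


def test_pool_habitat_covers_additive():
    pooled = msom.pool_habitat_covers(
        _seven_table([[0.1, 0.2, 0.0, 0.3, 0.1, 0.2, 0.1], [0] * 7])
    )
    np.testing.assert_allclose(pooled.values[0], [0.3, 0.4, 0.3], atol=1e-15)
    np.testing.assert_allclose(pooled.values[1], [0.0, 0.0, 0.0])


def test_pool_conserves_total_cover():
    rng = np.random.default_rng(5)
    raw = rng.dirichlet(np.ones(7), size=20)
    pooled = msom.pool_habitat_covers(_seven_table(raw))
    np.testing.assert_allclose(pooled.values.sum(axis=1), raw.sum(axis=1), atol=1e-12)


def test_pool_missing_column_rejected():
    tbl = msom.CovariateTable(["grassland"], "site", np.ones((3, 1)))
    with pytest.raises(ValueError, match="missing required"):
        msom.pool_habitat_covers(tbl)


def test_assign_habitat_classes_dominant_cover():
    pooled = msom.CovariateTable(
        names=["forest", "degraded_forest", "anthropogenic"],
        level="site",
        values=np.array([[0.7, 0.2, 0.1], [0.1, 0.2, 0.7]]),
        site_ids=["s1", "s2"],
    )
    classes = msom.assign_habitat_classes(pooled)
    assert classes.as_mapping() == {"s1": "forest", "s2": "anthropogenic"}


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------


def test_detection_counts_and_naive_occupancy(tiny_data):
    counts = msom.detection_counts(tiny_data)
    assert counts.loc["spA"].tolist() == [2, 2]
    assert counts.loc["spB"].tolist() == [1, 1]
    occ = msom.naive_occupancy(tiny_data)
    assert occ["spA"] == pytest.approx(2 / 3)


def test_detection_counts_thirteen_detections_five_sites():
    """A rare species seen 13 times across 5 of 35 sites tallies as (13, 5)."""
    x = np.zeros((1, 35, 6), dtype=np.int8)
    x[0, 0, :3] = 1
    x[0, 1, :3] = 1
    x[0, 2, :3] = 1
    x[0, 3, :3] = 1
    x[0, 4, 0] = 1
    data = msom.DetectionData(
        ["giant_squirrel"],
        [f"s{j}" for j in range(35)],
        [f"o{k}" for k in range(6)],
        x,
        np.ones((35, 6), dtype=np.int8),
    )
    counts = msom.detection_counts(data)
    assert counts.iloc[0].tolist() == [13, 5]
    assert msom.naive_occupancy(data).iloc[0] == pytest.approx(5 / 35)


def test_all_zero_history_counts_zero():
    data = msom.DetectionData(
        ["a", "b"], ["s1"], ["o1"],
        np.zeros((2, 1, 1), np.int8), np.ones((1, 1), np.int8),
    )
    assert msom.detection_counts(data)["n_detections"].tolist() == [0, 0]
    assert msom.naive_occupancy(data).tolist() == [0.0, 0.0]


def test_observed_richness_per_site_and_group(tiny_data):
    per_site = msom.observed_richness(tiny_data)
    assert per_site.tolist() == [2, 1, 0]
    grouped = msom.observed_richness(
        tiny_data, {"s1": "forest", "s2": "forest", "s3": "urban"}
    )
    assert grouped["forest"] == 2 and grouped["urban"] == 0
    with pytest.raises(ValueError, match="missing from grouping"):
        msom.observed_richness(tiny_data, {"s1": "forest"})


def test_observed_richness_matches_record_enumeration(sim_small):
    _, data, _ = sim_small
    df = data.to_dataframe()
    expected = (
        df[df.detected == 1].groupby("site")["species"].nunique()
    )
    rich = msom.observed_richness(data)
    for site in data.site_ids:
        assert rich[site] == expected.get(site, 0)
    assert (rich <= data.n_species).all()
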