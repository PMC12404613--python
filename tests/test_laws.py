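"""Neutrality-law predictions, residuals, and binned summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neutrality.laws import (
    LAWS,
    DivergenceError,
    MutantPairRecord,
    binned_summary,
    predict,
    records_to_frame,
    residuals,
)

fitness = st.floats(min_value=0.01, max_value=0.999)


@pytest.mark.parametrize(
    "law, w_x, w_y, expected",
    [
        ("product", 0.9, 0.8, 0.72),
        ("additive", 0.9, 0.8, 0.70),
        ("minimum", 0.9, 0.8, 0.80),
        ("scott_hwa", 0.5, 0.5, 1.0 / 3.0),
        ("scott_hwa", 0.9, 0.8, 0.72 / 0.98),
    ],
)
def test_predict_known_values(law, w_x, w_y, expected):
    assert predict(law, w_x, w_y) == pytest.approx(expected, abs=1e-12)


def test_scott_hwa_divergence_at_double_beneficial():
    with pytest.raises(DivergenceError):
        predict("scott_hwa", 2.0, 2.0)


def test_negative_fitness_rejected():
    with pytest.raises(ValueError):
        predict("product", -0.1, 0.5)


def test_unknown_law_rejected():
    with pytest.raises(ValueError):
        predict("geometric", 0.5, 0.5)


@given(w=fitness)
def test_neutral_partner_identity(w):
    """A co-mutation with a fully fit partner leaves fitness unchanged
    under every law."""
    for law in LAWS:
        assert predict(law, 1.0, w) == pytest.approx(w, abs=1e-12)


@given(w_x=fitness, w_y=fitness)
def test_law_ordering_and_sandwich(w_x, w_y):
    """additive <= product <= scott_hwa <= minimum on (0,1)^2."""
    a = predict("additive", w_x, w_y)
    p = predict("product", w_x, w_y)
    s = predict("scott_hwa", w_x, w_y)
    m = predict("minimum", w_x, w_y)
    assert a <= p + 1e-12
    assert p <= s + 1e-12
    assert s <= m + 1e-12


@given(w_x=fitness, w_y=fitness)
def test_product_closed_under_square_root_transform(w_x, w_y):
    """The Product law commutes with power transforms (colony rate
    proportional to the square root of the single-cell rate), so colony-
    and liquid-based fitnesses are equivalent under it."""
    assert np.sqrt(w_x * w_y) == pytest.approx(np.sqrt(w_x) * np.sqrt(w_y), rel=1e-12)


def _frame(rows):
    return pd.DataFrame(rows, columns=["query_gene", "array_gene", "w_x", "w_y", "w_xy"])


@pytest.mark.parametrize(
    "law, w_xy, expected",
    [("product", 0.70, -0.02), ("minimum", 0.70, -0.10), ("additive", 0.70, 0.0)],
)
def test_residual_sign_convention(law, w_xy, expected):
    """Residual is observed minus predicted: a law predicting too-high
    fitness yields negative residuals."""
    table = residuals(_frame([("a", "b", 0.9, 0.8, w_xy)]), law)
    assert table["residual"].iloc[0] == pytest.approx(expected, abs=1e-12)
    assert table["max_single"].iloc[0] == 0.9


def test_residual_zero_for_neutral_partner():
    for law in LAWS:
        table = residuals(_frame([("a", "b", 1.0, 0.7, 0.7)]), law)
        assert table["residual"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_residuals_exclude_divergent_records():
    frame = _frame([("a", "b", 2.0, 2.0, 3.0), ("c", "d", 0.9, 0.9, 0.8)])
    table = residuals(frame, "scott_hwa")
    assert len(table) == 1
    assert table.attrs["n_divergent_excluded"] == 1


def test_residuals_accept_record_objects():
    recs = [MutantPairRecord("a", "b", 0.9, 0.8, 0.7)]
    table = residuals(recs, "product")
    assert table["predicted"].iloc[0] == pytest.approx(0.72)


def test_record_invariants_enforced():
    with pytest.raises(ValueError):
        MutantPairRecord("a", "b", -0.1, 0.8, 0.7)
    with pytest.raises(ValueError):
        MutantPairRecord("a", "b", float("nan"), 0.8, 0.7)


class TestBinnedSummary:
    def test_single_bin_constant_residuals(self):
        table = pd.DataFrame({"max_single": [0.9] * 3, "residual": [0.1] * 3})
        bs = binned_summary(table, n_bins=1)
        row = bs.table.iloc[0]
        assert row["count"] == 3
        assert row["median"] == row["q25"] == row["q75"] == pytest.approx(0.1)

    def test_median_of_symmetric_values(self):
        table = pd.DataFrame({"max_single": [0.9] * 3, "residual": [-1.0, 0.0, 1.0]})
        bs = binned_summary(table, n_bins=1)
        assert bs.table["median"].iloc[0] == pytest.approx(0.0)

    def test_out_of_range_excluded_and_empty_bins_reported(self):
        table = pd.DataFrame({"max_single": [0.3, 0.72], "residual": [5.0, 0.2]})
        bs = binned_summary(table)
        assert bs.table["count"].sum() == 1
        empty = bs.table[bs.table["count"] == 0]
        assert len(empty) == 9
        assert empty["median"].isna().all()

    def test_last_bin_closed_at_upper_edge(self):
        table = pd.DataFrame({"max_single": [1.0], "residual": [0.5]})
        bs = binned_summary(table)
        assert bs.table["count"].iloc[-1] == 1

    def test_bin_containing_072_is_070_075(self):
        table = pd.DataFrame({"max_single": [0.72], "residual": [0.0]})
        bs = binned_summary(table)
        idx = bs.bin_index_containing(0.72)
        assert bs.bin_edges[idx] == pytest.approx(0.70)
        assert bs.bin_edges[idx + 1] == pytest.approx(0.75)

    def test_quartiles_bracket_median_on_random_data(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            {"max_single": rng.uniform(0.5, 1.0, 2000),
             "residual": rng.normal(0, 0.1, 2000)}
        )
        bs = binned_summary(table)
        filled = bs.table.dropna()
        assert (filled["q25"] <= filled["median"] + 1e-12).all()
        assert (filled["median"] <= filled["q75"] + 1e-12).all()

    def test_unbiased_noise_gives_near_zero_bin_medians(self, product_records):
        """Monte-Carlo: product-law data under the product law has every
        bin median within three standard errors of zero."""
        sigma = product_records.attrs["noise_sigma"]
        bs = binned_summary(residuals(product_records, "product"))
        for _, row in bs.table.iterrows():
            if row["count"] == 0:
                continue
            tol = 3 * 1.2533 * sigma / np.sqrt(row["count"])
            assert abs(row["median"]) < max(tol, 1e-4)

    def test_precondition_validation(self):
        table = pd.DataFrame({"max_single": [0.9], "residual": [0.0]})
        with pytest.raises(ValueError):
            binned_summary(table, n_bins=0)
        with pytest.raises(ValueError):
            binned_summary(table, lo=1.0, hi=0.5)


def test_serialisation_roundtrip(tmp_path):
    table = residuals(_frame([("a", "b", 0.9, 0.8, 0.7)]), "product")
    path = tmp_path / "res.csv"
    table.to_csv(path, index=False)
    back = pd.read_csv(path)
    assert list(back.columns) == list(table.columns)
    bs = binned_summary(table)
    d = bs.to_json_dict()
    assert len(d["bin_edges"]) == 11
    assert len(d["bins"]) == 10


def test_records_to_frame_validates_columns():
    with pytest.raises(ValueError):
        records_to_frame(pd.DataFrame({"w_x": [1.0]}))
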