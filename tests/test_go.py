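"""Process selection, disjoint-pair enumeration, residual profiles,
intra- vs inter-process tails."""

import numpy as np
import pandas as pd
import pytest

from neutrality import go
from neutrality.laws import residuals
from neutrality.synth import SynthConfig, generate_dataset


def _annotation(sizes, prefix="P"):
    ann = {}
    g = 0
    for i, size in enumerate(sizes):
        for _ in range(size):
            ann[f"g{g}"] = {f"{prefix}{i}"}
            g += 1
    return ann


class TestSelectProcesses:
    def test_min_count_threshold(self):
        ann = _annotation([60, 55, 10])
        selected = go.select_processes(ann, set(ann), min_count=50)
        assert selected == {"P0", "P1"}

    def test_min_count_one_keeps_all_represented(self):
        ann = _annotation([60, 55, 10])
        assert len(go.select_processes(ann, set(ann), min_count=1)) == 3

    def test_only_dataset_genes_count(self):
        ann = _annotation([60])
        few = set(list(ann)[:10])
        assert go.select_processes(ann, few, min_count=50) == set()

    def test_empty_annotation_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert go.select_processes({}, {"g"}, 50) == set()
        assert "empty annotation" in caplog.text


class TestDisjointPairs:
    def test_shared_gene_pair_excluded(self):
        ann = {"g1": {"A"}, "g2": {"A", "B"}, "g3": {"B"}}
        pairs = go.enumerate_disjoint_pairs({"A", "B"}, ann, set(ann))
        assert pairs == []

    def test_disjoint_pair_included(self):
        ann = {"g1": {"A"}, "g2": {"B"}}
        pairs = go.enumerate_disjoint_pairs({"A", "B"}, ann, set(ann))
        assert len(pairs) == 1
        assert pairs[0].disjoint

    def test_five_disjoint_processes_give_ten_pairs(self):
        ann = _annotation([3, 3, 3, 3, 3])
        processes = {f"P{i}" for i in range(5)}
        assert len(go.enumerate_disjoint_pairs(processes, ann, set(ann))) == 10


def _bridge_table(pair_genes, rng):
    rows = []
    for qg, ag in pair_genes:
        w_x, w_y = rng.uniform(0.5, 1.0, 2)
        rows.append((qg, ag, w_x, w_y, w_x * w_y + rng.normal(0, 0.03)))
    return pd.DataFrame(rows, columns=["query_gene", "array_gene", "w_x", "w_y", "w_xy"])


class TestPairProfile:
    def test_no_records_gives_empty_bins(self):
        pair = go.ProcessPair("A", "B", frozenset({"g1"}), frozenset({"g2"}))
        table = residuals(_bridge_table([("x", "y")], np.random.default_rng(0)), "product")
        bs = go.pair_residual_profile(pair, table)
        assert (bs.table["count"] == 0).all()

    def test_profile_symmetric_in_role_and_order(self):
        rng = np.random.default_rng(1)
        table = residuals(
            _bridge_table([("a1", "b1"), ("b2", "a2"), ("a2", "b2")], rng), "product"
        )
        ab = go.ProcessPair("A", "B", frozenset({"a1", "a2"}), frozenset({"b1", "b2"}))
        ba = go.ProcessPair("B", "A", ab.gene_set_b, ab.gene_set_a)
        pd.testing.assert_frame_equal(
            go.pair_residual_profile(ab, table).table,
            go.pair_residual_profile(ba, table).table,
        )

    def test_product_data_product_law_centred_minimum_biased(self):
        """On product-generated data the product profile is centred on zero
        while the minimum law over-predicts (negative medians, worsening
        with mutation severity)."""
        cfg = SynthConfig(n_genes=400, n_pairs=30_000, law="product",
                          noise_sigma=0.03, n_processes=2,
                          genes_per_process=200, seed=11)
        table, ann = generate_dataset(cfg)
        pair = go.ProcessPair(
            "P000", "P001",
            frozenset(g for g, ps in ann.items() if "P000" in ps),
            frozenset(g for g, ps in ann.items() if "P001" in ps),
        )
        prod = go.pair_residual_profile(pair, residuals(table, "product")).table
        filled = prod[prod["count"] > 30]
        assert (filled["median"].abs() < 0.01).all()
        mini = go.pair_residual_profile(pair, residuals(table, "minimum")).table
        filled = mini[mini["count"] > 30]
        assert (filled["median"] < 0.0).all()
        # over-prediction worsens as the mutations get more severe
        assert filled["median"].iloc[0] < filled["median"].iloc[-1]


class TestIntraInterTails:
    def test_zero_residuals_zero_fractions(self):
        table = pd.DataFrame(
            {"query_gene": ["g1"], "array_gene": ["g2"], "residual": [0.0]}
        )
        ann = {"g1": {"A"}, "g2": {"A"}}
        out = go.intra_vs_inter_tails(table, ann, threshold=0.1)
        assert (out[["frac_pos", "frac_neg"]] == 0.0).all().all()

    def test_single_intra_positive_tail(self):
        table = pd.DataFrame(
            {"query_gene": ["g1"], "array_gene": ["g2"], "residual": [0.5]}
        )
        ann = {"g1": {"A"}, "g2": {"A"}}
        out = go.intra_vs_inter_tails(table, ann, threshold=0.1)
        intra = out.set_index("class").loc["intra"]
        assert intra["frac_pos"] == 1.0
        assert intra["frac_neg"] == 0.0

    def test_unannotated_records_excluded_and_counted(self):
        table = pd.DataFrame(
            {"query_gene": ["g1", "gx"], "array_gene": ["g2", "g2"],
             "residual": [0.5, 0.5]}
        )
        ann = {"g1": {"A"}, "g2": {"A"}}
        out = go.intra_vs_inter_tails(table, ann, threshold=0.1)
        assert out.attrs["n_unannotated_excluded"] == 1

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            go.intra_vs_inter_tails(pd.DataFrame(), {}, threshold=0.0)

    def test_noisier_intra_pairs_have_heavier_tails(self):
        """Extra intra-process noise (sigma 0.2 vs 0.05) produces strictly
        larger two-sided tail fractions for the intra class."""
        cfg = SynthConfig(n_genes=300, n_pairs=20_000, law="product",
                          noise_sigma=0.05, sigma_intra=0.2,
                          n_processes=3, genes_per_process=100, seed=5)
        table, ann = generate_dataset(cfg)
        out = go.intra_vs_inter_tails(
            residuals(table, "product"), ann, threshold=0.1
        ).set_index("class")
        assert out.loc["intra", "frac_pos"] > out.loc["inter", "frac_pos"]
        assert out.loc["intra", "frac_neg"] > out.loc["inter", "frac_neg"]


def test_annotation_tsv_reader(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text("# comment\ng1\tP1\ng1\tP2\ng2\tP1\n")
    ann = go.read_annotation_tsv(path)
    assert ann == {"g1": {"P1", "P2"}, "g2": {"P1"}}


def test_gaf_reader_filters_aspect_and_not(tmp_path):
    path = tmp_path / "x.gaf"
    lines = [
        "!gaf-version: 2.2",
        "\t".join(["DB", "X1", "GENE1", "", "GO:1", "ref", "IDA", "", "P"] + [""] * 8),
        "\t".join(["DB", "X2", "GENE1", "NOT", "GO:2", "ref", "IDA", "", "P"] + [""] * 8),
        "\t".join(["DB", "X3", "GENE2", "", "GO:3", "ref", "IEA", "", "F"] + [""] * 8),
    ]
    path.write_text("\n".join(lines) + "\n")
    ann = go.read_gaf(path)
    assert ann == {"GENE1": {"GO:1"}}
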