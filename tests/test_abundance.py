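"""Data layer: RPKM, functional classification, aggregation, top-k, TSV I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redunet import (
    AbundanceTable,
    FunctionalCatalogConfig,
    GeneCatalog,
    aggregate,
    classify_functions,
    compute_rpkm,
    load_abundance_tsv,
    load_catalog_tsv,
    load_metadata_tsv,
    make_metadata,
    top_features,
    write_table_tsv,
)


class TestComputeRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [
            (10, 1000, 1_000_000, 10.0),   # unit length, unit depth
            (0, 700, 3_000_000, 0.0),      # zero counts stay zero
            (50, 500, 2_000_000, 50.0),    # 50 / 0.5 / 2
        ],
    )
    def test_definition(self, count, length, total, expected):
        counts = pd.DataFrame({"g": [count]}, index=["s"])
        out = compute_rpkm(counts, pd.Series({"g": length}), pd.Series({"s": total}))
        assert out.data.loc["s", "g"] == pytest.approx(expected)

    @given(
        count=st.integers(0, 10_000),
        length=st.integers(100, 5000),
        total=st.integers(1_000, 10_000_000),
        scale=st.integers(2, 7),
    )
    @settings(max_examples=60, deadline=None)
    def test_linearity(self, count, length, total, scale):
        """RPKM is linear in counts, inverse in length and depth."""
        def rpkm(c, l, t):
            counts = pd.DataFrame({"g": [c]}, index=["s"])
            return compute_rpkm(counts, pd.Series({"g": l}), pd.Series({"s": t})).data.iloc[0, 0]

        base = rpkm(count, length, total)
        assert rpkm(count * scale, length, total) == pytest.approx(scale * base)
        assert rpkm(count, length * scale, total) == pytest.approx(base / scale)
        assert rpkm(count, length, total * scale) == pytest.approx(base / scale)

    def test_zero_depth_sample_rejected(self, caplog):
        counts = pd.DataFrame({"g": [5, 7]}, index=["ok", "dead"])
        out = compute_rpkm(counts, pd.Series({"g": 1000}),
                           pd.Series({"ok": 1_000_000, "dead": 0}))
        assert out.samples == ["ok"]

    def test_missing_length_gene_rejected(self):
        counts = pd.DataFrame({"g1": [5], "g2": [7]}, index=["s"])
        out = compute_rpkm(counts, pd.Series({"g1": 1000}), pd.Series({"s": 1_000_000}))
        assert out.features == ["g1"]


class TestClassifyFunctions:
    def test_lookup(self, tiny_catalog, tiny_config):
        out = classify_functions(tiny_catalog, tiny_config)
        assert out.frame.loc["g1", "func_class"] == "broad"
        assert out.frame.loc["g2", "func_class"] == "specialized"

    def test_default_catalog_split(self):
        cfg = FunctionalCatalogConfig.default()
        assert cfg.n_by_class() == {"broad": 15, "specialized": 4}
        # a catalog touching all 19 categories partitions 15/4 by class
        cats = list(cfg.category_class)
        frame = pd.DataFrame({
            "species": "sp", "category": cats, "pathway": "p", "length_bp": 500,
        }, index=pd.Index([f"g{i}" for i in range(len(cats))], name="gene_id"))
        out = classify_functions(GeneCatalog(frame), cfg)
        counts = out.frame["func_class"].value_counts()
        assert counts["broad"] == 15 and counts["specialized"] == 4

    def test_unmapped_category_raises(self, tiny_catalog):
        cfg = FunctionalCatalogConfig({"CatA": "broad"})
        with pytest.raises(ValueError, match="CatB"):
            classify_functions(tiny_catalog, cfg)


class TestAggregate:
    @pytest.fixture()
    def gene_table(self):
        data = pd.DataFrame(
            [[3.0, 4.0, 1.0, 2.0, 5.0], [1.0, 0.0, 2.0, 2.0, 0.0]],
            index=["s1", "s2"], columns=["g1", "g2", "g3", "g4", "g5"],
        )
        return AbundanceTable(data)

    def test_species_additivity(self, gene_table, tiny_catalog):
        out = aggregate(gene_table, tiny_catalog, by="species")
        assert out.data.loc["s1", "sp1"] == pytest.approx(7.0)  # g1 + g2

    def test_conservation(self, gene_table, tiny_catalog):
        out = aggregate(gene_table, tiny_catalog, by="category")
        assert np.allclose(out.data.sum(axis=1), gene_table.data.sum(axis=1), rtol=1e-12)

    def test_species_within_category_vs_bruteforce(self, gene_table, tiny_catalog, tiny_config):
        cat = classify_functions(tiny_catalog, tiny_config)
        out = aggregate(gene_table, cat, by="species", func_class="specialized")
        # brute force: filter genes by class, then sum per species
        keep = [g for g in gene_table.features
                if cat.frame.loc[g, "func_class"] == "specialized"]
        brute = gene_table.data[keep].T.groupby(cat.frame.loc[keep, "species"].values).sum().T
        pd.testing.assert_frame_equal(out.data, brute.sort_index(axis=1), check_names=False)

    def test_empty_group_raises(self, gene_table, tiny_catalog, tiny_config):
        cat = classify_functions(tiny_catalog, tiny_config)
        with pytest.raises(ValueError, match="func_class"):
            aggregate(gene_table, cat, by="species", func_class="nonexistent")


class TestTopFeatures:
    def test_identity_coverage(self):
        t = AbundanceTable(pd.DataFrame([[1.0, 2.0, 3.0]], index=["s"], columns=list("abc")))
        _, cov = top_features(t, 3)
        assert cov == pytest.approx(1.0)

    def test_hand_ranking(self):
        t = AbundanceTable(pd.DataFrame([[50.0, 30.0, 20.0]], index=["s"],
                                        columns=["A", "B", "C"]))
        out, cov = top_features(t, 2)
        assert set(out.features) == {"A", "B"}
        assert cov == pytest.approx(0.8)

    def test_coverage_monotone_in_k(self, default_dataset):
        _, table, catalog, _, _ = default_dataset
        from redunet import aggregate as agg
        sp = agg(table, catalog, by="species")
        covs = [top_features(sp, k)[1] for k in (4, 8, 12, 20, 40)]
        assert all(a <= b + 1e-12 for a, b in zip(covs, covs[1:]))

    def test_synthetic_top12_covers_95pct(self, default_dataset):
        """Top-12 species hold >95% of abundance, as in the study community."""
        _, table, catalog, _, _ = default_dataset
        from redunet import aggregate as agg
        sp = agg(table, catalog, by="species")
        _, cov = top_features(sp, 12)
        assert cov > 0.95

    def test_bad_k(self):
        t = AbundanceTable(pd.DataFrame([[1.0]], index=["s"], columns=["a"]))
        with pytest.raises(ValueError):
            top_features(t, 0)
        with pytest.raises(ValueError):
            top_features(t, 5)


class TestIO:
    def test_abundance_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        t = AbundanceTable(pd.DataFrame(rng.random((3, 3)) * 100,
                                        index=["s1", "s2", "s3"],
                                        columns=["g1", "g2", "g3"]))
        p = tmp_path / "t.tsv"
        write_table_tsv(t, p)
        back = load_abundance_tsv(p, orientation="samples_by_features")
        pd.testing.assert_frame_equal(back.data, t.data)

    def test_duplicate_row_id(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene\ts1\ns1\t1.0\ns1\t2.0\n")
        with pytest.raises(ValueError, match="s1"):
            load_abundance_tsv(p)

    def test_missing_catalog_column(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("gene_id\tspecies\tcategory\ng1\tsp1\tCatA\n")
        with pytest.raises(ValueError, match="length_bp"):
            load_catalog_tsv(p)

    def test_metadata_roundtrip_and_validation(self, tmp_path):
        meta = make_metadata(replicates=2)
        p = tmp_path / "meta.tsv"
        meta.to_csv(p, sep="\t")
        back = load_metadata_tsv(p)
        assert list(back["treatment"]) == list(meta["treatment"])
        # corrupted derived label rejected
        bad = meta.copy()
        bad.loc[bad.index[0], "treatment"] = "G+P+"
        pbad = tmp_path / "bad.tsv"
        bad.to_csv(pbad, sep="\t")
        with pytest.raises(ValueError, match="treatment"):
            load_metadata_tsv(pbad)
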