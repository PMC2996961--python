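import numpy as np
import pandas as pd
import pytest

from seedscreen import gsea_preranked as gp
from seedscreen.masking import known_gene_enrichment, mask_enriched


def guides_for(seed_map):
    """sirna_id -> guide with the given hexamer at nt 2-7."""
    return {sid: "G" + hexamer + "ACGTACGTACGTAC" for sid, hexamer in seed_map.items()}


class TestMaskEnriched:
    def test_no_enriched_seeds_is_identity(self):
        ranked = gp.make_ranked(["a", "b", "c"], [3.0, 2.0, 1.0])
        guides = guides_for({"a": "ACTTGA", "b": "CAAGGT", "c": "TGTCCA"})
        rep = mask_enriched(ranked, guides)
        assert rep.removed == []
        assert rep.retained["item_id"].tolist() == ["a", "b", "c"]

    def test_rank1_removed_promotes_rank2(self):
        ranked = gp.make_ranked(["a", "b", "c"], [3.0, 2.0, 1.0])
        guides = guides_for({"a": "ACTTGA", "b": "CAAGGT", "c": "TGTCCA"})
        rep = mask_enriched(ranked, guides, enriched_hexamers=["ACTTGA"])
        assert rep.removed == ["a"]
        assert rep.retained["item_id"].tolist() == ["b", "c"]
        assert rep.retained["rank"].tolist() == [1, 2]

    def test_heptamer_masking(self):
        ranked = gp.make_ranked(["a", "b"], [2.0, 1.0])
        guides = {"a": "GTCAAGGTACGTACGTACGTA", "b": "GACTTGAACGTACGTACGTAC"}
        rep = mask_enriched(ranked, guides, enriched_heptamers=["TCAAGGT"])
        assert rep.removed == ["a"]

    def test_table1_masked_by_enriched_flag(self, table1):
        # guides reconstructed so nt 2-7 reads the printed hexamer
        ranked = gp.make_ranked(table1["symbol"], table1["score"])
        guides = guides_for(dict(zip(table1["symbol"], table1["hexamer"])))
        enriched = table1.loc[table1["enriched_flag"] == "+", "hexamer"].unique()
        rep = mask_enriched(ranked, guides, enriched_hexamers=enriched)
        assert len(rep.removed) == 10
        assert set(rep.removed) == {
            "TEGT", "CCNT1", "ACO1", "HAPIP", "LRPAP1", "INADL", "GPR132",
            "ADORA1", "MAGED1", "MYC",
        }

    def test_substring_mode_removes_on_any_occurrence(self):
        ranked = gp.make_ranked(["a", "b"], [2.0, 1.0])
        guides = {
            "a": "GGGGGGGGGGACTTGAGGGGG",  # seed deep in the 3' half
            "b": "GGGGGGGGGGGGGGGGGGGGG",
        }
        assert mask_enriched(ranked, guides, ["ACTTGA"]).removed == []
        assert mask_enriched(ranked, guides, ["ACTTGA"], mode="substring").removed == ["a"]

    def test_order_of_retained_preserved(self):
        rng = np.random.default_rng(0)
        n = 200
        ids = [f"s{i}" for i in range(n)]
        ranked = gp.make_ranked(ids, rng.normal(size=n))
        hexes = rng.choice(["ACTTGA", "CAAGGT", "TGTCCA", "AAAAAA"], n)
        guides = guides_for(dict(zip(ids, hexes)))
        rep = mask_enriched(ranked, guides, enriched_hexamers=["ACTTGA", "CAAGGT"])
        kept_order = [i for i in ranked["item_id"] if i not in set(rep.removed)]
        assert rep.retained["item_id"].tolist() == kept_order
        # removed count equals direct seed-membership count
        assert len(rep.removed) == int(np.isin(hexes, ["ACTTGA", "CAAGGT"]).sum())

    def test_unknown_sirna_rejected(self):
        ranked = gp.make_ranked(["a"], [1.0])
        with pytest.raises(KeyError):
            mask_enriched(ranked, {}, ["ACTTGA"])

    def test_bad_seed_length_rejected(self):
        ranked = gp.make_ranked(["a"], [1.0])
        with pytest.raises(ValueError):
            mask_enriched(ranked, guides_for({"a": "ACTTGA"}),
                          enriched_hexamers=["ACTTG"])


class TestKnownGeneEnrichment:
    def test_top_loaded_gene_set_is_enriched(self):
        rng = np.random.default_rng(1)
        n = 400
        ids = [f"s{i}" for i in range(n)]
        scores = rng.normal(size=n)
        scores[:20] += 2.5
        ranked = gp.make_ranked(ids, scores)
        gene_of = {f"s{i}": f"G{i // 2}" for i in range(n)}
        genes = {gene_of[i] for i in ids[:20]}
        row = known_gene_enrichment(ranked, gene_of, genes, n_perm=300, rng_seed=0)
        assert row["p_nominal"] < 0.05
        assert row["nes"] > 0

    def test_random_gene_set_not_extreme(self):
        rng = np.random.default_rng(2)
        n = 400
        ranked = gp.make_ranked([f"s{i}" for i in range(n)], rng.normal(size=n))
        gene_of = {f"s{i}": f"G{i // 2}" for i in range(n)}
        ps = []
        for j in range(20):
            genes = set(rng.choice([f"G{g}" for g in range(n // 2)], 12, replace=False))
            row = known_gene_enrichment(ranked, gene_of, genes, n_perm=200, rng_seed=j)
            ps.append(row["p_nominal"])
        # roughly uniform nominal p under the null: no pile-up at either end
        assert 0.02 < np.median(ps) < 0.98
        assert (np.array(ps) <= 0.05).mean() <= 0.25

    def test_absent_genes_skipped_and_empty_set_rejected(self, caplog):
        ranked = gp.make_ranked(["a", "b", "c"], [3.0, 2.0, 1.0])
        gene_of = {"a": "G1", "b": "G2", "c": "G3"}
        with caplog.at_level("WARNING"):
            row = known_gene_enrichment(ranked, gene_of, ["G1", "NOPE"],
                                        n_perm=100, rng_seed=0)
        assert "NOPE" in caplog.text
        assert row["size"] == 1
        with pytest.raises(ValueError):
            known_gene_enrichment(ranked, gene_of, ["NOPE"], n_perm=100)

    def test_set_covering_universe_rejected(self):
        ranked = gp.make_ranked(["a", "b"], [2.0, 1.0])
        gene_of = {"a": "G1", "b": "G1"}
        with pytest.raises(Exception):
            known_gene_enrichment(ranked, gene_of, ["G1"], n_perm=100)
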