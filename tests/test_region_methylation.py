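import numpy as np
import pandas as pd
import pytest

from methylquad import region_methylation as rm
from methylquad.differential_testing import differential_records, significant
from methylquad.io_formats import Manifest, OmicsMatrix


def beta_matrix(values: dict, n_case: int):
    df = pd.DataFrame(values).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    labels = pd.Series(
        ["case"] * n_case + ["control"] * (df.shape[1] - n_case), index=df.columns
    )
    return OmicsMatrix(df, labels, "methylation_beta")


def manifest_from(rows):
    return Manifest(
        pd.DataFrame(rows, columns=["probe_id", "chromosome", "position", "gene", "region"])
    )


class TestAggregateRegions:
    def test_region_mean_of_two_cpgs(self):
        mat = beta_matrix({"cg1": [0.2, 0.2, 0.2, 0.2], "cg2": [0.4, 0.4, 0.4, 0.4]}, 2)
        man = manifest_from(
            [("cg1", "1", 10, "A", "TSS200"), ("cg2", "1", 20, "A", "TSS200")]
        )
        out = rm.aggregate_regions(mat, man)
        assert np.allclose(out.values.loc["A|TSS200"], 0.3)

    def test_single_cpg_region_is_identity(self):
        mat = beta_matrix({"cg1": [0.25, 0.3, 0.4, 0.5]}, 2)
        man = manifest_from([("cg1", "1", 10, "A", "Body")])
        out = rm.aggregate_regions(mat, man)
        assert out.values.loc["A|Body"].tolist() == [0.25, 0.3, 0.4, 0.5]

    def test_multi_mapped_probe_contributes_to_both_keys(self):
        mat = beta_matrix({"cg1": [0.2, 0.2, 0.6, 0.6]}, 2)
        man = manifest_from(
            [("cg1", "1", 10, "A", "TSS200"), ("cg1", "1", 10, "B", "Body")]
        )
        out = rm.aggregate_regions(mat, man)
        assert set(out.feature_ids) == {"A|TSS200", "B|Body"}
        assert (out.values.loc["A|TSS200"] == out.values.loc["B|Body"]).all()

    def test_intergenic_probes_excluded(self):
        mat = beta_matrix({"cg1": [0.2, 0.2, 0.6, 0.6], "cg9": [0.5, 0.5, 0.5, 0.5]}, 2)
        man = manifest_from(
            [("cg1", "1", 10, "A", "TSS200"), ("cg9", "1", 99, "", "intergenic")]
        )
        out = rm.aggregate_regions(mat, man)
        assert out.feature_ids == ["A|TSS200"]

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(4)
        probes = [f"cg{i}" for i in range(12)]
        vals = {p: rng.uniform(0, 1, 6) for p in probes}
        man_rows = [(p, "1", 10 + i, "G", "Body") for i, p in enumerate(probes)]
        mat = beta_matrix(vals, 3)
        fwd = rm.aggregate_regions(mat, manifest_from(man_rows))
        perm = np.random.default_rng(1).permutation(12)
        mat2 = OmicsMatrix(mat.values.iloc[perm], mat.group_labels, "methylation_beta")
        rev = rm.aggregate_regions(mat2, manifest_from([man_rows[i] for i in perm]))
        assert np.allclose(fwd.values, rev.values)


def strong(case: float, ctrl: float, jitter=0.0):
    """8v8 sample row with a clear group difference."""
    rng = np.random.default_rng(99)
    return np.clip(
        np.concatenate([np.full(8, case), np.full(8, ctrl)])
        + rng.normal(0, 0.01 + jitter, 16),
        0, 1,
    )


class TestDmrDmg:
    def test_single_hyper_dmr_gives_hyper_dmg(self):
        region = beta_matrix({"A|TSS200": strong(0.8, 0.3), "A|Body": strong(0.5, 0.5)}, 8)
        calls = rm.call_dmr_dmg(region)
        (call,) = calls
        assert call.gene == "A" and call.direction == "hyper"
        assert call.dmr_regions == frozenset({"TSS200"})

    def test_mixed_directions_are_conflicted(self):
        region = beta_matrix({"A|TSS200": strong(0.8, 0.3), "A|Body": strong(0.2, 0.7)}, 8)
        (call,) = rm.call_dmr_dmg(region)
        assert call.conflicted and call.direction is None
        assert rm.dmg_genes([call]) == []

    def test_gene_without_dmr_absent(self):
        region = beta_matrix({"A|TSS200": strong(0.5, 0.5, jitter=0.05)}, 8)
        assert rm.call_dmr_dmg(region) == []

    def test_every_dmg_backed_by_dmr_in_same_direction(self):
        rng = np.random.default_rng(6)
        rows = {}
        for g in range(20):
            for region in ("TSS200", "Body"):
                base = rng.uniform(0.2, 0.8)
                shift = rng.choice([-0.3, 0.0, 0.3])
                case = np.clip(base + shift + rng.normal(0, 0.02, 8), 0, 1)
                ctrl = np.clip(base + rng.normal(0, 0.02, 8), 0, 1)
                rows[f"G{g}|{region}"] = np.concatenate([case, ctrl])
        region_mat = beta_matrix(rows, 8)
        records = significant(differential_records(region_mat))
        dmr_dirs = {}
        for key, row in records.iterrows():
            gene, _ = rm.split_region_key(key)
            dmr_dirs.setdefault(gene, set()).add(row["direction"])
        for call in rm.call_dmr_dmg(region_mat):
            if call.conflicted:
                assert dmr_dirs[call.gene] == {"up", "down"}
            else:
                expected = "up" if call.direction == "hyper" else "down"
                assert dmr_dirs[call.gene] == {expected}
                assert len(call.dmr_regions) >= 1

    def test_min_cpgs_floor_excludes_sparse_regions(self):
        region = beta_matrix({"A|TSS200": strong(0.8, 0.3)}, 8)
        counts = pd.Series({"A|TSS200": 1})
        assert rm.call_dmr_dmg(region, min_cpgs=2, cpg_counts=counts) == []


class TestDmcDistribution:
    def make_records(self, probes, directions):
        return pd.DataFrame(
            {
                "mean_case": 0.5, "mean_control": 0.4, "log2FC": 1.0, "delta": 0.1,
                "p_value": 0.01, "direction": directions,
            },
            index=pd.Index(probes, name="feature_id"),
        )

    def test_all_dmcs_in_body(self):
        probes = [f"cg{i}" for i in range(10)]
        man = manifest_from([(p, "1", i + 1, "A", "Body") for i, p in enumerate(probes)])
        rec = self.make_records(probes, ["up"] * 10)
        table = rm.dmc_region_distribution(rec, man)
        assert table.loc["Body", "count"] == 10
        assert table.loc["Body", "percent"] == 100.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(8)
        probes = [f"cg{i}" for i in range(50)]
        regions = rng.choice(["TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"], 50)
        man = manifest_from(
            [(p, "1", i + 1, "A", r) for i, (p, r) in enumerate(zip(probes, regions))]
        )
        dirs = rng.choice(["up", "down", "none"], 50, p=[0.4, 0.4, 0.2])
        table = rm.dmc_region_distribution(self.make_records(probes, dirs), man)
        assert table["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(15)
        probes = [f"cg{i}" for i in range(50)]
        genes = rng.choice(["A", "B", "C"], 50)
        regions = rng.choice(["TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"], 50)
        rows = [(p, "1", i + 1, g, r) for i, (p, g, r) in enumerate(zip(probes, genes, regions))]
        man = manifest_from(rows)
        dirs = rng.choice(["up", "down", "none"], 50)
        rec = self.make_records(probes, dirs)
        subset = ["A", "C"]
        table = rm.dmc_region_distribution(rec, man, gene_subset=subset)
        dmc_set = {p for p, d in zip(probes, dirs) if d != "none"}
        for region in table.index:
            brute = sum(
                1 for p, g, r in zip(probes, genes, regions)
                if p in dmc_set and g in subset and r == region
            )
            assert table.loc[region, "count"] == brute


class TestCombinationTable:
    def call(self, gene, direction, regions):
        return rm.DmgCall(gene, direction, frozenset(regions), conflicted=False)

    def test_all_single_region_fraction_is_one(self):
        calls = [self.call(f"G{i}", "hyper", ["TSS200"]) for i in range(5)]
        fr = rm.combination_fractions(rm.dmr_combination_table(calls))
        assert fr["hyper"]["single_region"] == 1.0

    def test_exact_subset_semantics(self):
        calls = [self.call("G1", "hyper", ["TSS200", "5UTR"])]
        table = rm.dmr_combination_table(calls)
        assert len(table) == 1
        assert table.iloc[0]["regions"] == "TSS200+5UTR"
        assert table.iloc[0]["count"] == 1

    def test_fractions_match_brute_force_enumeration(self):
        rng = np.random.default_rng(30)
        all_regions = ["TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"]
        calls = []
        for i in range(30):
            k = int(rng.integers(1, 5))
            regions = rng.choice(all_regions, size=k, replace=False)
            direction = str(rng.choice(["hyper", "hypo"]))
            calls.append(self.call(f"G{i}", direction, regions))
        fr = rm.combination_fractions(rm.dmr_combination_table(calls))
        for direction in ("hyper", "hypo"):
            mine = [c for c in calls if c.direction == direction]
            single = sum(1 for c in mine if len(c.dmr_regions) == 1) / len(mine)
            three = sum(1 for c in mine if len(c.dmr_regions) >= 3) / len(mine)
            assert fr[direction]["single_region"] == pytest.approx(single)
            assert fr[direction]["three_plus_regions"] == pytest.approx(three)
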