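import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phnatlas import synth, taxonomy
from phnatlas.io import AbundanceProfile, AlignmentBlock, ValidationError
from conftest import toy_catalog


def brute_force_patristic(tree: dendropy.Tree) -> dict:
    """Independent oracle: Dijkstra-free path sums over the unrooted tree
    graph, never touching dendropy's distance matrix."""
    adjacency: dict = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adjacency.setdefault(id(node), []).append((id(child), w))
            adjacency.setdefault(id(child), []).append((id(node), w))
    leaves = {id(lf): lf.taxon.label for lf in tree.leaf_node_iter()}

    out = {}
    for start in leaves:
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adjacency.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for other, label in leaves.items():
            out[(leaves[start], label)] = dist[other]
    return out


def parse(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


class TestTrimAndDedup:
    def test_gap_free_distinct_alignment_unchanged(self):
        aln = AlignmentBlock(["a", "b"], ["ACDE", "ACDF"])
        out = taxonomy.trim_and_dedup(aln)
        assert out.rows == aln.rows and out.names == aln.names

    def test_column_above_ten_percent_gaps_removed(self):
        rows = ["AC"] * 8 + ["-C"] * 2  # col 0: 20% gaps, col 1: none
        aln = AlignmentBlock([f"s{i}" for i in range(10)], rows)
        out = taxonomy.trim_and_dedup(aln)
        assert out.n_positions == 1
        # rows collapse post-trim: all become "C"
        assert out.n_sequences == 1 and out.names == ["s0"]

    def test_exactly_ten_percent_column_is_kept(self):
        rows = [f"A{chr(66 + i)}" for i in range(9)] + ["-Z"]
        aln = AlignmentBlock([f"s{i}" for i in range(10)], rows)
        out = taxonomy.trim_and_dedup(aln)
        assert out.n_positions == 2

    def test_duplicates_after_trim_keep_first_name(self):
        aln = AlignmentBlock(["first", "second"], ["A-C", "A+C".replace("+", "-")])
        out = taxonomy.trim_and_dedup(aln, max_gap_fraction=0.4)
        assert out.names == ["first"]

    def test_fully_gapped_alignment_rejected(self):
        aln = AlignmentBlock(["a", "b", "c"], ["--", "--", "A-"])
        with pytest.raises(ValidationError, match="fully gapped"):
            taxonomy.trim_and_dedup(aln, max_gap_fraction=0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_idempotent_and_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(3, 12)), int(rng.integers(2, 15))
        mat = rng.choice(list("AC-"), size=(n, m), p=[0.45, 0.45, 0.1])
        aln = AlignmentBlock(
            [f"s{i}" for i in range(n)], ["".join(r) for r in mat]
        )
        keep = (mat == "-").mean(axis=0) <= 0.10
        if not keep.any():
            return
        once = taxonomy.trim_and_dedup(aln)
        # column oracle: direct gap counting
        assert once.n_positions == int(keep.sum())
        # duplicate oracle: set of post-trim strings
        expected_rows = ["".join(r[keep]) for r in mat]
        assert once.n_sequences == len(dict.fromkeys(expected_rows))
        post = np.array([list(r) for r in once.rows])
        if ((post == "-").mean(axis=0) <= 0.10).all():
            twice = taxonomy.trim_and_dedup(once)
            assert twice.rows == once.rows


class TestCommonRankPrefix:
    def test_whole_rank_prefix_only(self):
        assert taxonomy.common_rank_prefix(["Alpha;SAR11", "Alpha;SAR116"]) == "Alpha"

    def test_no_shared_rank_is_unclassified(self):
        assert (
            taxonomy.common_rank_prefix(["Alpha;SAR11", "Gamma;Vibrio"])
            == taxonomy.UNCLASSIFIED
        )


class TestClassifyQueries:
    def test_sister_query_gets_reference_taxon(self):
        tree = parse("((Q:0.05,A:0.1):1.0,(B:0.5,C:0.5):1.0);")
        bins = taxonomy.classify_queries(
            tree, {"A": "Alphaproteobacteria;SAR11", "B": "t2", "C": "t3"}
        )
        row = bins.table.set_index("gene_id").loc["Q"]
        assert row["taxon"] == "Alphaproteobacteria;SAR11"
        assert row["support"] == pytest.approx(0.15)
        assert not row["tie_flag"]

    def test_equidistant_tie_truncates_to_common_rank(self):
        tree = parse("(Q:1.0,A:1.0,B:1.0);")
        bins = taxonomy.classify_queries(tree, {"A": "Alpha;SAR11", "B": "Alpha;SAR116"})
        row = bins.table.set_index("gene_id").loc["Q"]
        assert row["taxon"] == "Alpha"
        assert row["tie_flag"]

    def test_no_references_rejected(self):
        tree = parse("(Q:1.0,R:1.0);")
        with pytest.raises(ValidationError, match="reference"):
            taxonomy.classify_queries(tree, {})

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_patristic_oracle(self, seed):
        tree, taxonomy_map, truth = synth.generate_reference_tree(
            20, 10, 5, seed=seed
        )
        bins = taxonomy.classify_queries(tree, taxonomy_map).table.set_index("gene_id")
        oracle = brute_force_patristic(tree)
        refs = sorted(taxonomy_map)
        for query in truth:
            dists = {r: oracle[(query, r)] for r in refs}
            best = min(dists, key=lambda r: (dists[r], r))
            assert bins.loc[query, "support"] == pytest.approx(dists[best], rel=1e-9)
            assert bins.loc[query, "taxon"] == taxonomy_map[best] == truth[query]

    @pytest.mark.parametrize("seed", range(3))
    def test_rerooting_does_not_change_classifications(self, seed):
        tree, taxonomy_map, _ = synth.generate_reference_tree(15, 6, 4, seed=seed)
        before = taxonomy.classify_queries(tree, taxonomy_map).table
        internal_edges = [
            e for e in tree.preorder_edge_iter()
            if e.head_node.child_nodes() and e.tail_node is not None
        ]
        edge = internal_edges[seed % len(internal_edges)]
        tree.reroot_at_edge(edge, update_bipartitions=True)
        after = taxonomy.classify_queries(tree, taxonomy_map).table
        merged = before.merge(after, on="gene_id", suffixes=("_a", "_b"))
        assert (merged["taxon_a"] == merged["taxon_b"]).all()
        assert np.allclose(merged["support_a"], merged["support_b"], rtol=1e-9)


def _noise_free_community(copy_model, seed=31):
    config = synth.SimulationConfig(
        n_genomes=48, n_samples=6, copy_model=copy_model, noise_free=True, seed=seed
    )
    truth, catalog = synth.generate_community(config)
    dataset = synth.simulate_profiles(truth, catalog, config)
    focal = catalog.table[catalog.table["function_id"] == config.focal_function]
    bins = dict(zip(focal["gene_id"], focal["taxon_bin"]))  # truth bins
    return dataset, catalog, config, bins


class TestTaxonContribution:
    def test_single_taxon_contributes_everything(self):
        catalog = toy_catalog([("f1", "COG3627", 900), ("m1", "COG0468", 1000)])
        profile = AbundanceProfile(
            pd.DataFrame({"s1": [0.4, 0.2]}, index=["f1", "m1"])
        )
        out = taxonomy.taxon_contribution(profile, {"f1": "T"}, catalog)
        assert out.loc[out["taxon"] == "T", "contribution"].iloc[0] == 1.0

    def test_three_to_one_split(self):
        catalog = toy_catalog(
            [("f1", "COG3627", 900), ("f2", "COG3627", 900), ("m1", "COG0468", 1000)]
        )
        profile = AbundanceProfile(
            pd.DataFrame({"s1": [0.3, 0.1, 0.5]}, index=["f1", "f2", "m1"])
        )
        out = taxonomy.taxon_contribution(
            profile, {"f1": "A", "f2": "B"}, catalog
        ).set_index("taxon")
        assert out.loc["A", "contribution"] == pytest.approx(0.75)
        assert out.loc["B", "contribution"] == pytest.approx(0.25)

    def test_unbinned_genes_pool_into_unclassified(self):
        catalog = toy_catalog(
            [("f1", "COG3627", 900), ("f2", "COG3627", 900), ("m1", "COG0468", 1000)]
        )
        profile = AbundanceProfile(
            pd.DataFrame({"s1": [0.3, 0.1, 0.5]}, index=["f1", "f2", "m1"])
        )
        out = taxonomy.taxon_contribution(profile, {"f1": "A"}, catalog).set_index("taxon")
        assert out.loc[taxonomy.UNCLASSIFIED, "contribution"] == pytest.approx(0.25)

    def test_zero_total_abundance_is_missing(self):
        catalog = toy_catalog([("f1", "COG3627", 900), ("m1", "COG0468", 1000)])
        profile = AbundanceProfile(
            pd.DataFrame({"s1": [0.0, 0.5]}, index=["f1", "m1"])
        )
        out = taxonomy.taxon_contribution(profile, {"f1": "T"}, catalog)
        assert out["contribution"].isna().all()

    @pytest.mark.parametrize("seed", range(5))
    def test_contributions_sum_to_one_and_survive_permutation(self, seed):
        dataset, catalog, config, bins = _noise_free_community(
            {0: 0.4, 1: 0.6}, seed=40 + seed
        )
        out = taxonomy.taxon_contribution(dataset.profile, bins, catalog)
        sums = out.groupby("sample_id")["contribution"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(dataset.profile.values))
        shuffled = AbundanceProfile(dataset.profile.values.iloc[perm])
        out2 = taxonomy.taxon_contribution(shuffled, bins, catalog)
        merged = out.merge(out2, on=["sample_id", "taxon"], suffixes=("_a", "_b"))
        assert np.allclose(merged["contribution_a"], merged["contribution_b"])


class TestTaxonEnrichment:
    def test_all_single_copy_carriers_give_100_percent(self):
        dataset, catalog, config, bins = _noise_free_community({1: 1.0})
        out = taxonomy.taxon_enrichment(
            dataset.profile, bins, catalog, config.scg_functions
        )
        assert np.allclose(out["percent_in_taxon"], 100.0, rtol=1e-9)

    def test_triple_copy_carriers_give_300_percent(self):
        dataset, catalog, config, bins = _noise_free_community({3: 1.0})
        out = taxonomy.taxon_enrichment(
            dataset.profile, bins, catalog, config.scg_functions
        )
        assert np.allclose(out["percent_in_taxon"], 300.0, rtol=1e-9)

    def test_matches_truth_table_oracle_per_taxon(self):
        dataset, catalog, config, bins = _noise_free_community({0: 0.5, 1: 0.5})
        truth = dataset.truth
        out = taxonomy.taxon_enrichment(
            dataset.profile, bins, catalog, config.scg_functions
        ).set_index(["sample_id", "taxon"])
        copies = truth.copy_number[config.focal_function]
        for sample in dataset.profile.samples:
            ab = truth.genome_abundance.loc[sample]
            for taxon in config.taxa:
                members = truth.genome_taxon[truth.genome_taxon == taxon].index
                expected = 100.0 * float(
                    (ab[members] * copies[members]).sum() / ab[members].sum()
                )
                got = out.loc[(sample, taxon), "percent_in_taxon"]
                assert got == pytest.approx(expected, rel=1e-9)
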