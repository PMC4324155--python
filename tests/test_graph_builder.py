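"""Seeded neighborhood-graph construction against independent oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import hicgraph as hg

from conftest import random_instance


def _tiny(frag_intervals, genes, contact_rows, chrom="c"):
    rows = [
        (i, chrom, s, e, e - s, 0.5, 1.0) for i, (s, e) in enumerate(frag_intervals)
    ]
    fm = hg.FragmentMap(pd.DataFrame(rows, columns=hg.FragmentMap.COLUMNS))
    gt = hg.GeneTable(hg.GeneAnnotation(sym, chrom, s, e) for sym, s, e in genes)
    ct = hg.ContactTable(
        pd.DataFrame(contact_rows, columns=["frag_a", "frag_b", "count"])
    )
    return fm, gt, hg.overlap_genes(fm, gt), ct


def bfs_oracle(contacts, fragments, genes, seeds, level, min_weight=1):
    """Independent brute-force construction: quadratic overlaps + nx BFS."""
    frag_iv = {f.id: (f.chrom, f.start, f.end) for f in fragments}
    gene_of_frag = {}
    for fid, (c, s, e) in frag_iv.items():
        gene_of_frag[fid] = [
            g.symbol for g in genes if g.chrom == c and g.start < e and s < g.end
        ]
    support = {}
    for fa, fb, cnt in contacts.rows():
        seen = set()
        for ga in gene_of_frag.get(fa, []):
            for gb in gene_of_frag.get(fb, []):
                if ga != gb:
                    seen.add((min(ga, gb), max(ga, gb)))
        for key in seen:
            support[key] = support.get(key, 0) + cnt
    g = nx.Graph()
    g.add_nodes_from(seeds)
    for (a, b), w in support.items():
        if w >= min_weight:
            g.add_edge(a, b, weight=w)
    levels = {}
    for s in seeds:
        if s in g:
            for n, d in nx.single_source_shortest_path_length(g, s, cutoff=level).items():
                levels[n] = min(levels.get(n, d), d)
    for s in seeds:
        levels[s] = 0
    edges = {
        (min(a, b), max(a, b))
        for a, b in g.edges
        if a in levels and b in levels and min(levels[a], levels[b]) <= level - 1
    }
    return levels, edges


class TestBuildExamples:
    def test_single_contact_creates_edge(self):
        fm, gt, fg, ct = _tiny(
            [(0, 100), (100, 200), (200, 300), (300, 400)],
            [("A", 0, 100), ("B", 300, 400)],
            [(0, 3, 1)],
        )
        g = hg.build_neighborhood(["A"], ct, fg, gt)
        assert g.nodes() == ["A", "B"]
        assert g.level("A") == 0 and g.level("B") == 1
        assert g.g.edges["A", "B"]["weight"] == 1

    def test_chain_levels(self):
        fm, gt, fg, ct = _tiny(
            [(0, 100), (100, 200), (200, 300), (300, 400), (400, 500), (500, 600)],
            [("A", 0, 100), ("B", 200, 300), ("C", 400, 500)],
            [(0, 2, 1), (2, 4, 1)],
        )
        g1 = hg.build_neighborhood(["A"], ct, fg, gt, hg.BuildConfig(level=1))
        assert g1.edges() == [("A", "B")]
        g2 = hg.build_neighborhood(["A"], ct, fg, gt, hg.BuildConfig(level=2))
        assert g2.edges() == [("A", "B"), ("B", "C")]
        assert g2.level("C") == 2

    def test_unknown_seed_named_in_error(self):
        fm, gt, fg, ct = _tiny([(0, 100)], [("A", 0, 100)], [])
        with pytest.raises(KeyError, match="NOPE"):
            hg.build_neighborhood(["NOPE"], ct, fg, gt)

    def test_seed_without_fragments_warns_and_isolates(self):
        fm, gt, fg, ct = _tiny(
            [(0, 100)], [("A", 0, 100)], [], chrom="c"
        )
        # gene on the same chrom but zero-overlap after clamping
        gt2 = hg.GeneTable(
            [hg.GeneAnnotation("A", "c", 0, 100), hg.GeneAnnotation("B", "c", 100, 200)]
        )
        fg2 = hg.overlap_genes(fm, gt2)
        with pytest.warns(UserWarning, match="overlaps no restriction fragment"):
            g = hg.build_neighborhood(["B"], ct, fg2, gt2)
        assert g.nodes() == ["B"] and g.n_edges == 0

    def test_min_edge_weight_thresholds_support(self):
        fm, gt, fg, ct = _tiny(
            [(0, 100), (100, 200), (200, 300), (300, 400)],
            [("A", 0, 100), ("B", 300, 400)],
            [(0, 3, 1)],
        )
        g = hg.build_neighborhood(["A"], ct, fg, gt, hg.BuildConfig(min_edge_weight=2))
        assert g.nodes() == ["A"] and g.n_edges == 0

    def test_shared_fragment_pair_counted_once_per_gene_pair(self):
        # both genes overlap both fragments of one contact row
        fm, gt, fg, ct = _tiny(
            [(0, 100), (100, 200)],
            [("A", 0, 200), ("B", 50, 150)],
            [(0, 1, 3)],
        )
        g = hg.build_neighborhood(["A"], ct, fg, gt)
        assert g.g.edges["A", "B"]["weight"] == 3


class TestBuildProperties:
    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            fm, gt, ct = random_instance(rng)
            fg = hg.overlap_genes(fm, gt)
            seeds = [gt.symbols[0]]
            g = hg.build_neighborhood(seeds, ct, fg, gt, hg.BuildConfig(level=3))
            levels, edges = bfs_oracle(ct, fm, gt, seeds, 3)
            assert {n: g.level(n) for n in g.nodes()} == levels
            assert set(g.edges()) == edges

    def test_level_monotonicity(self, small_dataset, small_contacts):
        contacts, _ = small_contacts
        fg = hg.overlap_genes(small_dataset.fragments, small_dataset.genes)
        seeds = [small_dataset.genes.symbols[0]]
        prev_nodes, prev_edges = set(), set()
        for level in range(1, 5):
            g = hg.build_neighborhood(
                seeds, contacts, fg, small_dataset.genes, hg.BuildConfig(level=level)
            )
            nodes, edges = set(g.nodes()), set(g.edges())
            assert prev_nodes <= nodes and prev_edges <= edges
            prev_nodes, prev_edges = nodes, edges

    def test_seed_symmetry_union(self):
        rng = np.random.default_rng(3)
        fm, gt, ct = random_instance(rng, n_genes=30, n_contacts=200)
        fg = hg.overlap_genes(fm, gt)
        x, y = gt.symbols[0], gt.symbols[1]
        g_xy = hg.build_neighborhood([x, y], ct, fg, gt)
        for s in (x, y):
            g_s = hg.build_neighborhood([s], ct, fg, gt)
            assert set(g_s.nodes()) <= set(g_xy.nodes())
            assert set(g_s.edges()) <= set(g_xy.edges())

    def test_byte_identical_serialization(self, tmp_path, small_dataset, small_contacts):
        contacts, _ = small_contacts
        fg = hg.overlap_genes(small_dataset.fragments, small_dataset.genes)
        seeds = [small_dataset.genes.symbols[0]]
        outs = []
        for tag in ("a", "b"):
            g = hg.build_neighborhood(seeds, contacts, fg, small_dataset.genes)
            n, e = tmp_path / f"n{tag}.tsv", tmp_path / f"e{tag}.tsv"
            g.write_tsv(n, e)
            outs.append((n.read_bytes(), e.read_bytes()))
        assert outs[0] == outs[1]


class TestMerge:
    def _single_edge(self, a, b, coords):
        g = nx.Graph()
        for sym in (a, b):
            c, s, e = coords[sym]
            g.add_node(sym, chrom=c, start=s, end=e, level=0 if sym == a else 1)
        g.add_edge(a, b, weight=1, frag_pairs=((0, 1),))
        return hg.NeighborhoodGraph(g, seeds=[a])

    def test_merge_with_empty_is_identity(self):
        coords = {"A": ("c", 0, 100), "B": ("c", 200, 300)}
        g = self._single_edge("A", "B", coords)
        merged = hg.merge_graphs(g, hg.NeighborhoodGraph())
        assert merged.node_table().equals(g.node_table())
        assert merged.edge_table().equals(g.edge_table())

    def test_merge_self_idempotent_with_max(self):
        coords = {"A": ("c", 0, 100), "B": ("c", 200, 300)}
        g = self._single_edge("A", "B", coords)
        merged = hg.merge_graphs(g, g, weight_policy="max")
        assert merged.edge_table().equals(g.edge_table())

    def test_merge_path(self):
        coords = {"A": ("c", 0, 100), "B": ("c", 200, 300), "C": ("c", 400, 500)}
        ab = self._single_edge("A", "B", coords)
        bc = self._single_edge("B", "C", coords)
        merged = hg.merge_graphs(ab, bc)
        assert merged.edges() == [("A", "B"), ("B", "C")]
        assert merged.level("B") == 0  # min level wins (seed in bc)

    def test_conflicting_coordinates_error(self):
        ab = self._single_edge("A", "B", {"A": ("c", 0, 100), "B": ("c", 200, 300)})
        ab2 = self._single_edge("A", "B", {"A": ("c", 0, 99), "B": ("c", 200, 300)})
        with pytest.raises(ValueError, match="conflicting"):
            hg.merge_graphs(ab, ab2)

    def test_sum_policy_adds_weights(self):
        coords = {"A": ("c", 0, 100), "B": ("c", 200, 300)}
        g = self._single_edge("A", "B", coords)
        merged = hg.merge_graphs(g, g, weight_policy="sum")
        assert merged.g.edges["A", "B"]["weight"] == 2
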