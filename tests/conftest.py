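import numpy as np
import pytest

import hicgraph as hg


@pytest.fixture(scope="session")
def small_dataset():
    """One synthetic sample at the default study conditions."""
    return hg.simulate_dataset(hg.SimConfig(seed=11), with_sequence=True)


@pytest.fixture(scope="session")
def small_contacts(small_dataset):
    assigned, n_off = hg.assign_to_fragments(small_dataset.pairs, small_dataset.fragments)
    contacts, report = hg.filter_valid_pairs(assigned, small_dataset.fragments, 800, n_off)
    return contacts, report


@pytest.fixture(scope="session")
def small_graph(small_dataset, small_contacts):
    contacts, _ = small_contacts
    fg = hg.overlap_genes(small_dataset.fragments, small_dataset.genes)
    graph = hg.build_neighborhood(
        small_dataset.genes.symbols[:1], contacts, fg, small_dataset.genes,
        hg.BuildConfig(level=2),
    )
    cov = hg.gene_covariates(graph.nodes(), fg, small_dataset.fragments)
    fit = hg.fit_glm(hg.edge_design(graph, cov))
    hg.score_edges(graph, fit, cov)
    return graph


def random_instance(rng, n_genes=50, n_contacts=500, n_chroms=2, chrom_len=200_000):
    """A random fragment map + genes + contact table for oracle tests."""
    rows, frag_id = [], 0
    lengths = {f"chr{i+1}": chrom_len for i in range(n_chroms)}
    for chrom, length in lengths.items():
        cuts = np.unique(rng.integers(1, length, size=rng.integers(20, 60)))
        bounds = [0, *cuts.tolist(), length]
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((frag_id, chrom, s, e, e - s, 0.5, 1.0))
            frag_id += 1
    import pandas as pd

    fragments = hg.FragmentMap(pd.DataFrame(rows, columns=hg.FragmentMap.COLUMNS))
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_len - 5000))
        end = start + int(rng.integers(500, 5000))
        genes.append(hg.GeneAnnotation(f"G{i:03d}", chrom, start, end))
    gene_table = hg.GeneTable(genes)
    n_frag = len(fragments)
    pairs = set()
    while len(pairs) < n_contacts:
        a, b = rng.integers(0, n_frag, 2)
        if a == b:
            continue
        pairs.add((min(a, b), max(a, b)))
    contacts = hg.ContactTable(
        pd.DataFrame(
            [(a, b, int(rng.integers(1, 5))) for a, b in sorted(pairs)],
            columns=["frag_a", "frag_b", "count"],
        )
    )
    return fragments, gene_table, contacts
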