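"""Digestion, covariates and interval bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hicgraph as hg
from hicgraph.genome import gc_content


class TestDigest:
    def test_hindiii_example(self):
        fm = hg.digest({"c": "AAAGCTTAA"}, hg.HINDIII)
        assert [(f.start, f.end) for f in fm] == [(0, 2), (2, 9)]

    def test_no_motif_single_fragment(self):
        fm = hg.digest({"c": "ACGT" * 25}, hg.HINDIII)
        assert [(f.start, f.end) for f in fm] == [(0, 100)]

    def test_case_insensitive(self):
        fm = hg.digest({"c": "aaagcttaa"}, hg.HINDIII)
        assert [(f.start, f.end) for f in fm] == [(0, 2), (2, 9)]

    def test_overlapping_motifs_scanned_every_position(self):
        # motif AAA in AAAAAA matches at 0,1,2,3 -> cuts 1,2,3,4
        fm = hg.digest({"c": "AAAAAA"}, hg.Enzyme("x", "AAA", 1))
        assert [(f.start, f.end) for f in fm] == [
            (0, 1), (1, 2), (2, 3), (3, 4), (4, 6)]

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError, match="empty"):
            hg.digest({"c": ""}, hg.HINDIII)

    def test_random_sequence_partitions_chromosome(self):
        # brute-force per-base membership: every base in exactly one fragment
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
        fm = hg.digest({"c": seq}, hg.HINDIII)
        hits = np.zeros(10_000, dtype=int)
        for f in fm:
            hits[f.start:f.end] += 1
        assert (hits == 1).all()

    def test_deterministic_and_idempotent(self):
        rng = np.random.default_rng(1)
        seqs = {"c": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])}
        a, b = hg.digest(seqs, hg.HINDIII), hg.digest(seqs, hg.HINDIII)
        assert a.df.equals(b.df)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seq=st.text(alphabet="ACGTN", min_size=1, max_size=300),
    motif=st.text(alphabet="ACGT", min_size=1, max_size=4),
    data=st.data(),
)
def test_digest_partition_property(seq, motif, data):
    """For any sequence and enzyme, fragments tile [0, L) exactly."""
    offset = data.draw(st.integers(0, len(motif)))
    fm = hg.digest({"c": seq}, hg.Enzyme("e", motif, offset))
    frags = sorted((f.start, f.end) for f in fm)
    assert frags[0][0] == 0 and frags[-1][1] == len(seq)
    for (s1, e1), (s2, e2) in zip(frags, frags[1:]):
        assert e1 == s2


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5), ("ANNT", 0.0)]
    )
    def test_gc_values(self, seq, expected):
        gc, imputed = gc_content(seq)
        assert gc == expected and not imputed

    def test_all_ambiguous_imputed(self):
        gc, imputed = gc_content("NNNN")
        assert gc == 0.5 and imputed

    def test_covariates_from_sequence(self):
        fm = hg.digest({"c": "GGCCATAT"}, hg.HINDIII)
        fm = hg.fragment_covariates(fm, {"c": "GGCCATAT"})
        assert fm.df["gc"].iloc[0] == 0.5

    def test_out_of_bounds_fragment_error(self):
        fm = hg.digest({"c": "ACGTACGT"}, hg.HINDIII)
        with pytest.raises(ValueError, match="past chromosome"):
            hg.fragment_covariates(fm, {"c": "ACG"})

    def test_mappability_track_weighted_mean(self):
        fm = hg.digest({"c": "ACGTACGTAC"}, hg.HINDIII)  # one fragment [0,10)
        track = hg.FeatureTrack(
            "map", pd.DataFrame({"chrom": ["c", "c"], "start": [0, 5],
                                 "end": [5, 10], "score": [1.0, 0.5]})
        )
        fm = hg.fragment_covariates(fm, mappability_track=track)
        assert fm.df["mappability"].iloc[0] == pytest.approx(0.75)

    def test_default_mappability_is_one(self):
        fm = hg.digest({"c": "ACGT"}, hg.HINDIII)
        assert (fm.df["mappability"] == 1.0).all()


class TestOverlapGenes:
    def _map(self, frag_intervals, gene_intervals):
        rows = [
            (i, "c", s, e, e - s, 0.5, 1.0) for i, (s, e) in enumerate(frag_intervals)
        ]
        fm = hg.FragmentMap(pd.DataFrame(rows, columns=hg.FragmentMap.COLUMNS))
        genes = hg.GeneTable(
            hg.GeneAnnotation(f"G{i}", "c", s, e)
            for i, (s, e) in enumerate(gene_intervals)
        )
        return hg.overlap_genes(fm, genes)

    def test_one_bp_overlap_associates(self):
        m = self._map([(0, 150), (150, 300), (300, 400)], [(100, 200)])
        assert m.fragments_of("G0") == (0, 1)
        assert m.genes_of(0) == ("G0",)

    def test_half_open_abutment_not_associated(self):
        m = self._map([(0, 200), (200, 300)], [(100, 200)])
        assert m.fragments_of("G0") == (0,)

    def test_random_instances_match_quadratic_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            cuts = np.unique(rng.integers(1, 10_000, 60))
            bounds = [0, *cuts.tolist(), 10_000]
            frag_iv = list(zip(bounds[:-1], bounds[1:]))
            gene_iv = []
            for _ in range(100):
                s = int(rng.integers(0, 9_900))
                gene_iv.append((s, s + int(rng.integers(1, 500))))
            m = self._map(frag_iv, gene_iv)
            for gi, (gs, ge) in enumerate(gene_iv):
                expected = tuple(
                    fi for fi, (fs, fe) in enumerate(frag_iv) if fs < ge and gs < fe
                )
                assert m.fragments_of(f"G{gi}") == expected

    def test_unknown_chromosome_errors(self):
        fm = hg.digest({"c": "ACGT" * 100}, hg.HINDIII)
        genes = hg.GeneTable([hg.GeneAnnotation("G0", "chrX", 0, 10)])
        with pytest.raises(ValueError, match="chrX"):
            hg.overlap_genes(fm, genes)


class TestIO:
    def test_gene_bed_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "genes.bed"
        small_dataset.genes.to_bed(path)
        back = hg.GeneTable.from_bed(path)
        assert back.to_frame().equals(small_dataset.genes.to_frame())

    def test_fragment_tsv_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "frags.tsv"
        small_dataset.fragments.to_tsv(path)
        back = hg.FragmentMap.from_tsv(path)
        pd.testing.assert_frame_equal(
            back.df, small_dataset.fragments.df, check_dtype=False
        )

    def test_fasta_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "g.fa"
        hg.write_fasta(small_dataset.sequences, path)
        assert hg.read_fasta(path) == small_dataset.sequences

    def test_feature_track_bed_round_trip(self, tmp_path, small_dataset):
        track = small_dataset.scaffold.tracks[0]
        path = tmp_path / "t.bed"
        track.to_bed(path)
        back = hg.FeatureTrack.from_bed(path, track.name)
        pd.testing.assert_frame_equal(back.df, track.df, check_dtype=False)
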