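"""Read-pair ingestion, fragment assignment and valid-pair filtering."""

import numpy as np
import pandas as pd
import pytest

import hicgraph as hg
from hicgraph.hic import FilterReport, pairs_frame


def _fragmap(frag_intervals, chrom="c"):
    rows = [
        (i, chrom, s, e, e - s, 0.5, 1.0) for i, (s, e) in enumerate(frag_intervals)
    ]
    return hg.FragmentMap(pd.DataFrame(rows, columns=hg.FragmentMap.COLUMNS))


class TestReadPairsTSV:
    def test_single_row(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("chr1\t100\t+\tchr2\t500\t-\tr1\n")
        pairs = hg.read_pairs_tsv(p)
        assert pairs == [hg.ReadPair("chr1", 100, "+", "chr2", 500, "-", "r1")]

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("chr1\t100\t+\tchr2\t500\t-\tr1\nchr1\tbad\n")
        with pytest.raises(ValueError, match=":2:"):
            hg.read_pairs_tsv(p)

    def test_zero_pairs_error(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("# only a comment\n")
        with pytest.raises(ValueError, match="zero usable"):
            hg.read_pairs_tsv(p)

    def test_round_trip_thousand_pairs(self, tmp_path):
        rng = np.random.default_rng(2)
        pairs = [
            hg.ReadPair(
                f"chr{rng.integers(1, 3)}", int(rng.integers(0, 10_000)),
                "+-"[rng.integers(2)], f"chr{rng.integers(1, 3)}",
                int(rng.integers(0, 10_000)), "+-"[rng.integers(2)], f"r{i}",
            )
            for i in range(1000)
        ]
        path = tmp_path / "p.tsv"
        hg.write_pairs_tsv(pairs, path)
        assert hg.read_pairs_tsv(path) == pairs


class TestReadPairsSAM:
    def test_mapped_pair_and_unmapped_mate(self, tmp_path):
        sam = tmp_path / "t.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"
            # one proper pair
            "r1\t65\tchr1\t101\t60\t50M\t=\t1001\t0\t*\t*\n"
            "r1\t129\tchr1\t1001\t60\t50M\t=\t101\t0\t*\t*\n"
            # mate unmapped -> both records skipped
            "r2\t73\tchr1\t201\t60\t50M\t*\t0\t0\t*\t*\n"
            "r2\t133\tchr1\t0\t0\t*\t*\t0\t0\t*\t*\n"
        )
        pairs, skipped = hg.read_pairs_sam(sam)
        assert len(pairs) == 1 and skipped == 2
        # SAM POS is 1-based; 5' of a forward read is start
        assert (pairs[0].pos_a, pairs[0].pos_b) == (100, 1000)

    def test_sam_round_trip(self, tmp_path, small_dataset):
        lens = small_dataset.scaffold.chrom_lengths()
        sub = small_dataset.pairs.head(500)
        # keep away from chromosome ends where alignment clamping shifts 5'
        ok = (sub["pos_a"] > 60) & (sub["pos_b"] > 60)
        for c, L in lens.items():
            ok &= ~((sub["chrom_a"] == c) & (sub["pos_a"] > L - 60))
            ok &= ~((sub["chrom_b"] == c) & (sub["pos_b"] > L - 60))
        sub = sub[ok]
        path = tmp_path / "t.sam"
        hg.write_pairs_sam(sub, path, lens)
        back, _ = hg.read_pairs_sam(path)

        def canon(df):
            ends = [
                tuple(sorted([(r.chrom_a, r.pos_a, r.strand_a),
                              (r.chrom_b, r.pos_b, r.strand_b)])) + (r.read_id,)
                for r in df.itertuples(index=False)
            ]
            return sorted(ends)

        assert canon(pairs_frame(back)) == canon(sub)


class TestAssign:
    def test_boundary_assignment(self):
        fm = _fragmap([(0, 150), (150, 300)], chrom="chr1")
        pairs = [
            hg.ReadPair("chr1", 100, "+", "chr1", 150, "+", "r1"),
        ]
        assigned, n_skipped = hg.assign_to_fragments(pairs, fm)
        assert n_skipped == 0
        assert (assigned["frag_a"].iloc[0], assigned["frag_b"].iloc[0]) == (0, 1)

    def test_off_chromosome_skipped(self):
        fm = _fragmap([(0, 150)], chrom="chr1")
        pairs = [
            hg.ReadPair("chr1", 100, "+", "chr1", 999, "+", "r1"),
            hg.ReadPair("chrZ", 5, "+", "chr1", 10, "+", "r2"),
        ]
        assigned, n_skipped = hg.assign_to_fragments(pairs, fm)
        assert len(assigned) == 0 and n_skipped == 2

    def test_random_positions_match_linear_scan(self):
        rng = np.random.default_rng(9)
        cuts = np.unique(rng.integers(1, 50_000, 40))
        bounds = [0, *cuts.tolist(), 50_000]
        intervals = list(zip(bounds[:-1], bounds[1:]))
        fm = _fragmap(intervals, chrom="chr1")
        pos = rng.integers(0, 50_000, 10_000)
        got = fm.locate_many(np.repeat("chr1", len(pos)), pos)
        for p, fid in zip(pos[:500], got[:500]):
            expected = next(
                i for i, (s, e) in enumerate(intervals) if s <= p < e
            )
            assert fid == expected
        # full agreement via vector check
        starts = np.array([s for s, _ in intervals])
        assert (got == (np.searchsorted(starts, pos, side="right") - 1)).all()


class TestFilters:
    def _assigned(self, rows):
        df = pd.DataFrame(
            rows,
            columns=["chrom_a", "pos_a", "strand_a", "chrom_b", "pos_b",
                     "strand_b", "read_id", "frag_a", "frag_b"],
        )
        return df

    def test_three_filters_and_dedup(self):
        fm = _fragmap([(i * 100, (i + 1) * 100) for i in range(12)], chrom="chr1")
        rows = [
            ("chr1", 710, "+", "chr1", 790, "-", "r1", 7, 7),    # same fragment
            ("chr1", 710, "+", "chr1", 810, "-", "r2", 7, 8),    # adjacent
            ("chr1", 710, "+", "chr1", 910, "-", "r3", 7, 9),    # kept
            ("chr1", 915, "+", "chr1", 715, "-", "r4", 9, 7),    # same pair, flipped
        ]
        contacts, report = hg.filter_valid_pairs(self._assigned(rows), fm)
        assert report.same_fragment == 1
        assert report.adjacent_fragment == 1
        assert report.kept == 2
        assert contacts.count(7, 9) == 2
        assert contacts.count(9, 7) == 2  # symmetric-canonical query

    def test_cut_site_distance_filter(self):
        fm = _fragmap([(0, 5000), (5000, 5500), (5500, 10_500)], chrom="chr1")
        rows = [
            ("chr1", 2500, "+", "chr1", 10_400, "-", "r1", 0, 2),  # end A mid-fragment
            ("chr1", 100, "+", "chr1", 10_400, "-", "r2", 0, 2),   # both near cuts
        ]
        contacts, report = hg.filter_valid_pairs(self._assigned(rows), fm, 800)
        assert report.cut_distance == 1 and report.kept == 1
        assert contacts.count(0, 2) == 1

    def test_interchromosomal_adjacent_ids_pass(self):
        # fragments 0 (chr1) and 1 (chr2): |id diff| = 1 but different chrom
        rows1 = [(0, "chr1", 0, 1000, 1000, 0.5, 1.0), (1, "chr2", 0, 1000, 1000, 0.5, 1.0)]
        fm = hg.FragmentMap(pd.DataFrame(rows1, columns=hg.FragmentMap.COLUMNS))
        rows = [("chr1", 10, "+", "chr2", 20, "-", "r1", 0, 1)]
        contacts, report = hg.filter_valid_pairs(self._assigned(rows), fm)
        assert report.adjacent_fragment == 0 and contacts.count(0, 1) == 1

    def test_count_conservation(self, small_dataset, small_contacts):
        contacts, report = small_contacts
        total = (
            report.kept + report.same_fragment + report.adjacent_fragment
            + report.cut_distance + report.off_fragment
        )
        assert total == report.n_input == len(small_dataset.pairs)
        assert contacts.total_count == report.kept

    def test_order_independence(self, small_dataset):
        assigned, n_off = hg.assign_to_fragments(
            small_dataset.pairs, small_dataset.fragments
        )
        perm = assigned.sample(frac=1, random_state=5).reset_index(drop=True)
        a, _ = hg.filter_valid_pairs(assigned, small_dataset.fragments, 800, n_off)
        b, _ = hg.filter_valid_pairs(perm, small_dataset.fragments, 800, n_off)
        assert a == b

    def test_contact_table_tsv_round_trip(self, tmp_path, small_contacts):
        contacts, _ = small_contacts
        path = tmp_path / "c.tsv"
        contacts.to_tsv(path)
        assert hg.ContactTable.from_tsv(path) == contacts

    def test_filter_report_write(self, tmp_path):
        rep = FilterReport(n_input=10, kept=10)
        rep.write(tmp_path / "r.txt")
        assert "n_input\t10" in (tmp_path / "r.txt").read_text()
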