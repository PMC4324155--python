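"""Hi-C read-pair ingestion, fragment assignment and valid-pair filtering.

Read pairs arrive either as a minimal paired-end SAM subset (the output
stage of standard Hi-C preprocessing) or as a plain TSV interchange
format with columns ``chromA posA strandA chromB posB strandB id``.
Positions are the 0-based 5' coordinate of each read; SAM's 1-based
POS is converted on ingest and reverse-strand reads use the rightmost
aligned base as their 5' end.

Valid-pair filtering applies the three standard criteria before contact
counting: same-fragment pairs (dangling ends / self-circles), adjacent
fragments on one chromosome (re-ligation artifacts), and read ends lying
implausibly far from the nearest restriction cut site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import FragmentMap

__all__ = [
    "ReadPair",
    "ContactTable",
    "FilterReport",
    "read_pairs",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_pairs_sam",
    "write_pairs_sam",
    "pairs_frame",
    "assign_to_fragments",
    "filter_valid_pairs",
]

log = logging.getLogger(__name__)

PAIR_COLUMNS = ["chrom_a", "pos_a", "strand_a", "chrom_b", "pos_b", "strand_b", "read_id"]


@dataclass(frozen=True)
class ReadPair:
    """One Hi-C read pair: two mapped 5' positions plus a read id."""

    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    read_id: str


def pairs_frame(pairs: "Sequence[ReadPair] | pd.DataFrame") -> pd.DataFrame:
    """Normalize a pair collection to the canonical dataframe layout."""
    if isinstance(pairs, pd.DataFrame):
        missing = [c for c in PAIR_COLUMNS if c not in pairs.columns]
        if missing:
            raise ValueError(f"pair table missing columns: {missing}")
        return pairs[PAIR_COLUMNS].reset_index(drop=True)
    return pd.DataFrame(pairs, columns=PAIR_COLUMNS)


def read_pairs_tsv(path: str | Path) -> list[ReadPair]:
    """Read the pairs TSV dialect; errors carry the 1-based line number."""
    out: list[ReadPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(
                    f"{path}:{lineno}: expected 7 tab-separated fields, got {len(parts)}"
                )
            ca, pa, sa, cb, pb, sb, rid = parts
            try:
                pa_i, pb_i = int(pa), int(pb)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer position") from None
            if sa not in "+-" or sb not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand field")
            out.append(ReadPair(ca, pa_i, sa, cb, pb_i, sb, rid))
    if not out:
        raise ValueError(f"{path}: zero usable read pairs")
    return out


def write_pairs_tsv(pairs: "Sequence[ReadPair] | pd.DataFrame", path: str | Path) -> None:
    pairs_frame(pairs).to_csv(path, sep="\t", index=False, header=False)


def read_pairs_sam(path: str | Path) -> tuple[list[ReadPair], int]:
    """Read properly paired records from a minimal SAM subset.

    Records are paired by QNAME.  A record is usable when it is flagged
    paired, mapped, with a mapped mate, and is not secondary or
    supplementary.  The 5' position is ``reference_start`` on the forward
    strand and ``reference_end - 1`` on the reverse strand.  Returns the
    pairs plus the number of skipped records.
    """
    import pysam

    pending: dict[str, tuple[str, int, str]] = {}
    out: list[ReadPair] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if (
                not rec.is_paired
                or rec.is_unmapped
                or rec.mate_is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
            ):
                skipped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            pos = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            key = rec.query_name
            if key in pending:
                ca, pa, sa = pending.pop(key)
                out.append(ReadPair(ca, pa, sa, rec.reference_name, pos, strand, key))
            else:
                pending[key] = (rec.reference_name, pos, strand)
    skipped += len(pending)  # mates never seen
    if not out:
        raise ValueError(f"{path}: zero usable read pairs")
    if skipped:
        log.info("%s: skipped %d unpaired/unmapped records", path, skipped)
    return out, skipped


def write_pairs_sam(
    pairs: "Sequence[ReadPair] | pd.DataFrame",
    path: str | Path,
    chrom_lengths: dict[str, int],
    read_length: int = 50,
) -> None:
    """Write pairs as a minimal SAM file (for interchange and round-trips)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    df = pairs_frame(pairs)
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for row in df.itertuples(index=False):
            for which, (chrom, pos, strand, mchrom, mpos, mstrand) in enumerate(
                [
                    (row.chrom_a, row.pos_a, row.strand_a, row.chrom_b, row.pos_b, row.strand_b),
                    (row.chrom_b, row.pos_b, row.strand_b, row.chrom_a, row.pos_a, row.strand_a),
                ]
            ):
                a = pysam.AlignedSegment()
                a.query_name = str(row.read_id)
                flag = 0x1 | (0x40 if which == 0 else 0x80)
                ref_len = chrom_lengths[chrom]
                # keep the alignment inside the chromosome
                rl = min(read_length, ref_len)
                if strand == "-":
                    flag |= 0x10
                    start = max(0, pos - rl + 1)
                else:
                    start = min(pos, ref_len - rl)
                if mstrand == "-":
                    flag |= 0x20
                a.flag = flag
                a.reference_id = tid[chrom]
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = f"{rl}M"
                a.next_reference_id = tid[mchrom]
                a.next_reference_start = mpos
                a.query_sequence = "A" * rl
                sam.write(a)


def read_pairs(path: str | Path, fmt: str | None = None) -> list[ReadPair]:
    """Dispatch on format (``sam`` or ``tsv``; inferred from suffix)."""
    if fmt is None:
        fmt = "sam" if str(path).endswith(".sam") else "tsv"
    if fmt == "sam":
        return read_pairs_sam(path)[0]
    if fmt == "tsv":
        return read_pairs_tsv(path)
    raise ValueError(f"unknown pair format {fmt!r}")


@dataclass
class FilterReport:
    """Tallies from assignment + valid-pair filtering.

    ``n_input`` counts ingested pairs; kept + removed categories sum to
    it exactly.
    """

    n_input: int = 0
    off_fragment: int = 0
    same_fragment: int = 0
    adjacent_fragment: int = 0
    cut_distance: int = 0
    kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "off_fragment": self.off_fragment,
            "same_fragment": self.same_fragment,
            "adjacent_fragment": self.adjacent_fragment,
            "cut_distance": self.cut_distance,
            "kept": self.kept,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in self.as_dict().items():
                fh.write(f"{k}\t{v}\n")


class ContactTable:
    """Deduplicated fragment-pair contact counts, canonical ``idA < idB``."""

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        missing = [c for c in ("frag_a", "frag_b", "count") if c not in df.columns]
        if missing:
            raise ValueError(f"contact table missing columns: {missing}")
        if len(df):
            if not (df["frag_a"] < df["frag_b"]).all():
                raise ValueError("contact table not in canonical order (frag_a < frag_b)")
            if not (df["count"] >= 1).all():
                raise ValueError("contact counts must be >= 1")
            if df.duplicated(subset=["frag_a", "frag_b"]).any():
                raise ValueError("duplicate fragment pair rows")
        self.df = df[["frag_a", "frag_b", "count"]].astype(np.int64)
        self._lookup = {
            (int(a), int(b)): int(c)
            for a, b, c in zip(self.df["frag_a"], self.df["frag_b"], self.df["count"])
        }

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_count(self) -> int:
        return int(self.df["count"].sum())

    def count(self, frag_a: int, frag_b: int) -> int:
        """Count for an unordered fragment pair (0 when absent)."""
        a, b = (frag_a, frag_b) if frag_a < frag_b else (frag_b, frag_a)
        return self._lookup.get((a, b), 0)

    def rows(self) -> Iterable[tuple[int, int, int]]:
        return ((a, b, c) for (a, b), c in self._lookup.items())

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContactTable":
        return cls(pd.read_csv(path, sep="\t"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactTable):
            return NotImplemented
        return self._lookup == other._lookup


def assign_to_fragments(
    pairs: "Sequence[ReadPair] | pd.DataFrame", fragments: FragmentMap
) -> tuple[pd.DataFrame, int]:
    """Assign each read end to the fragment containing its 5' position.

    Returns the pair table with ``frag_a``/``frag_b`` columns (rows whose
    ends all fall inside a fragment) plus the number of skipped pairs.
    """
    df = pairs_frame(pairs).copy()
    df["frag_a"] = fragments.locate_many(
        df["chrom_a"].to_numpy(), df["pos_a"].to_numpy()
    )
    df["frag_b"] = fragments.locate_many(
        df["chrom_b"].to_numpy(), df["pos_b"].to_numpy()
    )
    ok = (df["frag_a"] >= 0) & (df["frag_b"] >= 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.info("skipped %d read pairs outside the fragment map", n_skipped)
    return df[ok].reset_index(drop=True), n_skipped


def filter_valid_pairs(
    assigned: pd.DataFrame,
    fragments: FragmentMap,
    max_cut_distance: int = 800,
    n_off_fragment: int = 0,
) -> tuple[ContactTable, FilterReport]:
    """Apply the three valid-pair filters and aggregate to contact counts.

    Removes, in order of precedence: same-fragment pairs, adjacent
    fragments on one chromosome (|id difference| = 1), and pairs with a
    read 5' end farther than ``max_cut_distance`` from the nearest end of
    its fragment.  Survivors are deduplicated into per-fragment-pair
    counts.  Filtering is order-independent by construction (pure row
    predicates + groupby).
    """
    report = FilterReport(n_input=len(assigned) + n_off_fragment,
                          off_fragment=n_off_fragment)
    if len(assigned) == 0:
        log.warning("no assigned pairs to filter")
        return ContactTable(pd.DataFrame(columns=["frag_a", "frag_b", "count"])), report

    fdf = fragments.df
    starts = fdf["start"].to_numpy()
    ends = fdf["end"].to_numpy()
    chroms = fdf["chrom"].to_numpy()

    fa = assigned["frag_a"].to_numpy()
    fb = assigned["frag_b"].to_numpy()
    same = fa == fb
    adjacent = (~same) & (np.abs(fa - fb) == 1) & (chroms[fa] == chroms[fb])

    def cut_dist(frag: np.ndarray, pos: np.ndarray) -> np.ndarray:
        return np.minimum(pos - starts[frag], ends[frag] - pos)

    too_far = (
        cut_dist(fa, assigned["pos_a"].to_numpy()) > max_cut_distance
    ) | (cut_dist(fb, assigned["pos_b"].to_numpy()) > max_cut_distance)
    too_far &= ~(same | adjacent)

    report.same_fragment = int(same.sum())
    report.adjacent_fragment = int(adjacent.sum())
    report.cut_distance = int(too_far.sum())
    keep = ~(same | adjacent | too_far)
    report.kept = int(keep.sum())

    lo = np.minimum(fa[keep], fb[keep])
    hi = np.maximum(fa[keep], fb[keep])
    grouped = (
        pd.DataFrame({"frag_a": lo, "frag_b": hi})
        .groupby(["frag_a", "frag_b"], sort=True)
        .size()
        .reset_index(name="count")
    )
    if grouped.empty:
        log.warning("valid-pair filtering left zero contacts")
    return ContactTable(grouped), report
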