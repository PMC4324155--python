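"""Genome-side bookkeeping: in-silico restriction digestion, fragment
covariates, gene annotations and BED feature tracks.

All coordinates are 0-based, half-open, on both the Python and the file
side (BED is read natively; SAM positions are converted on ingest by
:mod:`hicgraph.hic`).  A digested chromosome is a *partition*: restriction
fragments are non-overlapping, sorted, and tile ``[0, chrom_length)``
exactly, which is what makes read-to-fragment assignment a single binary
search.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Enzyme",
    "HINDIII",
    "RestrictionFragment",
    "FragmentMap",
    "GeneAnnotation",
    "GeneTable",
    "FeatureTrack",
    "FragmentGeneMap",
    "digest",
    "fragment_covariates",
    "overlap_genes",
    "gc_content",
    "read_fasta",
    "write_fasta",
]

_COMPLEMENTABLE = "ACGT"


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: recognition motif plus cut offset within it.

    ``cut_offset`` is the distance from the motif start to the cut
    position, e.g. HindIII cuts A^AGCTT, so motif ``AAGCTT`` with offset 1.
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("enzyme motif must be non-empty")
        if not set(self.motif.upper()) <= set(_COMPLEMENTABLE):
            raise ValueError(f"motif {self.motif!r} contains non-ACGT characters")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError("cut offset must lie within the motif")


#: HindIII (A^AGCTT), the enzyme used throughout as the named default.
HINDIII = Enzyme("HindIII", "AAGCTT", 1)


@dataclass(frozen=True)
class RestrictionFragment:
    """One restriction fragment with its three normalization covariates."""

    id: int
    chrom: str
    start: int
    end: int
    gc: float = 0.5
    mappability: float = 1.0
    gc_imputed: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.id}: start must be < end")


def gc_content(seq: str) -> tuple[float, bool]:
    """GC fraction of ``seq`` over unambiguous bases only.

    Ambiguous bases (anything outside ACGT) are excluded from both the
    numerator and the denominator.  A sequence with no unambiguous base
    gets 0.5, flagged as imputed in the second return value.
    """
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        return 0.5, True
    return gc / denom, False


class FragmentMap:
    """The digestion product for a genome.

    Wraps a dataframe with columns ``id chrom start end length gc
    mappability`` and validates the tiling invariant per chromosome.
    Fragment ids are global, dense, and follow genomic order.
    """

    COLUMNS = ["id", "chrom", "start", "end", "length", "gc", "mappability"]

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        missing = [c for c in ("id", "chrom", "start", "end") if c not in df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns: {missing}")
        if "length" not in df.columns:
            df["length"] = df["end"] - df["start"]
        if "gc" not in df.columns:
            df["gc"] = 0.5
        if "mappability" not in df.columns:
            df["mappability"] = 1.0
        self.df = df[self.COLUMNS].copy()
        self._validate()
        self._index: dict[str, tuple[np.ndarray, int, int]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            self._index[chrom] = (starts, int(sub["id"].iloc[0]), int(sub["end"].iloc[-1]))

    def _validate(self) -> None:
        df = self.df
        if df.empty:
            raise ValueError("fragment map is empty")
        if not (df["start"] < df["end"]).all():
            raise ValueError("fragment with start >= end")
        if not (df["length"] == df["end"] - df["start"]).all():
            raise ValueError("fragment length column inconsistent")
        if not (df["id"].to_numpy() == np.arange(len(df))).all():
            raise ValueError("fragment ids must be dense 0..n-1 in table order")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0:
                raise ValueError(f"{chrom}: fragments do not start at 0")
            if not (starts[1:] == ends[:-1]).all():
                raise ValueError(f"{chrom}: fragments do not tile the chromosome")

    # -- queries ---------------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return list(self._index)

    def chrom_length(self, chrom: str) -> int:
        return self._index[chrom][2]

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[RestrictionFragment]:
        for row in self.df.itertuples(index=False):
            yield RestrictionFragment(
                int(row.id), row.chrom, int(row.start), int(row.end),
                float(row.gc), float(row.mappability),
            )

    def fragment(self, frag_id: int) -> RestrictionFragment:
        row = self.df.iloc[frag_id]
        return RestrictionFragment(
            int(row.id), row.chrom, int(row.start), int(row.end),
            float(row.gc), float(row.mappability),
        )

    def locate(self, chrom: str, pos: int) -> int:
        """Fragment id containing position ``pos`` (half-open intervals)."""
        ids = self.locate_many(np.asarray([chrom]), np.asarray([pos]))
        if ids[0] < 0:
            raise ValueError(f"position {chrom}:{pos} outside any fragment")
        return int(ids[0])

    def locate_many(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Vectorized fragment lookup; -1 marks off-chromosome positions."""
        out = np.full(len(positions), -1, dtype=np.int64)
        chroms = np.asarray(chroms)
        positions = np.asarray(positions)
        for chrom, (starts, offset, chrom_len) in self._index.items():
            mask = chroms == chrom
            if not mask.any():
                continue
            pos = positions[mask]
            ok = (pos >= 0) & (pos < chrom_len)
            idx = np.searchsorted(starts, pos, side="right") - 1
            vals = np.where(ok, idx + offset, -1)
            out[mask] = vals
        return out

    # -- io --------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FragmentMap":
        return cls(pd.read_csv(path, sep="\t"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentMap):
            return NotImplemented
        return self.df.equals(other.df)


def _find_motif_positions(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) case-insensitive motif match starts."""
    s = seq.upper()
    m = motif.upper()
    hits = []
    i = s.find(m)
    while i != -1:
        hits.append(i)
        i = s.find(m, i + 1)
    return hits


def digest(
    sequences: Mapping[str, str],
    enzyme: Enzyme = HINDIII,
    mappability_track: "FeatureTrack | None" = None,
) -> FragmentMap:
    """Digest a genome in silico into a :class:`FragmentMap`.

    Cut positions are ``match_start + cut_offset`` for every exact,
    case-insensitive motif occurrence (overlapping occurrences included).
    GC content is computed per fragment from its sequence; mappability is
    1.0 unless ``mappability_track`` is given (then the score-weighted
    mean over the fragment, see :func:`fragment_covariates`).
    """
    rows = []
    frag_id = 0
    for chrom, seq in sequences.items():
        if len(seq) == 0:
            raise ValueError(f"chromosome {chrom!r} has empty sequence")
        cuts = sorted(
            {p + enzyme.cut_offset for p in _find_motif_positions(seq, enzyme.motif)}
        )
        cuts = [c for c in cuts if 0 < c < len(seq)]
        bounds = [0, *cuts, len(seq)]
        for start, end in zip(bounds[:-1], bounds[1:]):
            gc, _imputed = gc_content(seq[start:end])
            rows.append((frag_id, chrom, start, end, end - start, gc, 1.0))
            frag_id += 1
    fragmap = FragmentMap(
        pd.DataFrame(rows, columns=FragmentMap.COLUMNS)
    )
    if mappability_track is not None:
        fragmap = fragment_covariates(fragmap, mappability_track=mappability_track)
    return fragmap


def fragment_covariates(
    fragments: FragmentMap,
    sequences: Mapping[str, str] | None = None,
    mappability_track: "FeatureTrack | None" = None,
) -> FragmentMap:
    """Return a copy of ``fragments`` with gc / mappability (re)computed.

    ``gc`` comes from ``sequences`` when given; ``mappability`` is the
    score-weighted mean of ``mappability_track`` over the fragment, with
    uncovered bases contributing score 0.  Both are deterministic.
    """
    df = fragments.df.copy()
    if sequences is not None:
        gcs = np.empty(len(df))
        for i, row in enumerate(df.itertuples(index=False)):
            if row.chrom not in sequences:
                raise ValueError(f"no sequence for chromosome {row.chrom!r}")
            seq = sequences[row.chrom]
            if row.end > len(seq):
                raise ValueError(
                    f"fragment {row.id} extends past chromosome {row.chrom} "
                    f"({row.end} > {len(seq)})"
                )
            gcs[i], _ = gc_content(seq[row.start:row.end])
        df["gc"] = gcs
    if mappability_track is not None:
        maps = np.empty(len(df))
        track = mappability_track.df
        by_chrom = {c: sub for c, sub in track.groupby("chrom", sort=False)}
        for i, row in enumerate(df.itertuples(index=False)):
            sub = by_chrom.get(row.chrom)
            if sub is None:
                maps[i] = 0.0
                continue
            t_start = sub["start"].to_numpy()
            t_end = sub["end"].to_numpy()
            score = sub["score"].to_numpy(dtype=float)
            ov = np.minimum(t_end, row.end) - np.maximum(t_start, row.start)
            ov = np.clip(ov, 0, None)
            maps[i] = float(np.dot(ov, score)) / (row.end - row.start)
        df["mappability"] = np.clip(maps, 0.0, 1.0)
    return FragmentMap(df)


@dataclass(frozen=True)
class GeneAnnotation:
    """A named gene interval used for seeding and fragment association."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.symbol}: start must be < end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.symbol}: bad strand {self.strand!r}")


class GeneTable:
    """A set of gene annotations with unique symbols, BED-backed."""

    def __init__(self, genes: Iterable[GeneAnnotation]):
        self._genes: dict[str, GeneAnnotation] = {}
        for g in genes:
            if g.symbol in self._genes:
                raise ValueError(f"duplicate gene symbol {g.symbol!r}")
            self._genes[g.symbol] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneAnnotation]:
        return iter(self._genes.values())

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._genes

    def __getitem__(self, symbol: str) -> GeneAnnotation:
        try:
            return self._genes[symbol]
        except KeyError:
            raise KeyError(f"unknown gene symbol {symbol!r}") from None

    @property
    def symbols(self) -> list[str]:
        return list(self._genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.symbol, g.chrom, g.start, g.end, g.strand) for g in self],
            columns=["symbol", "chrom", "start", "end", "strand"],
        )

    def to_bed(self, path: str | Path) -> None:
        df = self.to_frame()
        out = df[["chrom", "start", "end", "symbol"]].copy()
        out["score"] = 0
        out["strand"] = df["strand"]
        out.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneTable":
        df = _read_bed_frame(path)
        if "name" not in df.columns:
            raise ValueError("gene BED needs >= 4 columns (name = gene symbol)")
        if "strand" not in df.columns:
            df["strand"] = "."
        return cls(
            GeneAnnotation(str(row.gene), row.chrom, int(row.start), int(row.end),
                           str(row.strand))
            for row in df.rename(columns={"name": "gene"}).itertuples(index=False)
        )


def _read_bed_frame(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


@dataclass
class FeatureTrack:
    """A named BED track of genomic intervals with an optional score."""

    name: str
    df: pd.DataFrame  # columns: chrom start end [score]

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        if "score" not in df.columns:
            df["score"] = 1.0
        if not (df["start"] < df["end"]).all():
            raise ValueError(f"track {self.name}: interval with start >= end")
        self.df = df[["chrom", "start", "end", "score"]]

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "FeatureTrack":
        raw = _read_bed_frame(path)
        df = raw[["chrom", "start", "end"]].copy()
        if "score" in raw.columns:
            df["score"] = pd.to_numeric(raw["score"], errors="coerce").fillna(1.0)
        return cls(name or Path(path).stem, df)

    def to_bed(self, path: str | Path) -> None:
        out = self.df.copy()
        out.insert(3, "name", [f"{self.name}_{i}" for i in range(len(out))])
        out.to_csv(path, sep="\t", index=False, header=False, float_format="%.10g")


class FragmentGeneMap:
    """Bidirectional fragment <-> gene association by >=1 bp overlap."""

    def __init__(self, frag_to_genes: dict[int, tuple[str, ...]],
                 gene_to_frags: dict[str, tuple[int, ...]]):
        self.frag_to_genes = frag_to_genes
        self.gene_to_frags = gene_to_frags

    def genes_of(self, frag_id: int) -> tuple[str, ...]:
        return self.frag_to_genes.get(frag_id, ())

    def fragments_of(self, symbol: str) -> tuple[int, ...]:
        return self.gene_to_frags.get(symbol, ())


def overlap_genes(fragments: FragmentMap, genes: GeneTable) -> FragmentGeneMap:
    """Associate fragments and genes that share >= 1 bp on one chromosome.

    Because fragments tile each chromosome, the fragments overlapping a
    gene form a contiguous id range found by binary search.
    """
    frag_to_genes: dict[int, list[str]] = {}
    gene_to_frags: dict[str, tuple[int, ...]] = {}
    for gene in genes:
        if gene.chrom not in fragments._index:
            raise ValueError(
                f"gene {gene.symbol}: chromosome {gene.chrom!r} absent from fragment map"
            )
        starts, offset, chrom_len = fragments._index[gene.chrom]
        lo = max(gene.start, 0)
        hi = min(gene.end, chrom_len)
        if lo >= hi:
            gene_to_frags[gene.symbol] = ()
            continue
        first = int(np.searchsorted(starts, lo, side="right")) - 1
        last = int(np.searchsorted(starts, hi, side="left")) - 1
        ids = tuple(range(first + offset, last + offset + 1))
        gene_to_frags[gene.symbol] = ids
        for fid in ids:
            frag_to_genes.setdefault(fid, []).append(gene.symbol)
    return FragmentGeneMap(
        {fid: tuple(sorted(syms)) for fid, syms in frag_to_genes.items()},
        gene_to_frags,
    )


# -- FASTA ---------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into an ordered dict of chromosome sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
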