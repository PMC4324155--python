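"""Synthetic Hi-C dataset generation with known ground truth.

The generator emulates the data regime of a two-condition Hi-C
comparison: a small multi-chromosome genome digested by a restriction
enzyme, non-overlapping genes, read pairs drawn from a fragment-pair
rate model with power-law distance decay within chromosomes
(rate proportional to separation^-gamma), a flat inter-chromosomal
background, multiplicative fragment-covariate effects (length, GC,
mappability), and optional *planted translocations*: gene pairs whose
inter-chromosomal contact rate is multiplied, the structural analogue
of a fusion event such as BCR-ABL1.

Cut sites are placed by geometric inter-arrival (mean fragment length
is a parameter) and the enzyme motif is stamped into the random
sequence at each cut, with accidental motif occurrences mutated away,
so that in-silico digestion of the emitted FASTA reproduces the
intended fragment map exactly.  Read 5' ends are placed near fragment
boundaries, mimicking ligation-junction geometry.

All randomness flows from a single integer seed through spawned
generator streams; identical configuration and seed give byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import (
    HINDIII,
    Enzyme,
    FeatureTrack,
    FragmentMap,
    GeneAnnotation,
    GeneTable,
    write_fasta,
)
from .hic import PAIR_COLUMNS, write_pairs_tsv

__all__ = [
    "SimConfig",
    "TranslocationSpec",
    "FeatureTrackSpec",
    "Scaffold",
    "Dataset",
    "simulate_scaffold",
    "simulate_pairs",
    "simulate_dataset",
    "make_case_control",
    "estimate_decay_slope",
]


@dataclass(frozen=True)
class TranslocationSpec:
    """A planted high-contact gene pair: (gene_a, gene_b, rate multiplier)."""

    gene_a: str
    gene_b: str
    multiplier: float = 50.0

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("translocation multiplier must be >= 1")


@dataclass(frozen=True)
class FeatureTrackSpec:
    """Uniform random BED track: interval count and length."""

    name: str
    n_intervals: int = 100
    length: int = 300


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the package's study conditions.

    Rates are relative: intra-chromosomal fragment pairs at separation
    ``s`` kb get base rate ``s**-gamma``; inter-chromosomal pairs get
    ``inter_rate`` (0.01 puts roughly a tenth of read pairs between
    chromosomes, a realistic Hi-C share).  Covariate exponents multiply
    each pair's rate by ``(len_i*len_j)**beta_len`` etc., matching the
    log-linear normalization model.
    """

    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 300_000), ("chr2", 300_000))
    mean_fragment_length: int = 3000
    min_fragment_length: int = 200
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (4000, 12000)
    n_pairs: int = 20_000
    gamma: float = 1.0
    inter_rate: float = 0.01
    beta_len: float = 0.5
    beta_gc: float = 0.3
    beta_map: float = 0.2
    gc_beta: tuple[float, float] = (20.0, 20.0)
    mappability_beta: tuple[float, float] = (10.0, 2.0)
    translocations: tuple[TranslocationSpec, ...] = ()
    feature_tracks: tuple[FeatureTrackSpec, ...] = (FeatureTrackSpec("ctcf"),)
    enzyme: Enzyme = HINDIII
    read_offset_max: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.inter_rate <= 0:
            raise ValueError("rates must be positive")
        if self.mean_fragment_length <= self.min_fragment_length:
            raise ValueError("mean fragment length must exceed the minimum")


@dataclass
class Scaffold:
    """Genome-side ground truth shared between case and control samples."""

    fragments: FragmentMap
    genes: GeneTable
    tracks: list[FeatureTrack]
    cut_sites: dict[str, list[int]]
    config: SimConfig

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.fragments.chrom_length(c) for c in self.fragments.chromosomes}


@dataclass
class Dataset:
    """A complete synthetic sample: scaffold + read pairs + truth report."""

    scaffold: Scaffold
    pairs: pd.DataFrame  # PAIR_COLUMNS layout
    truth: dict
    sequences: dict[str, str] | None = None

    @property
    def fragments(self) -> FragmentMap:
        return self.scaffold.fragments

    @property
    def genes(self) -> GeneTable:
        return self.scaffold.genes

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.sequences is not None:
            write_fasta(self.sequences, outdir / "genome.fa")
        self.fragments.to_tsv(outdir / "fragments.tsv")
        self.genes.to_bed(outdir / "genes.bed")
        for track in self.scaffold.tracks:
            track.to_bed(outdir / f"{track.name}.bed")
        mappability_track(self.fragments).to_bed(outdir / "mappability.bed")
        write_pairs_tsv(self.pairs, outdir / "pairs.tsv")
        with open(outdir / "truth.txt", "w") as fh:
            for k, v in self.truth.items():
                fh.write(f"{k}\t{v}\n")


def mappability_track(fragments: FragmentMap) -> FeatureTrack:
    """Per-fragment mappability as a scored BED track."""
    df = fragments.df[["chrom", "start", "end", "mappability"]].rename(
        columns={"mappability": "score"}
    )
    return FeatureTrack("mappability", df)


def _place_cut_sites(length: int, cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    mean_gap = cfg.mean_fragment_length - cfg.min_fragment_length
    cuts = []
    pos = 0
    while True:
        gap = cfg.min_fragment_length + int(rng.geometric(1.0 / mean_gap))
        pos += gap
        if pos >= length - cfg.min_fragment_length:
            break
        cuts.append(pos)
    return cuts


def _place_genes(
    scaffold_lengths: dict[str, int], cfg: SimConfig, rng: np.random.Generator
) -> GeneTable:
    chroms = list(scaffold_lengths)
    weights = np.array([scaffold_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes = []
    lo, hi = cfg.gene_length_range
    attempts = 0
    max_attempts = 200 * cfg.n_genes
    while len(genes) < cfg.n_genes:
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {cfg.n_genes} non-overlapping genes "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        glen = int(rng.integers(lo, hi + 1))
        if scaffold_lengths[chrom] <= glen:
            continue
        start = int(rng.integers(0, scaffold_lengths[chrom] - glen))
        end = start + glen
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((chrom, start, end, strand))
    genes.sort()
    return GeneTable(
        GeneAnnotation(f"GEN{i:03d}", chrom, start, end, strand)
        for i, (chrom, start, end, strand) in enumerate(genes)
    )


def _uniform_tracks(
    scaffold_lengths: dict[str, int], cfg: SimConfig, rng: np.random.Generator
) -> list[FeatureTrack]:
    chroms = list(scaffold_lengths)
    weights = np.array([scaffold_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    tracks = []
    for spec in cfg.feature_tracks:
        rows = []
        for _ in range(spec.n_intervals):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            start = int(rng.integers(0, scaffold_lengths[chrom] - spec.length))
            rows.append((chrom, start, start + spec.length, 1.0))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        tracks.append(FeatureTrack(spec.name, df))
    return tracks


def simulate_scaffold(cfg: SimConfig, rng: np.random.Generator | None = None) -> Scaffold:
    """Fragment map with covariates, genes and feature tracks."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    lengths = dict(cfg.chrom_lengths)
    rows = []
    frag_id = 0
    cut_sites = {}
    for chrom, length in lengths.items():
        cuts = _place_cut_sites(length, cfg, rng)
        cut_sites[chrom] = cuts
        bounds = [0, *cuts, length]
        for start, end in zip(bounds[:-1], bounds[1:]):
            gc = float(rng.beta(*cfg.gc_beta))
            mapp = float(rng.beta(*cfg.mappability_beta))
            rows.append((frag_id, chrom, start, end, end - start, gc, mapp))
            frag_id += 1
    fragments = FragmentMap(pd.DataFrame(rows, columns=FragmentMap.COLUMNS))
    genes = _place_genes(lengths, cfg, rng)
    tracks = _uniform_tracks(lengths, cfg, rng)
    return Scaffold(fragments, genes, tracks, cut_sites, cfg)


def realize_sequence(scaffold: Scaffold, rng: np.random.Generator) -> dict[str, str]:
    """Random sequence consistent with the scaffold's fragment map.

    Bases are drawn per fragment at that fragment's target GC; the
    enzyme motif is stamped at every internal cut site and accidental
    occurrences elsewhere are mutated away, so digestion reproduces the
    scaffold's fragment boundaries exactly.
    """
    cfg = scaffold.config
    motif = cfg.enzyme.motif.upper()
    offset = cfg.enzyme.cut_offset
    swap = str.maketrans("ACGT", "CATG")
    sequences = {}
    for chrom in scaffold.fragments.chromosomes:
        sub = scaffold.fragments.df[scaffold.fragments.df["chrom"] == chrom]
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        parts = []
        for row in sub.itertuples(index=False):
            gc = row.gc
            probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
            idx = rng.choice(4, row.length, p=probs)
            parts.append(alphabet[idx].tobytes().decode("ascii"))
        seq = list("".join(parts))
        cuts = set(scaffold.cut_sites[chrom])
        for cut in cuts:
            start = cut - offset
            seq[start : start + len(motif)] = motif
        stamped = {
            p for cut in cuts for p in range(cut - offset, cut - offset + len(motif))
        }
        s = "".join(seq)
        # destroy accidental motifs without touching stamped windows
        while True:
            changed = False
            idx = s.find(motif)
            while idx != -1:
                if idx + offset not in cuts:
                    for p in range(idx, idx + len(motif)):
                        if p not in stamped:
                            s = s[:p] + s[p].translate(swap) + s[p + 1 :]
                            changed = True
                            break
                idx = s.find(motif, idx + 1)
            if not changed:
                break
        sequences[chrom] = s
    return sequences


def _pair_rates(
    scaffold: Scaffold, translocations: Sequence[TranslocationSpec]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rate per eligible fragment pair (same-fragment and adjacent excluded)."""
    cfg = scaffold.config
    fdf = scaffold.fragments.df
    chrom_codes = pd.Categorical(fdf["chrom"]).codes
    mids = ((fdf["start"] + fdf["end"]) / 2).to_numpy()
    lens = fdf["length"].to_numpy(dtype=float)
    gcs = np.clip(fdf["gc"].to_numpy(dtype=float), 1e-3, 1.0)
    maps = np.clip(fdf["mappability"].to_numpy(dtype=float), 1e-3, 1.0)
    n = len(fdf)
    ia, ib = np.triu_indices(n, k=1)
    same_chrom = chrom_codes[ia] == chrom_codes[ib]
    adjacent = same_chrom & (ib - ia == 1)
    keep = ~adjacent
    ia, ib, same_chrom = ia[keep], ib[keep], same_chrom[keep]
    sep_kb = np.abs(mids[ia] - mids[ib]) / 1000.0
    base = np.where(same_chrom, np.maximum(sep_kb, 1e-3) ** -cfg.gamma, cfg.inter_rate)
    cov = (
        (lens[ia] * lens[ib]) ** cfg.beta_len
        * (gcs[ia] * gcs[ib]) ** cfg.beta_gc
        * (maps[ia] * maps[ib]) ** cfg.beta_map
    )
    # covariate factors scaled to mean 1 so base rates keep their meaning
    rate = base * cov / cov.mean()
    from .genome import overlap_genes

    if translocations:
        fg = overlap_genes(scaffold.fragments, scaffold.genes)
        for t in translocations:
            fa = set(fg.fragments_of(t.gene_a))
            fb = set(fg.fragments_of(t.gene_b))
            if not fa or not fb:
                raise ValueError(
                    f"translocation genes {t.gene_a}/{t.gene_b} overlap no fragments"
                )
            mask = (np.isin(ia, list(fa)) & np.isin(ib, list(fb))) | (
                np.isin(ia, list(fb)) & np.isin(ib, list(fa))
            )
            rate[mask] *= t.multiplier
    return ia, ib, rate


def simulate_pairs(
    scaffold: Scaffold,
    rng: np.random.Generator,
    n_pairs: int | None = None,
    translocations: Sequence[TranslocationSpec] | None = None,
) -> pd.DataFrame:
    """Draw read pairs from the rate model as a pairs dataframe."""
    cfg = scaffold.config
    n_pairs = cfg.n_pairs if n_pairs is None else n_pairs
    translocations = cfg.translocations if translocations is None else translocations
    ia, ib, rate = _pair_rates(scaffold, translocations)
    p = rate / rate.sum()
    counts = rng.multinomial(n_pairs, p)
    nz = counts > 0
    rep = np.repeat(np.arange(len(counts))[nz], counts[nz])
    fa, fb = ia[rep], ib[rep]

    fdf = scaffold.fragments.df
    starts = fdf["start"].to_numpy()
    ends = fdf["end"].to_numpy()
    chroms = fdf["chrom"].to_numpy()

    def positions(frag: np.ndarray) -> np.ndarray:
        lo = starts[frag]
        hi = ends[frag]
        span = np.minimum(hi - lo, cfg.read_offset_max)
        off = rng.integers(0, span)  # distance from the chosen cut-site end
        from_start = rng.random(len(frag)) < 0.5
        return np.where(from_start, lo + off, hi - 1 - off)

    pos_a = positions(fa)
    pos_b = positions(fb)
    strand = np.array(["+", "-"])
    df = pd.DataFrame(
        {
            "chrom_a": chroms[fa],
            "pos_a": pos_a,
            "strand_a": strand[rng.integers(0, 2, len(fa))],
            "chrom_b": chroms[fb],
            "pos_b": pos_b,
            "strand_b": strand[rng.integers(0, 2, len(fb))],
            "read_id": [f"r{i:07d}" for i in range(len(fa))],
        }
    )
    return df[PAIR_COLUMNS]


def simulate_dataset(cfg: SimConfig, with_sequence: bool = True) -> Dataset:
    """Generate one complete dataset from a config (seeded, reproducible)."""
    ss = np.random.SeedSequence(cfg.seed)
    scaffold_rng, seq_rng, pair_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    scaffold = simulate_scaffold(cfg, scaffold_rng)
    for t in cfg.translocations:
        for sym in (t.gene_a, t.gene_b):
            if sym not in scaffold.genes:
                raise ValueError(f"translocation references unknown gene {sym!r}")
    sequences = realize_sequence(scaffold, seq_rng) if with_sequence else None
    pairs = simulate_pairs(scaffold, pair_rng)
    truth = {
        "seed": cfg.seed,
        "n_pairs": cfg.n_pairs,
        "gamma": cfg.gamma,
        "inter_rate": cfg.inter_rate,
        "beta_len": cfg.beta_len,
        "beta_gc": cfg.beta_gc,
        "beta_map": cfg.beta_map,
        "translocations": ";".join(
            f"{t.gene_a}-{t.gene_b}x{t.multiplier:g}" for t in cfg.translocations
        )
        or "none",
    }
    return Dataset(scaffold, pairs, truth, sequences)


def make_case_control(
    cfg: SimConfig, with_sequence: bool = False
) -> tuple[Dataset, Dataset]:
    """Paired samples sharing genome/genes, differing only in planted
    translocations: the case keeps ``cfg.translocations``, the control
    sets every multiplier to 1.  Pair draws are independent streams
    spawned from the same seed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    scaffold_rng, seq_rng, case_rng, ctrl_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    scaffold = simulate_scaffold(cfg, scaffold_rng)
    for t in cfg.translocations:
        for sym in (t.gene_a, t.gene_b):
            if sym not in scaffold.genes:
                raise ValueError(f"translocation references unknown gene {sym!r}")
    sequences = realize_sequence(scaffold, seq_rng) if with_sequence else None
    case_pairs = simulate_pairs(scaffold, case_rng, translocations=cfg.translocations)
    ctrl_pairs = simulate_pairs(scaffold, ctrl_rng, translocations=())
    base_truth = {
        "seed": cfg.seed,
        "n_pairs": cfg.n_pairs,
        "gamma": cfg.gamma,
    }
    case = Dataset(
        scaffold,
        case_pairs,
        {**base_truth, "sample": "case",
         "translocations": ";".join(
             f"{t.gene_a}-{t.gene_b}x{t.multiplier:g}" for t in cfg.translocations
         ) or "none"},
        sequences,
    )
    control = Dataset(
        scaffold, ctrl_pairs, {**base_truth, "sample": "control",
                               "translocations": "none"}, sequences
    )
    return case, control


def central_gene_pair(scaffold: Scaffold) -> tuple[str, str]:
    """One gene per (first two) chromosomes, nearest the chromosome midpoint.

    Convenience for planting translocations: central genes keep the
    planted pair away from chromosome ends.
    """
    chroms = scaffold.fragments.chromosomes[:2]
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes for a translocation pair")
    out = []
    for chrom in chroms:
        gs = [g for g in scaffold.genes if g.chrom == chrom]
        if not gs:
            raise ValueError(f"no genes on chromosome {chrom}")
        mid = scaffold.fragments.chrom_length(chrom) / 2
        out.append(min(gs, key=lambda g: abs((g.start + g.end) / 2 - mid)).symbol)
    return out[0], out[1]


def estimate_decay_slope(
    contacts,
    fragments: FragmentMap,
    n_bins: int = 12,
    min_sep: float = 5_000,
    max_sep: float | None = None,
) -> float:
    """Log-log slope of mean contact count per intra-chromosomal
    fragment pair against genomic separation.

    Counts are binned by mid-to-mid separation and normalized by the
    number of *eligible* fragment pairs in each bin, so the slope
    estimates the decay exponent -gamma directly.
    """
    fdf = fragments.df
    mids = ((fdf["start"] + fdf["end"]) / 2).to_numpy()
    chrom_codes = pd.Categorical(fdf["chrom"]).codes
    n = len(fdf)
    ia, ib = np.triu_indices(n, k=1)
    same = chrom_codes[ia] == chrom_codes[ib]
    nonadj = same & (ib - ia > 1)
    ia, ib = ia[nonadj], ib[nonadj]
    sep = np.abs(mids[ia] - mids[ib])
    if max_sep is None:
        max_sep = float(sep.max())
    bins = np.geomspace(min_sep, max_sep, n_bins + 1)

    counts = np.zeros(n_bins)
    npairs = np.zeros(n_bins)
    which = np.clip(np.digitize(sep, bins) - 1, 0, n_bins - 1)
    valid = (sep >= min_sep) & (sep <= max_sep)
    np.add.at(npairs, which[valid], 1)

    lookup = {}
    for a, b, c in contacts.rows():
        lookup[(a, b)] = c
    obs = np.array([lookup.get((a, b), 0) for a, b in zip(ia, ib)], dtype=float)
    np.add.at(counts, which[valid], obs[valid])

    ok = (npairs > 0) & (counts > 0)
    centers = np.sqrt(bins[:-1] * bins[1:])
    x = np.log(centers[ok])
    y = np.log(counts[ok] / npairs[ok])
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)
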