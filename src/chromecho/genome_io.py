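"""Genome binning, one-hot sequence encoding and peak-derived labels.

The genome is tiled into fixed-width, non-overlapping bins (default 200 bp)
which form the node set of the chromatin contact graph.  Each bin's flanked
sequence is one-hot encoded (rows A, C, G, T); ambiguous bases and positions
beyond chromosome ends are encoded as 0.25 in all four rows, so every column
of the encoding sums to one.  Chromatin features (TF binding, histone marks,
DHS) arrive as BED-style peak intervals, one file per feature, and become a
binary label matrix: a bin is positive for a feature when more than half of
the bin lies inside the feature's (merged) peaks.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicBin",
    "BinIndex",
    "LabelMatrix",
    "ChromosomeSplit",
    "bin_genome",
    "encode_sequence",
    "encode_string",
    "reverse_complement",
    "label_bins",
    "filter_active_bins",
    "split_by_chromosome",
    "write_bins_bed",
    "write_label_matrix",
]

_BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class GenomicBin:
    """A fixed-width genomic interval [start, start+width) on `chrom`."""

    chrom: str
    start: int
    width: int
    index: int

    @property
    def end(self) -> int:
        return self.start + self.width


class BinIndex:
    """The ordered tiling of a genome into equal-width bins.

    Bin indices are consecutive integers assigned in genomic order
    (chromosomes in input order, bins by start coordinate within each).
    """

    def __init__(self, bins: Sequence[GenomicBin], width: int):
        self.bins = list(bins)
        self.width = int(width)
        self.n = len(self.bins)
        self.chrom_of = np.array([b.chrom for b in self.bins], dtype=object)
        self.start_of = np.array([b.start for b in self.bins], dtype=np.int64)
        # chrom -> (first bin index, number of bins)
        self.chrom_span: dict[str, tuple[int, int]] = {}
        for b in self.bins:
            if b.chrom not in self.chrom_span:
                self.chrom_span[b.chrom] = (b.index, 0)
            first, cnt = self.chrom_span[b.chrom]
            self.chrom_span[b.chrom] = (first, cnt + 1)

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> GenomicBin:
        return self.bins[i]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_span)

    def bin_at(self, chrom: str, pos: int) -> int:
        """Index of the bin containing position `pos` on `chrom`.

        Raises KeyError / IndexError when the position falls outside the
        binned portion of the genome.
        """
        if chrom not in self.chrom_span:
            raise KeyError(f"unknown chromosome {chrom!r}")
        first, cnt = self.chrom_span[chrom]
        k = pos // self.width
        if pos < 0 or k >= cnt:
            raise IndexError(f"position {chrom}:{pos} outside binned genome")
        return first + k

    def same_chromosome(self, i: int, j: int) -> bool:
        return self.chrom_of[i] == self.chrom_of[j]


def _chrom_lengths(genome) -> dict[str, int]:
    """Chromosome name -> length for a pyfaidx.Fasta or a str mapping."""
    if isinstance(genome, Mapping):
        return {c: len(s) for c, s in genome.items()}
    # pyfaidx.Fasta exposes keys() and len(record)
    return {name: len(genome[name]) for name in genome.keys()}


def bin_genome(genome, width: int = 200) -> BinIndex:
    """Tile every chromosome into consecutive `width`-bp bins.

    The trailing partial bin of each chromosome (fewer than `width` bp) is
    dropped.  Indices are assigned in genomic order across chromosomes.
    """
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    lengths = _chrom_lengths(genome)
    if not lengths:
        raise ValueError("empty genome: no chromosomes found")
    bins: list[GenomicBin] = []
    idx = 0
    for chrom, length in lengths.items():
        for start in range(0, (length // width) * width, width):
            bins.append(GenomicBin(chrom, start, width, idx))
            idx += 1
    if not bins:
        raise ValueError("no bins produced: all chromosomes shorter than width")
    return BinIndex(bins, width)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Sequence of [start, end) clipped to the chromosome; caller pads."""
    if isinstance(genome, Mapping):
        return genome[chrom][start:end]
    return str(genome[chrom][start:end])


def encode_string(seq: str) -> np.ndarray:
    """One-hot encode a sequence string to a 4 x len matrix (rows A,C,G,T).

    Any character outside A/C/G/T (case-insensitive) becomes 0.25 in all
    four rows.
    """
    n = len(seq)
    out = np.zeros((4, n), dtype=np.float32)
    for p, ch in enumerate(seq.upper()):
        row = _BASE_ROW.get(ch)
        if row is None:
            out[:, p] = 0.25
        else:
            out[row, p] = 1.0
    return out


def encode_sequence(bin_: GenomicBin, genome, flank: int = 400) -> np.ndarray:
    """One-hot encode a bin's sequence with `flank` bp on each side.

    Returns a 4 x (width + 2*flank) float32 matrix.  Positions beyond the
    chromosome boundaries are encoded as 0.25 in all four rows, the same
    encoding used for uncalled (N) bases.
    """
    lengths = _chrom_lengths(genome)
    if bin_.chrom not in lengths:
        raise KeyError(f"unknown chromosome {bin_.chrom!r}")
    L = lengths[bin_.chrom]
    a, b = bin_.start - flank, bin_.end + flank
    inner = _fetch(genome, bin_.chrom, max(a, 0), min(b, L))
    left_pad = max(0, -a)
    out = np.full((4, b - a), 0.25, dtype=np.float32)  # out-of-bounds stays 0.25
    if inner:
        out[:, left_pad : left_pad + len(inner)] = encode_string(inner)
    return out


def reverse_complement(x: np.ndarray) -> np.ndarray:
    """Reverse-complement a one-hot matrix.

    Reversing the row order swaps A<->T and C<->G, so the operation is a
    flip along both axes; 0.25 gap columns map to 0.25 gap columns.
    """
    return np.ascontiguousarray(x[::-1, ::-1])


@dataclass
class LabelMatrix:
    """Binary bin x feature labels plus per-feature metadata.

    `y[i, l]` is 1 iff more than half of bin i overlaps feature l's merged
    peaks.  `features` has columns name, category (TF / histone / DHS) and
    cell_type, aligned with the columns of `y`.
    """

    y: np.ndarray
    features: pd.DataFrame

    @property
    def n_bins(self) -> int:
        return self.y.shape[0]

    @property
    def n_features(self) -> int:
        return self.y.shape[1]


def _read_bed3(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        line = int(bad[0]) + 1
        raise ValueError(f"malformed interval (end <= start) in {path} line {line}")
    return df


def _merged_intervals(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-chromosome union of intervals as an (n, 2) array, sorted."""
    merged: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        iv = grp[["start", "end"]].to_numpy()
        iv = iv[np.argsort(iv[:, 0], kind="stable")]
        out = []
        cs, ce = iv[0]
        for s, e in iv[1:]:
            if s <= ce:  # abutting intervals merge: union in bp
                ce = max(ce, e)
            else:
                out.append((cs, ce))
                cs, ce = s, e
        out.append((cs, ce))
        merged[chrom] = np.array(out, dtype=np.int64)
    return merged


def label_bins(
    bins: BinIndex,
    peak_files: Mapping[str, object],
    feature_meta: pd.DataFrame | None = None,
) -> LabelMatrix:
    """Derive the binary label matrix from per-feature peak interval files.

    `peak_files` maps feature name -> BED3+/narrowPeak path (or an already
    loaded DataFrame with chrom/start/end columns).  A bin is positive when
    its total overlap with the feature's merged peaks strictly exceeds
    width/2 bp.  Record order within a peak file does not matter.
    """
    w = bins.width
    half = w / 2.0
    names = list(peak_files)
    y = np.zeros((len(bins), len(names)), dtype=np.uint8)
    for l, name in enumerate(names):
        src = peak_files[name]
        df = src if isinstance(src, pd.DataFrame) else _read_bed3(src)
        if df.empty:
            continue
        for chrom, iv in _merged_intervals(df).items():
            if chrom not in bins.chrom_span:
                continue
            first, cnt = bins.chrom_span[chrom]
            overlap = np.zeros(cnt, dtype=np.int64)
            for s, e in iv:
                k0 = max(s // w, 0)
                k1 = min((e - 1) // w, cnt - 1)
                for k in range(k0, k1 + 1):
                    overlap[k] += min(e, (k + 1) * w) - max(s, k * w)
            y[first : first + cnt, l] = (overlap > half).astype(np.uint8)
    if feature_meta is None:
        feature_meta = pd.DataFrame(
            {"name": names, "category": "TF", "cell_type": "NA"}
        )
    else:
        feature_meta = feature_meta.set_index("name").loc[names].reset_index()
    return LabelMatrix(y=y, features=feature_meta.reset_index(drop=True))


def filter_active_bins(
    labels: LabelMatrix, categories: Iterable[str] = ("TF",)
) -> np.ndarray:
    """Indices of bins positive for at least one feature of the categories.

    Mirrors the training-set restriction to segments bound by at least one
    TF; the category set is configurable so synthetic runs can widen it.
    """
    cats = set(categories)
    mask = labels.features["category"].isin(cats).to_numpy()
    if not mask.any():
        raise ValueError(f"no features of categories {sorted(cats)} present")
    keep = labels.y[:, mask].any(axis=1)
    return np.flatnonzero(keep)


@dataclass
class ChromosomeSplit:
    """Disjoint chromosome lists assigning bins to train/validation/test."""

    test: list[str]
    validation: list[str] = field(default_factory=list)
    train: list[str] | None = None  # None = all remaining chromosomes

    def resolve(self, chromosomes: Sequence[str]) -> dict[str, list[str]]:
        test = [c for c in self.test]
        val = [c for c in self.validation]
        if set(test) & set(val):
            raise ValueError("overlapping test/validation chromosome lists")
        if self.train is None:
            train = [c for c in chromosomes if c not in set(test) | set(val)]
        else:
            train = list(self.train)
            if set(train) & (set(test) | set(val)):
                raise ValueError("train chromosomes overlap test/validation")
        return {"train": train, "validation": val, "test": test}


def split_by_chromosome(
    bins: BinIndex,
    split: ChromosomeSplit,
    subset: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Partition bin indices (optionally a retained subset) by chromosome."""
    groups = split.resolve(bins.chromosomes)
    idx = np.arange(len(bins)) if subset is None else np.asarray(subset)
    chroms = bins.chrom_of[idx]
    out = {}
    for part, cl in groups.items():
        out[part] = idx[np.isin(chroms, cl)]
    return out


def write_bins_bed(bins: BinIndex, path, subset: np.ndarray | None = None) -> None:
    """Write (a subset of) the bin tiling as BED with the bin index in col 4."""
    idx = np.arange(len(bins)) if subset is None else np.asarray(subset)
    with open(path, "w") as fh:
        for i in idx:
            b = bins[int(i)]
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.index}\n")


def write_label_matrix(labels: LabelMatrix, prefix: str | os.PathLike) -> None:
    """Write labels as dense TSV plus a sidecar feature-metadata TSV."""
    prefix = str(prefix)
    np.savetxt(prefix + ".labels.tsv", labels.y, fmt="%d", delimiter="\t")
    labels.features.to_csv(prefix + ".features.tsv", sep="\t", index=False)
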