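"""SAMPLE and STACK: graph-to-grid neighborhood construction.

Convolution needs fixed-shape inputs, so each bin's variable-size
neighborhood is converted to a grid: the sequential neighborhood is the
window i-k_s ... i+k_s along the chromosome (center included, genomic
order), the spatial neighborhood is the top-k_c contact partners ranked by
contact value.  Missing slots — chromosome boundaries, bins with fewer than
k_c contacts — are filled by a virtual dummy node whose hidden
representation is all zeros.  Formally the stack is P @ phi+, where P is a
binary sampling matrix with exactly one 1 per row and phi+ is the hidden
matrix augmented with a final all-zero dummy row at index N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_maps import ContactGraph, spatial_neighbor_set
from .genome_io import BinIndex

__all__ = [
    "SamplingMatrix",
    "sample_sequential",
    "sample_spatial",
    "build_sampling_matrix",
    "stack_features",
    "gather_features",
    "augment_hidden",
    "build_neighborhoods",
    "export_neighbor_table",
]


@dataclass(frozen=True)
class SamplingMatrix:
    """A binary sampling matrix stored as one selected column per row.

    Row r selects column `indices[r]` of the augmented hidden matrix;
    column `n` (the last of n+1 columns) is the dummy node.
    """

    indices: np.ndarray  # shape (rows,), values in [0, n]
    n: int  # number of real bins; dummy column index

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if ((idx < 0) | (idx > self.n)).any():
            raise ValueError(f"sampling index outside [0, {self.n}]")
        object.__setattr__(self, "indices", idx)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.indices), self.n + 1)

    def dense(self) -> np.ndarray:
        """Materialize the full binary matrix (rows x (n+1))."""
        P = np.zeros(self.shape, dtype=np.float32)
        P[np.arange(len(self.indices)), self.indices] = 1.0
        return P


def sample_sequential(i: int, k_s: int, bins: BinIndex) -> np.ndarray:
    """Indices i-k_s ... i+k_s in genomic order, dummy-padded at boundaries.

    Slots that would cross a chromosome boundary (or the bin universe)
    become the dummy index N.
    """
    if k_s < 0:
        raise ValueError("k_s must be non-negative")
    n = len(bins)
    first, cnt = bins.chrom_span[bins.chrom_of[i]]
    out = np.full(1 + 2 * k_s, n, dtype=np.int64)
    for r, j in enumerate(range(i - k_s, i + k_s + 1)):
        if first <= j < first + cnt:
            out[r] = j
    return out


def sample_spatial(i: int, k_c: int, graph: ContactGraph) -> np.ndarray:
    """Top-k_c spatial neighbors of i by contact value, dummy-padded.

    Ordering comes from `spatial_neighbor_set` (value desc, then distance,
    then index); if fewer than k_c neighbors exist the tail is dummies.
    """
    if k_c < 1:
        raise ValueError("k_c must be at least 1")
    n = len(graph.bin_index)
    ranked = spatial_neighbor_set(graph, i)[:k_c]
    out = np.full(k_c, n, dtype=np.int64)
    for r, (j, _v) in enumerate(ranked):
        out[r] = j
    return out


def build_sampling_matrix(indices, n: int) -> SamplingMatrix:
    """Wrap an ordered index list (dummy = n) as a SamplingMatrix."""
    return SamplingMatrix(np.asarray(indices, dtype=np.int64), n)


def augment_hidden(phi: np.ndarray) -> np.ndarray:
    """Append the all-zero dummy row M' to the hidden matrix (N+1 x K)."""
    return np.vstack([phi, np.zeros((1, phi.shape[1]), dtype=phi.dtype)])


def stack_features(P: SamplingMatrix, phi: np.ndarray) -> np.ndarray:
    """STACK: the feature matrix Xi = P @ phi+ (dummy rows all-zero)."""
    if phi.shape[0] != P.n:
        raise ValueError(f"hidden matrix has {phi.shape[0]} rows, expected {P.n}")
    return P.dense() @ augment_hidden(phi)


def gather_features(indices: np.ndarray, phi_aug: np.ndarray) -> np.ndarray:
    """Row-gather equivalent of `stack_features` on pre-augmented phi.

    `indices` may be (rows,) for one center or (batch, rows); the result is
    bit-identical to the matrix-product formulation.
    """
    return phi_aug[indices]


def build_neighborhoods(
    bins: BinIndex, graph: ContactGraph, k_c: int, k_s: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin spatial (N x k_c) and sequential (N x (1+2k_s)) index arrays.

    With k_s == 0 the sequential array is the single center column, which a
    contacts-only model configuration simply ignores.
    """
    n = len(bins)
    idx_c = np.empty((n, k_c), dtype=np.int64)
    idx_s = np.empty((n, 1 + 2 * k_s), dtype=np.int64)
    for i in range(n):
        idx_c[i] = sample_spatial(i, k_c, graph)
        idx_s[i] = sample_sequential(i, k_s, bins)
    return idx_c, idx_s


def export_neighbor_table(
    path, bins: BinIndex, graph: ContactGraph, idx_c: np.ndarray, idx_s: np.ndarray
) -> None:
    """Audit TSV: center_index, rank, neighbor_index, kind, contact_value."""
    n = len(bins)
    with open(path, "w") as fh:
        fh.write("center_index\trank\tneighbor_index\tkind\tcontact_value\n")
        for i in range(idx_c.shape[0]):
            for r, j in enumerate(idx_s[i]):
                kind = "dummy" if j == n else "seq"
                fh.write(f"{i}\t{r}\t{j}\t{kind}\tNA\n")
            for r, j in enumerate(idx_c[i]):
                if j == n:
                    fh.write(f"{i}\t{r}\t{j}\tdummy\tNA\n")
                else:
                    fh.write(f"{i}\t{r}\t{j}\tspatial\t{graph.value(i, int(j)):.6g}\n")
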