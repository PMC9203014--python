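"""Chromatin contact maps as sparse symmetric weighted graphs over bins.

A contact map (Micro-C or Hi-C) is held as an undirected weighted graph on
the genome's bin tiling: edge (i, j) with i != j carries a positive contact
value.  The module covers the preprocessing chain used before training —
per-chromosome read-depth normalization of a pair of maps, cell-type merging
by entrywise maximum, thresholding of weak contacts, up-sampling of coarse
Hi-C maps to the fine bin resolution — plus contact-distance bookkeeping and
the deterministic spatial-neighbor ordering the sampler consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .genome_io import BinIndex

__all__ = [
    "ContactGraph",
    "DistanceRange",
    "load_contacts",
    "normalize_pair",
    "merge_maps",
    "threshold_contacts",
    "upsample_hic",
    "contact_distance",
    "stratify_by_distance",
    "spatial_neighbor_set",
    "write_triplets",
]

logger = logging.getLogger(__name__)


class ContactGraph:
    """Sparse symmetric map (i, j) -> positive contact value, no self loops.

    Edges are stored once with i < j; `neighbors` presents the symmetric
    view.  `resolution` is the bin width in bp; `provenance` records the
    processing applied (merged cell types, thresholds).
    """

    def __init__(
        self,
        bin_index: BinIndex,
        contacts: dict[tuple[int, int], float] | None = None,
        resolution: int | None = None,
        provenance: tuple[str, ...] = (),
    ):
        self.bin_index = bin_index
        self.resolution = int(resolution or bin_index.width)
        self.provenance = tuple(provenance)
        self._edges: dict[tuple[int, int], float] = {}
        if contacts:
            for (i, j), v in contacts.items():
                self._set(int(i), int(j), float(v))
        self._adj: dict[int, list[tuple[int, float]]] | None = None

    # -- construction ------------------------------------------------------
    def _set(self, i: int, j: int, v: float) -> None:
        if i == j:
            return
        if v <= 0:
            raise ValueError(f"contact value must be positive, got {v} at ({i},{j})")
        self._edges[(min(i, j), max(i, j))] = v
        self._adj = None

    @classmethod
    def from_edges(
        cls,
        bin_index: BinIndex,
        edges: Iterable[tuple[int, int, float]],
        combine: str = "sum",
        resolution: int | None = None,
        provenance: tuple[str, ...] = (),
    ) -> "ContactGraph":
        """Build a graph from (i, j, value) records.

        Duplicate records for an unordered pair are combined by `combine`
        ("sum" for read counts, "max" for already-aggregated values); self
        pairs are dropped.
        """
        g = cls(bin_index, resolution=resolution, provenance=provenance)
        acc: dict[tuple[int, int], float] = {}
        for i, j, v in edges:
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in acc:
                acc[key] = acc[key] + v if combine == "sum" else max(acc[key], v)
            else:
                acc[key] = float(v)
        for (i, j), v in acc.items():
            g._set(i, j, v)
        return g

    # -- queries -----------------------------------------------------------
    def value(self, i: int, j: int) -> float:
        return self._edges.get((min(i, j), max(i, j)), 0.0)

    def edges(self) -> Iterable[tuple[int, int, float]]:
        """Iterate (i, j, value) with i < j in sorted order."""
        for (i, j) in sorted(self._edges):
            yield i, j, self._edges[(i, j)]

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        if self._adj is None:
            adj: dict[int, list[tuple[int, float]]] = {}
            for (a, b), v in self._edges.items():
                adj.setdefault(a, []).append((b, v))
                adj.setdefault(b, []).append((a, v))
            self._adj = adj
        return self._adj.get(i, [])

    def to_coo(self) -> sp.coo_matrix:
        """Full symmetric sparse matrix view (both triangles populated)."""
        n = len(self.bin_index)
        if not self._edges:
            return sp.coo_matrix((n, n))
        ij = np.array(list(self._edges), dtype=np.int64)
        v = np.array(list(self._edges.values()))
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        return sp.coo_matrix((np.concatenate([v, v]), (rows, cols)), shape=(n, n))

    def copy_with(self, contacts, provenance_extra=()) -> "ContactGraph":
        return ContactGraph(
            self.bin_index,
            contacts,
            resolution=self.resolution,
            provenance=self.provenance + tuple(provenance_extra),
        )


def load_contacts(
    path,
    bin_index: BinIndex,
    dialect: str = "triplet",
    resolution: int | None = None,
) -> ContactGraph:
    """Read a contact map from text.

    dialect="triplet": whitespace-separated ``bin_i bin_j value`` records
    where the first two columns are bin indices.  dialect="pairs":
    ``chrom1 pos1 chrom2 pos2 [count]`` records (count defaults to 1);
    positions are assigned to the bin containing them.  Duplicate records
    for one pair are summed; self pairs are dropped.
    """
    edges: list[tuple[int, int, float]] = []
    n = len(bin_index)
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            try:
                if dialect == "triplet":
                    i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
                    if not (0 <= i < n and 0 <= j < n):
                        raise IndexError(f"bin index outside universe [0,{n})")
                elif dialect == "pairs":
                    c1, p1, c2, p2 = parts[0], int(parts[1]), parts[2], int(parts[3])
                    v = float(parts[4]) if len(parts) > 4 else 1.0
                    i = bin_index.bin_at(c1, p1)
                    j = bin_index.bin_at(c2, p2)
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except (ValueError, KeyError, IndexError) as exc:
                raise ValueError(f"{path} line {ln}: {exc}") from exc
            edges.append((i, j, v))
    return ContactGraph.from_edges(
        bin_index, edges, combine="sum", resolution=resolution,
        provenance=(f"load:{path}",),
    )


def _intra_totals(g: ContactGraph) -> dict[str, float]:
    totals: dict[str, float] = {c: 0.0 for c in g.bin_index.chromosomes}
    chrom = g.bin_index.chrom_of
    for i, j, v in g.edges():
        if chrom[i] == chrom[j]:
            totals[chrom[i]] += v
    return totals


def normalize_pair(map_a: ContactGraph, map_b: ContactGraph):
    """Equalize per-chromosome intra-chromosomal totals of two maps.

    For each chromosome, the map with the larger total read count is scaled
    by (smaller total / larger total), so both maps end with the smaller
    total; the smaller-total map is left untouched.  A chromosome with zero
    total in exactly one map is left unscaled with a warning.
    Inter-chromosomal edges are never scaled.
    """
    if len(map_a.bin_index) != len(map_b.bin_index) or map_a.resolution != map_b.resolution:
        raise ValueError("maps must share bin universe and resolution")
    ta, tb = _intra_totals(map_a), _intra_totals(map_b)
    chrom = map_a.bin_index.chrom_of

    def scaled(g: ContactGraph, own: dict, other: dict) -> ContactGraph:
        out: dict[tuple[int, int], float] = {}
        factor = {}
        for c in own:
            if own[c] > other[c] > 0:
                factor[c] = other[c] / own[c]
            elif (own[c] == 0) != (other[c] == 0):
                logger.warning("chromosome %s has zero total in one map; left unscaled", c)
        for (i, j), v in g._edges.items():
            f = factor.get(chrom[i], 1.0) if chrom[i] == chrom[j] else 1.0
            out[(i, j)] = v * f
        return g.copy_with(out, ("normalize_pair",))

    return scaled(map_a, ta, tb), scaled(map_b, tb, ta)


def merge_maps(maps: Sequence[ContactGraph]) -> ContactGraph:
    """Entrywise maximum over the union of edges (cell-type merging)."""
    if not maps:
        raise ValueError("no maps to merge")
    first = maps[0]
    for g in maps[1:]:
        if g.resolution != first.resolution or len(g.bin_index) != len(first.bin_index):
            raise ValueError("mismatched resolutions or bin universes")
    merged: dict[tuple[int, int], float] = {}
    tags = []
    for g in maps:
        tags.extend(g.provenance)
        for key, v in g._edges.items():
            merged[key] = max(merged.get(key, 0.0), v)
    return ContactGraph(
        first.bin_index, merged, resolution=first.resolution,
        provenance=tuple(tags) + ("merge:max",),
    )


def threshold_contacts(graph: ContactGraph, tau: float) -> ContactGraph:
    """Drop edges with value < tau (values exactly tau are kept)."""
    if tau <= 0:
        raise ValueError(f"threshold tau must be positive, got {tau}")
    kept = {k: v for k, v in graph._edges.items() if v >= tau}
    return graph.copy_with(kept, (f"threshold:{tau}",))


def upsample_hic(
    coarse: ContactGraph, fine_bins: BinIndex
) -> ContactGraph:
    """Up-sample a coarse (e.g. 1-kb) map onto the fine (e.g. 200-bp) tiling.

    Requires the coarse resolution R to be an odd multiple of the fine width
    r, so each coarse bin has a unique central fine bin.  Every fine bin c is
    connected to the central fine bin of each coarse neighbor of c's
    enclosing coarse bin, carrying the coarse contact value.  A fine pair
    reachable from both directions keeps the (identical) value via max.
    """
    R, r = coarse.resolution, fine_bins.width
    m = R // r
    if R != m * r or m % 2 == 0:
        raise ValueError(f"coarse resolution {R} must be an odd multiple of {r}")
    half = m // 2
    cb = coarse.bin_index

    def central_fine(coarse_idx: int) -> int | None:
        chrom = cb.chrom_of[coarse_idx]
        start = int(cb.start_of[coarse_idx]) + half * r
        try:
            return fine_bins.bin_at(chrom, start)
        except (KeyError, IndexError):
            return None

    def fine_members(coarse_idx: int) -> list[int]:
        chrom = cb.chrom_of[coarse_idx]
        base = int(cb.start_of[coarse_idx])
        out = []
        for k in range(m):
            try:
                out.append(fine_bins.bin_at(chrom, base + k * r))
            except (KeyError, IndexError):
                pass
        return out

    edges: list[tuple[int, int, float]] = []
    for I, J, v in coarse.edges():
        aJ, aI = central_fine(J), central_fine(I)
        if aJ is not None:
            for c in fine_members(I):
                if c != aJ:
                    edges.append((c, aJ, v))
        if aI is not None:
            for c in fine_members(J):
                if c != aI:
                    edges.append((c, aI, v))
    return ContactGraph.from_edges(
        fine_bins, edges, combine="max", resolution=r,
        provenance=coarse.provenance + (f"upsample:{R}->{r}",),
    )


def contact_distance(bin_index: BinIndex, i: int, j: int) -> float:
    """Genomic separation |start_i - start_j| in bp; inf across chromosomes."""
    if not bin_index.same_chromosome(i, j):
        return math.inf
    return float(abs(int(bin_index.start_of[i]) - int(bin_index.start_of[j])))


@dataclass(frozen=True)
class DistanceRange:
    """Half-open contact-distance range [lower, upper) in bp."""

    lower: float
    upper: float  # math.inf for an unbounded "over X" range

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"invalid range [{self.lower}, {self.upper})")

    def __contains__(self, d: float) -> bool:
        return self.lower <= d < self.upper


#: The four contact-distance groups used in the distance-stratified analysis.
DEFAULT_DISTANCE_RANGES = (
    DistanceRange(0, 1_000),
    DistanceRange(1_000, 5_000),
    DistanceRange(5_000, 20_000),
    DistanceRange(20_000, math.inf),
)


def stratify_by_distance(
    graph: ContactGraph, ranges: Sequence[DistanceRange]
) -> list[ContactGraph]:
    """Partition intra-chromosomal edges into contact-distance strata.

    Each edge goes to the unique range containing its distance; edges whose
    distance falls outside all ranges — including inter-chromosomal edges,
    whose distance is infinite — are dropped.
    """
    for a in range(len(ranges)):
        for b in range(a + 1, len(ranges)):
            lo = max(ranges[a].lower, ranges[b].lower)
            hi = min(ranges[a].upper, ranges[b].upper)
            if lo < hi:
                raise ValueError(f"overlapping ranges {ranges[a]} and {ranges[b]}")
    buckets: list[dict[tuple[int, int], float]] = [dict() for _ in ranges]
    for (i, j), v in graph._edges.items():
        d = contact_distance(graph.bin_index, i, j)
        for k, rng in enumerate(ranges):
            if d in rng:
                buckets[k][(i, j)] = v
                break
    return [
        graph.copy_with(b, (f"stratum:[{r.lower},{r.upper})",))
        for b, r in zip(buckets, ranges)
    ]


def spatial_neighbor_set(
    graph: ContactGraph, i: int, tau: float | None = None
) -> list[tuple[int, float]]:
    """Neighbors of bin i ordered for top-k sampling.

    Sorted by contact value descending; ties broken by smaller contact
    distance, then smaller bin index, so the ordering is deterministic.
    An optional tau re-filters values below the threshold.
    """
    nbrs = graph.neighbors(i)
    if tau is not None:
        nbrs = [(j, v) for j, v in nbrs if v >= tau]
    key = lambda jv: (-jv[1], contact_distance(graph.bin_index, i, jv[0]), jv[0])
    return sorted(nbrs, key=key)


def write_triplets(graph: ContactGraph, path) -> None:
    """Write the graph as sorted ``i j value`` triplet text (i < j)."""
    with open(path, "w") as fh:
        for i, j, v in graph.edges():
            fh.write(f"{i}\t{j}\t{v:.10g}\n")
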