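"""Synthetic genomes, peak files and contact maps with planted structure.

The generator emulates the three inputs of the pipeline on a desk scale:

* a multi-chromosome genome of i.i.d. uniform background sequence with
  known motif instances planted inside bins (an instance registry records
  every placement);
* intra-chromosomal contact maps whose counts are Poisson draws around a
  power-law distance decay, plus planted long-range loops that add a fixed
  strength to an anchor pair;
* per-feature peak BED files derived from planted binding rules — either
  sequence-only (motif on the bin) or collaborative (motif on the bin AND a
  second motif on a spatially contacting bin, optionally restricted to a
  contact-distance range).

Rules are evaluated on the same thresholded graph the model later samples
from, so recovery experiments are well-posed.  Everything is driven by one
seeded generator: a fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .contact_maps import ContactGraph, contact_distance, threshold_contacts, write_triplets
from .genome_io import BinIndex, bin_genome

__all__ = [
    "Motif",
    "LabelRule",
    "SyntheticSpec",
    "generate_genome",
    "generate_contact_map",
    "generate_labels",
    "make_fixture",
    "PRESETS",
]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Motif:
    """A consensus string planted with per-position mutation probability."""

    name: str
    consensus: str
    mutation_rate: float = 0.0


@dataclass(frozen=True)
class LabelRule:
    """How a chromatin feature's positive bins are derived.

    Sequence-only rule: `center_motif` present in the bin.  Collaborative
    rule: additionally `neighbor_motif` present in some spatial neighbor
    with contact value >= `min_contact` (and, if set, contact distance in
    [distance_lo, distance_hi) bp).  `noise` flips each label with the given
    probability.
    """

    name: str
    center_motif: str
    neighbor_motif: str | None = None
    min_contact: float | None = None
    distance_lo: float | None = None
    distance_hi: float | None = None
    noise: float = 0.0
    category: str = "TF"
    cell_type: str = "synthetic"


@dataclass
class SyntheticSpec:
    """Full description of a synthetic study; the seed fixes every byte."""

    chrom_lengths: dict = field(default_factory=lambda: {"c1": 40_000})
    bin_width: int = 200
    flank: int = 100
    motifs: list = field(default_factory=list)
    plant_rate: dict = field(default_factory=dict)  # motif name -> per-bin rate
    decay_exponent: float = 1.0
    count_scale: float = 10.0  # Poisson mean at one-bin separation
    loop_prob: float = 0.0  # per-bin probability of anchoring a planted loop
    loop_distance_bins: tuple = (5, 50)  # partner offset range, in bins
    loop_strength: float = 50.0
    explicit_loops: list = field(default_factory=list)  # (i, j, strength)
    tau: float = 2.0  # graph threshold the rules are evaluated on
    rules: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for m in self.motifs:
            if not 0.0 <= m.mutation_rate <= 1.0:
                raise ValueError(f"mutation rate of {m.name} outside [0,1]")
        for name, rate in self.plant_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"plant rate of {name} outside [0,1]")
        for r in self.rules:
            if not 0.0 <= r.noise <= 1.0:
                raise ValueError(f"noise rate of {r.name} outside [0,1]")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["motifs"] = [asdict(m) for m in self.motifs]
        d["rules"] = [asdict(r) for r in self.rules]
        return d


def _stream_rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag])


def generate_genome(spec: SyntheticSpec):
    """Random genome with planted motif instances.

    Returns (sequences: {chrom: str}, registry DataFrame with one row per
    planted instance: chrom, bin_start, bin_index, motif, offset, strand).
    Instances are confined within a single bin; within a bin, placements
    that would overlap an earlier instance are re-drawn (up to 20 tries)
    and dropped if no free slot is found.
    """
    rng = _stream_rng(spec.seed, 1)
    w = spec.bin_width
    motifs = {m.name: m for m in spec.motifs}
    for m in spec.motifs:
        if len(m.consensus) > w:
            raise ValueError(f"motif {m.name} longer than bin width {w}")
    seqs: dict[str, np.ndarray] = {}
    registry = []
    bin_index = 0
    for chrom, length in spec.chrom_lengths.items():
        arr = _BASES[rng.integers(0, 4, size=length)].copy()
        n_bins = length // w
        for b in range(n_bins):
            base = b * w
            occupied: list[tuple[int, int]] = []
            for name, rate in spec.plant_rate.items():
                if rng.random() >= rate:
                    continue
                motif = motifs[name]
                ml = len(motif.consensus)
                placed = None
                for _try in range(20):
                    off = int(rng.integers(0, w - ml + 1))
                    if all(off + ml <= s or off >= e for s, e in occupied):
                        placed = off
                        break
                if placed is None:
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                inst = _mutate(motif, rng)
                if strand == "-":
                    inst = inst.translate(_COMP)[::-1]
                arr[base + placed : base + placed + ml] = list(inst)
                occupied.append((placed, placed + ml))
                registry.append({
                    "chrom": chrom, "bin_start": base, "bin_index": bin_index,
                    "motif": name, "offset": placed, "strand": strand,
                })
            bin_index += 1
        seqs[chrom] = "".join(arr)
    reg = pd.DataFrame(registry, columns=["chrom", "bin_start", "bin_index", "motif", "offset", "strand"])
    return seqs, reg


def _mutate(motif: Motif, rng) -> str:
    if motif.mutation_rate == 0.0:
        return motif.consensus
    out = list(motif.consensus)
    for p in range(len(out)):
        if rng.random() < motif.mutation_rate:
            out[p] = str(rng.choice(_BASES))
    return "".join(out)


def generate_contact_map(spec: SyntheticSpec, bins: BinIndex):
    """Distance-decaying Poisson contact map with planted loops.

    The expected count of an intra-chromosomal pair at separation d bins is
    count_scale * d^(-decay_exponent); pairs are sampled out to the
    separation where the mean falls below 0.25 (counts beyond that are
    filtered by any threshold >= 1 anyway).  Planted loops — explicit ones
    plus per-bin random loops drawn with `loop_prob` — add `loop_strength`
    to the sampled value.  Returns (graph, loops list).
    """
    if spec.decay_exponent <= 0:
        raise ValueError("decay exponent must be positive")
    rng = _stream_rng(spec.seed, 2)
    max_sep = int(np.ceil((spec.count_scale / 0.25) ** (1.0 / spec.decay_exponent)))
    edges: dict[tuple[int, int], float] = {}
    for chrom, (first, cnt) in bins.chrom_span.items():
        for i in range(first, first + cnt):
            hi = min(i + max_sep, first + cnt - 1)
            for j in range(i + 1, hi + 1):
                mean = spec.count_scale * float(j - i) ** (-spec.decay_exponent)
                v = rng.poisson(mean)
                if v > 0:
                    edges[(i, j)] = float(v)
    loops: list[tuple[int, int, float]] = [tuple(l) for l in spec.explicit_loops]
    if spec.loop_prob > 0:
        lo, hi = spec.loop_distance_bins
        for chrom, (first, cnt) in bins.chrom_span.items():
            for i in range(first, first + cnt):
                if rng.random() >= spec.loop_prob:
                    continue
                off = int(rng.integers(lo, hi + 1))
                sign = 1 if rng.random() < 0.5 else -1
                j = i + sign * off
                if not (first <= j < first + cnt):
                    j = i - sign * off
                if not (first <= j < first + cnt) or j == i:
                    continue
                loops.append((i, j, spec.loop_strength))
    for i, j, s in loops:
        key = (min(i, j), max(i, j))
        edges[key] = edges.get(key, 0.0) + s
    graph = ContactGraph(bins, edges, resolution=bins.width, provenance=("synthetic",))
    return graph, loops


def generate_labels(registry: pd.DataFrame, graph: ContactGraph, spec: SyntheticSpec, bins: BinIndex):
    """Evaluate the planted rules into truth labels and peak intervals.

    Rules are evaluated on the tau-thresholded graph.  Returns
    (truth: N x n_rules uint8 array BEFORE noise, labels: after noise,
    peaks: {feature: list of (chrom, start, end)}).  Peaks cover each
    positive bin entirely, so the >half labelling rule reproduces the
    labels exactly.
    """
    motif_names = {m.name for m in spec.motifs}
    for r in spec.rules:
        for m in (r.center_motif, r.neighbor_motif):
            if m is not None and m not in motif_names:
                raise ValueError(f"rule {r.name} references unknown motif {m!r}")
    rng = _stream_rng(spec.seed, 3)
    n = len(bins)
    has = {
        name: np.isin(np.arange(n), registry.loc[registry["motif"] == name, "bin_index"].to_numpy())
        for name in motif_names
    }
    g = threshold_contacts(graph, spec.tau)
    truth = np.zeros((n, len(spec.rules)), dtype=np.uint8)
    labels = np.zeros_like(truth)
    peaks: dict[str, list[tuple[str, int, int]]] = {}
    for l, rule in enumerate(spec.rules):
        pos = has[rule.center_motif].copy()
        if rule.neighbor_motif is not None:
            min_c = rule.min_contact if rule.min_contact is not None else spec.tau
            for i in np.flatnonzero(pos):
                ok = False
                for j, v in g.neighbors(int(i)):
                    if v < min_c or not has[rule.neighbor_motif][j]:
                        continue
                    d = contact_distance(bins, int(i), j)
                    if rule.distance_lo is not None and d < rule.distance_lo:
                        continue
                    if rule.distance_hi is not None and d >= rule.distance_hi:
                        continue
                    ok = True
                    break
                pos[i] = ok
        truth[:, l] = pos.astype(np.uint8)
        lab = pos.copy()
        if rule.noise > 0:
            flip = rng.random(n) < rule.noise
            lab = lab ^ flip
        labels[:, l] = lab.astype(np.uint8)
        peaks[rule.name] = [
            (bins.chrom_of[i], int(bins.start_of[i]), int(bins.start_of[i]) + bins.width)
            for i in np.flatnonzero(labels[:, l])
        ]
    return truth, labels, peaks


def _write_fasta(seqs: dict[str, str], path, line: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, s in seqs.items():
            fh.write(f">{chrom}\n")
            for k in range(0, len(s), line):
                fh.write(s[k : k + line] + "\n")


_MOTIF_A = Motif("motifA", "AGGTCATGCC")
_MOTIF_B = Motif("motifB", "CTTGACGTAA")


def _tiny_spec(seed: int) -> SyntheticSpec:
    return SyntheticSpec(
        chrom_lengths={"c1": 40_000, "c2": 30_000, "c3": 30_000},
        motifs=[_MOTIF_A, _MOTIF_B],
        plant_rate={"motifA": 0.3, "motifB": 0.3},
        loop_prob=0.7,
        loop_distance_bins=(5, 50),
        rules=[
            LabelRule("f_seqA", "motifA"),
            LabelRule("f_seqB", "motifB"),
            LabelRule("f_collab", "motifA", neighbor_motif="motifB", min_contact=20.0),
        ],
        seed=seed,
    )


def _collaborative_spec(seed: int) -> SyntheticSpec:
    return SyntheticSpec(
        chrom_lengths={"c1": 160_000, "c2": 80_000, "c3": 80_000, "c4": 80_000},
        motifs=[_MOTIF_A, _MOTIF_B],
        plant_rate={"motifA": 0.3, "motifB": 0.3},
        loop_prob=0.7,
        loop_distance_bins=(5, 50),
        rules=[
            LabelRule("f_seqA", "motifA"),
            LabelRule("f_seqB", "motifB"),
            LabelRule("f_collab", "motifA", neighbor_motif="motifB", min_contact=20.0),
        ],
        seed=seed,
    )


def _distance_spec(seed: int) -> SyntheticSpec:
    # near loops land in [1 kb, 5 kb); far loops beyond 20 kb are planted
    # between random anchors and carry no label information.
    return SyntheticSpec(
        chrom_lengths={"c1": 160_000, "c2": 80_000, "c3": 80_000, "c4": 80_000},
        motifs=[_MOTIF_A, _MOTIF_B],
        plant_rate={"motifA": 0.3, "motifB": 0.3},
        loop_prob=0.7,
        loop_distance_bins=(6, 24),  # 1.2-4.8 kb: inside the wired stratum
        rules=[
            LabelRule("f_seqA", "motifA"),
            LabelRule("f_seqB", "motifB"),
            LabelRule(
                "f_dist", "motifA", neighbor_motif="motifB", min_contact=20.0,
                distance_lo=1_000.0, distance_hi=5_000.0,
            ),
        ],
        seed=seed,
    )


def _add_far_loops(spec: SyntheticSpec, bins: BinIndex) -> None:
    """Plant uninformative >20 kb loops so that stratum is populated."""
    rng = _stream_rng(spec.seed, 4)
    for chrom, (first, cnt) in bins.chrom_span.items():
        for i in range(first, first + cnt):
            if rng.random() >= 0.3:
                continue
            off = int(rng.integers(105, 200))
            j = i + off if i + off < first + cnt else i - off
            if first <= j < first + cnt and j != i:
                spec.explicit_loops.append((int(i), int(j), spec.loop_strength))


PRESETS = {
    "tiny": _tiny_spec,
    "collaborative": _collaborative_spec,
    "distance-specific": _distance_spec,
}

#: Chromosome roles shared by all presets (multi-chromosome splits).
PRESET_SPLIT = {"test": ["c2"], "validation": ["c3"]}


def make_fixture(preset: str, out_dir, seed: int = 0) -> dict:
    """Generate a complete input bundle plus a ground-truth manifest.

    Writes genome.fa, peaks/<feature>.bed, contacts.txt (triplet text),
    registry.tsv, truth.tsv and manifest.json under `out_dir` and returns
    the manifest dict.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[preset](seed)
    out_dir = str(out_dir)
    os.makedirs(os.path.join(out_dir, "peaks"), exist_ok=True)

    seqs, registry = generate_genome(spec)
    bins = bin_genome(seqs, spec.bin_width)
    if preset == "distance-specific":
        _add_far_loops(spec, bins)
    graph, loops = generate_contact_map(spec, bins)
    truth, labels, peaks = generate_labels(registry, graph, spec, bins)

    _write_fasta(seqs, os.path.join(out_dir, "genome.fa"))
    write_triplets(graph, os.path.join(out_dir, "contacts.txt"))
    registry.to_csv(os.path.join(out_dir, "registry.tsv"), sep="\t", index=False)
    np.savetxt(os.path.join(out_dir, "truth.tsv"), truth, fmt="%d", delimiter="\t")
    for name, iv in peaks.items():
        with open(os.path.join(out_dir, "peaks", f"{name}.bed"), "w") as fh:
            for chrom, s, e in iv:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    manifest = {
        "preset": preset,
        "seed": seed,
        "spec": spec.to_jsonable(),
        "split": PRESET_SPLIT,
        "n_bins": len(bins),
        "features": [r.name for r in spec.rules],
        "feature_categories": {r.name: r.category for r in spec.rules},
        "n_loops": len(loops),
        "loops": [[int(i), int(j), float(s)] for i, j, s in loops],
        "files": {
            "genome": "genome.fa",
            "contacts": "contacts.txt",
            "peaks": {name: f"peaks/{name}.bed" for name in peaks},
            "registry": "registry.tsv",
            "truth": "truth.tsv",
        },
        "expected": {
            "wired_feature": spec.rules[-1].name,
            "sequence_only_feature": "f_seqA",
            "wiring": "last feature requires motifA on the center and motifB on a "
                      "qualifying spatial neighbor",
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
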