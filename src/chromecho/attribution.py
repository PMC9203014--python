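"""Gradient-times-input attribution on contacts and sequences.

For a trained model, the contribution of each sampled neighbor to the
prediction of feature l at center i is scored on the binary sampling
matrices: S = P (Hadamard) d y_l / d P, which is nonzero exactly where P is.
Because Xi = P @ phi+, the gradient w.r.t. P factors as
(d y_l / d Xi) @ phi+^T, so each selected row r scores
grad_Xi[r] . phi[selected bin].  The two per-matrix score sets are
compressed to per-neighbor vectors (dummy column dropped, repeated
selections summed within a matrix), combined across the sequential and
spatial routes by maximum, and assembled into the sparse interaction
importance matrix M_l, whose rows are then normalized by their maximum
absolute value to give M_l_hat in [0, 1].

Sequence attribution propagates the same output gradient through the frozen
encoder to the one-hot input of every neighbor j:
S^(j) = x^(j) (Hadamard) (d y_l / d Xi . d Xi / d x^(j)), scoring base pairs
of the neighborhood for their contribution to the center's feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contact_maps import ContactGraph, contact_distance, DistanceRange
from .model import EchoModel, SequenceEncoder

__all__ = [
    "ContactAttribution",
    "attribute_contacts",
    "aggregate_labels",
    "compress_and_combine",
    "build_importance_matrix",
    "normalize_importance",
    "attribute_sequences",
    "select_collaborative_pairs",
    "interaction_percentage_analysis",
    "write_importance_triplets",
    "read_importance_triplets",
    "write_bedgraph",
]


@dataclass
class ContactAttribution:
    """Per-center attribution of the two sampling matrices for one feature.

    `S_c` is k_c x (N+1), `S_s` is (1+2k_s) x (N+1); entries are nonzero
    only at each row's selected column.  `idx_c` / `idx_s` record the
    selections (dummy = N).
    """

    center: int
    label: int | None
    S_c: np.ndarray
    S_s: np.ndarray
    idx_c: np.ndarray
    idx_s: np.ndarray
    n: int


def _xi_gradients(model: EchoModel, phi_aug, idx_c_row, idx_s_row, l, wrt="prob"):
    """d y_l / d Xi_c and d Xi_s for a single center, plus the probability."""
    probs = model.forward(phi_aug[idx_c_row][None], phi_aug[idx_s_row][None])
    L = probs.shape[1]
    if not (0 <= l < L):
        raise IndexError(f"feature index {l} out of range [0,{L})")
    seed = np.zeros((1, L), dtype=np.float32)
    seed[0, l] = 1.0
    if wrt == "prob":
        g_c, g_s = model.backward_from_probs(seed)
    elif wrt == "logit":
        g_c, g_s = model.backward(seed)
    else:
        raise ValueError(f"wrt must be 'prob' or 'logit', got {wrt!r}")
    return g_c[0], g_s[0], float(probs[0, l])


def attribute_contacts(
    model: EchoModel,
    phi_aug: np.ndarray,
    idx_c_row: np.ndarray,
    idx_s_row: np.ndarray,
    i: int,
    l: int,
    wrt: str = "prob",
) -> ContactAttribution:
    """gradient x input scores of the two sampling matrices for feature l.

    With Xi = P @ phi+, d y / d P[r, t] = grad_Xi[r] . phi+[t]; the Hadamard
    product with binary P leaves exactly one entry per row, at the selected
    column.  `wrt` picks the probability (default, matching the predicted
    y-hat) or the pre-sigmoid logit (useful when sigmoids saturate).
    """
    g_c, g_s, _ = _xi_gradients(model, phi_aug, idx_c_row, idx_s_row, l, wrt)
    n = phi_aug.shape[0] - 1

    def scores(g_xi, idx):
        S = np.zeros((len(idx), n + 1), dtype=np.float64)
        for r, t in enumerate(idx):
            S[r, t] = float(g_xi[r] @ phi_aug[t])
        return S

    return ContactAttribution(
        center=i, label=l,
        S_c=scores(g_c, idx_c_row), S_s=scores(g_s, idx_s_row),
        idx_c=np.asarray(idx_c_row), idx_s=np.asarray(idx_s_row), n=n,
    )


def aggregate_labels(attrs: Sequence[ContactAttribution]) -> ContactAttribution:
    """Elementwise sum of per-feature attributions over a feature set."""
    if not attrs:
        raise ValueError("empty attribution list")
    first = attrs[0]
    for a in attrs[1:]:
        if a.center != first.center:
            raise ValueError("attributions must share the same center")
    return ContactAttribution(
        center=first.center, label=None,
        S_c=sum(a.S_c for a in attrs), S_s=sum(a.S_s for a in attrs),
        idx_c=first.idx_c, idx_s=first.idx_s, n=first.n,
    )


def compress_and_combine(attr: ContactAttribution) -> np.ndarray:
    """Compress S_c / S_s to length-N vectors and take their combined row.

    Each matrix is compressed by reading the single nonzero per row into the
    selected neighbor's column; the dummy column is discarded and rows
    selecting the same neighbor twice are summed within a matrix.  Where a
    neighbor was sampled by both routes the maximum wins; where only one
    route sampled it, that route's value is used.
    """
    n = attr.n

    def compress(S, idx):
        v = np.zeros(n, dtype=np.float64)
        sampled = np.zeros(n, dtype=bool)
        for r, t in enumerate(idx):
            if t < n:
                v[t] += S[r, t]
                sampled[t] = True
        return v, sampled

    v_c, m_c = compress(attr.S_c, attr.idx_c)
    v_s, m_s = compress(attr.S_s, attr.idx_s)
    row = np.zeros(n, dtype=np.float64)
    both = m_c & m_s
    row[both] = np.maximum(v_c[both], v_s[both])
    row[m_c & ~m_s] = v_c[m_c & ~m_s]
    row[m_s & ~m_c] = v_s[m_s & ~m_c]
    return row


def build_importance_matrix(
    model: EchoModel,
    phi_aug: np.ndarray,
    idx_c: np.ndarray,
    idx_s: np.ndarray,
    labels: Sequence[int],
    centers: Sequence[int] | None = None,
    wrt: str = "prob",
) -> np.ndarray:
    """Signed interaction importance matrix M over the given feature set.

    Row i is zero unless i is in `centers` (default: every bin); entries at
    unsampled columns are zero by construction.
    """
    if not len(labels):
        raise ValueError("feature set must be nonempty")
    n = phi_aug.shape[0] - 1
    centers = range(idx_c.shape[0]) if centers is None else centers
    M = np.zeros((n, n), dtype=np.float64)
    for i in centers:
        per_l = [
            attribute_contacts(model, phi_aug, idx_c[i], idx_s[i], i, l, wrt)
            for l in labels
        ]
        M[i] = compress_and_combine(aggregate_labels(per_l))
    return M


def normalize_importance(M: np.ndarray) -> np.ndarray:
    """Row-wise |M| / max|row|; all-zero rows stay all-zero."""
    A = np.abs(np.asarray(M, dtype=np.float64))
    mx = A.max(axis=1, keepdims=True)
    out = np.zeros_like(A)
    nz = mx[:, 0] > 0
    out[nz] = A[nz] / mx[nz]
    return out


def attribute_sequences(
    model: EchoModel,
    encoder: SequenceEncoder,
    X: np.ndarray,
    phi_aug: np.ndarray,
    idx_c_row: np.ndarray,
    idx_s_row: np.ndarray,
    i: int,
    l: int,
    wrt: str = "prob",
) -> dict[int, np.ndarray]:
    """Base-level scores for the center and every sampled real neighbor.

    Returns {bin j -> 4 x W score matrix}, where each score is the one-hot
    input times the gradient of the center's feature l with respect to that
    input, chained through the frozen (but differentiable) encoder.  Gap
    positions encoded as 0.25 receive 0.25 x gradient — the formula is
    applied literally rather than masking gaps to zero.
    """
    g_c, g_s, _ = _xi_gradients(model, phi_aug, idx_c_row, idx_s_row, l, wrt)
    n = phi_aug.shape[0] - 1
    gphi: dict[int, np.ndarray] = {}
    for g_xi, idx in ((g_c, idx_c_row), (g_s, idx_s_row)):
        for r, t in enumerate(idx):
            if t < n:
                gphi[int(t)] = gphi.get(int(t), 0.0) + g_xi[r]
    out: dict[int, np.ndarray] = {}
    for j, g in gphi.items():
        encoder.forward(X[j][None])
        gx = encoder.backward(np.asarray(g, dtype=np.float32)[None])[0]
        out[j] = X[j] * gx
    return out


@dataclass(frozen=True)
class CollaborativePair:
    center: int
    neighbor: int
    contact_score: float


def select_collaborative_pairs(
    M_hat: np.ndarray,
    predictions: np.ndarray,
    labels: np.ndarray,
    l: int,
    score_threshold: float,
    pred_threshold: float = 0.5,
) -> list[CollaborativePair]:
    """Highly attributed contacts whose center is truly and predictedly positive.

    Keeps (i, j) with M_hat[i, j] >= score_threshold, label[i, l] == 1 and
    predicted probability >= pred_threshold ("successfully predicted").
    """
    pairs: list[CollaborativePair] = []
    ok_center = (labels[:, l] == 1) & (predictions[:, l] >= pred_threshold)
    for i in np.flatnonzero(ok_center):
        for j in np.flatnonzero(M_hat[i] >= score_threshold):
            pairs.append(CollaborativePair(int(i), int(j), float(M_hat[i, j])))
    return pairs


def interaction_percentage_analysis(
    M_hat: np.ndarray,
    positive: np.ndarray,
    graph: ContactGraph,
    distance_bins: Sequence[DistanceRange],
    score_thresholds: Sequence[float] = (0.1, 0.3, 0.5, 0.7),
) -> pd.DataFrame:
    """Fraction of attributed contacts whose far anchor shares the feature.

    Over directed contacts (center i, neighbor j) taken from the graph's
    edges with the center positive for the investigated feature set,
    reports — per contact-distance bin and per attribution-score threshold,
    plus an unfiltered 'all' baseline — the count of qualifying contacts and
    the fraction whose neighbor anchor is also positive.  Empty cells get
    percentage NA rather than 0.
    """
    positive = np.asarray(positive, dtype=bool)
    rows = []
    directed = []
    for i, j, _v in graph.edges():
        directed.append((i, j))
        directed.append((j, i))
    dist = {
        (i, j): contact_distance(graph.bin_index, i, j) for i, j in directed
    }
    for b, rng in enumerate(distance_bins):
        in_bin = [(i, j) for i, j in directed if dist[(i, j)] in rng and positive[i]]
        for thr in list(score_thresholds) + ["all"]:
            if thr == "all":
                sel = in_bin
            else:
                sel = [(i, j) for i, j in in_bin if M_hat[i, j] > thr]
            n_tot = len(sel)
            n_both = sum(1 for i, j in sel if positive[j])
            rows.append({
                "distance_bin": f"[{rng.lower:g},{rng.upper:g})",
                "threshold": thr,
                "n_center_bound": n_tot,
                "n_both_bound": n_both,
                "percentage": (100.0 * n_both / n_tot) if n_tot else np.nan,
            })
    return pd.DataFrame(rows)


def write_importance_triplets(M_hat: np.ndarray, path) -> None:
    """Write nonzero entries as sorted ``i j value`` text, round-trippable."""
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(M_hat)):
            fh.write(f"{i}\t{j}\t{float(M_hat[i, j])!r}\n")


def read_importance_triplets(path, n: int) -> np.ndarray:
    M = np.zeros((n, n), dtype=np.float64)
    with open(path) as fh:
        for line in fh:
            i, j, v = line.split()
            M[int(i), int(j)] = float(v)
    return M


def write_bedgraph(scores: np.ndarray, chrom: str, start: int, path, track_name: str = "attribution") -> None:
    """Per-base attribution track (scores summed over the nucleotide axis).

    `scores` is a 4 x W matrix aligned so column 0 sits at `start` on
    `chrom`; output intervals are 1 bp and tile the sequence without
    overlap.
    """
    per_base = np.asarray(scores).sum(axis=0)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for p, v in enumerate(per_base):
            fh.write(f"{chrom}\t{start + p}\t{start + p + 1}\t{v:.6g}\n")
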