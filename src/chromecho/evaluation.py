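"""Per-feature metrics, model comparisons and the distance-stratified harness.

AUROC uses midrank tie handling, AUPR is step-wise precision-recall
integration (no interpolation), and recall at a given FDR is the maximum
recall over score thresholds whose empirical false-discovery rate stays at
or below the target.  Features whose held-out labels contain a single class
get NA and are excluded from aggregate means.  Model comparisons use
two-sided paired t-tests on per-feature metric differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .contact_maps import ContactGraph, DistanceRange, stratify_by_distance
from .model import EchoModel, ModelConfig, TrainConfig, train_echo, predict
from .sampling import augment_hidden, build_neighborhoods

__all__ = [
    "auroc",
    "aupr",
    "recall_at_fdr",
    "paired_t_test",
    "TTestResult",
    "metric_table",
    "aggregate_by",
    "distance_experiment",
]

logger = logging.getLogger(__name__)


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(f"length mismatch: {scores.shape} vs {labels.shape}")
    return scores, labels


def auroc(scores, labels) -> float:
    """Rank-based AUROC with midrank ties; NA if one class is absent."""
    scores, labels = _check(scores, labels)
    if labels.min() == labels.max():
        return math.nan
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step integration); NA if no positives."""
    scores, labels = _check(scores, labels)
    if labels.sum() == 0:
        return math.nan
    return float(average_precision_score(labels, scores))


def recall_at_fdr(scores, labels, fdr: float = 0.5) -> float:
    """Maximum recall over thresholds with empirical FDR <= `fdr`.

    Thresholds sweep the distinct score values from high to low; tied
    scores enter together.  Returns 0 when no threshold qualifies.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr must be in (0,1), got {fdr}")
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        return math.nan
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # prefix boundaries at the last element of each tied block
    last_of_block = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    frac_fdr = fp[last_of_block] / (tp[last_of_block] + fp[last_of_block])
    recall = tp[last_of_block] / n_pos
    ok = frac_fdr <= fdr
    return float(recall[ok].max()) if ok.any() else 0.0


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    n_pairs: int
    zero_variance: bool


def paired_t_test(metrics_a, metrics_b) -> TTestResult:
    """Two-sided paired t-test on per-feature differences, NA pairs dropped.

    Zero-variance nonzero differences (possible on tiny synthetic runs) are
    reported as p -> 0 with a flag rather than erroring; identical tables
    give t = 0, p = 1.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("metric tables must align feature-wise")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least two valid feature pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TTestResult(0.0, 1.0, len(d), True)
        return TTestResult(math.copysign(math.inf, d.mean()), 0.0, len(d), True)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(float(t), float(p), len(d), False)


def metric_table(
    scores: np.ndarray,
    labels: np.ndarray,
    features: pd.DataFrame,
    fdr: float = 0.5,
) -> pd.DataFrame:
    """Per-feature AUROC / AUPR / recall@FDR with feature metadata attached."""
    rows = []
    for l in range(scores.shape[1]):
        rows.append({
            "name": features["name"].iloc[l],
            "category": features["category"].iloc[l],
            "cell_type": features["cell_type"].iloc[l],
            "auroc": auroc(scores[:, l], labels[:, l]),
            "aupr": aupr(scores[:, l], labels[:, l]),
            "recall_at_fdr": recall_at_fdr(scores[:, l], labels[:, l], fdr)
            if labels[:, l].sum() else math.nan,
        })
    return pd.DataFrame(rows)


def aggregate_by(table: pd.DataFrame, by: str = "category") -> pd.DataFrame:
    """Mean metrics per group, NA excluded, with the excluded count reported."""
    out = []
    for key, grp in table.groupby(by, sort=False):
        row = {by: key, "n_features": len(grp)}
        for m in ("auroc", "aupr", "recall_at_fdr"):
            row[m] = grp[m].mean(skipna=True)
            row[f"{m}_n_na"] = int(grp[m].isna().sum())
        out.append(row)
    return pd.DataFrame(out)


def distance_experiment(
    graph: ContactGraph,
    phi: np.ndarray,
    labels: np.ndarray,
    features: pd.DataFrame,
    split_idx: dict[str, np.ndarray],
    ranges: Sequence[DistanceRange],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    k_c: int,
) -> dict[str, pd.DataFrame]:
    """Retrain with a single contact-distance stratum at a time.

    For each range, the graph is restricted to contacts in that range, a
    fresh model with the same seed and configuration is trained with no
    sequential neighbors (k_s = 0), and the held-out metric table is
    returned keyed by the range.  Empty strata are skipped with a warning.
    Runs differ only through the contact input, so metric differences
    isolate the contribution of that distance range.
    """
    from dataclasses import replace

    strata = stratify_by_distance(graph, ranges)
    phi_aug = augment_hidden(phi)
    results: dict[str, pd.DataFrame] = {}
    for rng_, sub in zip(ranges, strata):
        key = f"[{rng_.lower:g},{rng_.upper:g})"
        if sub.n_edges == 0:
            logger.warning("distance stratum %s has no contacts; skipped", key)
            continue
        cfg = replace(model_cfg, k_s=0)
        idx_c, idx_s = build_neighborhoods(graph.bin_index, sub, k_c, 0)
        model = EchoModel(cfg, np.random.default_rng(train_cfg.seed))
        train_echo(phi_aug, idx_c, idx_s, labels,
                   split_idx["train"], split_idx["validation"], model, train_cfg)
        probs = predict(model, phi_aug, idx_c, idx_s, split_idx["test"])
        results[key] = metric_table(probs, labels[split_idx["test"]], features)
    return results
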