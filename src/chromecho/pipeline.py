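"""End-to-end orchestration: fixture -> bins/labels/graph -> training -> metrics.

This is the glue the CLI, the test-suite and the reproduction script share.
A `Bundle` holds everything derived from the raw inputs (bin tiling,
one-hot sequences, labels, thresholded contact graph, chromosome split);
`run_experiment` executes the full study on a bundle: pre-train the
sequence encoder, freeze it, train the graph model on sampled
neighborhoods, and score both the graph model and the sequence-only
baseline on the held-out chromosomes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact_maps import ContactGraph, load_contacts, threshold_contacts
from .genome_io import (
    BinIndex, ChromosomeSplit, LabelMatrix, bin_genome, encode_sequence,
    label_bins, split_by_chromosome,
)
from .model import (
    EchoModel, ModelConfig, SMALL_PRESET, TrainConfig, encode_all,
    pretrain_encoder, predict, sequence_only_predict, train_echo,
)
from .sampling import augment_hidden, build_neighborhoods

__all__ = ["Bundle", "RunParams", "load_fixture", "run_experiment"]


@dataclass
class RunParams:
    """Tunable knobs of a desk-scale run (architecture + optimization)."""

    bin_width: int = 200
    flank: int = 100
    tau: float = 2.0
    k_c: int = 8
    k_s: int = 2
    K: int = 64
    pretrain_epochs: int = 30
    pretrain_lr: float = 0.1
    train_epochs: int = 40
    train_lr: float = 0.05
    batch_size: int = 64
    seed: int = 0

    def model_config(self, seq_len: int, n_features: int) -> ModelConfig:
        # read motif presence from the central bin plus a motif-length margin
        frac = min(1.0, (self.bin_width + 20) / (self.bin_width + 2 * self.flank))
        return ModelConfig(
            seq_len=seq_len, K=self.K, k_c=self.k_c, k_s=self.k_s,
            n_features=n_features, enc_center_frac=frac,
            **{k: v for k, v in SMALL_PRESET.items() if k != "K"},
        )


@dataclass
class Bundle:
    """All inputs of one study, preprocessed and aligned on the bin tiling."""

    bins: BinIndex
    X: np.ndarray  # one-hot sequences, (N, 4, width + 2*flank)
    labels: LabelMatrix
    graph: ContactGraph  # thresholded
    split_idx: dict[str, np.ndarray]
    manifest: dict = field(default_factory=dict)


def load_fixture(fixture_dir, params: RunParams) -> Bundle:
    """Read a synthetic fixture directory into a preprocessed Bundle."""
    fixture_dir = str(fixture_dir)
    with open(os.path.join(fixture_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    import pyfaidx

    genome = pyfaidx.Fasta(os.path.join(fixture_dir, manifest["files"]["genome"]))
    bins = bin_genome(genome, params.bin_width)
    X = np.stack([encode_sequence(b, genome, params.flank) for b in bins.bins])
    peaks = {
        name: os.path.join(fixture_dir, rel)
        for name, rel in manifest["files"]["peaks"].items()
    }
    meta = pd.DataFrame({
        "name": list(peaks),
        "category": [manifest["feature_categories"][n] for n in peaks],
        "cell_type": "synthetic",
    })
    labels = label_bins(bins, peaks, meta)
    graph = load_contacts(os.path.join(fixture_dir, manifest["files"]["contacts"]), bins)
    graph = threshold_contacts(graph, params.tau)
    split = ChromosomeSplit(
        test=manifest["split"]["test"], validation=manifest["split"]["validation"]
    )
    split_idx = split_by_chromosome(bins, split)
    return Bundle(bins, X, labels, graph, split_idx, manifest)


def run_experiment(bundle: Bundle, params: RunParams) -> dict:
    """Pre-train, train and evaluate on one bundle.

    Returns a dict with the frozen encoder, the trained model, the
    augmented hidden matrix, neighbor index arrays, held-out probabilities
    for the graph model and the sequence-only baseline, and the loss
    histories.
    """
    seq_len = bundle.X.shape[2]
    L = bundle.labels.n_features
    cfg = params.model_config(seq_len, L)
    pre_tc = TrainConfig(
        batch_size=params.batch_size, lr=params.pretrain_lr,
        epochs=params.pretrain_epochs, seed=params.seed,
    )
    encoder, pre_head, pre_hist = pretrain_encoder(
        bundle.X, bundle.labels.y,
        bundle.split_idx["train"], bundle.split_idx["validation"], cfg, pre_tc,
    )
    phi = encode_all(encoder, bundle.X)
    phi_aug = augment_hidden(phi)
    idx_c, idx_s = build_neighborhoods(bundle.bins, bundle.graph, params.k_c, params.k_s)
    tc = TrainConfig(
        batch_size=params.batch_size, lr=params.train_lr,
        epochs=params.train_epochs, seed=params.seed,
    )
    model = EchoModel(cfg, np.random.default_rng(params.seed))
    hist = train_echo(
        phi_aug, idx_c, idx_s, bundle.labels.y,
        bundle.split_idx["train"], bundle.split_idx["validation"], model, tc,
    )
    test = bundle.split_idx["test"]
    return {
        "encoder": encoder,
        "pretrain_head": pre_head,
        "model": model,
        "model_config": cfg,
        "train_config": tc,
        "phi_aug": phi_aug,
        "idx_c": idx_c,
        "idx_s": idx_s,
        "probs_echo": predict(model, phi_aug, idx_c, idx_s, test),
        "probs_seq": sequence_only_predict(encoder, pre_head, bundle.X[test]),
        "probs_echo_all": predict(model, phi_aug, idx_c, idx_s),
        "test_idx": test,
        "pretrain_history": pre_hist,
        "train_history": hist,
    }
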