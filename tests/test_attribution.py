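"""gradient x input attribution: closed-form oracles and matrix assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from chromecho.attribution import (
    ContactAttribution,
    aggregate_labels,
    attribute_contacts,
    attribute_sequences,
    build_importance_matrix,
    compress_and_combine,
    interaction_percentage_analysis,
    normalize_importance,
    read_importance_triplets,
    select_collaborative_pairs,
    write_bedgraph,
    write_importance_triplets,
)
from chromecho.contact_maps import ContactGraph, DistanceRange
from chromecho.genome_io import bin_genome
from chromecho.model import EchoModel, ModelConfig, SequenceEncoder
from chromecho import nn


class LinearSurrogate:
    """EchoModel-compatible head that is a known linear map of vec(Xi_s||Xi_c).

    y_l = W_l . [vec(Xi_c); vec(Xi_s)], so d y_l / d Xi is a known reshape
    of W — the closed-form oracle for gradient x input scores.
    """

    def __init__(self, cfg: ModelConfig, rng):
        self.cfg = cfg
        S = 1 + 2 * cfg.k_s
        self.W = rng.normal(size=(cfg.n_features, (cfg.k_c + S) * cfg.K)).astype(np.float32)
        self._shapes = None

    def forward(self, xi_c, xi_s):
        self._shapes = (xi_c.shape, xi_s.shape)
        flat = np.concatenate(
            [xi_c.reshape(xi_c.shape[0], -1), xi_s.reshape(xi_s.shape[0], -1)], axis=1)
        self._probs = nn.sigmoid(flat @ self.W.T)
        return self._probs

    def backward(self, g_logits):
        g = g_logits @ self.W  # (B, (k_c+S)*K)
        (cs, ss) = self._shapes
        nc = cs[1] * cs[2]
        return g[:, :nc].reshape(cs), g[:, nc:].reshape(ss)

    def backward_from_probs(self, g_probs):
        return self.backward(g_probs * self._probs * (1.0 - self._probs))


def surrogate_setup(seed=0, N=12, K=4, k_c=3, k_s=1, L=2):
    cfg = ModelConfig(seq_len=20, K=K, k_c=k_c, k_s=k_s, n_features=L)
    r = np.random.default_rng(seed)
    model = LinearSurrogate(cfg, r)
    phi_aug = np.vstack([r.normal(size=(N, K)), np.zeros((1, K))]).astype(np.float32)
    idx_c = r.integers(0, N + 1, size=(N, k_c))
    idx_s = r.integers(0, N + 1, size=(N, 1 + 2 * k_s))
    return cfg, model, phi_aug, idx_c, idx_s


class TestContactAttribution:
    def test_matches_closed_form_on_linear_head(self):
        cfg, model, phi_aug, idx_c, idx_s = surrogate_setup()
        i, l = 3, 1
        attr = attribute_contacts(model, phi_aug, idx_c[i], idx_s[i], i, l, wrt="logit")
        K, k_c = cfg.K, cfg.k_c
        Wl = model.W[l]
        W_c = Wl[: k_c * K].reshape(k_c, K)
        W_s = Wl[k_c * K :].reshape(-1, K)
        for r, t in enumerate(idx_c[i]):
            assert attr.S_c[r, t] == pytest.approx(float(W_c[r] @ phi_aug[t]), abs=1e-6)
        for r, t in enumerate(idx_s[i]):
            assert attr.S_s[r, t] == pytest.approx(float(W_s[r] @ phi_aug[t]), abs=1e-6)

    def test_probability_mode_scales_by_sigmoid_derivative(self):
        cfg, model, phi_aug, idx_c, idx_s = surrogate_setup()
        i, l = 2, 0
        logit = attribute_contacts(model, phi_aug, idx_c[i], idx_s[i], i, l, wrt="logit")
        prob = attribute_contacts(model, phi_aug, idx_c[i], idx_s[i], i, l, wrt="prob")
        p = model.forward(phi_aug[idx_c[i]][None], phi_aug[idx_s[i]][None])[0, l]
        assert np.allclose(prob.S_c, logit.S_c * p * (1 - p), atol=1e-6)

    def test_unsampled_columns_are_exactly_zero(self):
        cfg, model, phi_aug, idx_c, idx_s = surrogate_setup()
        attr = attribute_contacts(model, phi_aug, idx_c[0], idx_s[0], 0, 0)
        for r, t in enumerate(idx_c[0]):
            row = attr.S_c[r].copy()
            row[t] = 0.0
            assert np.all(row == 0.0)

    def test_dummy_neighbor_scores_zero(self):
        cfg, model, phi_aug, idx_c, idx_s = surrogate_setup()
        idx = np.full_like(idx_c[0], phi_aug.shape[0] - 1)  # all dummy
        attr = attribute_contacts(model, phi_aug, idx, idx_s[0], 0, 0)
        assert np.all(attr.S_c == 0.0)

    def test_feature_index_out_of_range(self):
        cfg, model, phi_aug, idx_c, idx_s = surrogate_setup()
        with pytest.raises(IndexError):
            attribute_contacts(model, phi_aug, idx_c[0], idx_s[0], 0, 99)


class TestAggregateLabels:
    def _attrs(self):
        cfg, model, phi_aug, idx_c, idx_s = surrogate_setup(L=3)
        return [attribute_contacts(model, phi_aug, idx_c[1], idx_s[1], 1, l)
                for l in range(3)]

    def test_singleton_set_is_identity(self):
        a = self._attrs()[0]
        agg = aggregate_labels([a])
        assert np.array_equal(agg.S_c, a.S_c)

    def test_sum_is_order_independent(self):
        attrs = self._attrs()
        a = aggregate_labels(attrs)
        b = aggregate_labels(attrs[::-1])
        assert np.allclose(a.S_c, b.S_c) and np.allclose(a.S_s, b.S_s)

    def test_two_label_sum_matches_direct_addition(self):
        attrs = self._attrs()[:2]
        agg = aggregate_labels(attrs)
        assert np.allclose(agg.S_c, attrs[0].S_c + attrs[1].S_c)

    def test_mixed_centers_rejected(self):
        cfg, model, phi_aug, idx_c, idx_s = surrogate_setup()
        a = attribute_contacts(model, phi_aug, idx_c[0], idx_s[0], 0, 0)
        b = attribute_contacts(model, phi_aug, idx_c[1], idx_s[1], 1, 0)
        with pytest.raises(ValueError):
            aggregate_labels([a, b])


def manual_attr(n, idx_c, idx_s, vals_c, vals_s):
    """Hand-assembled ContactAttribution for compression tests."""
    S_c = np.zeros((len(idx_c), n + 1))
    S_s = np.zeros((len(idx_s), n + 1))
    for r, (t, v) in enumerate(zip(idx_c, vals_c)):
        S_c[r, t] = v
    for r, (t, v) in enumerate(zip(idx_s, vals_s)):
        S_s[r, t] = v
    return ContactAttribution(0, 0, S_c, S_s,
                              np.array(idx_c), np.array(idx_s), n)


class TestCompressAndCombine:
    def test_spatial_only_neighbor_keeps_its_value(self):
        row = compress_and_combine(manual_attr(5, [2], [5], [-0.4], [0.0]))
        assert row[2] == pytest.approx(-0.4)  # negative value preserved

    def test_doubly_sampled_neighbor_takes_maximum(self):
        row = compress_and_combine(manual_attr(5, [2], [2], [0.7], [0.2]))
        assert row[2] == pytest.approx(0.7)

    def test_three_neighbor_toy_matches_brute_force(self):
        # neighbor 1: spatial 0.3 only; neighbor 2: both, 0.1 vs 0.5;
        # neighbor 3: sequential rows 3 and 3 (duplicate) -> summed then max
        attr = manual_attr(6, [1, 2], [2, 3, 3], [0.3, 0.1], [0.5, 0.2, 0.15])
        row = compress_and_combine(attr)
        assert row[1] == pytest.approx(0.3)
        assert row[2] == pytest.approx(0.5)
        assert row[3] == pytest.approx(0.35)
        assert row[[0, 4, 5]].tolist() == [0.0, 0.0, 0.0]

    def test_dummy_column_dropped(self):
        row = compress_and_combine(manual_attr(4, [4], [4], [9.0], [9.0]))
        assert np.all(row == 0.0)


class TestNormalizeImportance:
    def test_signed_row_normalizes_by_max_abs(self):
        M = np.array([[-2.0, 1.0, 0.0]])
        assert normalize_importance(M)[0].tolist() == [1.0, 0.5, 0.0]

    def test_nonzero_rows_attain_exactly_one(self, rng):
        M = rng.normal(size=(6, 8)) * (rng.random((6, 8)) < 0.4)
        Mh = normalize_importance(M)
        for i in range(6):
            if np.any(M[i] != 0):
                assert Mh[i].max() == 1.0
            else:
                assert np.all(Mh[i] == 0.0)
        assert Mh.min() >= 0.0 and Mh.max() <= 1.0

    def test_matches_elementwise_formula(self, rng):
        M = rng.normal(size=(5, 7)) * (rng.random((5, 7)) < 0.5)
        Mh = normalize_importance(M)
        for i in range(5):
            mx = np.abs(M[i]).max()
            if mx > 0:
                assert np.allclose(Mh[i], np.abs(M[i]) / mx)


class TestSequenceAttribution:
    def _setup(self):
        cfg = ModelConfig(seq_len=40, K=8, k_c=2, k_s=1, n_features=2,
                          enc_channels=(6,), enc_kernels=(5,), enc_pools=(1,),
                          enc_readout="max", graph_channels=4)
        r = np.random.default_rng(0)
        enc = SequenceEncoder(cfg, np.random.default_rng(1))
        enc.freeze()
        model = EchoModel(cfg, np.random.default_rng(2))
        from chromecho.genome_io import encode_string
        bases = "ACGT"
        X = np.stack([
            np.array(encode_string("".join(bases[b] for b in r.integers(0, 4, 40))))
            for _ in range(6)])
        from chromecho.model import encode_all
        from chromecho.sampling import augment_hidden
        phi_aug = augment_hidden(encode_all(enc, X))
        idx_c = r.integers(0, 7, size=(6, 2))
        idx_s = r.integers(0, 7, size=(6, 3))
        return cfg, enc, model, X, phi_aug, idx_c, idx_s

    def test_scores_zero_where_one_hot_is_zero(self):
        cfg, enc, model, X, phi_aug, idx_c, idx_s = self._setup()
        scores = attribute_sequences(model, enc, X, phi_aug, idx_c[0], idx_s[0], 0, 0)
        for j, S in scores.items():
            assert np.all(S[X[j] == 0.0] == 0.0)

    def test_covers_center_and_all_real_neighbors(self):
        cfg, enc, model, X, phi_aug, idx_c, idx_s = self._setup()
        scores = attribute_sequences(model, enc, X, phi_aug, idx_c[1], idx_s[1], 1, 0)
        real = {int(t) for t in np.concatenate([idx_c[1], idx_s[1]]) if t < 6}
        assert set(scores) == real

    def test_directional_finite_difference(self):
        """Sum of scores for neighbor j ~ directional derivative along x^(j)."""
        cfg, enc, model, X, phi_aug, idx_c, idx_s = self._setup()
        i, l = 2, 1
        scores = attribute_sequences(model, enc, X, phi_aug, idx_c[i], idx_s[i], i, l,
                                     wrt="logit")
        j = next(iter(scores))

        def logit_with_scaled(eps):
            Xmod = X.copy()
            Xmod[j] = X[j] * (1.0 + eps)
            from chromecho.model import encode_all
            from chromecho.sampling import augment_hidden
            pa = augment_hidden(encode_all(enc, Xmod))
            p = model.forward(pa[idx_c[i]][None], pa[idx_s[i]][None])[0, l]
            return math.log(p / (1 - p))

        eps = 1e-3
        numeric = (logit_with_scaled(eps) - logit_with_scaled(-eps)) / (2 * eps)
        assert float(scores[j].sum()) == pytest.approx(numeric, rel=5e-2, abs=1e-4)


class TestSelectPairs:
    def _inputs(self):
        M_hat = np.array([[0.0, 1.0, 0.3], [0.0, 0.0, 0.95], [0.2, 0.0, 0.0]])
        preds = np.array([[0.9], [0.4], [0.8]])
        labels = np.array([[1], [1], [0]], dtype=np.uint8)
        return M_hat, preds, labels

    def test_threshold_above_one_selects_nothing(self):
        M_hat, preds, labels = self._inputs()
        assert select_collaborative_pairs(M_hat, preds, labels, 0, 1.1) == []

    def test_requires_true_and_predicted_positive_center(self):
        M_hat, preds, labels = self._inputs()
        pairs = select_collaborative_pairs(M_hat, preds, labels, 0, 0.9)
        # center 1 fails prediction (0.4), center 2 fails label
        assert [(p.center, p.neighbor) for p in pairs] == [(0, 1)]

    def test_lowering_threshold_is_monotone(self):
        M_hat, preds, labels = self._inputs()
        hi = {(p.center, p.neighbor)
              for p in select_collaborative_pairs(M_hat, preds, labels, 0, 0.9)}
        lo = {(p.center, p.neighbor)
              for p in select_collaborative_pairs(M_hat, preds, labels, 0, 0.2)}
        assert hi <= lo


class TestInteractionPercentage:
    def _graph(self):
        bins = bin_genome({"c1": "A" * 8000}, width=200)  # 40 bins
        edges = {(0, 5): 5.0, (0, 30): 5.0, (1, 6): 5.0, (2, 20): 5.0}
        return ContactGraph(bins, edges)

    def test_all_positive_neighbors_give_100_percent(self):
        g = self._graph()
        positive = np.ones(40, dtype=bool)
        M_hat = np.ones((40, 40))
        table = interaction_percentage_analysis(
            M_hat, positive, g, [DistanceRange(0, math.inf)], [0.5])
        assert (table.dropna()["percentage"] == 100.0).all()

    def test_counts_match_brute_force(self):
        g = self._graph()
        positive = np.zeros(40, dtype=bool)
        positive[[0, 5, 1, 20]] = True
        M_hat = np.zeros((40, 40))
        M_hat[0, 5] = 0.9
        M_hat[5, 0] = 0.9
        M_hat[0, 30] = 0.2
        bins_ = [DistanceRange(0, 2000), DistanceRange(2000, math.inf)]
        table = interaction_percentage_analysis(M_hat, positive, g, bins_, [0.1])
        near_thr = table[(table.distance_bin == "[0,2000)") & (table.threshold == 0.1)]
        # directed near contacts with positive center and score>0.1: (0,5) and (5,0)
        assert near_thr.n_center_bound.iloc[0] == 2
        assert near_thr.n_both_bound.iloc[0] == 2
        far_all = table[(table.distance_bin == "[2000,inf)") & (table.threshold == "all")]
        # directed far contacts with positive center: (0,30), (20,2): neighbor positive never
        assert far_all.n_center_bound.iloc[0] == 2
        assert far_all.percentage.iloc[0] == 0.0

    def test_baseline_counts_dominate_thresholded_counts(self):
        g = self._graph()
        positive = np.ones(40, dtype=bool)
        M_hat = np.zeros((40, 40))
        table = interaction_percentage_analysis(
            M_hat, positive, g, [DistanceRange(0, math.inf)], [0.1, 0.5])
        base = table[table.threshold == "all"].n_center_bound.iloc[0]
        assert (table.n_center_bound <= base).all()

    def test_empty_cell_reports_na_not_zero(self):
        g = self._graph()
        positive = np.zeros(40, dtype=bool)
        table = interaction_percentage_analysis(
            M_hat=np.zeros((40, 40)), positive=positive, graph=g,
            distance_bins=[DistanceRange(0, math.inf)], score_thresholds=[0.1])
        assert table.percentage.isna().all()


class TestExports:
    def test_importance_triplets_round_trip_exactly(self, tmp_path, rng):
        M = np.abs(rng.normal(size=(9, 9))) * (rng.random((9, 9)) < 0.3)
        Mh = normalize_importance(M)
        p = tmp_path / "imp.tsv"
        write_importance_triplets(Mh, p)
        assert np.array_equal(read_importance_triplets(p, 9), Mh)

    def test_bedgraph_tiles_without_overlap(self, tmp_path, rng):
        scores = rng.normal(size=(4, 30))
        p = tmp_path / "t.bedgraph"
        write_bedgraph(scores, "c1", 1000, p)
        rows = [l.split("\t") for l in p.read_text().splitlines()[1:]]
        starts = [int(r[1]) for r in rows]
        ends = [int(r[2]) for r in rows]
        assert starts == list(range(1000, 1030))
        assert all(e == s + 1 for s, e in zip(starts, ends))


def test_importance_matrix_is_sparse_on_sampling_pattern():
    cfg, model, phi_aug, idx_c, idx_s = surrogate_setup(N=10)
    M = build_importance_matrix(model, phi_aug, idx_c, idx_s, labels=[0, 1],
                                centers=[0, 4])
    n = 10
    for i in (0, 4):
        sampled = {int(t) for t in np.concatenate([idx_c[i], idx_s[i]]) if t < n}
        assert {int(j) for j in np.flatnonzero(M[i])} <= sampled
    assert np.all(M[[1, 2, 3, 5, 6, 7, 8, 9]] == 0.0)
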