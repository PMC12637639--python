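import numpy as np
import pytest

from hicgat.autograd import Tensor
from hicgat.graph_builder import SignalSubgraph
from hicgat.io_formats import GenomicLocus
from hicgat.model import (
    DenseProjector,
    GatLayer,
    GraphModel,
    ModelConfig,
    TrainConfig,
    chromosome_split,
    evaluate,
    masked_bce_loss,
    one_hot_sequence,
)


def bin_at(i, chrom="chr9"):
    return GenomicLocus(chrom, i * 5000, (i + 1) * 5000)


def star(center_i, neighbor_is, chrom="chr9", T=4, rng=None):
    g = SignalSubgraph(center=bin_at(center_i, chrom),
                       center_bin=bin_at(center_i, chrom),
                       neighbors=[bin_at(i, chrom) for i in neighbor_is],
                       labels=np.zeros(T), mask=np.ones(T))
    return g


@pytest.fixture
def tiny_cfg():
    return ModelConfig(d=8, heads=2, n_profiles=4, feature_mode="seq",
                       conv_channels=(4, 4), kernel=5, pool=10)


@pytest.fixture
def feature_fn(rng):
    cache = {}

    def fn(locus, is_center):
        key = (locus.key(), is_center)
        if key not in cache:
            r = np.random.default_rng(abs(hash(key)) % (2**31))
            cache[key] = r.random((4, 5000))
        return cache[key]

    return fn


class TestOneHot:
    def test_columns_sum_to_one_except_n(self):
        x = one_hot_sequence("ACGTN")
        assert np.array_equal(x.sum(axis=0), [1, 1, 1, 1, 0])
        assert x[0, 0] == 1 and x[3, 3] == 1


class TestEncoders:
    def test_identical_inputs_identical_embeddings(self, tiny_cfg):
        model = GraphModel(tiny_cfg, seed=0)
        x = np.random.default_rng(0).random((2, 4, 5000))
        a = model.encode(x).data
        b = model.encode(x.copy()).data
        assert np.array_equal(a, b)
        assert a.shape == (2, 8)

    def test_all_zero_input_gives_bias_constant(self, tiny_cfg):
        model = GraphModel(tiny_cfg, seed=0)
        out = model.encode(np.zeros((3, 4, 5000))).data
        assert np.allclose(out[0], out[1]) and np.allclose(out[1], out[2])

    def test_dense_projector_matches_affine_oracle(self):
        cfg = ModelConfig(d=16, heads=2, n_profiles=4, feature_mode="dense")
        rng = np.random.default_rng(3)
        proj = DenseProjector(cfg, rng)
        x = rng.normal(size=(5, 4096))
        got = proj(Tensor(x)).data
        h = x @ proj.fc1.w.data + proj.fc1.b.data
        expect = np.maximum(h, 0) @ proj.fc2.w.data + proj.fc2.b.data
        assert np.allclose(got, expect, atol=1e-12)


def dense_gat_oracle(h, edges, layer, slope):
    """Dense numpy re-implementation of one multi-head attention layer
    (projection, leaky-relu logits, per-destination softmax, weighted sum,
    ELU, head concat) -- before residual/norm."""
    M, dh = layer.a_dst.data.shape
    n = h.shape[0]
    hp = (h @ layer.w.data).reshape(n, M, dh)
    out = np.zeros((n, M, dh))
    alpha_full = np.zeros((len(edges), M))
    for m in range(M):
        sd = hp[:, m] @ layer.a_dst.data[m]
        ss = hp[:, m] @ layer.a_src.data[m]
        for v in range(n):
            in_edges = [k for k, (s, d) in enumerate(edges) if d == v]
            if not in_edges:
                continue
            logits = np.array([sd[v] + ss[edges[k][0]] for k in in_edges])
            logits = np.where(logits > 0, logits, slope * logits)
            ex = np.exp(logits - logits.max())
            alpha = ex / ex.sum()
            for a, k in zip(alpha, in_edges):
                alpha_full[k, m] = a
                out[v, m] += a * hp[edges[k][0], m]
    elu = np.where(out > 0, out, np.exp(np.minimum(out, 0)) - 1)
    return elu.reshape(n, M * dh), alpha_full


class TestGatLayer:
    def _layer(self, d_in=6, heads=2, d=8, seed=0):
        cfg = ModelConfig(d=d, heads=heads, n_profiles=2, dropout=0.0)
        return GatLayer(d_in, cfg, np.random.default_rng(seed)), cfg

    def test_single_in_neighbor_gets_full_attention(self):
        layer, _ = self._layer()
        h = Tensor(np.random.default_rng(1).normal(size=(2, 6)))
        edges = np.array([[1, 0]])
        _, alpha = layer(h, edges, 2, np.random.default_rng(0))
        assert np.allclose(alpha, 1.0)

    def test_identical_neighbors_share_attention_equally(self):
        rng = np.random.default_rng(2)
        layer, _ = self._layer()
        feat = rng.normal(size=6)
        h = Tensor(np.stack([rng.normal(size=6), feat, feat]))
        edges = np.array([[1, 0], [2, 0]])
        _, alpha = layer(h, edges, 3, np.random.default_rng(0))
        assert np.allclose(alpha, 0.5)

    def test_matches_dense_oracle_on_random_star(self):
        rng = np.random.default_rng(5)
        layer, cfg = self._layer(d_in=6, heads=2)
        layer.eval()
        n = 6
        h_np = rng.normal(size=(n, 6))
        edges = [(k, 0) for k in range(1, n)] + [(0, k) for k in range(1, n)]
        e = np.array(edges)
        out, alpha = layer(Tensor(h_np), e, n, rng)
        oracle_agg, oracle_alpha = dense_gat_oracle(h_np, edges, layer,
                                                    cfg.leaky_slope)
        assert np.allclose(alpha, oracle_alpha, atol=1e-5)
        # replicate residual + layer norm on top of the oracle aggregate
        res = h_np @ layer.shortcut.w.data + layer.shortcut.b.data
        pre = res + oracle_agg
        mu = pre.mean(axis=1, keepdims=True)
        var = ((pre - mu) ** 2).mean(axis=1, keepdims=True)
        expect = ((pre - mu) / np.sqrt(var + 1e-5)) * layer.norm.gamma.data \
            + layer.norm.beta.data
        assert np.allclose(out.data, expect, atol=1e-5)

    def test_isolated_nodes_pass_through_residual_path(self):
        layer, _ = self._layer(d_in=8, heads=2, d=8)
        layer.eval()
        h = Tensor(np.random.default_rng(3).normal(size=(3, 8)))
        out, _ = layer(h, np.zeros((0, 2), dtype=int), 3,
                       np.random.default_rng(0))
        # with no edges the update is norm(residual + elu(0)) = norm(h)
        mu = h.data.mean(axis=1, keepdims=True)
        var = ((h.data - mu) ** 2).mean(axis=1, keepdims=True)
        expect = (h.data - mu) / np.sqrt(var + 1e-5) * layer.norm.gamma.data \
            + layer.norm.beta.data
        assert np.allclose(out.data, expect, atol=1e-6)


class TestForwardSubgraphs:
    def test_zero_neighbor_graph_yields_probabilities(self, tiny_cfg,
                                                      feature_fn):
        model = GraphModel(tiny_cfg, seed=0).eval()
        res = model.forward_subgraphs([star(3, [])], feature_fn)
        assert res.probabilities.shape == (1, 4)
        assert np.all((res.probabilities > 0) & (res.probabilities < 1))

    def test_probabilities_in_unit_interval(self, tiny_cfg, feature_fn):
        model = GraphModel(tiny_cfg, seed=0).eval()
        res = model.forward_subgraphs(
            [star(3, [1, 7]), star(10, [2, 11, 30])], feature_fn)
        assert np.all((res.probabilities > 0) & (res.probabilities < 1))

    def test_neighbor_permutation_invariance(self, tiny_cfg, feature_fn):
        model = GraphModel(tiny_cfg, seed=0).eval()
        g1 = star(5, [1, 9, 20, 33])
        g2 = SignalSubgraph(center=g1.center, center_bin=g1.center_bin,
                            neighbors=list(reversed(g1.neighbors)),
                            labels=g1.labels, mask=g1.mask)
        z1 = model.forward_subgraphs([g1], feature_fn).z
        z2 = model.forward_subgraphs([g2], feature_fn).z
        assert np.allclose(z1, z2, atol=1e-6)

    def test_attention_rows_sum_to_one_on_every_pass(self, tiny_cfg,
                                                     feature_fn):
        model = GraphModel(tiny_cfg, seed=0).eval()
        res = model.forward_subgraphs([star(5, [1, 9, 20])], feature_fn,
                                      check_attention=True)
        rec = res.records[0]
        for layer_alpha in rec.alpha:
            sums = np.zeros((4, tiny_cfg.heads))
            np.add.at(sums, rec.edges[:, 1], layer_alpha)
            assert np.allclose(sums[sums > 0], 1.0, atol=1e-6)

    def test_z_concatenates_center_and_pooled(self, tiny_cfg, feature_fn):
        model = GraphModel(tiny_cfg, seed=0).eval()
        res = model.forward_subgraphs([star(5, [1, 9])], feature_fn)
        assert res.z.shape == (1, 2 * tiny_cfg.d)
        e_center = model.encode(feature_fn(bin_at(5), True)[None]).data[0]
        assert np.allclose(res.z[0, : tiny_cfg.d], e_center)
        assert np.allclose(res.z[0, tiny_cfg.d :], res.pooled[0])

    def test_gradient_reaches_every_parameter(self, tiny_cfg, feature_fn):
        model = GraphModel(tiny_cfg, seed=0)
        model.train()
        res = model.forward_subgraphs(
            [star(5, [1, 9]), star(20, [])], feature_fn,
            labels=np.array([[1., 0, 1, 0], [0., 1, 0, 1]]),
            mask=np.ones((2, 4)), rng=np.random.default_rng(0),
            check_attention=False)
        res.loss.backward()
        for name, p in model.parameters().items():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
            if not name.endswith("norm.beta") and not name.endswith(".b"):
                assert np.abs(p.grad).max() > 0, name


class TestMaskedBce:
    def test_closed_form_ln2(self):
        logits = Tensor(np.zeros((1, 1)))
        loss = masked_bce_loss(logits, np.array([[1.0]]), np.array([[1.0]]))
        assert np.isclose(float(loss.data), np.log(2), atol=1e-12)

    def test_empty_mask_centers_are_skipped(self):
        logits = Tensor(np.array([[0.0], [5.0]]))
        labels = np.array([[1.0], [1.0]])
        mask = np.array([[0.0], [1.0]])
        loss = masked_bce_loss(logits, labels, mask)
        expect = np.log1p(np.exp(-5.0))   # only the second center counts
        assert np.isclose(float(loss.data), expect, atol=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        logits_np = rng.normal(size=(7, 20)) * 3
        labels = rng.integers(0, 2, size=(7, 20)).astype(float)
        mask = rng.integers(0, 2, size=(7, 20)).astype(float)
        mask[0] = 0   # one fully-masked center
        loss = float(masked_bce_loss(Tensor(logits_np), labels, mask).data)
        p = 1 / (1 + np.exp(-logits_np))
        bce = -labels * np.log(p) - (1 - labels) * np.log(1 - p)
        per_center = (bce * mask).sum(axis=1) / np.maximum(mask.sum(axis=1), 1)
        expect = per_center[mask.sum(axis=1) > 0].mean()
        assert np.isclose(loss, expect, atol=1e-8)

    def test_logit_space_is_stable_at_extremes(self):
        logits = Tensor(np.array([[800.0, -800.0]]))
        loss = masked_bce_loss(logits, np.array([[1.0, 0.0]]),
                               np.array([[1.0, 1.0]]))
        assert np.isfinite(float(loss.data))
        assert float(loss.data) < 1e-6


class TestChromosomeSplit:
    def test_partition_follows_the_fixed_split(self):
        graphs = [star(1, [], chrom=c)
                  for c in ("chr1", "chr2", "chr8", "chr9", "chrY")]
        train, val, test = chromosome_split(graphs)
        assert [g.center.chrom for g in test] == ["chr9"]
        assert [g.center.chrom for g in val] == ["chr8"]
        assert sorted(g.center.chrom for g in train) == ["chr1", "chr2"]

    def test_splits_disjoint_and_cover_non_y(self):
        graphs = [star(i, [], chrom=f"chr{c}")
                  for i, c in enumerate([1, 2, 3, 8, 9, 9, "Y"])]
        train, val, test = chromosome_split(graphs)
        assert len(train) + len(val) + len(test) == 6


class TestEvaluate:
    def test_perfect_separation_gives_unit_metrics(self):
        pred = np.array([[0.9], [0.8], [0.1], [0.2]] * 10)
        labels = np.array([[1], [1], [0], [0]] * 10)
        mask = np.ones_like(labels)
        m = evaluate(pred, labels, mask, pred, labels, mask, min_positives=5)
        assert m["macro_aupr"] == 1.0
        assert m["macro_auroc"] == 1.0
        assert m["macro_f1"] == 1.0

    def test_single_class_excluded(self):
        pred = np.random.default_rng(0).random((10, 2))
        labels = np.column_stack([np.ones(10), np.r_[np.ones(5), np.zeros(5)]])
        m = evaluate(pred, labels, np.ones_like(labels), min_positives=0)
        assert m["per_class"][0] is None
        assert m["per_class"][1] is not None

    def test_aupr_matches_step_integration_oracle(self, rng):
        y = rng.integers(0, 2, size=100).astype(float)
        p = rng.random(100)
        m = evaluate(p[:, None], y[:, None], np.ones((100, 1)),
                     min_positives=0)
        # average precision by direct stepwise summation
        order = np.argsort(-p)
        ys = y[order]
        tp = np.cumsum(ys)
        prec = tp / np.arange(1, 101)
        ap = (prec * ys).sum() / ys.sum()
        assert np.isclose(m["per_class"][0]["aupr"], ap, atol=1e-12)


class TestPairedBootstrap:
    def test_identical_predictors_center_on_zero(self, rng):
        from hicgat.model import paired_bootstrap_delta

        pred = rng.random((60, 3))
        labels = rng.integers(0, 2, size=(60, 3)).astype(float)
        mask = np.ones_like(labels)
        res = paired_bootstrap_delta(pred, pred, labels, mask, n_boot=50,
                                     seed=1)
        assert res["mean"] == 0.0
        assert res["ci_low"] == res["ci_high"] == 0.0

    def test_better_predictor_shows_positive_delta(self, rng):
        from hicgat.model import paired_bootstrap_delta

        labels = rng.integers(0, 2, size=(80, 2)).astype(float)
        good = labels * 0.8 + rng.random((80, 2)) * 0.2
        bad = rng.random((80, 2))
        mask = np.ones_like(labels)
        res = paired_bootstrap_delta(good, bad, labels, mask, n_boot=50,
                                     seed=2)
        assert res["mean"] > 0
        assert res["ci_low"] > 0


class TestTrainingContracts:
    def test_seeded_pretraining_is_bit_reproducible(self, feature_fn):
        from hicgat.model import pretrain_encoder

        cfg = ModelConfig(d=8, heads=2, n_profiles=3, feature_mode="seq",
                          conv_channels=(4,), kernel=5, pool=10)
        rng = np.random.default_rng(0)
        graphs = []
        for c in ("chr1", "chr1", "chr8", "chr9"):
            for i in range(4):
                g = star(rng.integers(0, 50), [], chrom=c, T=3)
                g.labels = rng.integers(0, 2, 3).astype(float)
                graphs.append(g)
        tc = TrainConfig(lr=1e-3, epochs=2, batch_size=4, seed=7)
        s1, _ = pretrain_encoder(graphs, feature_fn, cfg, tc)
        s2, _ = pretrain_encoder(graphs, feature_fn, cfg, tc)
        for k in s1:
            assert np.array_equal(s1[k], s2[k]), k

    def test_early_stopping_halts_before_budget(self, feature_fn):
        from hicgat.model import pretrain_encoder

        cfg = ModelConfig(d=8, heads=2, n_profiles=2, feature_mode="seq",
                          conv_channels=(4,), kernel=5, pool=10)
        rng = np.random.default_rng(1)
        graphs = []
        for c in ("chr1", "chr1", "chr8"):
            for i in range(3):
                g = star(rng.integers(0, 50), [], chrom=c, T=2)
                g.labels = rng.integers(0, 2, 2).astype(float)
                graphs.append(g)
        tc = TrainConfig(lr=0.0, epochs=50, batch_size=4, patience=2, seed=0)
        _, history = pretrain_encoder(graphs, feature_fn, cfg, tc)
        assert len(history) < 50   # lr=0 never improves -> stops at patience

    def test_frozen_blocks_unchanged_by_finetuning(self, feature_fn):
        from hicgat.model import finetune_graph, pretrain_encoder

        cfg = ModelConfig(d=8, heads=2, n_profiles=2, feature_mode="seq",
                          conv_channels=(4, 4), kernel=5, pool=10,
                          freeze_depth=1)
        rng = np.random.default_rng(2)
        graphs = []
        for c in ("chr1", "chr1", "chr8", "chr9"):
            for i in range(3):
                g = star(int(rng.integers(0, 40)), [int(rng.integers(40, 50))],
                         chrom=c, T=2)
                g.labels = rng.integers(0, 2, 2).astype(float)
                graphs.append(g)
        tc = TrainConfig(lr=1e-2, epochs=2, batch_size=4, seed=0)
        state, _ = pretrain_encoder(graphs, feature_fn, cfg, tc)
        model, _ = finetune_graph(graphs, feature_fn, state, cfg, tc)
        for pname in ("w", "b"):
            assert np.array_equal(model.encoder.blocks[0]._params[pname].data,
                                  state[f"encoder.conv0.{pname}"])
            assert not np.array_equal(
                model.encoder.blocks[1]._params[pname].data,
                state[f"encoder.conv1.{pname}"])

    def test_default_finetune_lr_matches_published_setting(self):
        assert TrainConfig().lr == 3e-5
        assert TrainConfig().weight_decay == 1e-6
        assert TrainConfig().min_lr == 1e-7
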