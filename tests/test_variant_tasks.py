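import numpy as np
import pytest

from hicgat.graph_builder import SignalSubgraph, build_signal_subgraph
from hicgat.io_formats import GenomicLocus, Track
from hicgat.model import GraphModel, ModelConfig
from hicgat.polymer_null import NonRandomContactSet
from hicgat.variant_tasks import (
    Variant,
    clinvar_embedding,
    delta_probability,
    eqtl_embedding,
    perturbation_enrichment,
    sign_agreement,
    train_variant_classifier,
    variant_bin,
)


def bin_at(i, chrom="chr9"):
    return GenomicLocus(chrom, i * 5000, (i + 1) * 5000)


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    return {"chr9": "".join(bases[rng.integers(0, 4, 100 * 5000)])}


@pytest.fixture(scope="module")
def toy_track():
    t = Track()
    t.add("chr9", 0, 500_000, 0.7)
    return t


@pytest.fixture(scope="module")
def toy_model():
    cfg = ModelConfig(d=8, heads=2, n_profiles=4, feature_mode="seq_dnase",
                      conv_channels=(4, 4), kernel=5, pool=10)
    return GraphModel(cfg, seed=3).eval()


@pytest.fixture(scope="module")
def toy_contacts():
    return NonRandomContactSet(
        pairs=[(bin_at(10), bin_at(14), 1e-4, 1e-3),
               (bin_at(10), bin_at(30), 1e-4, 1e-3)])


class TestVariant:
    def test_validation(self):
        with pytest.raises(ValueError):
            Variant("chr1", 0, "A", "C")
        with pytest.raises(ValueError):
            Variant("chr1", 5, "", "C")

    def test_variant_bin_contains_position(self):
        v = Variant("chr9", 52_003, "A", "C")
        vb = variant_bin(v)
        assert vb.start <= v.pos0 < vb.end


class TestEmbeddings:
    def test_eqtl_embedding_equals_concat_of_halves(self, toy_model,
                                                    toy_genome, toy_track,
                                                    toy_contacts):
        from hicgat.model import locus_features

        v = Variant("chr9", 10 * 5000 + 100, toy_genome["chr9"][10 * 5000 + 99],
                    "T", label="eqtl", slope=0.5, tss=bin_at(40))
        z = eqtl_embedding(v, toy_contacts, toy_model, toy_genome, toy_track)
        assert z.shape == (16,)
        e_tss = toy_model.encode(locus_features(
            bin_at(40), toy_genome, "seq_dnase", toy_track)[None]).data[0]
        sub = build_signal_subgraph(bin_at(10), toy_contacts)
        res = toy_model.forward_subgraphs(
            [sub], lambda l, c: locus_features(l, toy_genome, "seq_dnase",
                                               toy_track))
        assert np.allclose(z[:8], e_tss)
        assert np.allclose(z[8:], res.pooled[0])

    def test_variant_without_contacts_gets_single_node_graph(self, toy_model,
                                                             toy_genome,
                                                             toy_track,
                                                             toy_contacts):
        v = Variant("chr9", 70 * 5000 + 1, toy_genome["chr9"][70 * 5000],
                    "T" if toy_genome["chr9"][70 * 5000] != "T" else "A",
                    tss=bin_at(40))
        z = eqtl_embedding(v, toy_contacts, toy_model, toy_genome, toy_track)
        assert z.shape == (16,) and np.isfinite(z).all()

    def test_missing_tss_is_an_error(self, toy_model, toy_genome, toy_track,
                                     toy_contacts):
        v = Variant("chr9", 100, toy_genome["chr9"][99], "T")
        with pytest.raises(ValueError, match="TSS"):
            eqtl_embedding(v, toy_contacts, toy_model, toy_genome, toy_track)

    def test_clinvar_embedding_matches_forward_pooled(self, toy_model,
                                                      toy_genome, toy_track,
                                                      toy_contacts):
        from hicgat.model import locus_features

        v = Variant("chr9", 10 * 5000 + 1, toy_genome["chr9"][10 * 5000], "T")
        e = clinvar_embedding(v, toy_contacts, toy_track, toy_model,
                              toy_genome)
        sub = build_signal_subgraph(bin_at(10), toy_contacts)
        res = toy_model.forward_subgraphs(
            [sub], lambda l, c: locus_features(l, toy_genome, "seq_dnase",
                                               toy_track))
        assert np.allclose(e, res.pooled[0])


class TestDeltaProbability:
    def _sub(self, toy_contacts):
        return build_signal_subgraph(bin_at(10), toy_contacts,
                                     center=bin_at(10))

    def test_identical_alleles_give_exact_zero(self, toy_model, toy_genome,
                                               toy_track, toy_contacts):
        ref = toy_genome["chr9"][10 * 5000 + 50]
        v = Variant("chr9", 10 * 5000 + 51, ref, ref)
        d = delta_probability(v, self._sub(toy_contacts), toy_model,
                              toy_genome, toy_track, mode="center")
        assert np.all(d == 0.0)

    def test_variant_outside_all_windows_gives_zero(self, toy_model,
                                                    toy_genome, toy_track,
                                                    toy_contacts):
        ref = toy_genome["chr9"][90 * 5000]
        v = Variant("chr9", 90 * 5000 + 1, ref, "A" if ref != "A" else "C")
        d = delta_probability(v, self._sub(toy_contacts), toy_model,
                              toy_genome, toy_track, mode="center")
        assert np.all(d == 0.0)

    def test_matches_two_pass_oracle(self, toy_model, toy_genome, toy_track,
                                     toy_contacts):
        from hicgat.model import locus_features, one_hot_sequence

        pos0 = 10 * 5000 + 123
        ref = toy_genome["chr9"][pos0]
        alt = "G" if ref != "G" else "C"
        v = Variant("chr9", pos0 + 1, ref, alt)
        sub = self._sub(toy_contacts)
        d = delta_probability(v, sub, toy_model, toy_genome, toy_track,
                              mode="center")

        def fn_for(seq_window):
            def fn(locus, is_center):
                if locus == bin_at(10):
                    x = one_hot_sequence(seq_window)
                    sig = toy_track.values(locus.chrom, locus.start, locus.end)
                    return np.vstack([x, sig[None, :]])
                return locus_features(locus, toy_genome, "seq_dnase",
                                      toy_track)
            return fn

        win = toy_genome["chr9"][10 * 5000 : 11 * 5000]
        alt_win = win[:123] + alt + win[124:]
        p_ref = toy_model.forward_subgraphs([sub], fn_for(win)).probabilities
        p_alt = toy_model.forward_subgraphs([sub],
                                            fn_for(alt_win)).probabilities
        assert np.allclose(d, (p_alt - p_ref)[0], atol=1e-12)

    def test_neighbor_mode_edits_the_neighbor(self, toy_model, toy_genome,
                                              toy_track, toy_contacts):
        pos0 = 14 * 5000 + 10
        ref = toy_genome["chr9"][pos0]
        v = Variant("chr9", pos0 + 1, ref, "A" if ref != "A" else "T")
        d = delta_probability(v, self._sub(toy_contacts), toy_model,
                              toy_genome, toy_track, mode="neighbor")
        assert np.abs(d).max() > 0

    def test_ref_mismatch_names_the_position(self, toy_model, toy_genome,
                                             toy_track, toy_contacts):
        pos0 = 10 * 5000 + 7
        wrong = "A" if toy_genome["chr9"][pos0] != "A" else "C"
        v = Variant("chr9", pos0 + 1, wrong, "G" if wrong != "G" else "T")
        with pytest.raises(ValueError, match=str(pos0 + 1)):
            delta_probability(v, self._sub(toy_contacts), toy_model,
                              toy_genome, toy_track, mode="center")

    def test_indel_keeps_window_length(self, toy_model, toy_genome,
                                       toy_track, toy_contacts):
        pos0 = 10 * 5000 + 2000
        ref = toy_genome["chr9"][pos0 : pos0 + 3]
        v = Variant("chr9", pos0 + 1, ref, ref[0])   # 2 bp deletion
        d = delta_probability(v, self._sub(toy_contacts), toy_model,
                              toy_genome, toy_track, mode="center")
        assert d.shape == (4,) and np.isfinite(d).all()

    def test_dense_mode_unsupported(self, toy_contacts):
        cfg = ModelConfig(d=8, heads=2, n_profiles=2, feature_mode="dense")
        model = GraphModel(cfg, seed=0)
        v = Variant("chr9", 100, "A", "C")
        with pytest.raises(ValueError, match="dense"):
            delta_probability(v, build_signal_subgraph(bin_at(0),
                                                       toy_contacts),
                              model, {}, None)


class TestSignAgreement:
    def test_perfect_agreement(self):
        slopes = np.array([0.5, -0.3, 1.0, -0.8])
        res = sign_agreement({"m": slopes.copy()}, slopes, n_boot=10)
        assert res["marks"]["m"]["agreement"] == 1.0
        assert res["baseline"] == 0.5

    def test_zero_deltas_excluded_and_counted(self):
        slopes = np.array([0.5, -0.3, 1.0])
        deltas = np.array([0.0, -0.1, 0.2])
        res = sign_agreement({"m": deltas}, slopes, n_boot=10)
        assert res["marks"]["m"]["n"] == 2
        assert res["marks"]["m"]["n_excluded"] == 1
        assert res["marks"]["m"]["agreement"] == 1.0

    def test_baseline_is_majority_direction(self):
        slopes = np.array([1.0, 1.0, 1.0, -1.0])
        res = sign_agreement({"m": slopes.copy()}, slopes, n_boot=10)
        assert res["baseline"] == 0.75

    def test_strata_match_per_bin_recount(self, rng):
        slopes = rng.normal(size=60)
        deltas = rng.normal(size=60)
        res = sign_agreement({"m": deltas}, slopes, n_strata=3, n_boot=20,
                             seed=1)
        valid = (deltas != 0) & (slopes != 0)
        agree = np.sign(deltas[valid]) == np.sign(slopes[valid])
        mags = np.abs(slopes[valid])
        q = np.quantile(mags, [0, 1 / 3, 2 / 3, 1])
        for s, stratum in enumerate(res["marks"]["m"]["strata"]):
            sel = (mags >= q[s]) & ((mags < q[s + 1]) if s < 2
                                    else (mags <= q[s + 1]))
            assert np.isclose(stratum["mean"], agree[sel].mean())


class TestPerturbationEnrichment:
    def test_counts_match_brute_force(self, rng):
        d = rng.random(500)
        y = rng.random(500) < 0.3
        res = perturbation_enrichment(d, y, top_fraction=0.02)
        k = 10
        top_idx = np.argsort(-d)[:k]
        top = np.zeros(500, dtype=bool)
        top[top_idx] = True
        a = int((top & y).sum())
        assert res["pooled"]["table"][0][0] == a
        assert res["pooled"]["table"][0][1] == k - a

    def test_independent_labels_give_or_near_one(self, rng):
        d = rng.random(4000)
        y = rng.random(4000) < 0.5
        res = perturbation_enrichment(d, y, top_fraction=0.05)
        assert 0.4 < res["pooled"]["odds_ratio"] < 2.5

    def test_full_separation_is_finite_sample_corrected(self):
        d = np.r_[np.ones(10), np.zeros(190)] + np.linspace(0, 0.1, 200)
        y = np.r_[np.ones(10, dtype=bool), np.zeros(190, dtype=bool)]
        res = perturbation_enrichment(d, y, top_fraction=0.05)
        assert np.isfinite(res["pooled"]["odds_ratio"])
        assert res["pooled"]["odds_ratio"] > 50

    def test_per_mode_tables(self, rng):
        d = rng.random(400)
        y = rng.random(400) < 0.4
        modes = np.array(["center", "neighbor"] * 200)
        res = perturbation_enrichment(d, y, top_fraction=0.05, modes=modes)
        assert "center" in res and "neighbor" in res

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            perturbation_enrichment(np.ones(5), np.ones(5, dtype=bool),
                                    top_fraction=0.01)


class TestVariantClassifier:
    def test_separable_embeddings_reach_perfect_f1(self, rng):
        n = 60
        emb = np.vstack([rng.normal(5, 0.2, size=(n // 2, 8)),
                         rng.normal(-5, 0.2, size=(n // 2, 8))])
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        res = train_variant_classifier(emb, y, folds=3, seed=0)
        assert res["summary"]["f1"]["mean"] == 1.0

    def test_permuted_labels_give_chance_auroc(self, rng):
        emb = rng.normal(size=(120, 8))
        y = rng.integers(0, 2, 120)
        res = train_variant_classifier(emb, y, folds=3, seed=0)
        assert abs(res["summary"]["auroc"]["mean"] - 0.5) < 0.2

    def test_fold_assignment_deterministic(self, rng):
        emb = rng.normal(size=(40, 4))
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        a = train_variant_classifier(emb, y, folds=4, seed=5)
        b = train_variant_classifier(emb, y, folds=4, seed=5)
        assert a["folds"][0]["aupr"] == b["folds"][0]["aupr"]

    def test_small_minority_class_reduces_folds(self, rng):
        emb = rng.normal(size=(20, 4))
        y = np.r_[np.ones(3), np.zeros(17)].astype(int)
        res = train_variant_classifier(emb, y, folds=5, seed=0)
        assert res["n_folds"] == 3

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_variant_classifier(rng.normal(size=(10, 4)),
                                     np.ones(10, dtype=int))
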