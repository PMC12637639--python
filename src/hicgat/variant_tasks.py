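"""Variant-level heads: eQTL and pathogenicity embeddings, allele-swap
delta-probabilities, sign agreement with effect slopes, and perturbation
enrichment.

Variant positions follow the 1-based VCF convention at the interface and are
converted to 0-based internally.  The "variant-centered 5 kb locus" is the
grid bin containing the variant; its subgraph comes from the cell-matched
(or consensus) non-random contact set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact
from sklearn.metrics import (average_precision_score, brier_score_loss,
                             f1_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .graph_builder import SignalSubgraph, build_signal_subgraph
from .io_formats import RESOLUTION, GenomicLocus, Track
from .model import WINDOW_BP, GraphModel, locus_features, one_hot_sequence
from .polymer_null import NonRandomContactSet

__all__ = [
    "Variant",
    "variant_bin",
    "eqtl_embedding",
    "train_variant_classifier",
    "clinvar_embedding",
    "delta_probability",
    "sign_agreement",
    "perturbation_enrichment",
]


@dataclass
class Variant:
    chrom: str
    pos: int                  # 1-based (VCF convention)
    ref: str
    alt: str
    label: str = "none"       # eqtl | benign | pathogenic | none
    slope: float | None = None
    tss: GenomicLocus | None = None

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be nonempty")
        if self.pos < 1:
            raise ValueError("variant position is 1-based")

    @property
    def pos0(self) -> int:
        return self.pos - 1


def variant_bin(variant: Variant, resolution: int = RESOLUTION) -> GenomicLocus:
    start = (variant.pos0 // resolution) * resolution
    return GenomicLocus(variant.chrom, start, start + resolution)


def _standard_feature_fn(genome, track, mode):
    def fn(locus: GenomicLocus, is_center: bool) -> np.ndarray:
        return locus_features(locus, genome, mode, track)
    return fn


def _graph_embedding(model: GraphModel, subgraph: SignalSubgraph,
                     feature_fn) -> np.ndarray:
    model.eval()
    res = model.forward_subgraphs([subgraph], feature_fn,
                                  check_attention=False)
    return res.pooled[0]


def eqtl_embedding(variant: Variant, contacts: NonRandomContactSet,
                   model: GraphModel, genome: dict[str, str],
                   track: Track | None = None) -> np.ndarray:
    """z = [e_TSS || e_var]: TSS locus through the pretrained encoder, the
    variant-centered subgraph through the graph trunk (pooled, length d)."""
    if variant.tss is None:
        raise ValueError("eQTL variant needs a paired TSS locus")
    mode = model.cfg.feature_mode
    tss_feat = locus_features(variant.tss, genome, mode, track)
    e_tss = model.encode(tss_feat[None])\
        .data[0]
    vb = variant_bin(variant, contacts.resolution)
    sub = build_signal_subgraph(vb, contacts)
    e_var = _graph_embedding(model, sub, _standard_feature_fn(genome, track, mode))
    return np.concatenate([e_tss, e_var])


def clinvar_embedding(variant: Variant, consensus: NonRandomContactSet,
                      averaged_track: Track | None, model: GraphModel,
                      genome: dict[str, str]) -> np.ndarray:
    """Variant subgraph over the consensus contact map; pooled d-vector."""
    vb = variant_bin(variant, consensus.resolution)
    sub = build_signal_subgraph(vb, consensus)
    mode = model.cfg.feature_mode
    return _graph_embedding(model, sub,
                            _standard_feature_fn(genome, averaged_track, mode))


def train_variant_classifier(embeddings: np.ndarray, labels: np.ndarray,
                             folds: int = 5, seed: int = 0,
                             hidden: int = 64, calibration_bins: int = 10,
                             top_k_fraction: float = 0.1) -> dict:
    """Stratified k-fold MLP head on variant embeddings.

    Two-layer perceptron (one hidden layer + logistic output) per fold with
    cross-entropy; reports per-fold AUPR/AUROC/F1, Brier score, reliability
    bins and top-k precision, plus mean +/- sd aggregates.  Fold assignment
    is a deterministic function of (seed, n).
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to train the variant head")
    folds = min(folds, int(np.bincount(labels).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics = []
    for tr, te in skf.split(embeddings, labels):
        clf = MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=800,
                            random_state=seed, alpha=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(embeddings[tr], labels[tr])
        p = clf.predict_proba(embeddings[te])[:, 1]
        y = labels[te]
        k = max(1, int(round(top_k_fraction * len(y))))
        top = np.argsort(-p)[:k]
        edges = np.linspace(0, 1, calibration_bins + 1)
        bins = np.clip(np.digitize(p, edges) - 1, 0, calibration_bins - 1)
        reliability = [
            {"bin": b, "mean_pred": float(p[bins == b].mean()),
             "frac_pos": float(y[bins == b].mean()),
             "n": int((bins == b).sum())}
            for b in range(calibration_bins) if (bins == b).any()
        ]
        fold_metrics.append({
            "aupr": float(average_precision_score(y, p)),
            "auroc": float(roc_auc_score(y, p)),
            "f1": float(f1_score(y, p >= 0.5)),
            "brier": float(brier_score_loss(y, p)),
            "top_k_precision": float(y[top].mean()),
            "reliability": reliability,
        })
    summary = {}
    for key in ("aupr", "auroc", "f1", "brier", "top_k_precision"):
        vals = np.array([m[key] for m in fold_metrics])
        summary[key] = {"mean": float(vals.mean()), "sd": float(vals.std())}
    return {"folds": fold_metrics, "summary": summary, "n_folds": folds}


# ---------------------------------------------------------------------------
# allele-swap predictions
# ---------------------------------------------------------------------------

def _edited_window(genome: dict[str, str], variant: Variant,
                   locus: GenomicLocus) -> tuple[str, str]:
    """(ref_window, alt_window), both length 5000.

    A substitution is applied in place; an indel re-centers a 5000 bp window
    on the variant after the edit so tensor shapes stay fixed.
    """
    seq = genome[variant.chrom]
    p = variant.pos0
    if seq[p : p + len(variant.ref)].upper() != variant.ref.upper():
        raise ValueError(
            f"reference allele mismatch at {variant.chrom}:{variant.pos}")
    ref_win = seq[locus.start : locus.end]
    if len(variant.ref) == len(variant.alt) == 1:
        off = p - locus.start
        alt_win = ref_win[:off] + variant.alt + ref_win[off + 1 :]
        return ref_win, alt_win
    edited = seq[:p] + variant.alt + seq[p + len(variant.ref) :]
    half = WINDOW_BP // 2
    lo = max(0, p - half)
    alt_win = edited[lo : lo + WINDOW_BP]
    ref_lo = max(0, p - half)
    ref_win = seq[ref_lo : ref_lo + WINDOW_BP]
    pad = "N" * (WINDOW_BP - len(alt_win))
    return (ref_win + "N" * (WINDOW_BP - len(ref_win)), alt_win + pad)


def delta_probability(variant: Variant, subgraph: SignalSubgraph,
                      model: GraphModel, genome: dict[str, str],
                      track: Track | None = None,
                      mode: str = "center",
                      target_profiles: list[int] | None = None) -> np.ndarray:
    """Per-profile probability change from substituting the alternate allele.

    The allele is swapped in the one node whose window contains the variant
    (the center window in ``center`` mode, a neighbor bin in ``neighbor``
    mode); a variant outside every node window gives exactly zero change.
    Dense-embedding models are not supported.
    """
    if model.cfg.feature_mode == "dense":
        raise ValueError("allele swaps are undefined for dense embeddings")
    if mode not in ("center", "neighbor"):
        raise ValueError("mode must be 'center' or 'neighbor'")
    targets = (np.arange(model.cfg.n_profiles) if target_profiles is None
               else np.asarray(target_profiles))
    loci = ([subgraph.center] if mode == "center" else list(subgraph.neighbors))
    hit = next((l for l in loci
                if l.chrom == variant.chrom and l.start <= variant.pos0 < l.end),
               None)
    if hit is None or variant.ref.upper() == variant.alt.upper():
        return np.zeros(len(targets))
    ref_win, alt_win = _edited_window(genome, variant, hit)
    mode_feat = model.cfg.feature_mode

    def make_fn(window_seq):
        def fn(locus: GenomicLocus, is_center: bool) -> np.ndarray:
            if locus == hit:
                x = one_hot_sequence(window_seq)
                if mode_feat == "seq_dnase":
                    sig = track.values(locus.chrom, locus.start, locus.end)
                    x = np.vstack([x, sig[None, :]])
                return x
            return locus_features(locus, genome, mode_feat, track)
        return fn

    model.eval()
    p_ref = model.forward_subgraphs([subgraph], make_fn(ref_win),
                                    check_attention=False).probabilities[0]
    p_alt = model.forward_subgraphs([subgraph], make_fn(alt_win),
                                    check_attention=False).probabilities[0]
    return (p_alt - p_ref)[targets]


def sign_agreement(deltas: dict[str, np.ndarray], slopes: np.ndarray,
                   n_strata: int = 3, n_boot: int = 200, seed: int = 0) -> dict:
    """Per-mark fraction of variants with sign(delta) == sign(slope).

    Baseline is the majority direction among the slopes.  Variants with an
    exactly zero delta carry no sign and are excluded (their count is
    reported).  The stratified curve bins variants by |slope| quantile with
    bootstrap CIs.
    """
    slopes = np.asarray(slopes, dtype=float)
    rng = np.random.default_rng(seed)
    nonzero_slope = slopes != 0
    p_up = float((slopes[nonzero_slope] > 0).mean()) if nonzero_slope.any() else 0.5
    baseline = max(p_up, 1.0 - p_up)
    out = {"baseline": baseline, "marks": {}}
    for mark, d in deltas.items():
        d = np.asarray(d, dtype=float)
        valid = (d != 0) & nonzero_slope
        excluded = int((~valid).sum())
        if not valid.any():
            out["marks"][mark] = {"agreement": None, "n": 0,
                                  "n_excluded": excluded}
            continue
        agree = np.sign(d[valid]) == np.sign(slopes[valid])
        mags = np.abs(slopes[valid])
        qedges = np.quantile(mags, np.linspace(0, 1, n_strata + 1))
        strata = []
        for s in range(n_strata):
            sel = ((mags >= qedges[s]) & (mags <= qedges[s + 1]) if s == n_strata - 1
                   else (mags >= qedges[s]) & (mags < qedges[s + 1]))
            if not sel.any():
                strata.append(None)
                continue
            vals = agree[sel].astype(float)
            boots = [vals[rng.integers(0, len(vals), len(vals))].mean()
                     for _ in range(n_boot)]
            strata.append({"mean": float(vals.mean()),
                           "ci_low": float(np.percentile(boots, 2.5)),
                           "ci_high": float(np.percentile(boots, 97.5)),
                           "n": int(sel.sum())})
        out["marks"][mark] = {"agreement": float(agree.mean()),
                              "n": int(valid.sum()), "n_excluded": excluded,
                              "strata": strata}
    return out


def perturbation_enrichment(abs_deltas: np.ndarray, is_pathogenic: np.ndarray,
                            top_fraction: float = 0.01,
                            modes: np.ndarray | None = None) -> dict:
    """Pathogenic enrichment in the top |delta-probability| stratum.

    Records are pooled (variant, profile) pairs.  Returns the 2x2 table,
    odds ratio (Haldane-corrected when a cell is empty) and Fisher-exact
    p-value, pooled and per mode (center / neighbor) when modes are given.
    """
    abs_deltas = np.asarray(abs_deltas, dtype=float)
    is_pathogenic = np.asarray(is_pathogenic, dtype=bool)
    if len(abs_deltas) < 1 / top_fraction:
        raise ValueError("too few records for the requested top fraction")

    def one(sel: np.ndarray) -> dict:
        d, y = abs_deltas[sel], is_pathogenic[sel]
        k = max(1, int(round(top_fraction * len(d))))
        thr_idx = np.argsort(-d)[:k]
        top = np.zeros(len(d), dtype=bool)
        top[thr_idx] = True
        a = int((top & y).sum())        # top, pathogenic
        b = int((top & ~y).sum())
        c = int((~top & y).sum())
        dd = int((~top & ~y).sum())
        if min(a, b, c, dd) == 0:
            orr = ((a + 0.5) * (dd + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * dd) / (b * c)
        _, pval = fisher_exact([[a, b], [c, dd]], alternative="greater")
        return {"table": [[a, b], [c, dd]], "odds_ratio": float(orr),
                "fisher_p": float(pval),
                "top_pathogenic_fraction": a / max(a + b, 1),
                "rest_pathogenic_fraction": c / max(c + dd, 1)}

    result = {"pooled": one(np.ones(len(abs_deltas), dtype=bool))}
    if modes is not None:
        modes = np.asarray(modes)
        for m in np.unique(modes):
            sel = modes == m
            if sel.sum() >= 1 / top_fraction:
                result[str(m)] = one(sel)
    return result
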