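"""End-to-end wiring of the synthetic world through the full method.

These helpers connect the pieces the way a real analysis would: fit the
polymer ensemble null once, test each chromosome's contact map against it,
build signal-centered subgraphs with neighbor-dependent labels, train the
two-stage model, and hand back everything downstream analyses need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_builder import SignalSubgraph, build_signal_subgraph, peak_center_window
from .io_formats import GenomicLocus
from .model import GraphModel, ModelConfig, TrainConfig, finetune_graph, pretrain_encoder
from .polymer_null import EnsembleNull, NonRandomContactSet, build_ensemble_null, fdr_filter, test_contacts
from .synthetic_data import SyntheticWorld, WorldConfig, build_world, generate_labels

__all__ = [
    "desk_model_config",
    "desk_train_config",
    "mini_world_config",
    "randomize_graphs",
    "filter_world_contacts",
    "world_subgraphs",
    "make_feature_fn",
    "TrainedExperiment",
    "run_synthetic_experiment",
]


def desk_model_config(**overrides) -> ModelConfig:
    """Model sized for CPU-scale synthetic runs (d=32, 4 heads, small CNN)."""
    base = dict(d=32, heads=4, n_profiles=8, feature_mode="seq_dnase",
                conv_channels=(16, 16, 32), kernel=15)
    base.update(overrides)
    return ModelConfig(**base)


def desk_train_config(stage: int, seed: int = 0, **overrides) -> TrainConfig:
    """Training schedules for the synthetic world (larger lr than the
    full-scale default so few epochs suffice on the small model)."""
    # the sequence signal emerges late (plateau then drop), so stage 1 runs
    # its full budget and relies on the best-validation checkpoint instead
    # of early stopping
    base = dict(lr=3e-3 if stage == 1 else 1e-3,
                weight_decay=1e-4 if stage == 1 else 1e-6,
                epochs=80 if stage == 1 else 30,
                batch_size=16, patience=80, augment=True, seed=seed)
    base.update(overrides)
    return TrainConfig(**base)


def mini_world_config(**overrides) -> WorldConfig:
    """Reduced world (1 Mb windows, 120 centers) for multi-seed ablations."""
    base = dict(n_bins=200, centers_per_chrom=40, n_anchors=8, depth=20_000)
    base.update(overrides)
    return WorldConfig(**base)


def randomize_graphs(graphs, candidate_bins_by_chrom, seed: int = 0):
    """Ablation arm: every subgraph's neighbor set replaced by degree- and
    distance-matched random bins (labels and masks untouched)."""
    from .graph_builder import matched_random_controls

    out = []
    for k, g in enumerate(graphs):
        if g.degree == 0:
            out.append(g)
            continue
        out.append(matched_random_controls(
            g, candidate_bins_by_chrom[g.center_bin.chrom], seed=seed + k))
    return out


def filter_world_contacts(world: SyntheticWorld, null: EnsembleNull,
                          q: float = 0.05) -> dict[str, NonRandomContactSet]:
    """Polymer-null test + BH filter for every chromosome window."""
    out = {}
    for chrom, cmap in world.contact_maps.items():
        out[chrom] = fdr_filter(test_contacts(cmap, null), q)
    return out


def world_subgraphs(world: SyntheticWorld,
                    contacts: dict[str, NonRandomContactSet],
                    seed: int = 0) -> tuple[list[SignalSubgraph], dict]:
    """Signal-centered subgraphs with neighbor-dependent labels and masks."""
    cfg = world.config
    centers, center_bins = [], []
    for peak in world.peaks:
        center, center_bin = peak_center_window(peak, cfg.window_bp)
        centers.append(center)
        center_bins.append(center_bin)

    class _Union:
        """Contact view across chromosomes for label generation."""

        def neighbors_of(self, locus):
            c = contacts.get(locus.chrom)
            return c.neighbors_of(locus) if c is not None else []

    doses = {chrom: {b: len(pos) for b, pos in
                     world.ledger["genome"][chrom]["motif_instances"].items()}
             for chrom in cfg.chroms}
    labels, mask, label_ledger = generate_labels(
        center_bins, _Union(), doses, cfg.n_assays, cfg.flip_noise,
        cfg.mask_drop, seed, resolution=cfg.resolution)
    graphs = []
    for i, peak in enumerate(world.peaks):
        graphs.append(build_signal_subgraph(
            center_bins[i], contacts[peak.locus.chrom], labels[i], mask[i],
            center=centers[i], assay_id=peak.assay_id,
            cell_context=peak.cell_context))
    return graphs, label_ledger


def make_feature_fn(world: SyntheticWorld, mode: str):
    from .model import locus_features

    def fn(locus: GenomicLocus, is_center: bool) -> np.ndarray:
        return locus_features(locus, world.genome, mode, world.track)

    return fn


@dataclass
class TrainedExperiment:
    world: SyntheticWorld
    null: EnsembleNull
    contacts: dict[str, NonRandomContactSet]
    graphs: list[SignalSubgraph]
    label_ledger: dict
    encoder_state: dict
    stage1_history: list
    model: GraphModel
    stage2_history: list
    feature_fn: object


def run_synthetic_experiment(seed: int = 0,
                             world_config: WorldConfig | None = None,
                             model_config: ModelConfig | None = None,
                             n_chains: int = 2000,
                             stage1: TrainConfig | None = None,
                             stage2: TrainConfig | None = None,
                             q: float = 0.05) -> TrainedExperiment:
    """Generate world, fit null, filter contacts, run two-stage training."""
    wcfg = world_config or WorldConfig()
    mcfg = model_config or desk_model_config(n_profiles=wcfg.n_assays,
                                             pwm_init=(wcfg.motif,))
    tc1 = stage1 or desk_train_config(1, seed=seed)
    tc2 = stage2 or desk_train_config(2, seed=seed)
    world = build_world(wcfg, seed=seed)
    null = build_ensemble_null(n_chains, wcfg.n_bins, seed=seed + 1)
    contacts = filter_world_contacts(world, null, q)
    graphs, label_ledger = world_subgraphs(world, contacts, seed=seed + 2)
    feature_fn = make_feature_fn(world, mcfg.feature_mode)
    encoder_state, hist1 = pretrain_encoder(graphs, feature_fn, mcfg, tc1)
    model, hist2 = finetune_graph(graphs, feature_fn, encoder_state, mcfg, tc2)
    return TrainedExperiment(world=world, null=null, contacts=contacts,
                             graphs=graphs, label_ledger=label_ledger,
                             encoder_state=encoder_state, stage1_history=hist1,
                             model=model, stage2_history=hist2,
                             feature_fn=feature_fn)
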