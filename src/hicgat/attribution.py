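"""Attention-derived neighbor-to-center contribution maps.

The softmax attention coefficients on center-incoming edges act as intrinsic
attributions of each neighbor's influence on the center.  The default
aggregation averages the coefficients over all heads of both layers and
renormalizes over neighbors; final-layer-only and per-head views are
available for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np

from .graph_builder import SignalSubgraph
from .io_formats import GenomicLocus
from .model import AttentionRecord

__all__ = [
    "ContributionMap",
    "neighbor_contributions",
    "real_share",
    "distance_decay_profile",
    "external_score_comparison",
    "export_contribution_map",
]


class ContributionMap:
    """Normalized neighbor-to-center influence weights for one center."""

    def __init__(self, center: GenomicLocus, center_bin: GenomicLocus,
                 entries: list[tuple[GenomicLocus, float, float, bool | None]]):
        self.center = center
        self.center_bin = center_bin
        self.entries = entries  # (neighbor, weight, distance_bp, real_flag)
        if entries:
            total = sum(w for _, w, _, _ in entries)
            if not np.isclose(total, 1.0, atol=1e-6):
                raise AssertionError("contribution weights must sum to 1")
            if any(w < 0 for _, w, _, _ in entries):
                raise AssertionError("contribution weights must be nonnegative")

    def __len__(self):
        return len(self.entries)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w, _, _ in self.entries])

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, _, d, _ in self.entries])


def neighbor_contributions(record: AttentionRecord, subgraph: SignalSubgraph,
                           aggregation: str = "mean_all") -> ContributionMap:
    """Aggregate attention into per-neighbor contributions.

    ``mean_all`` (default) averages alpha on center-incoming edges over every
    head of every layer; ``final_layer`` uses the last layer only;
    ``head:<layer>:<head>`` selects one coefficient set.
    """
    if subgraph.degree == 0:
        return ContributionMap(subgraph.center, subgraph.center_bin, [])
    # center is graph-local node 0; incoming edges have dst == 0
    incoming = record.edges[:, 1] == 0
    src = record.edges[incoming, 0]
    if aggregation == "mean_all":
        alpha = np.mean([a[incoming].mean(axis=1) for a in record.alpha], axis=0)
    elif aggregation == "final_layer":
        alpha = record.alpha[-1][incoming].mean(axis=1)
    elif aggregation.startswith("head:"):
        _, layer, head = aggregation.split(":")
        alpha = record.alpha[int(layer)][incoming, int(head)]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    weights = np.zeros(subgraph.degree)
    for s, a in zip(src, alpha):
        weights[s - 1] += a   # node k+1 is neighbor k
    weights = weights / weights.sum()
    cmid = subgraph.center_bin.midpoint
    entries = []
    for k, nb in enumerate(subgraph.neighbors):
        flag = None if subgraph.provenance is None else bool(subgraph.provenance[k])
        entries.append((nb, float(weights[k]), abs(nb.midpoint - cmid), flag))
    return ContributionMap(subgraph.center, subgraph.center_bin, entries)


def real_share(cmap: ContributionMap) -> float:
    """Fraction of total contribution carried by real (non-random) neighbors."""
    if any(flag is None for _, _, _, flag in cmap.entries) or len(cmap) == 0:
        raise ValueError("contribution map lacks real/random provenance flags")
    return float(sum(w for _, w, _, flag in cmap.entries if flag))


def distance_decay_profile(maps: list[ContributionMap], bin_edges,
                           n_boot: int = 200, seed: int = 0) -> dict:
    """Mean contribution per genomic-distance bin, with bootstrap CIs.

    Bootstrap resamples centers.  Distance bins with no observations are
    reported as missing (None), not as zero.
    """
    if not maps:
        raise ValueError("no contribution maps given")
    bin_edges = np.asarray(bin_edges, dtype=float)
    nb = len(bin_edges) - 1

    def per_bin_mean(selected: list[ContributionMap]):
        sums = np.zeros(nb)
        cnts = np.zeros(nb)
        for m in selected:
            if len(m) == 0:
                continue
            idx = np.digitize(m.distances, bin_edges) - 1
            ok = (idx >= 0) & (idx < nb)
            np.add.at(sums, idx[ok], m.weights[ok])
            np.add.at(cnts, idx[ok], 1)
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)

    mean = per_bin_mean(maps)
    rng = np.random.default_rng(seed)
    boots = np.array([per_bin_mean([maps[i] for i in
                                    rng.integers(0, len(maps), len(maps))])
                      for _ in range(n_boot)])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
    return {
        "bin_edges": bin_edges.tolist(),
        "mean": [None if np.isnan(v) else float(v) for v in mean],
        "ci_low": [None if np.isnan(v) else float(v) for v in lo],
        "ci_high": [None if np.isnan(v) else float(v) for v in hi],
    }


def external_score_comparison(maps: list[ContributionMap],
                              score_table: dict[str, float],
                              deciles: int = 10) -> dict:
    """Join neighbor contributions to an external per-locus score table.

    The table is keyed by 5 kb grid loci (pre-binned by max score per locus
    upstream, with any score threshold applied by the caller).  Returns
    per-decile mean contributions and the Spearman rank correlation; a
    degenerate score distribution yields a missing correlation.
    """
    from scipy.stats import rankdata, spearmanr

    contrib, scores = [], []
    for m in maps:
        for nb, w, _, _ in m.entries:
            if nb.key() in score_table:
                contrib.append(w)
                scores.append(score_table[nb.key()])
    if not contrib:
        raise ValueError("no neighbor loci overlap the score table")
    contrib = np.asarray(contrib)
    scores = np.asarray(scores)
    if np.ptp(scores) == 0:
        rho = None
    else:
        rho = float(spearmanr(contrib, scores).statistic)
    ranks = rankdata(scores, method="average")
    dec = np.minimum((ranks - 1) * deciles // len(scores), deciles - 1)
    decile_means = [float(contrib[dec == d].mean()) if (dec == d).any() else None
                    for d in range(deciles)]
    return {"decile_means": decile_means, "spearman_rho": rho,
            "n_pairs": len(contrib)}


def export_contribution_map(cmap: ContributionMap, bedpe_path,
                            plot_path=None):
    """BEDPE rows (sorted by neighbor coordinate) plus an optional bar plot."""
    rows = sorted((nb.chrom, nb.start, nb.end, w)
                  for nb, w, _, _ in cmap.entries)
    c = cmap.center_bin
    with open(bedpe_path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tcontribution\n")
        for chrom, s, e, w in rows:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{chrom}\t{s}\t{e}\t{w:.8g}\n")
    if plot_path is not None and len(cmap):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 2.5))
        xs = [nb.midpoint for nb, _, _, _ in cmap.entries]
        ax.bar(xs, cmap.weights, width=4000, color="steelblue")
        ax.axvline(c.midpoint, color="orange", lw=2)
        ax.set_xlabel(f"{c.chrom} position (bp)")
        ax.set_ylabel("contribution")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
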