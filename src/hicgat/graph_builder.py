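"""Signal-centered star subgraphs from peaks and filtered contacts.

Each 1 kb peak defines a 5 kb feature window (2 kb flank on each side) whose
maximum-overlap grid bin anchors contact lookup; the subgraph is the star of
that bin's non-random contact partners.  Degree- and distance-matched random
controls support the ablations: every true neighbor is paired with a random
bin sampled within +/-100 kb of it, excluding the true neighbor set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import RESOLUTION, GenomicLocus, Peak
from .polymer_null import NonRandomContactSet

log = logging.getLogger(__name__)

__all__ = [
    "SignalSubgraph",
    "peak_center_window",
    "build_signal_subgraph",
    "consensus_contacts",
    "matched_random_controls",
    "mix_real_random",
    "write_subgraphs_jsonl",
    "read_subgraphs_jsonl",
]

FLANK_BP = 2000
CONTROL_WINDOW_BP = 100_000


@dataclass
class SignalSubgraph:
    """Star graph: one center locus plus its direct non-random neighbors."""

    center: GenomicLocus              # 5 kb feature window (may be off-grid)
    center_bin: GenomicLocus          # grid bin used for contact lookup
    neighbors: list[GenomicLocus] = field(default_factory=list)
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mask: np.ndarray = field(default_factory=lambda: np.zeros(0))
    provenance: np.ndarray | None = None   # per-neighbor True = real contact
    assay_id: str = ""
    cell_context: str = ""

    def __post_init__(self):
        if len(set(self.neighbors)) != len(self.neighbors):
            raise ValueError("duplicate neighbors")
        if self.center_bin in self.neighbors:
            raise ValueError("center bin cannot be its own neighbor")
        if self.labels.shape != self.mask.shape:
            raise ValueError("labels and mask must have equal length")
        if self.provenance is not None and len(self.provenance) != self.degree:
            raise ValueError("provenance flags must cover every neighbor")

    @property
    def degree(self) -> int:
        return len(self.neighbors)

    @property
    def edges(self) -> list[tuple[GenomicLocus, GenomicLocus]]:
        return [(self.center_bin, nb) for nb in self.neighbors]


def peak_center_window(peak: Peak,
                       chrom_length: int | None = None,
                       resolution: int = RESOLUTION
                       ) -> tuple[GenomicLocus, GenomicLocus]:
    """5 kb feature window (2 kb flanks) and its maximum-overlap grid bin.

    A window running past the chromosome start is clipped at 0 and restored
    to 5 kb by right extension (logged); ties between the two candidate grid
    bins break toward the lower coordinate.
    """
    loc = peak.locus
    start = loc.start - FLANK_BP
    end = loc.end + FLANK_BP
    if start < 0:
        log.info("center window for %s clipped at chromosome start", loc.key())
        start, end = 0, end - start
    if chrom_length is not None and end > chrom_length:
        shift = end - chrom_length
        start, end = max(0, start - shift), chrom_length
    center = GenomicLocus(loc.chrom, start, end)

    first_bin = (center.start // resolution) * resolution
    best, best_ov = None, -1
    for bs in range(first_bin, center.end, resolution):
        ov = min(center.end, bs + resolution) - max(center.start, bs)
        if ov > best_ov:  # strict: ties keep the lower-coordinate bin
            best, best_ov = bs, ov
    center_bin = GenomicLocus(loc.chrom, best, best + resolution)
    return center, center_bin


def build_signal_subgraph(center_bin: GenomicLocus,
                          contacts: NonRandomContactSet,
                          labels: np.ndarray | None = None,
                          mask: np.ndarray | None = None,
                          center: GenomicLocus | None = None,
                          assay_id: str = "",
                          cell_context: str = "") -> SignalSubgraph:
    """Star of all loci paired with ``center_bin``; sorted, possibly empty."""
    neighbors = contacts.neighbors_of(center_bin)
    T = 0 if labels is None else len(labels)
    return SignalSubgraph(
        center=center if center is not None else center_bin,
        center_bin=center_bin,
        neighbors=neighbors,
        labels=np.asarray(labels) if labels is not None else np.zeros(T),
        mask=np.asarray(mask) if mask is not None else np.ones(T),
        provenance=np.ones(len(neighbors), dtype=bool),
        assay_id=assay_id,
        cell_context=cell_context,
    )


def consensus_contacts(sets: list[NonRandomContactSet]) -> NonRandomContactSet:
    """Pairs present in every input; p/q are the per-pair maxima (conservative)."""
    if not sets:
        raise ValueError("need at least one contact set")
    if len({s.resolution for s in sets}) != 1:
        raise ValueError("mixed resolutions")
    common = set.intersection(*(s.pair_keys() for s in sets))
    agg: dict[tuple[str, str], list[float]] = {}
    loci: dict[tuple[str, str], tuple[GenomicLocus, GenomicLocus]] = {}
    for s in sets:
        for a, b, p, q in s.pairs:
            k = (a.key(), b.key())
            if k in common:
                agg.setdefault(k, []).append((p, q))
                loci[k] = (a, b)
    pairs = [(loci[k][0], loci[k][1],
              max(p for p, _ in v), max(q for _, q in v))
             for k, v in agg.items()]
    return NonRandomContactSet(pairs=pairs,
                               fdr_level=max(s.fdr_level for s in sets),
                               resolution=sets[0].resolution)


def matched_random_controls(subgraph: SignalSubgraph,
                            candidate_bins: list[GenomicLocus],
                            window: int = CONTROL_WINDOW_BP,
                            seed: int = 0) -> SignalSubgraph:
    """Degree-preserving control: one random bin within +/-window per neighbor.

    Candidates exclude the center bin, every true neighbor, and bins already
    chosen (sampling without replacement).  If a neighbor has no eligible
    candidate the window is widened by one bin step (logged); a second
    failure is an error.
    """
    rng = np.random.default_rng(seed)
    forbidden = set(subgraph.neighbors) | {subgraph.center_bin}
    chosen: list[GenomicLocus] = []
    same_chrom = [b for b in candidate_bins
                  if b.chrom == subgraph.center_bin.chrom]
    for nb in subgraph.neighbors:
        for w in (window, window + subgraph.center_bin.width):
            pool = [b for b in same_chrom
                    if b not in forbidden and b not in chosen
                    and abs(b.start - nb.start) <= w]
            if pool:
                break
            log.info("no control candidate within %d bp of %s; widening",
                     w, nb.key())
        else:
            raise ValueError(f"no eligible control bin near {nb.key()}")
        pool.sort()
        chosen.append(pool[rng.integers(len(pool))])
    return SignalSubgraph(
        center=subgraph.center, center_bin=subgraph.center_bin,
        neighbors=chosen, labels=subgraph.labels.copy(),
        mask=subgraph.mask.copy(),
        provenance=np.zeros(len(chosen), dtype=bool),
        assay_id=subgraph.assay_id, cell_context=subgraph.cell_context,
    )


def mix_real_random(subgraph: SignalSubgraph,
                    control: SignalSubgraph) -> SignalSubgraph:
    """Union of real and control neighbors with provenance flags.

    Doubles the edge set up to collisions (control bins that coincide with a
    real neighbor are dropped and logged).
    """
    if control.center_bin != subgraph.center_bin:
        raise ValueError("mixed graphs must share the same center")
    real = list(subgraph.neighbors)
    added = [b for b in control.neighbors if b not in set(real)]
    if len(added) < len(control.neighbors):
        log.info("dropped %d colliding control neighbors",
                 len(control.neighbors) - len(added))
    prov = np.concatenate([np.ones(len(real), dtype=bool),
                           np.zeros(len(added), dtype=bool)])
    return SignalSubgraph(
        center=subgraph.center, center_bin=subgraph.center_bin,
        neighbors=real + added, labels=subgraph.labels.copy(),
        mask=subgraph.mask.copy(), provenance=prov,
        assay_id=subgraph.assay_id, cell_context=subgraph.cell_context,
    )


# ---------------------------------------------------------------------------
# serialization (JSON lines, one subgraph per line)
# ---------------------------------------------------------------------------

def write_subgraphs_jsonl(graphs: list[SignalSubgraph], path):
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(json.dumps({
                "center": g.center.key(),
                "center_bin": g.center_bin.key(),
                "neighbors": [nb.key() for nb in g.neighbors],
                "labels": np.asarray(g.labels).tolist(),
                "mask": np.asarray(g.mask).tolist(),
                "provenance": (None if g.provenance is None
                               else np.asarray(g.provenance, dtype=int).tolist()),
                "assay_id": g.assay_id,
                "cell_context": g.cell_context,
            }) + "\n")


def read_subgraphs_jsonl(path) -> list[SignalSubgraph]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(SignalSubgraph(
                center=GenomicLocus.from_key(d["center"]),
                center_bin=GenomicLocus.from_key(d["center_bin"]),
                neighbors=[GenomicLocus.from_key(k) for k in d["neighbors"]],
                labels=np.asarray(d["labels"]),
                mask=np.asarray(d["mask"]),
                provenance=(None if d["provenance"] is None
                            else np.asarray(d["provenance"], dtype=bool)),
                assay_id=d["assay_id"], cell_context=d["cell_context"],
            ))
    return out
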