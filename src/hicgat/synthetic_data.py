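"""Seeded generators for every input the pipeline consumes.

The synthetic world emulates the statistical structure the method assumes:
a distance-decaying Hi-C background with planted enriched ("specific") locus
pairs, a genome with a planted regulatory motif, accessibility elevated over
motif-bearing loci, multi-assay labels whose truth depends on motif content
of the center *or of its contacted neighbors* (so graph context is genuinely
informative), and variants whose signed effect follows motif disruption or
creation.  Every planted fact is recorded in a ledger keyed by chromosome,
and generation is fully determined by (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import RESOLUTION, ContactMap, GenomicLocus, Peak, Track

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_hic",
    "generate_genome_and_tracks",
    "generate_labels",
    "generate_variants",
    "build_world",
]

BASES = np.array(list("ACGT"))


@dataclass
class WorldConfig:
    """Desk-scale defaults: 800-bin (4 Mb) windows, T=8 assays, ~200 centers."""

    chroms: tuple[str, ...] = ("chr1", "chr8", "chr9")
    n_bins: int = 800
    resolution: int = RESOLUTION
    n_assays: int = 8
    centers_per_chrom: int = 120
    depth: int = 100_000
    decay_exponent: float = 1.0
    enrichment: float = 8.0
    n_anchors: int = 20                            # hub loci with planted contacts
    partners_per_anchor_mean: float = 3.0          # mean planted partners per hub
    partner_motif_prob: float = 0.7                # informative vs inert partners
    planted_sep_range: tuple[int, int] = (2, 20)   # 10-100 kb: loop scale
    motif: str = "TGACGTCATGCA"
    motif_bin_fraction: float = 0.25
    near_motif_bin_fraction: float = 0.125         # degenerate sites (open, inactive)
    near_mismatches: int = 1                       # substitutions per degenerate copy
    motif_copies_range: tuple[int, int] = (8, 24)  # homotypic cluster dose (active)
    near_copies_range: tuple[int, int] = (1, 4)    # degenerate copies (inactive)
    accessibility_baseline: float = 0.3
    accessibility_noise: float = 0.1
    accessibility_bump: float = 1.0
    flip_noise: float = 0.05
    mask_drop: float = 0.10

    @property
    def window_bp(self) -> int:
        return self.n_bins * self.resolution


@dataclass
class SyntheticWorld:
    config: WorldConfig
    genome: dict[str, str]
    track: Track
    contact_maps: dict[str, ContactMap]
    peaks: list[Peak]
    ledger: dict

    def grid_bins(self, chrom: str) -> list[GenomicLocus]:
        r = self.config.resolution
        return [GenomicLocus(chrom, i * r, (i + 1) * r)
                for i in range(self.config.n_bins)]


# ---------------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------------

def generate_hic(n_bins: int, depth: int, decay_exponent: float,
                 planted_pairs: list[tuple[int, int]], enrichment: float,
                 seed: int, window: GenomicLocus,
                 resolution: int = RESOLUTION,
                 base_probs: np.ndarray | None = None):
    """Poisson contact map with power-law decay and planted enriched pairs.

    Expected counts are lambda_ij proportional to |i-j|^-alpha (or to a
    caller-supplied per-separation probability table), multiplied by
    ``enrichment`` on planted pairs, and normalized to total ``depth``.
    Returns (ContactMap, ledger).
    """
    if decay_exponent <= 0:
        raise ValueError("decay exponent must be positive")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_bins, k=1)
    sep = ju - iu
    if base_probs is not None:
        weights = base_probs[sep].astype(float)
    else:
        weights = sep.astype(float) ** -decay_exponent
    planted = set()
    for a, b in planted_pairs:
        lo, hi = min(a, b), max(a, b)
        if not (0 <= lo < hi < n_bins):
            raise ValueError(f"planted pair ({a},{b}) outside window")
        planted.add((lo, hi))
    if planted:
        pi_arr = np.array(sorted(planted))
        flat = pi_arr[:, 0] * n_bins + pi_arr[:, 1]
        mask = np.isin(iu * n_bins + ju, flat)
        weights = weights.copy()
        weights[mask] *= enrichment
    lam = weights * (depth / weights.sum()) if depth > 0 else np.zeros_like(weights)
    counts = rng.poisson(lam)
    nz = counts > 0
    cmap = ContactMap.from_triplets(window, iu[nz], ju[nz], counts[nz],
                                    resolution)
    ledger = {"planted_pairs": sorted(planted),
              "depth": depth, "enrichment": enrichment,
              "decay_exponent": decay_exponent}
    return cmap, ledger


# ---------------------------------------------------------------------------
# genome + accessibility
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def generate_genome_and_tracks(chrom: str, n_bins: int, motif: str,
                               motif_bins: list[int], noise: float, seed: int,
                               resolution: int = RESOLUTION,
                               near_motif_bins: list[int] = (),
                               baseline: float = 0.3, bump: float = 1.0,
                               near_mismatches: int = 1,
                               copies_range: tuple[int, int] = (8, 24),
                               near_copies_range: tuple[int, int] = (1, 4)):
    """Random-background sequence with a homotypic motif cluster per listed bin.

    Each motif bin carries a cluster of exact instances whose size (the
    "dose") is drawn from ``copies_range``, so downstream models see a
    graded rather than thresholded signal; each ``near_motif_bins`` entry
    carries a few degenerate instances with ``near_mismatches`` recorded
    substitutions each (substrate for motif-creating variants).
    Accessibility is piecewise constant per bin: truncated-gaussian baseline
    plus a bump on open (motif or degenerate) bins.  Returns (sequence
    string, Track, ledger).
    """
    if len(motif) >= resolution:
        raise ValueError("motif must be shorter than one locus")
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, n_bins * resolution)
    motif_arr = np.array(list(motif))
    ledger = {"motif": motif, "motif_instances": {}, "near_motif_instances": {}}
    # scrub chance background hits so 'motif absent' holds where not planted
    seq_str = "".join(seq)
    start = seq_str.find(motif)
    while start != -1:
        seq[start] = BASES[(np.where(BASES == seq[start])[0][0] + 1) % 4]
        seq_str = "".join(seq)
        start = seq_str.find(motif)
    span = 2 * len(motif)   # spacing that keeps instances non-overlapping

    def _offsets(k):
        slots = (resolution - span) // span
        picks = rng.choice(slots, size=min(k, slots), replace=False)
        return sorted(int(p) * span + int(rng.integers(0, span - len(motif)))
                      for p in picks)

    for b in motif_bins:
        dose = int(rng.integers(copies_range[0], copies_range[1] + 1))
        positions = [b * resolution + off for off in _offsets(dose)]
        for pos in positions:
            seq[pos : pos + len(motif)] = motif_arr
        ledger["motif_instances"][b] = positions
    for b in near_motif_bins:
        instances = []
        k = int(rng.integers(near_copies_range[0], near_copies_range[1] + 1))
        for off in _offsets(k):
            pos = b * resolution + off
            mism = sorted(int(i) for i in
                          rng.choice(len(motif), size=near_mismatches,
                                     replace=False))
            inst = motif_arr.copy()
            correct = []
            for m in mism:
                orig = inst[m]
                correct.append(str(orig))
                inst[m] = BASES[(np.where(BASES == orig)[0][0] + 1) % 4]
            seq[pos : pos + len(motif)] = inst
            instances.append({"pos": pos, "mismatch_offsets": mism,
                              "correct_bases": correct})
        ledger["near_motif_instances"][b] = instances
    track = Track()
    # open chromatin marks exact and degenerate sites alike: accessibility
    # alone cannot separate active from inactive open loci
    open_set = set(motif_bins) | set(near_motif_bins)
    values = np.maximum(rng.normal(baseline, noise, size=n_bins), 0.0)
    for i in range(n_bins):
        v = values[i] + (bump if i in open_set else 0.0)
        track.add(chrom, i * resolution, (i + 1) * resolution, v)
    ledger["accessibility"] = values.tolist()
    return "".join(seq), track, ledger


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def generate_labels(center_bins: list[GenomicLocus], contacts,
                    motif_doses_by_chrom: dict[str, dict[int, int]],
                    n_assays: int, flip_noise: float, mask_drop: float,
                    seed: int, dose_thresholds=None,
                    resolution: int = RESOLUTION):
    """Neighbor-dependent multi-assay labels driven by motif-cluster dose.

    Assay t fires on loci whose homotypic cluster has at least
    ``dose_thresholds[t]`` exact motif copies (different factors need
    different site densities); a center is positive iff its own bin or at
    least one contacted neighbor exceeds the assay's threshold, then flipped
    with probability ``flip_noise``.  Masks drop a random fraction of
    (center, assay) entries.  Returns (labels, mask, ledger); the ledger
    records per-center informative neighbors (motif-bearing contacted bins),
    the thresholds, and the noise-free labels.
    """
    rng = np.random.default_rng(seed)
    doses = {c: dict(d) for c, d in motif_doses_by_chrom.items()}
    all_doses = [v for d in doses.values() for v in d.values()]
    if dose_thresholds is None:
        hi = max(all_doses, default=1)
        dose_thresholds = np.unique(
            np.linspace(1, hi, n_assays).round().astype(int))
        dose_thresholds = list(dose_thresholds) + [
            dose_thresholds[-1]] * (n_assays - len(dose_thresholds))
    n = len(center_bins)
    labels = np.zeros((n, n_assays), dtype=np.int8)
    clean = np.zeros((n, n_assays), dtype=np.int8)
    mask = (rng.random((n, n_assays)) >= mask_drop).astype(np.int8)
    informative: list[list[str]] = []

    def dose_of(chrom, b):
        return doses.get(chrom, {}).get(b, 0)

    for i, cb in enumerate(center_bins):
        own = dose_of(cb.chrom, cb.start // resolution)
        nbs = contacts.neighbors_of(cb)
        nb_doses = [dose_of(nb.chrom, nb.start // resolution) for nb in nbs]
        informative.append([nb.key() for nb, d in zip(nbs, nb_doses) if d > 0])
        best = max([own] + nb_doses)
        for t in range(n_assays):
            y = int(best >= dose_thresholds[t])
            clean[i, t] = y
            if rng.random() < flip_noise:
                y = 1 - y
            labels[i, t] = y
    ledger = {
        "dose_thresholds": [int(t) for t in dose_thresholds],
        "informative_neighbors": informative,
        "clean_labels": clean.tolist(),
        "flip_noise": flip_noise,
    }
    return labels, mask, ledger


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def generate_variants(world: SyntheticWorld, contacts_by_chrom: dict,
                      n_eqtl: int, n_pathogenic: int, seed: int):
    """Variant tables with signed planted effects.

    Effect variants act at the level of whole binding-site copies, the unit
    the dose-coded labels are defined on: an eQTL positive either deletes
    one exact motif copy from a cluster *wired to a gene* (negative slope)
    or inserts one copy into a wired partner locus (positive slope).
    Negatives are type-matched edits in loci that contact no center --
    copy deletions in unwired clusters, motif insertions into unwired bins,
    plus neutral substitutions and deletions -- so the variant's local
    appearance alone cannot settle the label; only the chromatin wiring can.
    The paired TSS is the contacted center for positives and a random
    center for negatives.

    Pathogenic variants disrupt motif clusters (substitutions and single-
    copy deletions); benign variants are type-matched edits in neutral
    sequence.  Returns (eqtl_variants, clinvar_variants, ledger); both
    lists hold :class:`hicgat.variant_tasks.Variant`.
    """
    from .variant_tasks import Variant

    cfg = world.config
    rng = np.random.default_rng(seed)
    res = cfg.resolution
    L = len(cfg.motif)
    ledger = {"eqtl": [], "clinvar": []}
    chroms = list(cfg.chroms)

    def locus_of_bin(chrom, b):
        return GenomicLocus(chrom, b * res, (b + 1) * res)

    center_bins = {c: set() for c in chroms}
    for peak in world.peaks:
        mid = (peak.locus.start + peak.locus.end) // 2
        center_bins[peak.locus.chrom].add(mid // res)

    # bins contacted by at least one center, with one contacting center each
    contacted: dict[str, dict[int, int]] = {}
    for chrom in chroms:
        contacted[chrom] = {}
        contacts = contacts_by_chrom.get(chrom)
        if contacts is None:
            continue
        for cb in sorted(center_bins[chrom]):
            for nb in contacts.neighbors_of(locus_of_bin(chrom, cb)):
                contacted[chrom].setdefault(nb.start // res, cb)

    def special_bins(chrom):
        led = world.ledger["genome"][chrom]
        return set(led["motif_bins"]) | set(led["near_motif_bins"])

    def wired_motif_bins(chrom):
        motif = set(world.ledger["genome"][chrom]["motif_bins"])
        return sorted(motif & set(contacted[chrom]))

    def unwired_motif_bins(chrom):
        motif = set(world.ledger["genome"][chrom]["motif_bins"])
        return sorted(motif - set(contacted[chrom]))

    def wired_plain_bins(chrom):
        return sorted((set(contacted[chrom]) - special_bins(chrom))
                      - center_bins[chrom])

    def unwired_plain_bins(chrom):
        return sorted(set(range(cfg.n_bins)) - special_bins(chrom)
                      - set(contacted[chrom]) - center_bins[chrom])

    def random_center(chrom):
        pool = sorted(center_bins[chrom])
        return locus_of_bin(chrom, pool[int(rng.integers(len(pool)))])

    def copy_deletion(chrom, b):
        """Delete one whole motif copy (VCF-style left-anchored indel)."""
        positions = world.ledger["genome"][chrom]["motif_instances"][b]
        mpos = positions[int(rng.integers(len(positions)))]
        pos0 = mpos - 1
        ref = world.genome[chrom][pos0 : pos0 + L + 1]
        return pos0, ref, ref[0]

    def motif_insertion(chrom, b):
        """Insert one full motif copy mid-bin."""
        pos0 = b * res + res // 2
        ref = world.genome[chrom][pos0]
        return pos0, ref, ref + cfg.motif

    def neutral_position(chrom, margin=0):
        special = special_bins(chrom)
        while True:
            pos = int(rng.integers(1, cfg.window_bp - margin - 1))
            if pos // res not in special and (pos + margin) // res \
                    not in special:
                return pos

    def neutral_substitution(chrom):
        pos0 = neutral_position(chrom)
        ref = world.genome[chrom][pos0]
        return pos0, ref, str(BASES[(np.where(BASES == ref)[0][0] + 1) % 4])

    def neutral_deletion(chrom):
        pos0 = neutral_position(chrom, margin=L + 1)
        ref = world.genome[chrom][pos0 : pos0 + L + 1]
        return pos0, ref, ref[0]

    def cluster_substitution(chrom, b):
        positions = world.ledger["genome"][chrom]["motif_instances"][b]
        mpos = positions[int(rng.integers(len(positions)))]
        pos0 = mpos + int(rng.integers(0, L))
        ref = world.genome[chrom][pos0]
        return pos0, ref, str(BASES[(np.where(BASES == ref)[0][0] + 1) % 4])

    def pick(pool):
        return pool[int(rng.integers(len(pool)))] if pool else None

    eqtl: list[Variant] = []
    made = 0
    attempts = 0
    while made < n_eqtl:
        attempts += 1
        if attempts > 100 * n_eqtl:
            raise ValueError("could not place the requested eQTL variants; "
                             "the world has too few wired loci")
        chrom = chroms[int(rng.integers(len(chroms)))]
        if made % 2 == 0:
            b = pick(wired_motif_bins(chrom))
            if b is None:
                continue
            pos0, ref, alt = copy_deletion(chrom, b)
            slope = -float(rng.uniform(0.2, 1.0))
        else:
            b = pick(wired_plain_bins(chrom))
            if b is None:
                continue
            pos0, ref, alt = motif_insertion(chrom, b)
            slope = float(rng.uniform(0.2, 1.0))
        tss = locus_of_bin(chrom, contacted[chrom][b])
        eqtl.append(Variant(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                            label="eqtl", slope=slope, tss=tss))
        ledger["eqtl"].append({"chrom": chrom, "pos0": pos0, "bin": b,
                               "slope": slope})
        made += 1
    made = 0
    attempts = 0
    while made < n_eqtl:   # type-matched negatives, all unwired
        attempts += 1
        if attempts > 100 * n_eqtl:
            raise ValueError("could not place the requested eQTL negatives")
        chrom = chroms[int(rng.integers(len(chroms)))]
        kind = made % 4
        if kind == 0:
            b = pick(unwired_motif_bins(chrom))
            if b is None:
                continue
            pos0, ref, alt = copy_deletion(chrom, b)
        elif kind == 1:
            b = pick(unwired_plain_bins(chrom))
            if b is None:
                continue
            pos0, ref, alt = motif_insertion(chrom, b)
        elif kind == 2:
            pos0, ref, alt = neutral_substitution(chrom)
        else:
            pos0, ref, alt = neutral_deletion(chrom)
        eqtl.append(Variant(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                            label="none", slope=0.0,
                            tss=random_center(chrom)))
        made += 1

    clinvar: list[Variant] = []
    made = 0
    while made < n_pathogenic:
        chrom = chroms[int(rng.integers(len(chroms)))]
        b = pick(sorted(world.ledger["genome"][chrom]["motif_instances"]))
        if b is None:
            continue
        if made % 2 == 0:
            pos0, ref, alt = copy_deletion(chrom, b)
        else:
            pos0, ref, alt = cluster_substitution(chrom, b)
        clinvar.append(Variant(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                               label="pathogenic"))
        ledger["clinvar"].append({"chrom": chrom, "pos0": pos0,
                                  "label": "pathogenic"})
        made += 1
    for k in range(n_pathogenic):
        chrom = chroms[int(rng.integers(len(chroms)))]
        if k % 2 == 0:
            pos0, ref, alt = neutral_deletion(chrom)
        else:
            pos0, ref, alt = neutral_substitution(chrom)
        clinvar.append(Variant(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                               label="benign"))
        ledger["clinvar"].append({"chrom": chrom, "pos0": pos0,
                                  "label": "benign"})
    return eqtl, clinvar, ledger


# ---------------------------------------------------------------------------
# whole world
# ---------------------------------------------------------------------------

def build_world(config: WorldConfig | None = None, seed: int = 0
                ) -> SyntheticWorld:
    """Generate genome, accessibility, contact maps and center peaks."""
    cfg = config or WorldConfig()
    root = np.random.SeedSequence(seed)
    genome: dict[str, str] = {}
    track = Track()
    contact_maps: dict[str, ContactMap] = {}
    ledger: dict = {"genome": {}, "hic": {}, "centers": {}, "seed": seed}
    n_motif = int(round(cfg.motif_bin_fraction * cfg.n_bins))
    n_near = int(round(cfg.near_motif_bin_fraction * cfg.n_bins))
    for chrom, ss in zip(cfg.chroms, root.spawn(len(cfg.chroms))):
        s_gen, s_hic, s_centers = ss.generate_state(3) >> np.uint32(1)
        rng = np.random.default_rng(int(s_centers))
        special = rng.choice(cfg.n_bins, size=n_motif + n_near, replace=False)
        motif_bins = sorted(int(b) for b in special[:n_motif])
        near_bins = sorted(int(b) for b in special[n_motif:])
        seq, chrom_track, gled = generate_genome_and_tracks(
            chrom, cfg.n_bins, cfg.motif, motif_bins,
            cfg.accessibility_noise, int(s_gen), cfg.resolution, near_bins,
            cfg.accessibility_baseline, cfg.accessibility_bump,
            cfg.near_mismatches, cfg.motif_copies_range,
            cfg.near_copies_range)
        genome[chrom] = seq
        for s, e, v in chrom_track._ivals[chrom]:
            track.add(chrom, s, e, v)
        gled["motif_bins"] = motif_bins
        gled["near_motif_bins"] = near_bins
        ledger["genome"][chrom] = gled

        # planted specific pairs link non-motif "anchor" hubs to nearby
        # motif-bearing bins (enhancer-promoter style): each hub contacts
        # several partners, so anchors get neighbor-dependent labels and
        # multi-neighbor stars downstream
        lo, hi = cfg.planted_sep_range
        motif_set = set(motif_bins)
        non_motif = [b for b in range(cfg.n_bins) if b not in motif_set]
        anchors = sorted(int(non_motif[i]) for i in
                         rng.choice(len(non_motif), size=cfg.n_anchors,
                                    replace=False))
        planted = []
        used = set()
        for a in anchors:
            elig_m = [m for m in motif_bins if lo <= abs(m - a) <= hi]
            elig_n = [m for m in non_motif
                      if lo <= abs(m - a) <= hi and m not in anchors]
            k = 1 + rng.poisson(max(cfg.partners_per_anchor_mean - 1, 0))
            for _ in range(k):
                take_motif = rng.random() < cfg.partner_motif_prob
                pool = elig_m if (take_motif and elig_m) else elig_n
                if not pool:
                    continue
                m = pool[int(rng.integers(len(pool)))]
                pair = (min(a, m), max(a, m))
                if pair not in used:
                    used.add(pair)
                    planted.append(pair)
        window = GenomicLocus(chrom, 0, cfg.window_bp)
        cmap, hled = generate_hic(cfg.n_bins, cfg.depth, cfg.decay_exponent,
                                  planted, cfg.enrichment, int(s_hic), window,
                                  cfg.resolution)
        contact_maps[chrom] = cmap
        ledger["hic"][chrom] = hled

        # centers: every planted anchor plus fill biased toward open bins
        # (peaks arise at accessible loci), so exact-vs-degenerate motif
        # status is directly supervised
        center_bins = set(anchors)
        n_fill = max(0, cfg.centers_per_chrom - len(center_bins))
        open_pool = [b for b in sorted(motif_set | set(near_bins))
                     if b not in center_bins]
        other_pool = [b for b in range(cfg.n_bins)
                      if b not in center_bins and b not in motif_set
                      and b not in set(near_bins)]
        n_open = min(int(round(0.7 * n_fill)), len(open_pool))
        pick_open = rng.choice(len(open_pool), size=n_open, replace=False)
        pick_other = rng.choice(len(other_pool), size=n_fill - n_open,
                                replace=False)
        center_bins |= {open_pool[int(i)] for i in pick_open}
        center_bins |= {other_pool[int(i)] for i in pick_other}
        center_bins = sorted(center_bins)
        ledger["centers"][chrom] = center_bins
        ledger["hic"][chrom]["anchor_bins"] = sorted(set(anchors))
    peaks = []
    for chrom in cfg.chroms:
        for b in ledger["centers"][chrom]:
            start = b * cfg.resolution + 2000   # peak centered in its bin
            peaks.append(Peak(GenomicLocus(chrom, start, start + 1000),
                              assay_id="synthetic", cell_context="world"))
    return SyntheticWorld(config=cfg, genome=genome, track=track,
                          contact_maps=contact_maps, peaks=peaks,
                          ledger=ledger)
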