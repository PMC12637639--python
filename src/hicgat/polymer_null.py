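"""Self-avoiding polymer null model for Hi-C contact specificity.

A confined self-avoiding chain (one bead per 5 kb locus, unit bond length)
is grown off-lattice: each bead is placed at unit distance from its
predecessor in a uniformly random direction and rejected if it enters the
excluded volume of an earlier bead or leaves the confinement sphere.  An
ensemble of such chains yields the null contact probability p0(s) per
genomic separation s = |i - j|, pooled over positions by the translation
symmetry of a homopolymer.

Observed counts are then tested pair-by-pair: total depth N is allocated to
pairs proportionally to the null probabilities (a multinomial null), and
each pair's count gets a one-sided binomial upper-tail p-value, corrected by
Benjamini-Hochberg over all pairs of the modeled window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .io_formats import ContactMap, GenomicLocus

__all__ = [
    "PolymerChain",
    "EnsembleNull",
    "NonRandomContactSet",
    "ContactTests",
    "SimulationError",
    "simulate_saw_chain",
    "build_ensemble_null",
    "test_contacts",
    "fdr_filter",
    "default_confinement_radius",
]

DEFAULT_EXCLUDED_DIAMETER = 0.8   # bond-length units
DEFAULT_CONTACT_THRESHOLD = 1.5   # bond-length units
DEFAULT_VOLUME_FRACTION = 0.10    # bead volume / confinement volume
DEFAULT_FDR = 0.05


class SimulationError(RuntimeError):
    pass


@dataclass
class PolymerChain:
    """Ordered 3-D bead positions of one self-avoiding conformation."""

    coords: np.ndarray  # (n_beads, 3)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def validate(self, excluded_diameter: float, confinement_radius: float,
                 tol: float = 1e-9):
        c = self.coords
        if c.shape[0] > 1:
            bonds = np.linalg.norm(np.diff(c, axis=0), axis=1)
            if np.any(np.abs(bonds - 1.0) > tol):
                raise ValueError("bond length violated")
            d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
            mask = ~np.eye(len(c), dtype=bool) & (
                np.abs(np.subtract.outer(np.arange(len(c)), np.arange(len(c)))) > 1
            )
            if mask.any() and d[mask].min() < excluded_diameter - tol:
                raise ValueError("excluded volume violated")
        if np.any(np.linalg.norm(c, axis=1) > confinement_radius + tol):
            raise ValueError("bead outside confinement sphere")


def default_confinement_radius(n_beads: int,
                               excluded_diameter: float = DEFAULT_EXCLUDED_DIAMETER,
                               volume_fraction: float = DEFAULT_VOLUME_FRACTION
                               ) -> float:
    """Sphere radius putting the beads at the requested volume fraction."""
    return (excluded_diameter / 2.0) * (n_beads / volume_fraction) ** (1.0 / 3.0)


@njit(cache=True)
def _grow_chain(n_beads, excl2, radius, seed, tries_per_bead, backtrack,
                restart_budget):  # pragma: no cover - numba
    np.random.seed(seed)
    coords = np.empty((n_beads, 3))
    r2 = radius * radius
    # first bead uniform in the sphere
    while True:
        x = radius * (2.0 * np.random.random() - 1.0)
        y = radius * (2.0 * np.random.random() - 1.0)
        z = radius * (2.0 * np.random.random() - 1.0)
        if x * x + y * y + z * z <= r2:
            coords[0, 0], coords[0, 1], coords[0, 2] = x, y, z
            break
    k = 1
    failures = 0
    while k < n_beads:
        placed = False
        for _ in range(tries_per_bead):
            # uniform direction via normalized gaussian
            dx = np.random.normal()
            dy = np.random.normal()
            dz = np.random.normal()
            nrm = np.sqrt(dx * dx + dy * dy + dz * dz)
            if nrm == 0.0:
                continue
            cx = coords[k - 1, 0] + dx / nrm
            cy = coords[k - 1, 1] + dy / nrm
            cz = coords[k - 1, 2] + dz / nrm
            if cx * cx + cy * cy + cz * cz > r2:
                continue
            ok = True
            for m in range(k - 1):  # predecessor sits at distance exactly 1
                ddx = cx - coords[m, 0]
                ddy = cy - coords[m, 1]
                ddz = cz - coords[m, 2]
                if ddx * ddx + ddy * ddy + ddz * ddz < excl2:
                    ok = False
                    break
            if ok:
                coords[k, 0], coords[k, 1], coords[k, 2] = cx, cy, cz
                placed = True
                break
        if placed:
            k += 1
        else:
            failures += 1
            if failures > restart_budget:
                return coords, False
            k = max(1, k - backtrack)  # unwind and regrow
    return coords, True


@njit(cache=True)
def _count_contacts_by_separation(coords, thr2, cnt, tot):  # pragma: no cover
    n = coords.shape[0]
    for i in range(n - 1):
        for j in range(i + 1, n):
            s = j - i
            tot[s] += 1
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            if dx * dx + dy * dy + dz * dz <= thr2:
                cnt[s] += 1


def simulate_saw_chain(n_beads: int,
                       excluded_diameter: float = DEFAULT_EXCLUDED_DIAMETER,
                       confinement_radius: float | None = None,
                       seed: int = 0) -> PolymerChain:
    """Grow one confined self-avoiding chain; identical seed, identical chain."""
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if not (0 < excluded_diameter < 1):
        raise ValueError("excluded_diameter must lie in (0, 1) bond lengths")
    if confinement_radius is None:
        confinement_radius = default_confinement_radius(n_beads, excluded_diameter)
    coords, ok = _grow_chain(n_beads, excluded_diameter**2, confinement_radius,
                             np.uint32(seed) & np.uint32(0x7FFFFFFF),
                             100, 20, 200 * n_beads)
    if not ok:
        raise SimulationError(
            "chain growth exhausted its dead-end budget; "
            "try a larger confinement radius")
    return PolymerChain(coords=np.asarray(coords))


@dataclass
class EnsembleNull:
    """Separation-pooled null contact probabilities from a chain ensemble."""

    n_chains: int
    n_beads: int
    contact_threshold: float
    excluded_diameter: float
    confinement_radius: float
    p0: np.ndarray  # index = separation s; p0[0] is unused (diagonal)
    seed: int = 0

    def pair_probability_table(self) -> np.ndarray:
        """pi(s) = p0(s) / Z with Z summed over all i<j pairs of the window."""
        n = self.n_beads
        s = np.arange(1, n)
        z = float(np.sum((n - s) * self.p0[1:n]))
        if z <= 0:
            raise ValueError("degenerate null: all p0 are zero")
        pi = np.zeros(n)
        pi[1:] = self.p0[1:n] / z
        return pi

    def to_json(self, path):
        payload = {
            "n_chains": self.n_chains, "n_beads": self.n_beads,
            "contact_threshold": self.contact_threshold,
            "excluded_diameter": self.excluded_diameter,
            "confinement_radius": self.confinement_radius,
            "seed": self.seed, "p0": self.p0.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def from_json(path) -> "EnsembleNull":
        with open(path) as fh:
            d = json.load(fh)
        d["p0"] = np.asarray(d.pop("p0"))
        return EnsembleNull(**d)


def build_ensemble_null(n_chains: int, n_beads: int,
                        contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
                        excluded_diameter: float = DEFAULT_EXCLUDED_DIAMETER,
                        confinement_radius: float | None = None,
                        seed: int = 0,
                        return_chains: bool = False):
    """Simulate an ensemble and pool contacts into p0(s).

    p0(s) = (# in-contact (i, i+s) pairs across all chains) /
            (# (i, i+s) pairs across all chains).
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if confinement_radius is None:
        confinement_radius = default_confinement_radius(n_beads, excluded_diameter)
    chain_seeds = np.random.SeedSequence(seed).generate_state(n_chains)
    cnt = np.zeros(n_beads, dtype=np.int64)
    tot = np.zeros(n_beads, dtype=np.int64)
    chains = []
    thr2 = contact_threshold**2
    for cs in chain_seeds:
        chain = simulate_saw_chain(n_beads, excluded_diameter,
                                   confinement_radius, seed=int(cs))
        _count_contacts_by_separation(chain.coords, thr2, cnt, tot)
        if return_chains:
            chains.append(chain)
    with np.errstate(invalid="ignore"):
        p0 = np.where(tot > 0, cnt / np.maximum(tot, 1), 0.0)
    null = EnsembleNull(n_chains, n_beads, contact_threshold, excluded_diameter,
                        confinement_radius, p0, seed)
    return (null, chains) if return_chains else null


@dataclass
class ContactTests:
    """Per-pair binomial test results over one modeled window."""

    window: GenomicLocus
    resolution: int
    bin_i: np.ndarray     # pairs with nonzero counts, i < j
    bin_j: np.ndarray
    count: np.ndarray
    p_value: np.ndarray
    n_total_pairs: int    # full BH family: all i < j pairs of the window

    def __len__(self):
        return len(self.bin_i)


def test_contacts(cmap: ContactMap, null: EnsembleNull) -> ContactTests:
    """One-sided binomial upper-tail test of each pair against the null.

    Pairs with zero observed count have p-value 1 and are carried implicitly
    (they can never be discovered but they do count in the BH family).
    """
    if cmap.n_bins != null.n_beads:
        raise ValueError("contact map bin count must equal the null chain length")
    n_reads = cmap.total
    if n_reads == 0:
        raise ValueError("empty contact map")
    pi_s = null.pair_probability_table()
    bi, bj, counts = cmap.nonzero_pairs()
    sep = bj - bi
    pi = pi_s[sep]
    pvals = binom.sf(counts - 1, n_reads, pi)
    n = cmap.n_bins
    return ContactTests(cmap.window, cmap.resolution, bi, bj,
                        counts.astype(np.int64), pvals, n * (n - 1) // 2)


def fdr_filter(tests: ContactTests, q: float = DEFAULT_FDR) -> "NonRandomContactSet":
    """Benjamini-Hochberg over all pairs of the window; keep q-value <= q."""
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    if len(tests) == 0:
        return NonRandomContactSet(pairs=[], fdr_level=q,
                                   resolution=tests.resolution)
    n_implicit = tests.n_total_pairs - len(tests)
    full_p = np.concatenate([tests.p_value, np.ones(n_implicit)])
    _, qvals, _, _ = multipletests(full_p, alpha=q, method="fdr_bh")
    qvals = qvals[: len(tests)]
    keep = qvals <= q
    pairs = []
    for i, j, p, qv in zip(tests.bin_i[keep], tests.bin_j[keep],
                           tests.p_value[keep], qvals[keep]):
        a = _bin_locus(tests, int(i))
        b = _bin_locus(tests, int(j))
        pairs.append((a, b, float(p), float(qv)))
    return NonRandomContactSet(pairs=pairs, fdr_level=q,
                               resolution=tests.resolution)


def _bin_locus(tests: ContactTests, i: int) -> GenomicLocus:
    start = tests.window.start + i * tests.resolution
    return GenomicLocus(tests.window.chrom, start,
                        min(start + tests.resolution, tests.window.end))


@dataclass
class NonRandomContactSet:
    """Locus pairs surviving the polymer-null FDR test."""

    pairs: list[tuple[GenomicLocus, GenomicLocus, float, float]]
    fdr_level: float = DEFAULT_FDR
    resolution: int = 5000
    _adj: dict = field(default=None, repr=False, compare=False)  # type: ignore

    def __post_init__(self):
        norm = []
        for a, b, p, q in self.pairs:
            if (b.chrom, b.start) < (a.chrom, a.start):
                a, b = b, a
            if a == b:
                raise ValueError("self-pair in contact set")
            norm.append((a, b, p, q))
        self.pairs = norm
        self._adj = None

    def __len__(self):
        return len(self.pairs)

    def pair_keys(self) -> set[tuple[str, str]]:
        return {(a.key(), b.key()) for a, b, _, _ in self.pairs}

    def neighbors_of(self, locus: GenomicLocus) -> list[GenomicLocus]:
        if self._adj is None:
            adj: dict[GenomicLocus, list[GenomicLocus]] = {}
            for a, b, _, _ in self.pairs:
                adj.setdefault(a, []).append(b)
                adj.setdefault(b, []).append(a)
            self._adj = adj
        return sorted(self._adj.get(locus, []), key=lambda x: (x.chrom, x.start))
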