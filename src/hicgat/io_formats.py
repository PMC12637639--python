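"""On-disk formats and the core coordinate types.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package; any other dialect is converted at the reader boundary.  Contact
matrices are stored upper-triangular (i < j) and diagonal entries are dropped
on ingestion — a self-contact carries no edge semantics downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)

RESOLUTION = 5000  # bp per grid locus
PEAK_WIDTH = 1000  # bp

__all__ = [
    "GenomicLocus",
    "ContactMap",
    "Peak",
    "Track",
    "read_contact_triplets",
    "read_peaks_bed",
    "write_nonrandom_bedpe",
    "read_nonrandom_bedpe",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_embeddings_tsv",
]


@dataclass(frozen=True, order=True)
class GenomicLocus:
    """Half-open genomic interval; grid-aligned loci are 5 kb and phase 0."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def is_grid_aligned(self, resolution: int = RESOLUTION) -> bool:
        return self.start % resolution == 0 and self.width == resolution

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @staticmethod
    def from_key(key: str) -> "GenomicLocus":
        chrom, span = key.rsplit(":", 1)
        start, end = span.split("-")
        return GenomicLocus(chrom, int(start), int(end))


@dataclass
class ContactMap:
    """Symmetric contact counts over one modeled window, stored upper-triangular."""

    window: GenomicLocus
    resolution: int = RESOLUTION
    counts: sp.csr_matrix = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        n = self.n_bins
        if self.counts is None:
            self.counts = sp.csr_matrix((n, n), dtype=np.int64)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match window/resolution")

    @property
    def n_bins(self) -> int:
        return -(-self.window.width // self.resolution)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        return int(self.counts[i, j])

    def nonzero_pairs(self):
        """(i, j, count) arrays over stored entries, i < j."""
        coo = self.counts.tocoo()
        return coo.row, coo.col, coo.data

    def bin_locus(self, i: int) -> GenomicLocus:
        start = self.window.start + i * self.resolution
        end = min(start + self.resolution, self.window.end)
        return GenomicLocus(self.window.chrom, start, end)

    @staticmethod
    def from_triplets(window: GenomicLocus, bin_i, bin_j, count,
                      resolution: int = RESOLUTION) -> "ContactMap":
        bin_i = np.asarray(bin_i, dtype=np.int64)
        bin_j = np.asarray(bin_j, dtype=np.int64)
        count = np.asarray(count, dtype=np.int64)
        if np.any(count < 0):
            raise ValueError("negative contact count")
        n = -(-window.width // resolution)
        if bin_i.size and (bin_i.min() < 0 or bin_j.min() < 0
                           or bin_i.max() >= n or bin_j.max() >= n):
            raise ValueError("bin index outside the modeled window")
        lo = np.minimum(bin_i, bin_j)
        hi = np.maximum(bin_i, bin_j)
        keep = lo != hi
        if keep.sum() < lo.size:
            log.debug("dropping %d diagonal contact entries", lo.size - keep.sum())
        mat = sp.coo_matrix((count[keep], (lo[keep], hi[keep])), shape=(n, n))
        return ContactMap(window, resolution, mat.tocsr())


@dataclass(frozen=True)
class Peak:
    """A 1 kb signal peak with its assay and cell-context annotation."""

    locus: GenomicLocus
    assay_id: str = ""
    cell_context: str = ""

    def __post_init__(self):
        if self.locus.width != PEAK_WIDTH:
            raise ValueError(f"peak width must be {PEAK_WIDTH} bp")


class Track:
    """Piecewise-constant nonnegative signal (accessibility); gaps read as 0."""

    def __init__(self):
        self._ivals: dict[str, list[tuple[int, int, float]]] = {}

    def add(self, chrom: str, start: int, end: int, value: float):
        if value < 0:
            raise ValueError("track values must be nonnegative")
        self._ivals.setdefault(chrom, []).append((start, end, float(value)))

    def chroms(self):
        return list(self._ivals)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Base-resolution signal over [start, end); uncovered bases are 0."""
        out = np.zeros(end - start, dtype=np.float64)
        for s, e, v in self._ivals.get(chrom, ()):
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out[lo - start : hi - start] = v
        return out

    @staticmethod
    def average(tracks: list["Track"], chrom: str, start: int, end: int) -> np.ndarray:
        return np.mean([t.values(chrom, start, end) for t in tracks], axis=0)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_contact_triplets(path, window: GenomicLocus,
                          resolution: int = RESOLUTION) -> ContactMap:
    """Read a ``bin_i\\tbin_j\\tcount`` TSV; (i,j)/(j,i) duplicates are summed."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["bin_i", "bin_j", "count"])
    except pd.errors.EmptyDataError:
        return ContactMap.from_triplets(window, [], [], [], resolution)
    if df.empty:
        return ContactMap.from_triplets(window, [], [], [], resolution)
    if not np.issubdtype(np.asarray(df.bin_i).dtype, np.number):  # header row
        df = df.iloc[1:].astype({"bin_i": int, "bin_j": int, "count": int})
    return ContactMap.from_triplets(window, df.bin_i, df.bin_j, df["count"],
                                    resolution)


def read_peaks_bed(path) -> list[Peak]:
    """BED3+ peak reader; off-width rows are recentered to 1 kb (logged)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED row at line {lineno}") from exc
            assay = fields[3] if len(fields) > 3 else ""
            cell = fields[4] if len(fields) > 4 else ""
            if end - start != PEAK_WIDTH:
                mid = (start + end) // 2
                start, end = mid - PEAK_WIDTH // 2, mid + PEAK_WIDTH // 2
                log.info("line %d: recentered %d bp peak to %s:%d-%d",
                         lineno, int(fields[2]) - int(fields[1]), chrom, start, end)
            peaks.append(Peak(GenomicLocus(chrom, start, end), assay, cell))
    return peaks


_BEDPE_HEADER = "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tp_value\tq_value"


def write_nonrandom_bedpe(contact_set, path):
    """Write a NonRandomContactSet as sorted BEDPE with p/q columns."""
    rows = sorted(
        (a.chrom, a.start, a.end, b.chrom, b.start, b.end, p, q)
        for a, b, p, q in contact_set.pairs
    )
    with open(path, "w") as fh:
        fh.write(_BEDPE_HEADER + f"\t{contact_set.fdr_level}\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r[:6]) + f"\t{r[6]:.8g}\t{r[7]:.8g}\n")


def read_nonrandom_bedpe(path):
    from .polymer_null import NonRandomContactSet

    pairs = []
    fdr_level = 0.05
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                tail = line.rstrip("\n").split("\t")[-1]
                try:
                    fdr_level = float(tail)
                except ValueError:
                    pass
                continue
            c1, s1, e1, c2, s2, e2, p, q = line.rstrip("\n").split("\t")
            pairs.append((GenomicLocus(c1, int(s1), int(e1)),
                          GenomicLocus(c2, int(s2), int(e2)), float(p), float(q)))
    return NonRandomContactSet(pairs=pairs, fdr_level=fdr_level)


def read_bedgraph(path) -> Track:
    track = Track()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()
            track.add(chrom, int(start), int(end), float(value))
    return track


def write_bedgraph(track: Track, path):
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for s, e, v in track._ivals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_fasta(path) -> dict[str, str]:
    """Load a (small) FASTA into chrom -> uppercase sequence strings."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(seqs: dict[str, str], path, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_embeddings_tsv(path) -> dict[str, np.ndarray]:
    """Locus-keyed dense vectors: first column ``chrom:start-end``, then floats."""
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = np.asarray(parts[1:], dtype=np.float64)
    return out
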