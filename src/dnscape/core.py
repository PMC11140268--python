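"""Shared genomic primitives.

Coordinates are 0-based, half-open everywhere inside the package; BED is the
native on-disk convention and GFF3 (1-based, closed) is converted on read and
write.  Intervals are ``(start, end)`` with ``start < end``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GENOTYPES = ("A2", "D5", "F1", "AD1")
DIGESTIONS = ("light", "heavy")

#: genotype -> subgenome labels it carries (diploids expose a single subgenome)
GENOTYPE_SUBGENOMES = {
    "A2": ("A",),
    "D5": ("D",),
    "F1": ("A", "D"),
    "AD1": ("A", "D"),
}


class PlacementError(ValueError):
    """Raised when intervals cannot be placed in the available space."""


@dataclass(frozen=True)
class GeneModel:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    #: exon intervals (0-based half-open); empty tuple means a single-exon gene
    exons: tuple = ()

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class TEInterval:
    chrom: str
    start: int
    end: int
    superfamily: str
    family: str


@dataclass
class Genome:
    label: str
    chroms: dict  # chrom name -> length (bp)
    sequence: dict | None = None  # chrom name -> str, optional

    @property
    def total_length(self) -> int:
        return int(sum(self.chroms.values()))


@dataclass(frozen=True)
class SampleSpec:
    """One sequencing library of the factorial design.

    ``genotype`` is one of A2/D5/F1/AD1, ``subgenome`` "A" or "D" (for the
    diploids it matches their own genome), ``digestion`` light or heavy.
    """

    genotype: str
    subgenome: str
    digestion: str
    replicate: int
    n_fragments: int

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.subgenome not in GENOTYPE_SUBGENOMES[self.genotype]:
            raise ValueError(
                f"genotype {self.genotype} has no subgenome {self.subgenome!r}"
            )
        if self.digestion not in DIGESTIONS:
            raise ValueError(f"digestion must be light or heavy, got {self.digestion!r}")

    @property
    def track_key(self) -> str:
        """Analysis track this library contributes to, e.g. ``F1:At``."""
        if self.genotype in ("A2", "D5"):
            return self.genotype
        return f"{self.genotype}:{self.subgenome}t"

    @property
    def genome_label(self) -> str:
        return self.subgenome


def track_genome(track_key: str) -> str:
    """Genome ("A" or "D") a track key lives on."""
    if track_key == "A2":
        return "A"
    if track_key == "D5":
        return "D"
    genotype, sub = track_key.split(":")
    return sub[0]


def derive_seed(seed: int, *tags) -> int:
    """Stable child seed (< 2**31) from a parent seed and string tags.

    Uses an FNV-style fold over the tag characters so derived seeds are
    reproducible across processes (unlike the builtin ``hash``).
    """
    h = ((int(seed) + 1) * 2654435761) % 2**64
    for t in tags:
        for ch in str(t):
            h = ((h ^ ord(ch)) * 1099511628211) % 2**64
    return h % (2**31 - 1)


# ---------------------------------------------------------------------------
# interval arithmetic


def as_interval_array(intervals) -> np.ndarray:
    arr = np.asarray(intervals, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be an (n, 2) array of (start, end)")
    return arr


def merge_intervals(intervals, max_gap: int = 0) -> np.ndarray:
    """Merge overlapping (or ``max_gap``-separated) intervals into a sorted union."""
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = []
    cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        if s <= cur_e + max_gap:
            cur_e = max(cur_e, int(e))
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64)


def union_length(intervals) -> int:
    merged = merge_intervals(intervals)
    if len(merged) == 0:
        return 0
    return int(np.sum(merged[:, 1] - merged[:, 0]))


def intervals_to_mask(intervals, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in as_interval_array(intervals):
        mask[max(0, s) : min(length, e)] = True
    return mask


def mask_to_intervals(mask: np.ndarray) -> np.ndarray:
    """Maximal runs of True as an (n, 2) interval array."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0 or not m.any():
        return np.empty((0, 2), dtype=np.int64)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    return np.column_stack([starts, ends]).astype(np.int64)
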