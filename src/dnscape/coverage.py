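"""Fragment coverage tracks, quantile normalization and TSS-anchored profiles.

The central container is :class:`SignalTrack`: per-chromosome numeric vectors
at 1 bp resolution (or on a fixed window grid, ``step`` > 1) with a units tag
(``RPM``, ``DNS`` or ``SPO-RPM``).  Fragment sets are per-chromosome
``(n, 2)`` integer arrays of 0-based half-open intervals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UNITS = ("RPM", "DNS", "SPO-RPM")


@dataclass
class FragmentSet:
    """Aligned paired-end fragments of one library (or a replicate pool)."""

    fragments: dict  # chrom -> (n, 2) int64 array
    chrom_lengths: dict  # chrom -> length
    genotype: str = ""
    subgenome: str = ""
    digestion: str = ""
    replicate: int = 0

    def __post_init__(self):
        for chrom, arr in self.fragments.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(f"fragments on unknown chromosome {chrom!r}")
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and not (arr[:, 0] < arr[:, 1]).all():
                raise ValueError("fragment with start >= end")
            self.fragments[chrom] = arr

    @property
    def n_fragments(self) -> int:
        return int(sum(len(a) for a in self.fragments.values()))

    def lengths(self) -> np.ndarray:
        parts = [a[:, 1] - a[:, 0] for a in self.fragments.values()]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    def midpoints(self, chrom: str) -> np.ndarray:
        """Fragment midpoints, floor((start + end) / 2)."""
        arr = self.fragments.get(chrom)
        if arr is None or arr.size == 0:
            return np.empty(0, dtype=np.int64)
        return (arr[:, 0] + arr[:, 1]) // 2


def pool_fragments(fragsets) -> FragmentSet:
    """Concatenate replicate fragment sets before any RPM scaling."""
    fragsets = list(fragsets)
    if not fragsets:
        raise ValueError("no fragment sets to pool")
    first = fragsets[0]
    merged: dict = {}
    for fs in fragsets:
        for chrom, arr in fs.fragments.items():
            merged.setdefault(chrom, []).append(arr)
    pooled = {c: np.concatenate(parts) for c, parts in merged.items()}
    return FragmentSet(
        fragments=pooled,
        chrom_lengths=dict(first.chrom_lengths),
        genotype=first.genotype,
        subgenome=first.subgenome,
        digestion=first.digestion,
        replicate=0,
    )


@dataclass
class SignalTrack:
    """Per-chromosome numeric signal with a units tag and provenance trail."""

    data: dict  # chrom -> float64 vector
    units: str
    step: int = 1  # grid spacing; 1 = base resolution
    provenance: tuple = ()

    def __post_init__(self):
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        self.data = {c: np.asarray(v, dtype=np.float64) for c, v in self.data.items()}

    def flat(self) -> np.ndarray:
        """Genome-wide concatenation in sorted chromosome order."""
        return np.concatenate([self.data[c] for c in sorted(self.data)])

    def with_data(self, data: dict, units=None, note=None) -> "SignalTrack":
        prov = self.provenance + ((note,) if note else ())
        return SignalTrack(data, units or self.units, self.step, prov)

    def chrom_lengths(self) -> dict:
        return {c: len(v) * self.step for c, v in self.data.items()}


def _depth(starts, ends, length) -> np.ndarray:
    d = np.zeros(length + 1, dtype=np.float64)
    np.add.at(d, np.clip(starts, 0, length), 1.0)
    np.add.at(d, np.clip(ends, 0, length), -1.0)
    return np.cumsum(d)[:length]


def fragment_coverage(
    frags: FragmentSet,
    mode: str = "full",
    trim_to: int = 50,
    max_len: int = 260,
) -> SignalTrack:
    """Per-base RPM coverage from a fragment set.

    ``mode="center_trimmed"`` replaces each fragment shorter than ``max_len``
    with the ``trim_to``-bp window centred on its midpoint (fragments of
    ``max_len`` or more are discarded); ``mode="full"`` uses the fragments as
    they are.  Depth is scaled by 1e6 / (number of fragments used) to reads
    per million.
    """
    if mode not in ("full", "center_trimmed"):
        raise ValueError(f"unknown mode {mode!r}")
    if frags.n_fragments == 0:
        raise ValueError("empty fragment set: RPM scaling undefined")
    data = {}
    total = 0
    half = trim_to // 2
    pieces = {}
    for chrom, length in frags.chrom_lengths.items():
        arr = frags.fragments.get(chrom)
        if arr is None or arr.size == 0:
            pieces[chrom] = (np.empty(0, np.int64), np.empty(0, np.int64))
            continue
        if mode == "center_trimmed":
            keep = (arr[:, 1] - arr[:, 0]) < max_len
            arr = arr[keep]
            mid = (arr[:, 0] + arr[:, 1]) // 2
            starts, ends = mid - half, mid - half + trim_to
        else:
            starts, ends = arr[:, 0], arr[:, 1]
        pieces[chrom] = (starts, ends)
        total += len(starts)
    if total == 0:
        raise ValueError("no fragments retained after length filtering")
    scale = 1e6 / total
    for chrom, length in frags.chrom_lengths.items():
        starts, ends = pieces[chrom]
        data[chrom] = _depth(starts, ends, length) * scale
    return SignalTrack(data, "RPM", provenance=(f"coverage:{mode}",))


# ---------------------------------------------------------------------------
# quantile normalization


def _reference_quantiles(sorted_vals: list, n_out: int) -> np.ndarray:
    """Rank-wise mean of sorted inputs, interpolated to ``n_out`` ranks."""
    q_out = np.linspace(0.0, 1.0, n_out)
    acc = np.zeros(n_out)
    for sv in sorted_vals:
        if len(sv) == n_out:
            acc += sv
        else:
            acc += np.interp(q_out, np.linspace(0.0, 1.0, len(sv)), sv)
    return acc / len(sorted_vals)


def quantile_normalize(tracks, ties: str = "average") -> list:
    """Quantile-normalize signal tracks to a common value distribution.

    Each output track carries the rank-wise mean distribution of the inputs
    (linear rank interpolation when genome lengths differ) and rank order
    within every track is preserved.

    ``ties="average"`` gives tied input values the mean of the target values
    over their rank span (order-independent, but sorted outputs of different
    tracks then agree only up to tie structure); ``ties="rank"`` assigns
    reference values by stable rank so every output track has the *identical*
    sorted value multiset, at the price of tied inputs mapping to a spread of
    outputs.  Cross-genome DNS normalization uses ``"rank"``.
    """
    import warnings

    if ties not in ("average", "rank"):
        raise ValueError(f"unknown tie rule {ties!r}")
    tracks = list(tracks)
    if len(tracks) < 2:
        warnings.warn("quantile_normalize with fewer than 2 tracks is an identity")
        return tracks
    flats = [t.flat() for t in tracks]
    sorted_vals = [np.sort(f) for f in flats]
    outs = []
    for t, flat, sv in zip(tracks, flats, sorted_vals):
        ref = _reference_quantiles(sorted_vals, len(flat))
        order = np.argsort(flat, kind="stable")
        out_flat = np.empty(len(flat))
        out_flat[order] = ref
        if ties == "average":
            uniq, inv = np.unique(flat, return_inverse=True)
            sums = np.bincount(inv, weights=out_flat)
            counts = np.bincount(inv)
            out_flat = (sums / counts)[inv]
        data = {}
        off = 0
        for chrom in sorted(t.data):
            n = len(t.data[chrom])
            data[chrom] = out_flat[off : off + n]
            off += n
        outs.append(t.with_data(data, note=f"quantile_normalized:{ties}"))
    return outs


# ---------------------------------------------------------------------------
# aggregate profiles


@dataclass
class ProfileMatrix:
    """Group-wise mean signal around anchors with 95% confidence half-widths."""

    offsets: np.ndarray  # (2*flank + 1,)
    groups: list
    mean: np.ndarray  # (n_groups, n_offsets)
    ci_half: np.ndarray
    n_anchors: dict
    n_dropped: int = 0


def aggregate_profile(track: SignalTrack, anchors, flank: int = 1500, groups=None) -> ProfileMatrix:
    """Mean signal in ``[-flank, +flank]`` around anchors, strand-oriented.

    Minus-strand anchors are flipped so positive offsets always point
    downstream of the anchor (e.g. into the gene body for a TSS).
    """
    if track.step != 1:
        raise ValueError("aggregate_profile requires a base-resolution track")
    anchors = list(anchors)
    if not anchors:
        raise ValueError("empty anchor list")
    if groups is None:
        groups = ["all"] * len(anchors)
    rows, labels = [], []
    dropped = 0
    width = 2 * flank + 1
    for (chrom, pos, strand), lab in zip(anchors, groups):
        v = track.data.get(chrom)
        if v is None or pos - flank < 0 or pos + flank + 1 > len(v):
            dropped += 1
            continue
        win = v[pos - flank : pos + flank + 1]
        rows.append(win[::-1] if strand == "-" else win)
        labels.append(lab)
    if not rows:
        raise ValueError("all anchors dropped (out of bounds)")
    mat = np.vstack(rows)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    mean = np.zeros((len(uniq), width))
    ci = np.zeros((len(uniq), width))
    n_anchors = {}
    for i, g in enumerate(uniq):
        sub = mat[labels == g]
        n_anchors[g] = len(sub)
        mean[i] = sub.mean(axis=0)
        if len(sub) > 1:
            ci[i] = 1.96 * sub.std(axis=0, ddof=1) / np.sqrt(len(sub))
    return ProfileMatrix(
        offsets=np.arange(-flank, flank + 1),
        groups=uniq,
        mean=mean,
        ci_half=ci,
        n_anchors=n_anchors,
        n_dropped=dropped,
    )
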