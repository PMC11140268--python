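"""Differential nuclease sensitivity (DNS), subnucleosomal particle occupancy
(SPO) and segmentation into accessible chromatin regions (ACRs).

DNS = light - heavy RPM coverage per base; positive signal is MNase
sensitive (open chromatin), negative is resistant.  SPO is the smoothed,
RPM-normalized density of midpoints of small (<= 130 bp) fragments from the
light digestion on a 21 bp / 5 bp sliding-window grid.

Segmentation is a deliberately simple stand-in for an external genomic
segmentation algorithm: tracks are robustly standardized (centered on the
median of their nonzero values and scaled by 1.4826 x the median absolute
deviation), smoothed with a 21 bp running mean, and maximal runs with
|z| >= BC (the "biological cutoff", in robust SD units) become segments.
Nearby runs are gap-merged and short runs dropped.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import FragmentSet, SignalTrack, quantile_normalize
from .core import mask_to_intervals


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    mean_score: float
    peak_score: float  # max |z| within the segment
    polarity: str  # "sensitive" | "resistant"


@dataclass(frozen=True)
class ACR:
    chrom: str
    start: int
    end: int
    mean_score: float
    peak_score: float
    source: str  # "MSF" | "SPO" | "combined"

    @property
    def width(self) -> int:
        return self.end - self.start


def dns_track(light: SignalTrack, heavy: SignalTrack, quantile_norm_group=None) -> SignalTrack:
    """DNS score track: light minus heavy RPM coverage, per base.

    If ``quantile_norm_group`` (other genomes' DNS tracks) is supplied, this
    track is quantile-normalized together with the group before return, so
    DNS scores are comparable across (sub)genomes.
    """
    for t, name in ((light, "light"), (heavy, "heavy")):
        if t.units != "RPM":
            raise ValueError(f"{name} track has units {t.units!r}, expected RPM")
    if set(light.data) != set(heavy.data):
        raise ValueError("light and heavy tracks cover different chromosomes")
    data = {c: light.data[c] - heavy.data[c] for c in light.data}
    dns = SignalTrack(data, "DNS", provenance=("dns:light-heavy",))
    if quantile_norm_group:
        dns = quantile_normalize([dns] + list(quantile_norm_group), ties="rank")[0]
    return dns


def normalize_dns_group(tracks) -> list:
    """Quantile-normalize DNS tracks across (sub)genomes (the pipeline path).

    SPO tracks are never passed through this: cross-genome quantile
    normalization of SPO would discard most of its sparse signal, so SPO is
    segmented per genome instead.
    """
    for t in tracks:
        if t.units != "DNS":
            raise ValueError("normalize_dns_group only accepts DNS tracks")
    return quantile_normalize(tracks, ties="rank")


def spo_track(frags: FragmentSet, max_small: int = 130, window: int = 21, step: int = 5) -> SignalTrack:
    """Subnucleosomal particle occupancy on a sliding-window grid.

    Fragments of length <= ``max_small`` contribute their midpoint; each
    window of ``window`` bp placed every ``step`` bp accumulates the midpoint
    count, scaled by 1e6 / (total small-fragment count).
    """
    if frags.digestion and frags.digestion != "light":
        raise ValueError("SPO is defined on light-digest fragments")
    total_small = 0
    mids_by_chrom = {}
    for chrom in frags.chrom_lengths:
        arr = frags.fragments.get(chrom)
        if arr is None or arr.size == 0:
            mids_by_chrom[chrom] = np.empty(0, dtype=np.int64)
            continue
        small = arr[(arr[:, 1] - arr[:, 0]) <= max_small]
        mids_by_chrom[chrom] = (small[:, 0] + small[:, 1]) // 2
        total_small += len(small)
    if total_small == 0:
        raise ValueError(f"no fragments of length <= {max_small} bp in this set")
    scale = 1e6 / total_small
    data = {}
    for chrom, L in frags.chrom_lengths.items():
        n_windows = (L + step - 1) // step
        c = np.bincount(mids_by_chrom[chrom], minlength=L + window)
        csum = np.r_[0, np.cumsum(c)]
        starts = np.arange(n_windows) * step
        ends = np.minimum(starts + window, L)
        data[chrom] = (csum[ends] - csum[starts]) * scale
    return SignalTrack(data, "SPO-RPM", step=step, provenance=(f"spo:w{window}s{step}",))


def spo_to_base(track: SignalTrack, window: int = 21) -> SignalTrack:
    """Expand an SPO grid track to base resolution (nearest window center)."""
    if track.step == 1:
        return track
    step = track.step
    data = {}
    for chrom, v in track.data.items():
        L = len(v) * step
        centers = np.arange(len(v)) * step + window // 2
        idx = np.clip(
            np.searchsorted(centers, np.arange(L) - step // 2), 0, len(v) - 1
        )
        data[chrom] = v[idx]
    return SignalTrack(data, track.units, step=1, provenance=track.provenance + ("spo_to_base",))


def robust_scale(values: np.ndarray) -> tuple:
    """(center, scale): median and 1.4826 x MAD of the nonzero values.

    The SD of the nonzero values stands in when the MAD collapses to 0 (a
    discrete track dominated by a single nonzero value); a truly constant
    track is an error.
    """
    nz = values[values != 0]
    if nz.size == 0:
        raise ValueError("track is all zero: no background scale")
    center = float(np.median(nz))
    mad = np.median(np.abs(nz - center))
    scale = 1.4826 * mad
    if scale == 0:
        scale = float(np.std(nz))
    if scale == 0:
        raise ValueError("constant track: segmentation scale undefined")
    return center, float(scale)


def segment_track(
    track: SignalTrack,
    bc: float = 6.0,
    min_len: int = 10,
    max_gap: int = 10,
    two_sided: bool = True,
    smooth_window: int = 21,
) -> list:
    """Threshold a standardized track into sensitive/resistant segments."""
    flat = track.flat()
    if not np.isfinite(flat).all():
        raise ValueError("track contains non-finite values")
    center, scale = robust_scale(flat)
    kernel = np.ones(smooth_window) / smooth_window
    segments = []
    for chrom in sorted(track.data):
        z = np.convolve((track.data[chrom] - center) / scale, kernel, mode="same")
        for polarity, mask in (
            ("sensitive", z >= bc),
            ("resistant", (z <= -bc) if two_sided else np.zeros_like(z, bool)),
        ):
            runs = mask_to_intervals(mask)
            if len(runs) == 0:
                continue
            # merge runs separated by <= max_gap, then drop short ones
            merged = []
            cur_s, cur_e = runs[0]
            for s, e in runs[1:]:
                if s - cur_e <= max_gap:
                    cur_e = e
                else:
                    merged.append((cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((cur_s, cur_e))
            for s, e in merged:
                if e - s < min_len:
                    continue
                zseg = z[s:e]
                segments.append(
                    Segment(
                        chrom,
                        int(s * track.step),
                        int(e * track.step),
                        float(zseg.mean()),
                        float(np.max(np.abs(zseg))),
                        polarity,
                    )
                )
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def combine_acrs(msf, spo) -> list:
    """Merge MSF and SPO sensitive segments into the final ACR set."""
    for seg in list(msf) + list(spo):
        if seg.polarity != "sensitive":
            raise ValueError("combine_acrs only accepts sensitive-polarity segments")
    tagged = [(s.chrom, s.start, s.end, s.mean_score, s.peak_score, "MSF") for s in msf]
    tagged += [(s.chrom, s.start, s.end, s.mean_score, s.peak_score, "SPO") for s in spo]
    tagged.sort(key=lambda t: (t[0], t[1]))
    acrs = []
    cur = None
    for chrom, s, e, mean, peak, src in tagged:
        if cur is not None and chrom == cur[0] and s <= cur[2]:
            cur = (
                chrom,
                cur[1],
                max(cur[2], e),
                max(cur[3], mean),
                max(cur[4], peak),
                cur[5] | {src},
            )
        else:
            if cur is not None:
                acrs.append(_finish_acr(cur))
            cur = (chrom, s, e, mean, peak, {src})
    if cur is not None:
        acrs.append(_finish_acr(cur))
    return acrs


def _finish_acr(cur):
    chrom, s, e, mean, peak, sources = cur
    source = sources.pop() if len(sources) == 1 else "combined"
    return ACR(chrom, s, e, mean, peak, source)
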