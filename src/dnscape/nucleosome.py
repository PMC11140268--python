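"""Nucleosome peak calling, classification, coverage and repeat length.

Peak calling works on a center-trimmed heavy-digest RPM track: the coverage
is low-pass filtered by keeping the lowest fraction of Fourier components
(``pc_keep``), candidate 147 bp peaks are placed at filtered local maxima
above a background percentile, and candidates overlapping by at least
``min_overlap`` bp are merged.  Each call gets

* ``height_score`` — empirical-CDF rank of the summit's filtered value among
  all nonzero filtered values genome-wide, and
* ``width_score`` — a sharpness score ``1 - fwhm / 147`` where ``fwhm`` is the
  number of positions within summit +- 73 bp at or above half the summit on
  the lightly smoothed raw coverage (11 bp running mean); the heavy low-pass
  filter is kept for peak *detection* but would blur the width of sharp and
  fuzzy peaks alike, so peak *shape* is read from the raw profile.

Calls wider than 150 bp are "overlapping" (more than two merged dyads);
among the rest, well-positioned (W) calls have height_score > 0.6 and
width_score > 0.4, everything else is fuzzy (F).  The scores are explicit,
testable surrogates for nucleR-style peak scoring, calibrated so planted
arrays with 10 bp vs 40 bp dyad jitter separate at the 0.6/0.4 thresholds.

The nucleosome repeat length (NRL) is the slope of an ordinary least squares
fit of phasogram peak positions against peak index, where the phasogram is
the histogram of pairwise distances between mononucleosomal fragment
midpoints.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.signal import find_peaks

from .coverage import FragmentSet, SignalTrack
from .core import merge_intervals, union_length

HEIGHT_THRESHOLD = 0.6
WIDTH_THRESHOLD = 0.4
MAX_NONOVERLAPPING_WIDTH = 150
PEAK_HALF = 73  # 147 bp peak width


@dataclass(frozen=True)
class NucleosomeCall:
    chrom: str
    start: int
    end: int
    summit: int
    height_score: float
    width_score: float
    label: str  # "W", "F" or "overlapping"

    @property
    def width(self) -> int:
        return self.end - self.start


def classify_call(height_score: float, width_score: float, width: int) -> str:
    """Class label from the two scores and the call width."""
    if width > MAX_NONOVERLAPPING_WIDTH:
        return "overlapping"
    if height_score > HEIGHT_THRESHOLD and width_score > WIDTH_THRESHOLD:
        return "W"
    return "F"


def lowpass_filter(values: np.ndarray, pc_keep: float) -> np.ndarray:
    """Keep the lowest ``pc_keep`` fraction of Fourier components."""
    if not 0 < pc_keep <= 1:
        raise ValueError("pc_keep must be in (0, 1]")
    spec = rfft(values)
    k = max(2, int(round(pc_keep * len(spec))))
    spec[k:] = 0
    return irfft(spec, n=len(values))


def call_nucleosomes(
    track: SignalTrack,
    pc_keep: float = 0.02,
    peak_width: int = 147,
    threshold_pct: float = 35.0,
    min_overlap: int = 50,
) -> list:
    """Call and classify nucleosome peaks from a heavy-digest RPM track."""
    half = peak_width // 2
    shape_kernel = np.ones(11) / 11
    filtered = {c: lowpass_filter(v, pc_keep) for c, v in track.data.items()}
    shape = {c: np.convolve(v, shape_kernel, mode="same") for c, v in track.data.items()}
    nonzero_vals = np.concatenate(
        [f[f > 0] for f in filtered.values()] or [np.empty(0)]
    )
    if nonzero_vals.size == 0:
        warnings.warn("all-zero coverage track: no nucleosome calls")
        return []
    sorted_nonzero = np.sort(nonzero_vals)
    calls = []
    for chrom in sorted(track.data):
        f = filtered[chrom]
        pos_vals = f[f > 0]
        if pos_vals.size == 0:
            continue
        background = np.percentile(pos_vals, threshold_pct)
        peaks, _ = find_peaks(f, height=background)
        if peaks.size == 0:
            continue
        # merge candidate 147 bp spans overlapping by >= min_overlap
        spans = np.column_stack([peaks - half, peaks + half + 1])
        merged = []
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if cur_e - s >= min_overlap:
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        L = len(f)
        for s, e in merged:
            s, e = int(max(s, 0)), int(min(e, L))
            summit = s + int(np.argmax(f[s:e]))
            sval = f[summit]
            height = np.searchsorted(sorted_nonzero, sval, side="right") / len(
                sorted_nonzero
            )
            lo, hi = max(summit - half, 0), min(summit + half + 1, L)
            raw = shape[chrom]
            fwhm = int(np.count_nonzero(raw[lo:hi] >= 0.5 * raw[summit]))
            width_score = float(np.clip(1.0 - fwhm / peak_width, 0.0, 1.0))
            calls.append(
                NucleosomeCall(
                    chrom, s, e, summit, float(height), width_score,
                    classify_call(float(height), width_score, e - s),
                )
            )
    return calls


def nucleosome_coverage(calls, genome_length: int) -> float:
    """Percentage of the genome occupied by the union of nucleosome calls."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if not calls:
        return 0.0
    by_chrom: dict = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    covered = sum(union_length(iv) for iv in by_chrom.values())
    return 100.0 * covered / genome_length


# ---------------------------------------------------------------------------
# phasogram / NRL


@dataclass
class PhasogramResult:
    lags: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    peak_lags: np.ndarray
    nrl: float
    nrl_se: float
    r_squared: float
    replicate_nrls: np.ndarray | None = None  # set when replicates supplied


class PhasogramError(RuntimeError):
    def __init__(self, message, lags=None, counts=None):
        super().__init__(message)
        self.lags = lags
        self.counts = counts


def _pair_distance_histogram(frags: FragmentSet, max_lag: int) -> np.ndarray:
    """Counts of unordered midpoint pairs at each lag 0..max_lag (exact)."""
    hist = np.zeros(max_lag + 1)
    for chrom in sorted(frags.fragments):
        mids = frags.midpoints(chrom)
        if mids.size == 0:
            continue
        mids = mids - mids.min()
        n = int(mids.max()) + 1
        c = np.bincount(mids, minlength=n).astype(np.float64)
        m = next_fast_len(n + max_lag + 1)
        spec = rfft(c, n=m)
        ac = irfft(spec * np.conj(spec), n=m)[: max_lag + 1]
        hist += np.rint(ac)
    return hist


def phasogram_nrl(
    frags,
    min_lag: int = 50,
    max_lag: int = 1500,
    smooth_window: int = 21,
    prominence_fraction: float = 0.05,
) -> PhasogramResult:
    """Estimate the NRL from the phasogram of fragment midpoint distances.

    ``frags`` may be a single :class:`FragmentSet` or a list of replicate
    sets; with replicates the NRL is estimated per replicate and reported as
    mean +- SD, while the returned histogram is the replicate sum.
    """
    if isinstance(frags, FragmentSet):
        fragsets = [frags]
    else:
        fragsets = list(frags)
    hists = []
    for fs in fragsets:
        if fs.n_fragments < 10_000:
            warnings.warn("fewer than 10,000 fragments: NRL estimate may be unstable")
        hists.append(_pair_distance_histogram(fs, max_lag + smooth_window))
    results = [
        _phasogram_from_hist(h, min_lag, max_lag, smooth_window, prominence_fraction)
        for h in hists
    ]
    if len(results) == 1:
        return results[0]
    nrls = np.array([r.nrl for r in results])
    pooled = _phasogram_from_hist(
        np.sum(hists, axis=0), min_lag, max_lag, smooth_window, prominence_fraction
    )
    return PhasogramResult(
        lags=pooled.lags,
        counts=pooled.counts,
        smoothed=pooled.smoothed,
        peak_lags=pooled.peak_lags,
        nrl=float(nrls.mean()),
        nrl_se=float(nrls.std(ddof=1)),
        r_squared=pooled.r_squared,
        replicate_nrls=nrls,
    )


def _phasogram_from_hist(hist, min_lag, max_lag, smooth_window, prominence_fraction):
    """Peak detection and NRL fit on a full lag histogram (index = lag)."""
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(hist, kernel, mode="same")
    lo, hi = min_lag, min(max_lag, len(hist) - 1)
    window = smoothed[lo : hi + 1]
    dyn = window.max() - window.min()
    peaks, _ = find_peaks(window, prominence=prominence_fraction * dyn)
    peak_lags = peaks + lo
    if len(peak_lags) < 3:
        raise PhasogramError(
            f"only {len(peak_lags)} phasogram peaks detected (need >= 3)",
            lags=np.arange(len(hist)),
            counts=hist,
        )
    idx = np.arange(1, len(peak_lags) + 1, dtype=float)
    slope, intercept = np.polyfit(idx, peak_lags.astype(float), 1)
    fitted = slope * idx + intercept
    resid = peak_lags - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((peak_lags - peak_lags.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = max(len(idx) - 2, 1)
    se = float(
        np.sqrt(ss_res / dof / np.sum((idx - idx.mean()) ** 2))
    )
    return PhasogramResult(
        lags=np.arange(lo, hi + 1),
        counts=hist[lo : hi + 1],
        smoothed=window,
        peak_lags=peak_lags.astype(np.int64),
        nrl=float(slope),
        nrl_se=se,
        r_squared=float(r2),
    )
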