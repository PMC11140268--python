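"""ACR annotation: gene proximity, feature subcategories, GC content and
transposable-element enrichment.

Proximity classes follow the gACR/pACR/dACR convention: genic (>= 1 bp
overlap with a gene body), proximal (within 2 kb of a gene) and distal
(> 2 kb).  Feature subcategories bin each region relative to its nearest
gene: promoter (< 1 kb, 1-2 kb, 2-3 kb upstream of the TSS), exon, intron,
downstream (< 1 kb, 1-2 kb, 2-3 kb past the TTS) and intergenic (> 3 kb on
both sides).  Where two genes compete for a region, the gene with the nearer
TSS wins; exact ties go to the lower gene coordinate.

TE enrichment scores are log2 fold changes of observed versus
permutation-derived mean ACR proportions within each TE superfamily, with
controls shuffled separately in distal space (excluding gene bodies + 2 kb
flanks) and genic/proximal space (restricted to them) to match the ACR
composition.  TE families additionally get a hypergeometric tail test of
overlap bp against the genome background.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import PlacementError, derive_seed, merge_intervals

PROXIMAL_DISTANCE = 2_000
FEATURE_MAX = 3_000
_BINS = ((0, 1_000, "lt1kb"), (1_000, 2_000, "1to2kb"), (2_000, 3_000, "2to3kb"))


def _intervals_frame(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        return intervals[["chrom", "start", "end"]].reset_index(drop=True)
    rows = []
    for iv in intervals:
        if hasattr(iv, "chrom"):
            rows.append((iv.chrom, iv.start, iv.end))
        else:
            rows.append(tuple(iv[:3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _gap(s, e, g_start, g_end) -> int:
    """Bases separating [s, e) and [g_start, g_end); 0 when they overlap."""
    if s < g_end and g_start < e:
        return 0
    return g_start - e if g_start >= e else s - g_end


def _tss_distance(s, e, tss) -> int:
    if s <= tss < e:
        return 0
    return min(abs(tss - s), abs(tss - (e - 1)))


def classify_acr(acrs, genes) -> pd.DataFrame:
    """Annotate regions with proximity class and feature subcategory."""
    df = _intervals_frame(acrs)
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    known_chroms = set(by_chrom)
    out = []
    for row in df.itertuples():
        s, e = int(row.start), int(row.end)
        chrom_genes = by_chrom.get(row.chrom)
        if chrom_genes is None:
            if known_chroms:
                raise ValueError(f"region on chromosome {row.chrom!r} absent from annotation")
            chrom_genes = []
        best = None  # nearest-TSS candidate with gap < 3 kb: (tss_dist, start, gene, gap)
        best_overlap = None  # same, restricted to overlapping genes
        min_gap = None
        for g in chrom_genes:
            gap = _gap(s, e, g.start, g.end)
            min_gap = gap if min_gap is None else min(min_gap, gap)
            if gap >= FEATURE_MAX:
                continue
            cand = (_tss_distance(s, e, g.tss), g.start, g, gap)
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
            if gap == 0 and (
                best_overlap is None or (cand[0], cand[1]) < (best_overlap[0], best_overlap[1])
            ):
                best_overlap = cand
        if min_gap is None:
            proximity, feature = "distal", "intergenic"
        elif min_gap == 0:
            proximity = "genic"
            feature = _genic_feature(s, e, best_overlap[2])
        else:
            proximity = "proximal" if min_gap <= PROXIMAL_DISTANCE else "distal"
            feature = "intergenic" if best is None else _flank_feature(s, e, best[2], best[3])
        out.append((row.chrom, s, e, proximity, feature))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "proximity", "feature"])


def _genic_feature(s, e, gene) -> str:
    if not gene.exons:
        return "exon"
    for es, ee in gene.exons:
        if s < ee and es < e:
            return "exon"
    return "intron"


def _flank_feature(s, e, gene, gap) -> str:
    # upstream of the TSS (gene strand) is promoter, past the TTS downstream
    before = e <= gene.start
    if gene.strand == "+":
        side = "promoter" if before else "downstream"
    else:
        side = "downstream" if before else "promoter"
    for lo, hi, tag in _BINS:
        if lo <= gap < hi:
            return f"{side}_{tag}"
    return "intergenic"


# ---------------------------------------------------------------------------
# shuffled controls


def gene_flank_space(genes, chrom_lengths, flank: int = PROXIMAL_DISTANCE) -> dict:
    """Gene bodies + ``flank`` bp on both sides, merged, per chromosome."""
    per_chrom: dict = {c: [] for c in chrom_lengths}
    for g in genes:
        per_chrom[g.chrom].append(
            (max(0, g.start - flank), min(chrom_lengths[g.chrom], g.end + flank))
        )
    return {c: merge_intervals(iv) for c, iv in per_chrom.items()}


def _complement(intervals, length) -> np.ndarray:
    out, pos = [], 0
    for s, e in intervals:
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def shuffle_controls(intervals, space: str, genes, chrom_lengths, n: int, seed: int, exclude=None):
    """Length- and chromosome-preserving random placements of intervals.

    ``space="distal_space"`` excludes gene bodies + 2 kb flanks;
    ``space="genic_proximal_space"`` is restricted to them.  Returns a list
    of ``n`` DataFrames, deterministic given ``seed``.
    """
    if space not in ("distal_space", "genic_proximal_space"):
        raise ValueError(f"unknown space {space!r}")
    df = _intervals_frame(intervals)
    gene_space = gene_flank_space(genes, chrom_lengths)
    allowed = {}
    for chrom, L in chrom_lengths.items():
        iv = gene_space.get(chrom, np.empty((0, 2), np.int64))
        allowed_iv = iv if space == "genic_proximal_space" else _complement(iv, L)
        if exclude is not None:
            excl_df = _intervals_frame(exclude)
            excl = merge_intervals(
                [(r.start, r.end) for r in excl_df.itertuples() if r.chrom == chrom]
            )
            allowed_iv = _subtract(allowed_iv, excl)
        allowed[chrom] = np.asarray(allowed_iv, dtype=np.int64).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    # cache valid-start bookkeeping per (chrom, length); intervals sharing a
    # key are placed with one vectorized draw per permutation
    cache = {}
    chroms = df["chrom"].to_numpy()
    lengths = (df["end"] - df["start"]).to_numpy()
    for chrom, L in sorted({(c, int(l)) for c, l in zip(chroms, lengths)}):
        gaps = allowed[chrom]
        room = np.maximum(gaps[:, 1] - gaps[:, 0] - L + 1, 0)
        total = int(room.sum())
        if total == 0:
            raise PlacementError(f"no room for a {L} bp interval in {space} on {chrom}")
        cache[(chrom, L)] = (gaps[:, 0], np.cumsum(room), total)
    keys = list(cache)
    members = {
        k: np.flatnonzero((chroms == k[0]) & (lengths == k[1])) for k in keys
    }
    placements = []
    for _ in range(n):
        starts = np.empty(len(df), dtype=np.int64)
        for k in keys:
            gap_starts, cum, total = cache[k]
            idx = members[k]
            u = rng.integers(total, size=len(idx))
            gi = np.searchsorted(cum, u, side="right")
            offset = u - np.where(gi > 0, cum[gi - 1], 0)
            starts[idx] = gap_starts[gi] + offset
        placements.append(
            pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + lengths})
        )
    return placements


def _subtract(intervals, remove):
    if len(remove) == 0:
        return intervals
    out = []
    for s, e in intervals:
        cur = s
        for rs, re in remove:
            if re <= cur or rs >= e:
                continue
            if rs > cur:
                out.append((cur, rs))
            cur = max(cur, re)
        if cur < e:
            out.append((cur, e))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def gc_content(intervals, sequences: dict) -> np.ndarray:
    """(G + C) / counted bases per interval; ambiguous bases excluded."""
    df = _intervals_frame(intervals)
    out = np.empty(len(df))
    for i, r in enumerate(df.itertuples()):
        if r.end <= r.start:
            raise ValueError("zero-length interval")
        seq = sequences[r.chrom][r.start : r.end].upper()
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        out[i] = gc / (gc + at) if gc + at else np.nan
    return out


# ---------------------------------------------------------------------------
# TE enrichment


def _overlap_lookup(intervals, chrom_lengths):
    """Per-chromosome cumulative-coverage arrays for O(1) overlap queries."""
    lookup = {}
    for chrom, L in chrom_lengths.items():
        iv = merge_intervals([(s, e) for c, s, e in intervals if c == chrom])
        cov = np.zeros(L + 1, dtype=np.int64)
        for s, e in iv:
            cov[s] += 1
            cov[min(e, L)] -= 1
        lookup[chrom] = np.r_[0, np.cumsum(np.cumsum(cov)[:L])]
    return lookup


def _overlaps(df, lookup):
    """bp overlap of each interval in df against a cumulative lookup."""
    out = np.zeros(len(df), dtype=np.int64)
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    for chrom in np.unique(chroms):
        c = lookup[chrom]
        sel = chroms == chrom
        out[sel] = c[ends[sel]] - c[starts[sel]]
    return out


def te_enrichment(acrs, tes, genes, chrom_lengths, n_perm: int = 1000, seed: int = 0, exclude=None) -> pd.DataFrame:
    """Permutation enrichment per TE superfamily plus family hypergeometrics.

    Observed proportions are computed bp-wise (fraction of ACR bp inside the
    superfamily; the enrichment-score default) and element-wise (fraction of
    ACRs with >= 1 bp overlap); the null distribution comes from ``n_perm``
    composition-matched shuffles.  p values are two-sided with a +1
    pseudo-count.
    """
    acr_df = _intervals_frame(acrs)
    if len(acr_df) == 0:
        raise ValueError("no ACRs supplied")
    ann = classify_acr(acr_df, genes)
    is_distal = (ann["proximity"] == "distal").to_numpy()
    groups = {
        "distal_space": acr_df[is_distal],
        "genic_proximal_space": acr_df[~is_distal],
    }
    superfams = sorted({t.superfamily for t in tes})
    lookups = {
        sf: _overlap_lookup([(t.chrom, t.start, t.end) for t in tes if t.superfamily == sf], chrom_lengths)
        for sf in superfams
    }
    total_bp = int((acr_df["end"] - acr_df["start"]).sum())
    n_acrs = len(acr_df)
    genome_bp = int(sum(chrom_lengths.values()))

    obs_bp, obs_el = {}, {}
    for sf in superfams:
        ov = _overlaps(acr_df, lookups[sf])
        obs_bp[sf] = ov.sum() / total_bp
        obs_el[sf] = (ov > 0).sum() / n_acrs

    shuffles = {
        name: (
            shuffle_controls(sub, name, genes, chrom_lengths, n_perm, _spawn(seed, name), exclude)
            if len(sub)
            else [None] * n_perm
        )
        for name, sub in groups.items()
    }
    perm_bp = {sf: np.zeros(n_perm) for sf in superfams}
    for k in range(n_perm):
        parts = [s[k] for s in shuffles.values() if s[k] is not None]
        perm = pd.concat(parts, ignore_index=True)
        for sf in superfams:
            perm_bp[sf][k] = _overlaps(perm, lookups[sf]).sum() / total_bp

    rows = []
    for sf in superfams:
        sf_bp = sum(e - s for t in tes if t.superfamily == sf for s, e in [(t.start, t.end)])
        if sf_bp == 0:
            continue
        perms = perm_bp[sf]
        mean, sd = perms.mean(), perms.std(ddof=1)
        obs = obs_bp[sf]
        # half-bp pseudo-proportion keeps the score finite at zero overlap
        eps = 0.5 / total_bp
        enr = 0.0 if obs == mean else float(np.log2((obs + eps) / (mean + eps)))
        hi = (1 + np.sum(perms >= obs)) / (n_perm + 1)
        lo = (1 + np.sum(perms <= obs)) / (n_perm + 1)
        p = min(1.0, 2 * min(hi, lo))
        rows.append(
            ("superfamily", sf, obs, obs_el[sf], mean, sd, enr, p, np.nan)
        )

    fam_bp: dict = {}
    for t in tes:
        fam_bp[t.family] = fam_bp.get(t.family, 0) + (t.end - t.start)
    for fam in sorted(fam_bp):
        lookup = _overlap_lookup([(t.chrom, t.start, t.end) for t in tes if t.family == fam], chrom_lengths)
        k_bp = int(_overlaps(acr_df, lookup).sum())
        p_hyp = float(hypergeom.sf(k_bp - 1, genome_bp, fam_bp[fam], total_bp))
        exp = fam_bp[fam] / genome_bp
        obs = k_bp / total_bp
        eps = 0.5 / total_bp
        enr = 0.0 if obs == exp else float(np.log2((obs + eps) / (exp + eps)))
        rows.append(("family", fam, obs, np.nan, exp, np.nan, enr, np.nan, p_hyp))
    return pd.DataFrame(
        rows,
        columns=[
            "level", "unit", "observed_prop", "observed_prop_elements",
            "perm_mean", "perm_sd", "enrichment", "p_perm", "p_hypergeom",
        ],
    )


def _spawn(seed, tag):
    return derive_seed(seed, "te_enrichment", tag)
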