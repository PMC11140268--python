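"""Count-based statistics shared by the expression and accessibility layers.

This is a self-contained negative-binomial testing stack:

* TMM (trimmed mean of M-values) normalization factors;
* per-unit NB dispersion by method of moments, shrunk 50/50 toward a fitted
  mean-dispersion trend ``a + b / mean``;
* Wald tests on log2 fold changes for two-group and 2x2 interaction
  contrasts, with Benjamini-Hochberg correction across units;
* windowed differential-accessibility contrasts over fragment midpoint
  counts (light vs heavy within a genotype; hybridization = F1:light-heavy
  vs diploid:light-heavy; polyploidization = AD1 vs F1), with merging of
  adjacent significant windows into directional regions.

The NB Wald pipeline is an explicit surrogate for empirical-Bayes GLM
frameworks (DESeq2/edgeR): simpler shrinkage, fully specified, testable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

ALPHA = 0.05
_PSEUDO = 0.5  # normalized pseudo-count stabilizing log fold changes


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# TMM


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """TMM normalization factors, scaled to geometric mean 1.

    The reference is the deepest library.  M (log ratio) and A (log
    abundance) values of units expressed in both libraries are doubly
    trimmed, and the factor is 2**(precision-weighted mean M).
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("library with zero total count")
    ref = lib.idxmax()
    yr = counts[ref].to_numpy(float)
    nr = lib[ref]
    factors = {}
    for col in counts.columns:
        if col == ref:
            factors[col] = 1.0
            continue
        yk = counts[col].to_numpy(float)
        nk = lib[col]
        keep = (yk > 0) & (yr > 0)
        if not keep.any():
            raise ValueError(f"sample {col} shares no expressed units with the reference")
        pk, pr = yk[keep] / nk, yr[keep] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (nk - yk[keep]) / (nk * yk[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not sel.any():
            sel = np.ones_like(m, dtype=bool)
        factors[col] = float(2 ** (np.sum(m[sel] / w[sel]) / np.sum(1 / w[sel])))
    f = pd.Series(factors)[counts.columns]
    return f / np.exp(np.log(f).mean())


def effective_sizes(counts: pd.DataFrame) -> pd.Series:
    """Library size x TMM factor, rescaled to geometric mean 1."""
    lib = counts.sum(axis=0).astype(float)
    eff = lib * tmm_factors(counts)
    return eff / np.exp(np.log(eff).mean())


# ---------------------------------------------------------------------------
# NB Wald machinery


def _group_arrays(counts, groups):
    cols = list(counts.columns)
    by_group: dict = {}
    for c in cols:
        g = groups[c]
        by_group.setdefault(g, []).append(c)
    return by_group


def _moment_dispersion(norm_by_group, inv_s_by_group):
    """Method-of-moments dispersion pooled across groups (unclipped)."""
    num = 0.0
    den = 0.0
    for g, mat in norm_by_group.items():
        n = mat.shape[1]
        if n < 2:
            continue
        mu = mat.mean(axis=1)
        var = mat.var(axis=1, ddof=1)
        cbar = np.mean(inv_s_by_group[g])
        num = num + (n - 1) * (var - mu * cbar)
        den = den + (n - 1) * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return phi


def _trend_dispersion(phi_hat, mu):
    """Fit phi = a + b / mu by least squares, both coefficients >= 0."""
    ok = mu > 0
    if ok.sum() < 10:
        return np.full_like(phi_hat, max(float(np.median(phi_hat)), 0.0))
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(x, phi_hat[ok], rcond=None)
    a, b = np.clip(coef, 0.0, None)
    with np.errstate(divide="ignore"):
        return a + np.where(mu > 0, b / mu, 0.0)


def _shrunk_dispersion(norm_by_group, inv_s_by_group, method):
    phi_raw = _moment_dispersion(norm_by_group, inv_s_by_group)
    phi_hat = np.clip(phi_raw, 0.0, None)
    mu_all = np.mean([m.mean(axis=1) for m in norm_by_group.values()], axis=0)
    if method == "pooled":
        return np.full_like(phi_hat, max(float(np.median(phi_raw)), 0.0))
    if method != "moment":
        raise ValueError(f"unknown dispersion method {method!r}")
    # fit the trend on the unclipped estimates: clipping first would bias the
    # trend upward on near-Poisson data and make the Wald test conservative
    trend = np.clip(_trend_dispersion(phi_raw, mu_all), 0.0, None)
    return 0.5 * phi_hat + 0.5 * trend


def _log2_mean_and_var(mat, inv_s, phi):
    """Group mean of normalized counts and delta-method var of its log2."""
    n = mat.shape[1]
    mu = mat.mean(axis=1)
    var_mu = (mu[:, None] * inv_s[None, :] + phi[:, None] * mu[:, None] ** 2).sum(axis=1) / n**2
    mu_p = mu + _PSEUDO
    var_log2 = var_mu / (mu_p**2 * np.log(2) ** 2)
    return mu, np.log2(mu_p), var_log2


def _finish(units, lfc, var, alpha):
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    p = 2 * norm.sf(np.abs(z))
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "se": se,
            "wald_p": p,
            "fdr_q": q,
            "significant": q < alpha,
        },
        index=units,
    )


def _prepare(counts, groups, size_factors, used_groups, dispersion):
    by_group = _group_arrays(counts, groups)
    for g in used_groups:
        if g not in by_group:
            raise ValueError(f"contrast group {g!r} absent from design")
        if len(by_group[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    if size_factors is None:
        size_factors = effective_sizes(counts)
    s = size_factors
    norm_by_group = {}
    inv_s_by_group = {}
    for g in used_groups:
        cols = by_group[g]
        sf = np.array([s[c] for c in cols], dtype=float)
        norm_by_group[g] = counts[cols].to_numpy(float) / sf[None, :]
        inv_s_by_group[g] = 1.0 / sf
    nonzero = np.zeros(len(counts), dtype=bool)
    for g in used_groups:
        nonzero |= norm_by_group[g].sum(axis=1) > 0
    phi = _shrunk_dispersion(
        {g: m[nonzero] for g, m in norm_by_group.items()}, inv_s_by_group, dispersion
    )
    return norm_by_group, inv_s_by_group, nonzero, phi


def nb_test(
    counts: pd.DataFrame,
    groups,
    contrast,
    size_factors=None,
    dispersion: str = "moment",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Two-group NB Wald test of ``contrast = (numerator, denominator)``.

    Returns per-unit log2 fold change, SE, Wald p, BH q and a derived
    ``significant`` flag (q < alpha).  Units with zero counts in every used
    sample are excluded and reported in ``result.attrs["excluded"]``.
    """
    g1, g2 = contrast
    norm_by_group, inv_s, nonzero, phi = _prepare(
        counts, groups, size_factors, (g1, g2), dispersion
    )
    m1, m2 = norm_by_group[g1][nonzero], norm_by_group[g2][nonzero]
    _, l1, v1 = _log2_mean_and_var(m1, inv_s[g1], phi)
    _, l2, v2 = _log2_mean_and_var(m2, inv_s[g2], phi)
    res = _finish(counts.index[nonzero], l1 - l2, v1 + v2, alpha)
    res.attrs["excluded"] = list(counts.index[~nonzero])
    return res


def nb_interaction_test(
    counts: pd.DataFrame,
    groups,
    contrast,
    size_factors=None,
    dispersion: str = "moment",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """2x2 interaction Wald test: ``(a/b) vs (c/d)`` as ((a, b), (c, d)).

    The statistic is [log2 mean(a) - log2 mean(b)] - [log2 mean(c) -
    log2 mean(d)], e.g. a homoeolog ratio in the hybrid versus the parental
    ratio, or light-heavy accessibility shifts between genotypes.
    """
    (a, b), (c, d) = contrast
    used = (a, b, c, d)
    norm_by_group, inv_s, nonzero, phi = _prepare(
        counts, groups, size_factors, used, dispersion
    )
    lfc = None
    var = None
    for g, sign in ((a, 1), (b, -1), (c, -1), (d, 1)):
        _, lg, vg = _log2_mean_and_var(norm_by_group[g][nonzero], inv_s[g], phi)
        lfc = lg * sign if lfc is None else lfc + lg * sign
        var = vg if var is None else var + vg
    res = _finish(counts.index[nonzero], lfc, var, alpha)
    res.attrs["excluded"] = list(counts.index[~nonzero])
    return res


# ---------------------------------------------------------------------------
# windowed differential accessibility


@dataclass
class DAResult:
    contrast: str
    windows: pd.DataFrame  # chrom, start, end + TestResult columns
    regions: pd.DataFrame  # merged significant windows with direction
    bp_increase: int
    bp_decrease: int


def window_counts(fragsets, window: int = 200) -> pd.DataFrame:
    """Fragment midpoints counted into non-overlapping windows per sample."""
    if not fragsets:
        raise ValueError("no fragment sets")
    chrom_lengths = fragsets[0].chrom_lengths
    index = []
    for chrom in sorted(chrom_lengths):
        n = (chrom_lengths[chrom] + window - 1) // window
        index += [(chrom, i * window, min((i + 1) * window, chrom_lengths[chrom])) for i in range(n)]
    mi = pd.MultiIndex.from_tuples(index, names=["chrom", "start", "end"])
    data = {}
    for fs in fragsets:
        name = f"{fs.genotype}:{fs.digestion}:r{fs.replicate}"
        cols = []
        for chrom in sorted(chrom_lengths):
            n = (chrom_lengths[chrom] + window - 1) // window
            mids = fs.midpoints(chrom)
            cols.append(np.bincount(mids // window, minlength=n)[:n])
        data[name] = np.concatenate(cols)
    return pd.DataFrame(data, index=mi)


def window_da(fragsets, contrast: str, window: int = 200, alpha: float = ALPHA, dispersion: str = "moment") -> DAResult:
    """Windowed differential accessibility for a named contrast.

    ``light_vs_heavy_within`` needs one genotype's light+heavy sets;
    ``hybridization`` contrasts F1:light-heavy against a diploid's;
    ``polyploidization`` contrasts AD1 against F1.  Positive log2 fold
    change means an accessibility increase in the first-named condition.
    """
    counts = window_counts(fragsets, window)
    groups = {c: ":".join(c.split(":")[:2]) for c in counts.columns}
    genotypes = sorted({g.split(":")[0] for g in groups.values()})
    for gt in genotypes:
        have = {g.split(":")[1] for g in groups.values() if g.startswith(gt + ":")}
        if have != {"light", "heavy"}:
            raise ValueError(f"genotype {gt} is missing a digestion condition")
    if contrast == "light_vs_heavy_within":
        if len(genotypes) != 1:
            raise ValueError("within-genotype contrast expects a single genotype")
        gt = genotypes[0]
        res = nb_test(counts, groups, (f"{gt}:light", f"{gt}:heavy"), dispersion=dispersion, alpha=alpha)
    elif contrast in ("hybridization", "polyploidization"):
        first = "F1" if contrast == "hybridization" else "AD1"
        others = [g for g in genotypes if g != first]
        if first not in genotypes or len(others) != 1:
            raise ValueError(f"{contrast} contrast expects {first} plus one other genotype")
        other = others[0]
        res = nb_interaction_test(
            counts,
            groups,
            ((f"{first}:light", f"{first}:heavy"), (f"{other}:light", f"{other}:heavy")),
            dispersion=dispersion,
            alpha=alpha,
        )
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    aligned = res.reindex(counts.index)
    windows = pd.concat(
        [counts.index.to_frame(index=False), aligned.reset_index(drop=True)], axis=1
    )
    windows["significant"] = windows["significant"].fillna(False).astype(bool)
    regions = _merge_significant(windows)
    bp_inc = int((regions.query("direction == 'increase'")["end"] - regions.query("direction == 'increase'")["start"]).sum()) if len(regions) else 0
    bp_dec = int((regions.query("direction == 'decrease'")["end"] - regions.query("direction == 'decrease'")["start"]).sum()) if len(regions) else 0
    return DAResult(contrast, windows, regions, bp_inc, bp_dec)


def _merge_significant(windows: pd.DataFrame) -> pd.DataFrame:
    sig = windows[windows["significant"]].copy()
    if sig.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "direction"])
    sig["direction"] = np.where(sig["log2fc"] > 0, "increase", "decrease")
    rows = []
    cur = None
    for r in sig.sort_values(["chrom", "start"]).itertuples():
        if cur is not None and r.chrom == cur[0] and r.direction == cur[3] and r.start <= cur[2]:
            cur = (cur[0], cur[1], max(cur[2], r.end), cur[3])
        else:
            if cur is not None:
                rows.append(cur)
            cur = (r.chrom, r.start, r.end, r.direction)
    rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])
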