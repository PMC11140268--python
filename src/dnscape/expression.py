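"""Duplicated-gene expression classification for hybrid and allopolyploid
designs.

Per ortho-homoeolog group (one gene each for A2, D5, F1:At, F1:Dt, AD1:At
and AD1:Dt) this module estimates and tests

* ``A  = log2(A2 / D5)`` — total parental divergence,
* ``B  = log2(At / Dt)`` in the F1 — the cis contribution (homoeolog
  expression bias, HEB), ``Bp`` its allopolyploid counterpart,
* inheritance of total (At + Dt) expression: additive (equal to the
  mid-parent value), expression level dominance toward A or D (ELD), or
  transgressive up/down-regulation,
* the cis-trans decomposition from the significance of A, B and A - B,
* the evolutionary impacts Hr = B - A (hybridization), Pr = Bp - A
  (allopolyploidization) and Wr = Bp - B (genome doubling), which satisfy
  Hr + Wr = Pr exactly.

"Statistically equivalent" is operationalized as non-rejection at
BH-FDR 0.05, mirroring common practice; this is absence of evidence, not an
equivalence test, and is documented as such.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .count_stats import ALPHA, bh_adjust, effective_sizes, nb_interaction_test, nb_test
from .simulate import ExpressionData, OG_SLOTS

INHERITANCE_LABELS = (
    "additive",
    "ELD_A",
    "ELD_D",
    "transgressive_up",
    "transgressive_down",
    "other_nonadditive",
)
CISTRANS_LABELS = (
    "cis_only",
    "trans_only",
    "cis_trans_enhancing",
    "cis_trans_compensating",
    "compensatory",
    "conserved",
    "ambiguous",
)


def og_matrices(data: ExpressionData) -> dict:
    """Count matrices aligned on orthogroups.

    ``total``: OG x all samples, with F1/AD1 entries summed over homoeologs
    (makes genotypes comparable for normalization and total-expression
    tests); per-slot matrices carry the partitioned homoeolog counts.
    """
    counts, samples, ogs = data.counts, data.samples, data.ogs
    slot_mats = {
        slot: counts.loc[ogs[slot].to_numpy(), samples.index[samples["genotype"] == slot.split("_")[0]]].set_axis(ogs.index, axis=0)
        for slot in OG_SLOTS
    }
    total_cols = {}
    for sample in samples.index:
        genotype = samples.at[sample, "genotype"]
        if genotype in ("A2", "D5"):
            total_cols[sample] = slot_mats[genotype][sample]
        else:
            total_cols[sample] = (
                slot_mats[f"{genotype}_At"][sample] + slot_mats[f"{genotype}_Dt"][sample]
            )
    total = pd.DataFrame(total_cols)
    return {"total": total, **slot_mats}


def og_size_factors(data: ExpressionData) -> pd.Series:
    """Per-sample effective sizes from the OG-level total matrix (TMM)."""
    return effective_sizes(og_matrices(data)["total"])


def _two_group(mat1, mat2, s1, s2, labels=("g1", "g2"), alpha=ALPHA, dispersion="moment"):
    counts = pd.concat(
        [mat1.add_suffix("|1"), mat2.add_suffix("|2")], axis=1
    )
    groups = {c: labels[0] if c.endswith("|1") else labels[1] for c in counts.columns}
    sf = pd.Series(
        {**{f"{c}|1": s1[c] for c in mat1.columns}, **{f"{c}|2": s2[c] for c in mat2.columns}}
    )
    return nb_test(counts, groups, labels, size_factors=sf, alpha=alpha, dispersion=dispersion)


# ---------------------------------------------------------------------------
# inheritance (additivity / ELD / transgression)


def midparent_pseudo_counts(data: ExpressionData, size_factors) -> pd.DataFrame:
    """Per-replicate mean of size-factor-normalized A2 and D5 counts, rounded.

    The pseudo-samples act as mid-parent libraries with effective size 1.
    """
    mats = og_matrices(data)
    a2 = mats["A2"]
    d5 = mats["D5"]
    reps = min(a2.shape[1], d5.shape[1])
    cols = {}
    for i in range(reps):
        ca, cd = a2.columns[i], d5.columns[i]
        cols[f"mid_r{i + 1}"] = np.rint(
            (a2[ca] / size_factors[ca] + d5[cd] / size_factors[cd]) / 2
        ).astype(np.int64)
    return pd.DataFrame(cols, index=a2.index)


def classify_inheritance(data: ExpressionData, genotype: str, alpha: float = ALPHA) -> pd.DataFrame:
    """Label each OG's total-expression inheritance in F1 or AD1.

    Decision precedence (documented): transgressive patterns are evaluated
    first, then ELD, then additivity (non-rejection vs the mid-parent);
    anything left is other_nonadditive.
    """
    if genotype not in ("F1", "AD1"):
        raise ValueError("genotype must be F1 or AD1")
    mats = og_matrices(data)
    sf = og_size_factors(data)
    t = mats["total"][data.samples.index[data.samples["genotype"] == genotype]]
    a2 = mats["A2"]
    d5 = mats["D5"]
    mid = midparent_pseudo_counts(data, sf)
    ones = pd.Series(1.0, index=mid.columns)
    res_a = _two_group(t, a2, sf, sf, ("T", "A2"), alpha)
    res_d = _two_group(t, d5, sf, sf, ("T", "D5"), alpha)
    res_m = _two_group(t, mid, sf, ones, ("T", "mid"), alpha)
    out = pd.DataFrame(index=mats["total"].index)
    for name, res in (("vs_A2", res_a), ("vs_D5", res_d), ("vs_mid", res_m)):
        out[f"lfc_{name}"] = res["log2fc"].reindex(out.index)
        out[f"q_{name}"] = res["fdr_q"].reindex(out.index)
        out[f"sig_{name}"] = res["significant"].reindex(out.index).fillna(False).astype(bool)
    labels = []
    for r in out.itertuples():
        labels.append(
            inheritance_label(
                r.sig_vs_A2, np.sign(r.lfc_vs_A2) if np.isfinite(r.lfc_vs_A2) else 0,
                r.sig_vs_D5, np.sign(r.lfc_vs_D5) if np.isfinite(r.lfc_vs_D5) else 0,
                r.sig_vs_mid,
            )
        )
    out["inheritance"] = labels
    skipped = set(res_a.attrs["excluded"]) | set(res_d.attrs["excluded"]) | set(res_m.attrs["excluded"])
    out.attrs["skipped"] = sorted(skipped)
    return out


def inheritance_label(sig_a, sign_a, sig_d, sign_d, sig_mid) -> str:
    """Total function of the three test outcomes; precedence as documented."""
    if sig_a and sig_d and sign_a > 0 and sign_d > 0:
        return "transgressive_up"
    if sig_a and sig_d and sign_a < 0 and sign_d < 0:
        return "transgressive_down"
    if not sig_a and sig_d and sig_mid:
        return "ELD_A"
    if sig_a and not sig_d and sig_mid:
        return "ELD_D"
    if not sig_mid:
        return "additive"
    return "other_nonadditive"


# ---------------------------------------------------------------------------
# homoeolog expression bias


def classify_heb(data: ExpressionData, genotype: str, alpha: float = ALPHA) -> pd.DataFrame:
    """Homoeolog expression bias (B in F1, Bp in AD1) with NB Wald tests.

    Genome-wide imbalance is summarized by an exact two-sided binomial test
    on the direction split of biased OGs (a chi-square statistic is also
    reported when at least 50 OGs are biased).
    """
    if genotype not in ("F1", "AD1"):
        raise ValueError("genotype must be F1 or AD1")
    mats = og_matrices(data)
    sf = og_size_factors(data)
    at, dt = mats[f"{genotype}_At"], mats[f"{genotype}_Dt"]
    res = _two_group(at, dt, sf, sf, ("At", "Dt"), alpha)
    out = res.rename(columns={"log2fc": "B"}).reindex(mats["total"].index)
    out["significant"] = out["significant"].fillna(False).astype(bool)
    out["direction"] = np.select(
        [out["significant"] & (out["B"] > 0), out["significant"] & (out["B"] < 0)],
        ["A_biased", "D_biased"],
        default="unbiased",
    )
    n_a = int((out["direction"] == "A_biased").sum())
    n_d = int((out["direction"] == "D_biased").sum())
    summary = {"n_A_biased": n_a, "n_D_biased": n_d}
    if n_a + n_d > 0:
        summary["p_binomial"] = float(binomtest(n_a, n_a + n_d, 0.5).pvalue)
    if n_a + n_d >= 50:
        expected = (n_a + n_d) / 2
        chi2 = (n_a - expected) ** 2 / expected + (n_d - expected) ** 2 / expected
        from scipy.stats import chi2 as chi2_dist

        summary["p_chi2"] = float(chi2_dist.sf(chi2, df=1))
    out.attrs["imbalance"] = summary
    return out


# ---------------------------------------------------------------------------
# cis / trans decomposition


def cistrans_category(sig_a, sign_a, sig_b, sign_b, sig_diff, sign_diff) -> str:
    """Map the (A, B, A-B) significance/sign triple to one regulatory class."""
    if sig_a and sig_b and not sig_diff:
        return "cis_only"
    if sig_a and not sig_b and sig_diff:
        return "trans_only"
    if sig_a and sig_b and sig_diff:
        if sign_b == sign_diff:
            return "cis_trans_enhancing"
        return "cis_trans_compensating"
    if not sig_a and sig_b and sig_diff:
        return "compensatory"
    if not sig_a and not sig_b:
        return "conserved"
    return "ambiguous"


def classify_cistrans(data: ExpressionData, alpha: float = ALPHA) -> pd.DataFrame:
    """Six-way cis/trans classification from A, B and A - B tests."""
    mats = og_matrices(data)
    sf = og_size_factors(data)
    res_a = _two_group(mats["A2"], mats["D5"], sf, sf, ("A2", "D5"), alpha)
    heb = classify_heb(data, "F1", alpha)
    diff = _impact_contrast(data, ("A2", "D5"), ("F1_At", "F1_Dt"), alpha)
    out = pd.DataFrame(index=mats["total"].index)
    out["A"] = res_a["log2fc"].reindex(out.index)
    out["sig_A"] = res_a["significant"].reindex(out.index).fillna(False).astype(bool)
    out["B"] = heb["B"]
    out["sig_B"] = heb["significant"]
    out["A_minus_B"] = diff["log2fc"].reindex(out.index)
    out["sig_diff"] = diff["significant"].reindex(out.index).fillna(False).astype(bool)
    out["category"] = [
        cistrans_category(
            r.sig_A, np.sign(r.A) if np.isfinite(r.A) else 0,
            r.sig_B, np.sign(r.B) if np.isfinite(r.B) else 0,
            r.sig_diff, np.sign(r.A_minus_B) if np.isfinite(r.A_minus_B) else 0,
        )
        for r in out.itertuples()
    ]
    return out


def _impact_contrast(data, num_pair, den_pair, alpha):
    """Interaction Wald test of log2(num_pair ratio) - log2(den_pair ratio)."""
    mats = og_matrices(data)
    sf = og_size_factors(data)
    parts, groups, sfs = [], {}, {}
    for tag, slot in zip(("a", "b", "c", "d"), (*num_pair, *den_pair)):
        mat = mats[slot].add_suffix(f"|{tag}")
        parts.append(mat)
        for c_orig, c_new in zip(mats[slot].columns, mat.columns):
            groups[c_new] = tag
            sfs[c_new] = sf[c_orig]
    counts = pd.concat(parts, axis=1)
    return nb_interaction_test(
        counts, groups, (("a", "b"), ("c", "d")), size_factors=pd.Series(sfs), alpha=alpha
    )


def classify_impact(data: ExpressionData, alpha: float = ALPHA) -> pd.DataFrame:
    """Hr, Pr and Wr point estimates with interaction Wald tests.

    Hr = B - A, Pr = Bp - A, Wr = Bp - B; the identity Hr + Wr = Pr holds
    exactly on point estimates because all three derive from the same group
    means.  An OG shows "parental legacy" when Hr (resp. Pr) is not
    significant.
    """
    index = data.ogs.index
    out = pd.DataFrame(index=index)
    specs = {
        "Hr": (("F1_At", "F1_Dt"), ("A2", "D5")),
        "Pr": (("AD1_At", "AD1_Dt"), ("A2", "D5")),
        "Wr": (("AD1_At", "AD1_Dt"), ("F1_At", "F1_Dt")),
    }
    for name, (num, den) in specs.items():
        res = _impact_contrast(data, num, den, alpha)
        out[name] = res["log2fc"].reindex(index)
        out[f"q_{name}"] = res["fdr_q"].reindex(index)
        out[f"sig_{name}"] = res["significant"].reindex(index).fillna(False).astype(bool)
    out["parental_legacy_F1"] = ~out["sig_Hr"]
    out["parental_legacy_AD1"] = ~out["sig_Pr"]
    return out


# ---------------------------------------------------------------------------
# consensus hook


def intersect_classifications(label_frames, column: str) -> pd.Series:
    """Consensus across classification runs (e.g. mapping strategies).

    OGs whose label differs between runs get ``"inconsistent"``.
    """
    frames = list(label_frames)
    if not frames:
        raise ValueError("no classification runs supplied")
    base = frames[0][column]
    out = base.copy()
    for f in frames[1:]:
        other = f[column].reindex(base.index)
        out = out.where(out == other, "inconsistent")
    return out


def summarize_categories(labels: pd.Series) -> pd.DataFrame:
    counts = labels.value_counts()
    return pd.DataFrame(
        {"count": counts, "percent": 100 * counts / counts.sum()}
    )
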