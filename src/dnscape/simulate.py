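"""Synthetic multi-genome scenarios with planted chromatin and expression truth.

The generator emulates the statistical structure of a differential MNase
(DNS-seq) study of two diploid genomes (A and D), their F1 hybrid and an
allopolyploid (AD1) with At/Dt subgenomes:

* heavy digestion yields mononucleosome-sized fragments (~147 bp) whose
  midpoints sit on planted, phased dyad arrays with genome-specific spacing
  (the nucleosome repeat length, NRL);
* light digestion yields a mixture of mononucleosomes (depleted over planted
  accessible regions, the "fragile" effect) and 30-130 bp subnucleosomal
  fragments concentrated inside planted accessible chromatin regions (ACRs);
* transposable-element intervals avoid planted ACRs with a configurable
  exclusion probability, planting accessibility depletion in TEs;
* gene expression counts are negative binomial with planted parental
  divergence (A), homoeolog expression bias (B, Bp), inheritance category
  (additive / expression-level dominance / transgression) and cis-trans
  architecture per ortho-homoeolog group.

Everything is deterministic given the scenario seed; per-operation seeds are
spawned from it so individual stages can be reproduced in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GENOTYPE_SUBGENOMES,
    GeneModel,
    Genome,
    PlacementError,
    SampleSpec,
    TEInterval,
    intervals_to_mask,
    merge_intervals,
    track_genome,
)
from .coverage import FragmentSet

TRACK_KEYS = ("A2", "D5", "F1:At", "F1:Dt", "AD1:At", "AD1:Dt")

INHERITANCE_CATEGORIES = (
    "additive",
    "ELD_A",
    "ELD_D",
    "transgressive_up",
    "transgressive_down",
)
CISTRANS_CATEGORIES = (
    "cis_only",
    "trans_only",
    "cis_trans_enhancing",
    "cis_trans_compensating",
    "compensatory",
    "conserved",
)

_NUCLEOSOME_CORE = 147


@dataclass(frozen=True)
class PlantedACR:
    chrom: str
    start: int
    end: int
    kind: str  # "promoter" | "distal"
    strength: float  # fold enrichment of subnucleosomal midpoint density

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class ScenarioConfig:
    """Study-condition knobs for :func:`build_scenario`.

    Defaults describe the package's reference scenario: two 1 Mb chromosomes
    per genome, ~5,000 nucleosomes per chromosome (stable phasograms), strong
    promoter/distal ACRs, and a 2,000-orthogroup expression design with
    3 replicates at negative-binomial dispersion 0.05.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    gc_content: dict = field(default_factory=lambda: {"A": 0.34, "D": 0.36})
    with_sequence: bool = True

    # genes
    n_genes: int = 80  # per chromosome
    gene_length: int = 2_000
    min_gene_gap: int = 2_000
    multi_exon: bool = False  # if True, genes get two exons and one intron

    # nucleosome arrays
    planted_nrl: dict = field(
        default_factory=lambda: {
            "A2": 198.0,
            "D5": 196.0,
            "F1:At": 198.0,
            "F1:Dt": 196.0,
            "AD1:At": 200.0,
            "AD1:Dt": 199.0,
        }
    )
    well_positioned_fraction: float = 0.5
    sigma_well: float = 10.0
    sigma_fuzzy: float = 40.0
    array_size: int = 25  # dyads per positioning array

    # accessible regions
    n_acrs: int = 150  # per genome
    acr_width: int = 200
    acr_strength: float = 20.0  # planted regions sit ~8-10 robust SD above background
    promoter_fraction: float = 0.4
    promoter_max_offset: int = 800  # TSS-to-ACR-edge distance < 1 kb
    acr_track_scale: dict = field(default_factory=dict)  # track key -> multiplier
    uniform_acrs: bool = False  # place ACRs uniformly, ignoring genes/TEs

    # transposable elements
    n_tes: int = 300  # per genome
    te_length_mean: float = 800.0
    te_length_sigma: float = 0.6  # lognormal sigma of TE lengths
    te_acr_exclusion: float = 0.9  # P(reject TE placement overlapping an ACR)
    te_superfamily_weights: dict = field(
        default_factory=lambda: {
            "Gypsy": 0.35,
            "Copia": 0.20,
            "LINE": 0.10,
            "Mutator": 0.15,
            "hAT": 0.10,
            "CACTA": 0.10,
        }
    )
    te_families_per_superfamily: int = 4

    # fragment sampling
    fragments_per_sample: int = 500_000
    replicates: int = 2
    background_fraction: float = 0.10
    light_small_fraction: float = 0.35
    fragile_depletion: float = 0.3  # survival of mononucleosomes inside ACRs (light)
    heavy_length_mean: float = 147.0
    heavy_length_sd: float = 10.0
    heavy_length_range: tuple = (100, 200)
    small_length_range: tuple = (30, 130)

    # expression
    n_ogs: int = 2_000
    expression_replicates: int = 3
    dispersion: float = 0.05
    effect_size: float = 2.0
    base_mean_range: tuple = (50.0, 500.0)
    transgressive_factor: float = 3.0
    inheritance_proportions: dict = field(
        default_factory=lambda: {
            "additive": 0.6,
            "ELD_A": 0.1,
            "ELD_D": 0.1,
            "transgressive_up": 0.1,
            "transgressive_down": 0.1,
        }
    )
    cistrans_proportions: dict = field(
        default_factory=lambda: {
            "conserved": 0.5,
            "cis_only": 0.2,
            "trans_only": 0.1,
            "compensatory": 0.1,
            "cis_trans_enhancing": 0.05,
            "cis_trans_compensating": 0.05,
        }
    )
    wr_fraction: float = 0.1  # OGs with a planted genome-doubling shift (Wr != 0)
    library_jitter: float = 0.1


@dataclass
class Scenario:
    genomes: dict  # "A"/"D" -> Genome
    genes: dict  # genome label -> list[GeneModel]
    tes: dict  # genome label -> list[TEInterval]
    samples: list  # list[SampleSpec]
    seed: int
    config: ScenarioConfig


@dataclass
class ScenarioTruth:
    """Planted ground truth for recovery testing."""

    planted_nrl: dict  # track key -> bp
    planted_dyads: dict  # track key -> {chrom: int array}
    dyad_sigma: dict  # track key -> {chrom: float array}, jitter per dyad
    planted_acrs: dict  # genome label -> list[PlantedACR]
    acr_track_scale: dict  # track key -> multiplier on ACR strength
    planted_expression: pd.DataFrame  # one row per orthogroup
    dispersion: float


@dataclass
class ExpressionData:
    """Count matrix plus the sample and ortho-homoeolog group tables."""

    counts: pd.DataFrame  # gene id x sample id
    samples: pd.DataFrame  # sample id -> genotype, replicate, lib_factor
    ogs: pd.DataFrame  # og id -> gene id per slot (A2, D5, F1_At, ...)


OG_SLOTS = ("A2", "D5", "F1_At", "F1_Dt", "AD1_At", "AD1_Dt")


from .core import derive_seed as _child_seed


# ---------------------------------------------------------------------------
# scenario construction


def _random_sequence(rng, length, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _place_genes(rng, chrom, length, n_genes, gene_length, min_gap, prefix, multi_exon):
    slack = length - n_genes * (gene_length + min_gap)
    if slack < 0:
        raise PlacementError(
            f"cannot place {n_genes} genes of {gene_length} bp with {min_gap} bp "
            f"gaps on a {length} bp chromosome"
        )
    extra = rng.multinomial(slack, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    genes = []
    pos = 0
    for i in range(n_genes):
        pos += extra[i] + min_gap // 2
        start = pos
        end = start + gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        if multi_exon:
            third = gene_length // 3
            exons = ((start, start + third), (end - third, end))
        else:
            exons = ()
        genes.append(GeneModel(chrom, start, end, strand, f"{prefix}g{i + 1:04d}", exons))
        pos = end + min_gap - min_gap // 2
    return genes


def _place_acrs(rng, cfg, chrom, length, genes):
    """Plant promoter-proximal and distal ACRs on one chromosome."""
    acrs = []
    w = cfg.acr_width
    n = max(1, round(cfg.n_acrs / cfg.n_chroms))
    if cfg.uniform_acrs:
        starts = rng.integers(0, length - w, size=n)
        return [PlantedACR(chrom, int(s), int(s) + w, "distal", cfg.acr_strength) for s in starts]
    n_prom = int(round(n * cfg.promoter_fraction))
    chrom_genes = [g for g in genes if g.chrom == chrom]
    if n_prom > 0 and chrom_genes:
        picks = rng.choice(len(chrom_genes), size=min(n_prom, len(chrom_genes)), replace=False)
        for gi in np.sort(picks):
            g = chrom_genes[gi]
            off = int(rng.integers(50, cfg.promoter_max_offset))
            if g.strand == "+":
                s = g.start - off - w
            else:
                s = g.end + off
            if 0 <= s and s + w <= length:
                acrs.append(PlantedACR(chrom, s, s + w, "promoter", cfg.acr_strength))
    # distal: > 2 kb from every gene, non-overlapping with other ACRs
    forbidden = [(g.start - 2_000 - w, g.end + 2_000) for g in chrom_genes]
    n_distal = n - len(acrs)
    placed = [(a.start, a.end) for a in acrs]
    tries = 0
    while n_distal > 0 and tries < 200 * n:
        tries += 1
        s = int(rng.integers(0, length - w))
        if any(fs < s + w and s < fe for fs, fe in forbidden):
            continue
        if any(ps < s + w + 500 and s - 500 < pe for ps, pe in placed):
            continue
        acrs.append(PlantedACR(chrom, s, s + w, "distal", cfg.acr_strength))
        placed.append((s, s + w))
        n_distal -= 1
    if n_distal > 0:
        raise PlacementError(
            f"could not place {n_distal} distal ACRs on {chrom}: insufficient "
            "gene-free space (> 2 kb from genes)"
        )
    acrs.sort(key=lambda a: a.start)
    return acrs


def _place_tes(rng, cfg, chrom, length, acrs, prefix):
    sfs = list(cfg.te_superfamily_weights)
    weights = np.array([cfg.te_superfamily_weights[s] for s in sfs], dtype=float)
    weights /= weights.sum()
    n = max(1, round(cfg.n_tes / cfg.n_chroms))
    tes = []
    tries = 0
    while len(tes) < n and tries < 100 * n:
        tries += 1
        L = int(np.clip(rng.lognormal(np.log(cfg.te_length_mean), cfg.te_length_sigma), 100, 20_000))
        if L >= length:
            continue
        s = int(rng.integers(0, length - L))
        overlaps_acr = any(a.start < s + L and s < a.end for a in acrs)
        if overlaps_acr and rng.random() < cfg.te_acr_exclusion:
            continue
        sf = sfs[int(rng.choice(len(sfs), p=weights))]
        fam = f"{sf}-{int(rng.integers(1, cfg.te_families_per_superfamily + 1))}"
        tes.append(TEInterval(chrom, s, s + L, sf, fam))
    tes.sort(key=lambda t: t.start)
    return tes


def _plant_dyads(rng, nrl, length, cfg):
    phase = float(rng.uniform(0, nrl))
    dyads = np.arange(phase + 74, length - 74, nrl).astype(np.int64)
    n_arrays = int(np.ceil(len(dyads) / cfg.array_size))
    well = rng.random(n_arrays) < cfg.well_positioned_fraction
    sigma = np.where(
        np.repeat(well, cfg.array_size)[: len(dyads)], cfg.sigma_well, cfg.sigma_fuzzy
    ).astype(float)
    return dyads, sigma


def default_samples(cfg: ScenarioConfig) -> list:
    samples = []
    for genotype in ("A2", "D5", "F1", "AD1"):
        for sub in GENOTYPE_SUBGENOMES[genotype]:
            for digestion in ("light", "heavy"):
                for rep in range(1, cfg.replicates + 1):
                    samples.append(
                        SampleSpec(genotype, sub, digestion, rep, cfg.fragments_per_sample)
                    )
    return samples


def build_scenario(config: ScenarioConfig):
    """Build a deterministic scenario and its ground truth.

    Raises :class:`ValueError` for a planted NRL <= 147 bp (a nucleosome core
    of 147 bp cannot overlap itself) and :class:`PlacementError` when genes or
    ACRs cannot be placed without violating spacing rules.
    """
    cfg = config
    for key, nrl in cfg.planted_nrl.items():
        if nrl <= _NUCLEOSOME_CORE:
            raise ValueError(
                f"planted NRL for {key} must exceed the {_NUCLEOSOME_CORE} bp "
                f"nucleosome core, got {nrl}"
            )
    genomes, genes, tes, acrs = {}, {}, {}, {}
    for label in ("A", "D"):
        rng = np.random.default_rng(_child_seed(cfg.seed, "genome", label))
        chroms = {
            f"chr{label}{i + 1:02d}": cfg.chrom_length for i in range(cfg.n_chroms)
        }
        seq = None
        if cfg.with_sequence:
            gc = cfg.gc_content.get(label, 0.35)
            seq = {c: _random_sequence(rng, L, gc) for c, L in chroms.items()}
        genomes[label] = Genome(label, chroms, seq)
        g_list, a_list, t_list = [], [], []
        for chrom, L in chroms.items():
            g_chrom = _place_genes(
                rng, chrom, L, cfg.n_genes, cfg.gene_length, cfg.min_gene_gap,
                f"{label}.{chrom}.", cfg.multi_exon,
            )
            g_list.extend(g_chrom)
            a_chrom = _place_acrs(rng, cfg, chrom, L, g_chrom)
            a_list.extend(a_chrom)
            t_list.extend(_place_tes(rng, cfg, chrom, L, a_chrom, label))
        genes[label], acrs[label], tes[label] = g_list, a_list, t_list

    planted_dyads, dyad_sigma, planted_nrl = {}, {}, {}
    for key in TRACK_KEYS:
        nrl = float(cfg.planted_nrl.get(key, 198.0))
        planted_nrl[key] = nrl
        rng = np.random.default_rng(_child_seed(cfg.seed, "dyads", key))
        glabel = track_genome(key)
        planted_dyads[key] = {}
        dyad_sigma[key] = {}
        for chrom, L in genomes[glabel].chroms.items():
            d, s = _plant_dyads(rng, nrl, L, cfg)
            planted_dyads[key][chrom] = d
            dyad_sigma[key][chrom] = s

    expression = _plant_expression(cfg)
    truth = ScenarioTruth(
        planted_nrl=planted_nrl,
        planted_dyads=planted_dyads,
        dyad_sigma=dyad_sigma,
        planted_acrs=acrs,
        acr_track_scale={k: float(cfg.acr_track_scale.get(k, 1.0)) for k in TRACK_KEYS},
        planted_expression=expression,
        dispersion=cfg.dispersion,
    )
    scenario = Scenario(
        genomes=genomes,
        genes=genes,
        tes=tes,
        samples=default_samples(cfg),
        seed=cfg.seed,
        config=cfg,
    )
    return scenario, truth


# ---------------------------------------------------------------------------
# expression truth


def _plant_expression(cfg: ScenarioConfig) -> pd.DataFrame:
    rng = np.random.default_rng(_child_seed(cfg.seed, "expression"))
    n = cfg.n_ogs
    eff = cfg.effect_size

    ct_names = list(cfg.cistrans_proportions)
    ct_p = np.array([cfg.cistrans_proportions[k] for k in ct_names], dtype=float)
    ct_p /= ct_p.sum()
    cistrans = np.array(ct_names)[rng.choice(len(ct_names), size=n, p=ct_p)]

    sign = rng.choice([-1.0, 1.0], size=n)
    sign2 = rng.choice([-1.0, 1.0], size=n)
    A = np.zeros(n)
    B = np.zeros(n)
    for i, cat in enumerate(cistrans):
        if cat == "cis_only":
            A[i] = sign[i] * eff
            B[i] = A[i]
        elif cat == "trans_only":
            A[i] = sign[i] * eff
            B[i] = 0.0
        elif cat == "compensatory":
            A[i] = 0.0
            B[i] = sign[i] * eff
        elif cat == "cis_trans_enhancing":
            # A = B + (A - B), sign(B) == sign(A - B)
            B[i] = sign[i] * eff
            A[i] = B[i] + sign[i] * eff
        elif cat == "cis_trans_compensating":
            B[i] = sign[i] * 2 * eff
            A[i] = B[i] - sign[i] * eff  # A - B opposite sign to B, still != 0
        # conserved: A = B = 0

    inh_names = list(cfg.inheritance_proportions)
    inh_p = np.array([cfg.inheritance_proportions[k] for k in inh_names], dtype=float)
    inh_p /= inh_p.sum()

    def draw_inheritance(a_val):
        while True:
            cat = inh_names[int(rng.choice(len(inh_names), p=inh_p))]
            if cat in ("ELD_A", "ELD_D") and a_val == 0.0:
                continue  # dominance toward one parent needs parental divergence
            return cat

    inh_f1 = np.array([draw_inheritance(a) for a in A], dtype=object)
    inh_ad1 = np.array([draw_inheritance(a) for a in A], dtype=object)

    lo, hi = cfg.base_mean_range
    gm = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    mean_a2 = gm * 2.0 ** (A / 2)
    mean_d5 = gm * 2.0 ** (-A / 2)

    def total_for(cat, a2, d5):
        mid = (a2 + d5) / 2
        if cat == "additive":
            return mid
        if cat == "ELD_A":
            return a2
        if cat == "ELD_D":
            return d5
        if cat == "transgressive_up":
            return cfg.transgressive_factor * max(a2, d5)
        if cat == "transgressive_down":
            return min(a2, d5) / cfg.transgressive_factor
        raise ValueError(cat)

    total_f1 = np.array([total_for(c, a, d) for c, a, d in zip(inh_f1, mean_a2, mean_d5)])
    total_ad1 = np.array([total_for(c, a, d) for c, a, d in zip(inh_ad1, mean_a2, mean_d5)])

    wr = np.where(rng.random(n) < cfg.wr_fraction, sign2 * eff, 0.0)
    Bp = B + wr

    r_f1 = 2.0 ** B
    f1_at = total_f1 * r_f1 / (1 + r_f1)
    f1_dt = total_f1 / (1 + r_f1)
    r_ad1 = 2.0 ** Bp
    ad1_at = total_ad1 * r_ad1 / (1 + r_ad1)
    ad1_dt = total_ad1 / (1 + r_ad1)

    df = pd.DataFrame(
        {
            "og_id": [f"OG{i + 1:05d}" for i in range(n)],
            "mean_A2": mean_a2,
            "mean_D5": mean_d5,
            "mean_F1_At": f1_at,
            "mean_F1_Dt": f1_dt,
            "mean_AD1_At": ad1_at,
            "mean_AD1_Dt": ad1_dt,
            "A": A,
            "B": B,
            "Bp": Bp,
            "Hr": B - A,
            "Pr": Bp - A,
            "Wr": Bp - B,
            "inheritance_F1": inh_f1,
            "inheritance_AD1": inh_ad1,
            "cistrans": cistrans,
        }
    ).set_index("og_id")
    _check_expression_truth(df, cfg)
    return df


def _check_expression_truth(df: pd.DataFrame, cfg: ScenarioConfig) -> None:
    """Self-consistency: re-derive every planted label from the planted means."""
    mid = (df["mean_A2"] + df["mean_D5"]) / 2
    for genotype in ("F1", "AD1"):
        total = df[f"mean_{genotype}_At"] + df[f"mean_{genotype}_Dt"]
        for og, cat in df[f"inheritance_{genotype}"].items():
            t, a2, d5, m = total[og], df.at[og, "mean_A2"], df.at[og, "mean_D5"], mid[og]
            ok = {
                "additive": np.isclose(t, m),
                "ELD_A": np.isclose(t, a2) and not np.isclose(a2, d5),
                "ELD_D": np.isclose(t, d5) and not np.isclose(a2, d5),
                "transgressive_up": t > max(a2, d5) * 1.001,
                "transgressive_down": t < min(a2, d5) * 0.999,
            }[cat]
            if not ok:
                raise ValueError(
                    f"planted {genotype} inheritance {cat!r} for {og} is inconsistent "
                    f"with its planted means (total={t:.3g}, A2={a2:.3g}, D5={d5:.3g})"
                )
    if not np.allclose(df["Hr"] + df["Wr"], df["Pr"]):
        raise ValueError("planted Hr + Wr != Pr")
    realized_b = np.log2(df["mean_F1_At"] / df["mean_F1_Dt"])
    if not np.allclose(realized_b, df["B"], atol=1e-9):
        raise ValueError("planted homoeolog means do not realize B")


# ---------------------------------------------------------------------------
# fragment sampling


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _fragments_from_midpoints(mids, lengths, L):
    mids = np.asarray(np.rint(mids), dtype=np.int64)
    lengths = np.asarray(np.rint(lengths), dtype=np.int64)
    starts = mids - lengths // 2
    starts = np.clip(starts, 0, np.maximum(L - lengths, 0))
    return np.column_stack([starts, starts + lengths])


def sample_fragments(scenario: Scenario, truth: ScenarioTruth, sample: SampleSpec, seed: int) -> FragmentSet:
    """Draw one library's fragments from the planted chromatin structure."""
    cfg = scenario.config
    if sample.n_fragments <= 0:
        raise ValueError("sample with zero fragment count")
    key = sample.track_key
    glabel = track_genome(key)
    if glabel not in scenario.genomes:
        raise ValueError(f"unknown genome label {glabel!r}")
    genome = scenario.genomes[glabel]
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.chroms)
    lengths = np.array([genome.chroms[c] for c in chroms], dtype=float)
    per_chrom = rng.multinomial(sample.n_fragments, lengths / lengths.sum())
    scale = truth.acr_track_scale.get(key, 1.0)
    lo, hi = cfg.heavy_length_range
    slo, shi = cfg.small_length_range
    frags = {}
    for chrom, n in zip(chroms, per_chrom):
        L = genome.chroms[chrom]
        dyads = truth.planted_dyads[key][chrom]
        sigma = truth.dyad_sigma[key][chrom]
        acr_list = [a for a in truth.planted_acrs[glabel] if a.chrom == chrom]
        acr_mask = intervals_to_mask([(a.start, a.end) for a in acr_list], L)
        parts = []

        n_small = 0
        if sample.digestion == "light":
            n_small = rng.binomial(n, cfg.light_small_fraction)
        n_mono = n - n_small
        n_bg = rng.binomial(n_mono, cfg.background_fraction)
        n_dyad = n_mono - n_bg

        if n_dyad > 0 and len(dyads) > 0:
            idx = rng.integers(0, len(dyads), size=n_dyad)
            mids = dyads[idx] + rng.normal(0.0, sigma[idx])
            if sample.digestion == "light":
                # fragile nucleosomes: mononucleosome recovery drops inside ACRs
                pos = np.clip(np.rint(mids), 0, L - 1).astype(np.int64)
                inside = acr_mask[pos]
                keep = ~inside | (rng.random(n_dyad) < cfg.fragile_depletion)
                mids = mids[keep]
            lens = _truncated_normal(
                rng, cfg.heavy_length_mean, cfg.heavy_length_sd, lo, hi, len(mids)
            )
            parts.append(_fragments_from_midpoints(mids, lens, L))
        if n_bg > 0:
            mids = rng.uniform(0, L, size=n_bg)
            lens = _truncated_normal(rng, cfg.heavy_length_mean, cfg.heavy_length_sd, lo, hi, n_bg)
            parts.append(_fragments_from_midpoints(mids, lens, L))
        if n_small > 0:
            # midpoint density: 1 unit genome-wide background plus
            # (strength - 1) extra units inside each planted ACR
            extra = np.array(
                [max(a.strength * scale - 1.0, 0.0) * (a.end - a.start) for a in acr_list]
            )
            weights = np.r_[float(L), extra]
            cum = np.cumsum(weights / weights.sum())
            u = rng.random(n_small)
            which = np.searchsorted(cum, u)
            mids = np.empty(n_small)
            bg = which == 0
            mids[bg] = rng.uniform(0, L, size=int(bg.sum()))
            for j, a in enumerate(acr_list, start=1):
                sel = which == j
                if sel.any():
                    mids[sel] = rng.uniform(a.start, a.end, size=int(sel.sum()))
            lens = rng.integers(slo, shi + 1, size=n_small)
            parts.append(_fragments_from_midpoints(mids, lens, L))
        frags[chrom] = (
            np.concatenate(parts) if parts else np.empty((0, 2), dtype=np.int64)
        )
    return FragmentSet(
        fragments=frags,
        chrom_lengths=dict(genome.chroms),
        genotype=sample.genotype,
        subgenome=sample.subgenome,
        digestion=sample.digestion,
        replicate=sample.replicate,
    )


# ---------------------------------------------------------------------------
# expression counts


def _nb_draw(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(truth: ScenarioTruth, reps: int, lib_size: int | None = None, seed: int = 0, library_jitter: float = 0.1) -> ExpressionData:
    """Negative-binomial counts realizing the planted expression truth.

    Counts are NB(mean * library factor, dispersion); library factors jitter
    +-``library_jitter`` around 1 (and around ``lib_size`` / sum-of-means when
    ``lib_size`` is given).  F1 and AD1 produce separate At and Dt homoeolog
    rows that realize the planted B and Bp log2 ratios exactly in expectation.
    """
    if reps < 2:
        raise ValueError("at least 2 replicates required")
    if truth.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    expr = truth.planted_expression
    slot_mean = {slot: expr[f"mean_{slot}"].to_numpy() for slot in OG_SLOTS}
    gene_ids = {slot: [f"{og}.{slot}" for og in expr.index] for slot in OG_SLOTS}
    genotype_slots = {
        "A2": ("A2",),
        "D5": ("D5",),
        "F1": ("F1_At", "F1_Dt"),
        "AD1": ("AD1_At", "AD1_Dt"),
    }
    cols, col_meta = {}, []
    for genotype, slots in genotype_slots.items():
        base = np.concatenate([slot_mean[s] for s in slots])
        for rep in range(1, reps + 1):
            factor = 1.0 + rng.uniform(-library_jitter, library_jitter)
            if lib_size is not None:
                factor *= lib_size / base.sum()
            name = f"{genotype}_r{rep}"
            cols[name] = _nb_draw(rng, base * factor, truth.dispersion)
            col_meta.append((name, genotype, rep, factor))
    index = pd.Index(
        [g for genotype, slots in genotype_slots.items() for s in slots for g in gene_ids[s]],
        name="gene_id",
    )
    # columns were drawn against per-genotype gene blocks; assemble aligned frame
    counts = pd.DataFrame(0, index=index, columns=[m[0] for m in col_meta], dtype=np.int64)
    for genotype, slots in genotype_slots.items():
        ids = [g for s in slots for g in gene_ids[s]]
        for name, gt, rep, factor in col_meta:
            if gt == genotype:
                counts.loc[ids, name] = cols[name]
    samples = pd.DataFrame(
        [(m[1], m[2], m[3]) for m in col_meta],
        index=pd.Index([m[0] for m in col_meta], name="sample_id"),
        columns=["genotype", "replicate", "lib_factor"],
    )
    ogs = pd.DataFrame(
        {slot: gene_ids[slot] for slot in OG_SLOTS},
        index=pd.Index(expr.index, name="og_id"),
    )
    return ExpressionData(counts=counts, samples=samples, ogs=ogs)
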