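"""ACR annotation: proximity/feature oracle, shuffles, GC, TE enrichment."""
import numpy as np
import pandas as pd
import pytest

from dnscape.annotation import (
    classify_acr,
    gc_content,
    shuffle_controls,
    te_enrichment,
)
from dnscape.core import GeneModel, PlacementError, TEInterval, intervals_to_mask


GENES = [
    GeneModel("c1", 5_000, 8_000, "+", "g1"),
    GeneModel("c1", 20_000, 24_000, "-", "g2"),
    GeneModel("c1", 40_000, 43_000, "+", "g3", exons=((40_000, 41_000), (42_000, 43_000))),
]
CHROMS = {"c1": 60_000}


def brute_force_classify(s, e, genes):
    """Independent re-derivation of proximity + feature labels."""
    gaps = {}
    for g in genes:
        if s < g.end and g.start < e:
            gaps[g.gene_id] = 0
        elif g.start >= e:
            gaps[g.gene_id] = g.start - e
        else:
            gaps[g.gene_id] = s - g.end
    min_gap = min(gaps.values()) if gaps else None
    if min_gap is None:
        return "distal", "intergenic"
    proximity = (
        "genic" if min_gap == 0 else ("proximal" if min_gap <= 2000 else "distal")
    )
    def tssd(g):
        if s <= g.tss < e:
            return 0
        return min(abs(g.tss - s), abs(g.tss - (e - 1)))
    cands = [g for g in genes if gaps[g.gene_id] < 3000]
    if not cands:
        return proximity, "intergenic"
    overlapping = [g for g in cands if gaps[g.gene_id] == 0]
    pool = overlapping if overlapping else cands
    best = min(pool, key=lambda g: (tssd(g), g.start))
    if gaps[best.gene_id] == 0:
        if not best.exons:
            return proximity, "exon"
        hit = any(s < ee and es < e for es, ee in best.exons)
        return proximity, "exon" if hit else "intron"
    gap = gaps[best.gene_id]
    before = e <= best.start
    side = ("promoter" if before else "downstream") if best.strand == "+" else (
        "downstream" if before else "promoter")
    for lo, hi, tag in ((0, 1000, "lt1kb"), (1000, 2000, "1to2kb"), (2000, 3000, "2to3kb")):
        if lo <= gap < hi:
            return proximity, f"{side}_{tag}"
    return proximity, "intergenic"


class TestClassifyAcr:
    def test_genic_exon_example(self):
        ann = classify_acr([("c1", 5_100, 5_200)], GENES)
        assert tuple(ann.iloc[0][["proximity", "feature"]]) == ("genic", "exon")

    def test_promoter_1to2kb_example(self):
        ann = classify_acr([("c1", 3_500, 3_600)], GENES)  # TSS gap 1,400
        assert tuple(ann.iloc[0][["proximity", "feature"]]) == ("proximal", "promoter_1to2kb")

    def test_intron_of_multi_exon_gene(self):
        ann = classify_acr([("c1", 41_200, 41_400)], GENES)
        assert tuple(ann.iloc[0][["proximity", "feature"]]) == ("genic", "intron")

    def test_minus_strand_promoter_side(self):
        # gene g2 is on the minus strand: its promoter lies right of 24,000
        ann = classify_acr([("c1", 24_200, 24_300)], GENES)
        assert ann.iloc[0]["feature"] == "promoter_lt1kb"

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            classify_acr([("c9", 0, 100)], GENES)

    def test_random_acrs_match_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        starts = rng.integers(0, 59_000, 1000)
        ends = starts + rng.integers(20, 800, 1000)
        ends = np.minimum(ends, 60_000)
        ann = classify_acr(pd.DataFrame({"chrom": "c1", "start": starts, "end": ends}), GENES)
        for row, s, e in zip(ann.itertuples(), starts, ends):
            prox, feat = brute_force_classify(int(s), int(e), GENES)
            assert (row.proximity, row.feature) == (prox, feat), (s, e)

    def test_proximity_partition(self):
        rng = np.random.default_rng(11)
        starts = rng.integers(0, 59_000, 300)
        ann = classify_acr(
            pd.DataFrame({"chrom": "c1", "start": starts, "end": starts + 100}), GENES
        )
        assert set(ann["proximity"]) <= {"genic", "proximal", "distal"}
        assert ann["proximity"].notna().all()


class TestShuffleControls:
    def test_forced_single_gap_placement(self):
        genes = [GeneModel("c1", 0, 2_000, "+", "g")]
        chroms = {"c1": 6_100}
        # distal space excludes gene +- 2 kb: only [4000, 6100) remains; a
        # 2,100 bp interval fits exactly one way
        shufs = shuffle_controls(
            [("c1", 0, 2_100)], "distal_space", genes, chroms, n=5, seed=1
        )
        for s in shufs:
            assert tuple(s.iloc[0][["start", "end"]]) == (4_000, 6_100)

    def test_no_overlap_with_forbidden_space(self):
        shufs = shuffle_controls(
            [("c1", 0, 150)] * 40, "distal_space", GENES, CHROMS, n=20, seed=2
        )
        forbidden = intervals_to_mask(
            [(max(0, g.start - 2000), g.end + 2000) for g in GENES], 60_000
        )
        for s in shufs:
            for r in s.itertuples():
                assert not forbidden[r.start:r.end].any()

    def test_genic_proximal_space_containment(self):
        shufs = shuffle_controls(
            [("c1", 0, 200)] * 20, "genic_proximal_space", GENES, CHROMS, n=10, seed=3
        )
        allowed = intervals_to_mask(
            [(max(0, g.start - 2000), g.end + 2000) for g in GENES], 60_000
        )
        for s in shufs:
            for r in s.itertuples():
                assert allowed[r.start:r.end].all()

    def test_length_multiset_and_chromosome_preserved(self):
        rng = np.random.default_rng(12)
        lengths = rng.integers(50, 400, 30)
        iv = [("c1", 0, int(l)) for l in lengths]
        shufs = shuffle_controls(iv, "distal_space", GENES, CHROMS, n=7, seed=4)
        for s in shufs:
            assert sorted(s["end"] - s["start"]) == sorted(lengths)
            assert (s["chrom"] == "c1").all()

    def test_deterministic_given_seed(self):
        a = shuffle_controls([("c1", 0, 100)] * 5, "distal_space", GENES, CHROMS, 3, seed=9)
        b = shuffle_controls([("c1", 0, 100)] * 5, "distal_space", GENES, CHROMS, 3, seed=9)
        for x, y in zip(a, b):
            assert x.equals(y)

    def test_infeasible_placement_raises(self):
        genes = [GeneModel("c1", 0, 50_000, "+", "g")]
        with pytest.raises(PlacementError):
            shuffle_controls([("c1", 0, 9_000)], "distal_space", genes, CHROMS, 1, seed=1)


class TestGcContent:
    def test_examples(self):
        seqs = {"c": "GGGGATATGANN"}
        assert gc_content([("c", 0, 4)], seqs)[0] == 1.0
        assert gc_content([("c", 4, 8)], seqs)[0] == 0.0
        assert gc_content([("c", 8, 12)], seqs)[0] == 0.5  # GANN: N excluded

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            gc_content([("c", 5, 5)], {"c": "ACGT" * 10})

    def test_matches_per_base_oracle(self, seq_scenario):
        scen, _ = seq_scenario
        seqs = scen.genomes["A"].sequence
        chrom = next(iter(seqs))
        rng = np.random.default_rng(13)
        starts = rng.integers(0, len(seqs[chrom]) - 500, 100)
        iv = [(chrom, int(s), int(s) + int(rng.integers(10, 500))) for s in starts]
        got = gc_content(iv, seqs)
        for (c, s, e), g in zip(iv, got):
            counts = {b: seqs[c][s:e].count(b) for b in "ACGT"}
            assert np.isclose(g, (counts["G"] + counts["C"]) / sum(counts.values()))


def _uniform_acrs(rng, n, width, chroms):
    rows = []
    names = sorted(chroms)
    for _ in range(n):
        c = names[int(rng.integers(len(names)))]
        s = int(rng.integers(0, chroms[c] - width))
        rows.append((c, s, s + width))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestTeEnrichment:
    CHROMS = {"c1": 400_000, "c2": 400_000}

    def _tes(self, seed=14, n=140, lo=1_500, hi=4_000):
        rng = np.random.default_rng(seed)
        tes = []
        sfs = ["Gypsy", "Copia", "Mutator", "hAT"]
        for _ in range(n):
            c = "c1" if rng.random() < 0.5 else "c2"
            L = int(rng.integers(lo, hi))
            s = int(rng.integers(0, self.CHROMS[c] - L))
            sf = sfs[int(rng.integers(len(sfs)))]
            tes.append(TEInterval(c, s, s + L, sf, f"{sf}-{int(rng.integers(1, 4))}"))
        return tes

    def test_null_enrichment_near_zero(self):
        # |enrichment| under uniform placement is O(1/sqrt(n_acrs * p)):
        # at 2,000 ACRs and p ~ 0.12 the per-superfamily noise is ~0.08 log2
        rng = np.random.default_rng(15)
        acrs = _uniform_acrs(rng, 2000, 200, self.CHROMS)
        res = te_enrichment(acrs, self._tes(), [], self.CHROMS, n_perm=200, seed=5)
        sf = res[res["level"] == "superfamily"]
        assert sf["enrichment"].abs().mean() <= 0.15

    def test_planted_depletion_recovered(self):
        rng = np.random.default_rng(16)
        tes = self._tes(seed=17, n=40, lo=2_000, hi=4_000)
        mask = {c: intervals_to_mask([(t.start, t.end) for t in tes if t.chrom == c], L)
                for c, L in self.CHROMS.items()}
        share = np.mean([m.mean() for m in mask.values()])
        rows = []
        while len(rows) < 1500:
            c = "c1" if rng.random() < 0.5 else "c2"
            s = int(rng.integers(50, self.CHROMS[c] - 150))
            if mask[c][s + 50] and rng.random() > 0.25:
                continue  # 4-fold thinning of placements inside TEs
            rows.append((c, s, s + 100))
        acrs = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        one_sf = [TEInterval(t.chrom, t.start, t.end, "TE", t.family) for t in tes]
        res = te_enrichment(acrs, one_sf, [], self.CHROMS, n_perm=400, seed=6)
        enr = res[res["level"] == "superfamily"].iloc[0]["enrichment"]
        expected = np.log2(0.25 / (1 - 0.75 * share))  # thinning-model oracle
        assert abs(enr - expected) < 0.25

    def test_whole_genome_family_enrichment_zero(self):
        tes = [TEInterval("c1", 0, 400_000, "ALL", "ALL-1"),
               TEInterval("c2", 0, 400_000, "ALL", "ALL-1")]
        rng = np.random.default_rng(18)
        acrs = _uniform_acrs(rng, 50, 100, self.CHROMS)
        res = te_enrichment(acrs, tes, [], self.CHROMS, n_perm=50, seed=7)
        fam = res[res["level"] == "family"].iloc[0]
        assert fam["enrichment"] == 0.0  # observed == expected == 1

    def test_enrichment_sign_flips_with_planting(self):
        tes = self._tes(seed=19, n=40)
        mask = {c: intervals_to_mask([(t.start, t.end) for t in tes if t.chrom == c], L)
                for c, L in self.CHROMS.items()}
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            signs = {}
            for mode, keep_in in (("deplete", 0.25), ("enrich", 1.0)):
                rows = []
                while len(rows) < 400:
                    c = "c1" if rng.random() < 0.5 else "c2"
                    s = int(rng.integers(50, self.CHROMS[c] - 150))
                    inside = bool(mask[c][s + 50])
                    if mode == "deplete" and inside and rng.random() > keep_in:
                        continue
                    if mode == "enrich" and not inside and rng.random() > 0.25:
                        continue
                    rows.append((c, s, s + 100))
                one = [TEInterval(t.chrom, t.start, t.end, "TE", t.family) for t in tes]
                res = te_enrichment(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                                    one, [], self.CHROMS, n_perm=150, seed=8 + seed)
                signs[mode] = res[res["level"] == "superfamily"].iloc[0]["enrichment"]
            assert signs["deplete"] < 0 < signs["enrich"]

    def test_permutation_p_in_unit_interval(self):
        rng = np.random.default_rng(20)
        acrs = _uniform_acrs(rng, 100, 150, self.CHROMS)
        res = te_enrichment(acrs, self._tes(), [], self.CHROMS, n_perm=99, seed=9)
        sf = res[res["level"] == "superfamily"]
        assert ((sf["p_perm"] > 0) & (sf["p_perm"] <= 1)).all()
        fam = res[res["level"] == "family"]
        assert ((fam["p_hypergeom"] > 0) & (fam["p_hypergeom"] <= 1)).all()
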