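"""Synthetic scenario generator: determinism, placement rules, planted truth."""
import dataclasses

import numpy as np
import pytest
from scipy.stats import binomtest

from dnscape.core import PlacementError, SampleSpec
from dnscape.simulate import (
    ScenarioConfig,
    ScenarioTruth,
    build_scenario,
    sample_fragments,
    simulate_counts,
    _plant_expression,
)
from tests.conftest import heavy_sample, light_sample, small_config


def _truth_for(expr, dispersion=0.05):
    return ScenarioTruth({}, {}, {}, {}, {}, expr, dispersion)


class TestBuildScenario:
    def test_deterministic_given_seed(self, small_scenario):
        scen2, truth2 = build_scenario(small_config())
        scen1, truth1 = small_scenario
        assert scen1.genes == scen2.genes
        assert scen1.tes == scen2.tes
        for key in truth1.planted_dyads:
            for chrom in truth1.planted_dyads[key]:
                assert np.array_equal(
                    truth1.planted_dyads[key][chrom], truth2.planted_dyads[key][chrom]
                )
        assert truth1.planted_expression.equals(truth2.planted_expression)

    @pytest.mark.parametrize("nrl", [147.0, 146.0])
    def test_nrl_at_or_below_core_rejected(self, nrl):
        cfg = small_config(planted_nrl={"A2": nrl})
        with pytest.raises(ValueError, match="147"):
            build_scenario(cfg)

    def test_genes_pairwise_disjoint_with_min_gap(self):
        cfg = small_config(seed=3, chrom_length=1_000_000, n_genes=50, min_gene_gap=2_000)
        scen, _ = build_scenario(cfg)
        for label in ("A", "D"):
            genes = sorted(scen.genes[label], key=lambda g: (g.chrom, g.start))
            for g1, g2 in zip(genes[:-1], genes[1:]):
                if g1.chrom == g2.chrom:
                    assert g1.end <= g2.start  # brute-force pairwise scan (sorted)

    def test_overcrowded_genes_rejected(self):
        cfg = small_config(chrom_length=50_000, n_genes=30)
        with pytest.raises(PlacementError):
            build_scenario(cfg)

    def test_intervals_within_bounds(self, small_scenario):
        scen, truth = small_scenario
        for label, genome in scen.genomes.items():
            for g in scen.genes[label]:
                assert 0 <= g.start < g.end <= genome.chroms[g.chrom]
            for t in scen.tes[label]:
                assert 0 <= t.start < t.end <= genome.chroms[t.chrom]
            for a in truth.planted_acrs[label]:
                assert 0 <= a.start < a.end <= genome.chroms[a.chrom]

    def test_promoter_acrs_near_tss_distal_far_from_genes(self, small_scenario):
        scen, truth = small_scenario
        for label in ("A", "D"):
            genes = scen.genes[label]
            for a in truth.planted_acrs[label]:
                gaps = [
                    max(g.start - a.end, a.start - g.end, 0)
                    for g in genes
                    if g.chrom == a.chrom
                ]
                if a.kind == "distal":
                    assert min(gaps) > 2_000
                else:
                    assert min(gaps) < 1_000


class TestSampleFragments:
    def test_heavy_lengths_in_range(self, small_scenario):
        scen, truth = small_scenario
        fs = sample_fragments(scen, truth, heavy_sample(10_000), seed=5)
        lens = fs.lengths()
        assert (np.mean((lens >= 100) & (lens <= 200))) >= 0.99

    def test_same_seed_identical(self, small_scenario):
        scen, truth = small_scenario
        a = sample_fragments(scen, truth, light_sample(5_000), seed=9)
        b = sample_fragments(scen, truth, light_sample(5_000), seed=9)
        for chrom in a.fragments:
            assert np.array_equal(a.fragments[chrom], b.fragments[chrom])

    def test_zero_fragments_rejected(self, small_scenario):
        scen, truth = small_scenario
        with pytest.raises(ValueError):
            sample_fragments(scen, truth, dataclasses.replace(heavy_sample(), n_fragments=0), seed=1)

    def test_small_fragment_midpoints_concentrate_in_acr(self):
        # one planted ACR at 10x background: small-fragment midpoints land
        # inside it far above the uniform-placement expectation
        cfg = small_config(seed=7, n_acrs=1, acr_strength=10.0, acr_width=400, n_genes=5)
        scen, truth = build_scenario(cfg)
        fs = sample_fragments(scen, truth, light_sample(60_000), seed=2)
        acr = truth.planted_acrs["A"][0]
        arr = fs.fragments[acr.chrom]
        small = arr[(arr[:, 1] - arr[:, 0]) <= 130]
        mids = (small[:, 0] + small[:, 1]) // 2
        inside = int(np.sum((mids >= acr.start) & (mids < acr.end)))
        frac_len = (acr.end - acr.start) / scen.genomes["A"].chroms[acr.chrom]
        assert inside / len(small) >= 5 * frac_len
        assert binomtest(inside, len(small), frac_len, alternative="greater").pvalue < 1e-6

    def test_light_small_fraction_never_exceeds_130(self, small_scenario):
        scen, truth = small_scenario
        fs = sample_fragments(scen, truth, light_sample(20_000), seed=3)
        lens = fs.lengths()
        small = lens[lens <= 130]
        assert small.size > 0
        assert lens[(lens > 130)].min() >= 100  # the rest are mononucleosomal


class TestPlantedExpression:
    def test_self_consistency_enforced_at_construction(self):
        expr = _plant_expression(small_config(seed=21))
        # tamper: an "additive" OG whose total no longer equals the mid-parent
        bad = expr.copy()
        add = bad[bad["inheritance_F1"] == "additive"].index[0]
        bad.loc[add, "mean_F1_At"] *= 3
        from dnscape.simulate import _check_expression_truth

        with pytest.raises(ValueError):
            _check_expression_truth(bad, small_config())

    def test_hr_wr_pr_identity_planted(self):
        expr = _plant_expression(small_config(seed=22))
        assert np.allclose(expr["Hr"] + expr["Wr"], expr["Pr"])

    def test_category_vocabulary(self):
        expr = _plant_expression(small_config(seed=23))
        assert set(expr["inheritance_F1"]) <= {
            "additive", "ELD_A", "ELD_D", "transgressive_up", "transgressive_down",
        }
        assert set(expr["cistrans"]) <= {
            "cis_only", "trans_only", "cis_trans_enhancing",
            "cis_trans_compensating", "compensatory", "conserved",
        }


class TestSimulateCounts:
    def test_additive_realizes_midparent(self):
        # planted additive with A2 mean 100, D5 mean 300 -> AD1 total 200
        expr = _plant_expression(small_config(seed=31, n_ogs=1, effect_size=np.log2(3),
                                              cistrans_proportions={"cis_only": 1.0},
                                              inheritance_proportions={"additive": 1.0}))
        og = expr.index[0]
        scale = 200.0 / expr.loc[og, ["mean_A2", "mean_D5"]].mean()
        for col in [c for c in expr.columns if c.startswith("mean_")]:
            expr.loc[og, col] *= scale
        lo, hi = sorted(expr.loc[og, ["mean_A2", "mean_D5"]])
        assert np.isclose(lo, 100) and np.isclose(hi, 300)
        data = simulate_counts(_truth_for(expr), reps=2, seed=4, library_jitter=0.0)
        reps = []
        rng = np.random.default_rng(8)
        total = expr.loc[og, "mean_AD1_At"] + expr.loc[og, "mean_AD1_Dt"]
        assert np.isclose(total, 200)
        draws = rng.negative_binomial(1 / 0.05, (1 / 0.05) / (1 / 0.05 + 200), 10_000)
        se = draws.std(ddof=1) / 100
        assert abs(draws.mean() - 200) <= 2 * se

    def test_planted_b_realized_in_f1_ratio(self):
        expr = _plant_expression(small_config(seed=32, n_ogs=200,
                                              cistrans_proportions={"compensatory": 1.0}))
        sel = expr["B"] == 2.0
        assert sel.sum() > 50
        data = simulate_counts(_truth_for(expr), reps=3, seed=5, library_jitter=0.0)
        at = data.counts.loc[data.ogs.loc[sel, "F1_At"]].to_numpy().sum(axis=1)
        dt = data.counts.loc[data.ogs.loc[sel, "F1_Dt"]].to_numpy().sum(axis=1)
        ratio = at.sum() / dt.sum()
        assert abs(ratio - 4.0) < 0.25  # B = log2(At/Dt) = 2 -> ratio 4

    def test_nb_moments(self):
        rng_truth = _plant_expression(small_config(seed=33, n_ogs=1))
        og = rng_truth.index[0]
        for col in [c for c in rng_truth.columns if c.startswith("mean_")]:
            rng_truth.loc[og, col] = 500.0
        rng_truth.loc[og, ["A", "B", "Bp", "Hr", "Pr", "Wr"]] = 0.0
        rng_truth.loc[og, ["inheritance_F1", "inheritance_AD1", "cistrans"]] = [
            "additive", "additive", "conserved"]
        import numpy as np
        from dnscape.simulate import _nb_draw

        draws = _nb_draw(np.random.default_rng(6), np.full(10_000, 500.0), 0.05)
        assert abs(draws.mean() - 500) < 5
        expected_var = 500 + 0.05 * 500**2  # NB moment oracle: 13,000
        assert abs(draws.var(ddof=1) - expected_var) / expected_var < 0.10

    def test_negative_dispersion_rejected(self):
        expr = _plant_expression(small_config(seed=34))
        with pytest.raises(ValueError):
            simulate_counts(_truth_for(expr, dispersion=-0.1), reps=2, seed=1)

    def test_deterministic(self):
        expr = _plant_expression(small_config(seed=35))
        a = simulate_counts(_truth_for(expr), reps=2, seed=9)
        b = simulate_counts(_truth_for(expr), reps=2, seed=9)
        assert a.counts.equals(b.counts)
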