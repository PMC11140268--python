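"""BH correction, TMM factors, NB Wald tests and windowed DA."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnscape.count_stats import (
    bh_adjust,
    nb_interaction_test,
    nb_test,
    tmm_factors,
    window_da,
)
from tests.conftest import mk_fragset

GROUPS_3V3 = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}


def bh_oracle(p):
    """Brute-force step-up: q_i = min over j>=rank(i) of p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


class TestBH:
    def test_closed_form_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(500)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_monotone_in_p_order(self, p):
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestTMM:
    def _counts(self, seed=2, n=2000):
        rng = np.random.default_rng(seed)
        mu = np.exp(rng.uniform(np.log(20), np.log(500), n))
        return pd.DataFrame(
            {f"s{i}": rng.poisson(mu) for i in range(4)}
        )

    def test_identical_samples_unit_factors(self):
        c = self._counts()
        c = pd.DataFrame({f"s{i}": c["s0"] for i in range(3)})
        assert np.allclose(tmm_factors(c), 1.0)

    def test_pure_depth_shift_compensated(self):
        c = self._counts()
        c["s1"] = 2 * c["s0"]
        f = tmm_factors(c[["s0", "s1"]])
        lib = c[["s0", "s1"]].sum()
        norm = c[["s0", "s1"]] / (lib * f)
        assert np.allclose(norm["s0"], norm["s1"], rtol=1e-6)

    def test_scale_invariance(self):
        c = self._counts(seed=3)
        assert np.allclose(tmm_factors(c), tmm_factors(7 * c))

    def test_planted_de_factors_match_null_subset_oracle(self):
        rng = np.random.default_rng(4)
        n = 2000
        mu = np.exp(rng.uniform(np.log(50), np.log(500), n))
        de = np.zeros(n, bool)
        de[: n // 5] = True  # 20% of units 4x up in sample B
        a = rng.poisson(mu)
        b = rng.poisson(mu * np.where(de, 4.0, 1.0))
        counts = pd.DataFrame({"A": a, "B": b})
        f = tmm_factors(counts)
        # oracle: after normalization the known-null units must match, so the
        # effective-size ratio equals the null-unit total-count ratio (~1)
        null = counts[~de]
        expected = null["B"].sum() / null["A"].sum()
        lib = counts.sum()
        got_ratio = (lib["B"] * f["B"]) / (lib["A"] * f["A"])
        assert abs(got_ratio / expected - 1) < 0.05

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(pd.DataFrame({"a": [0, 0], "b": [1, 2]}))


class TestNbTest:
    def test_type_one_error_on_poisson_null(self):
        rng = np.random.default_rng(5)
        mu = np.exp(rng.uniform(np.log(50), np.log(500), 2000))
        counts = pd.DataFrame(rng.poisson(mu[:, None], (2000, 6)), columns=list(GROUPS_3V3))
        res = nb_test(counts, GROUPS_3V3, ("g1", "g2"))
        rate = float(np.mean(res["wald_p"] < 0.05))
        assert 0.03 <= rate <= 0.07

    def test_power_at_planted_lfc2(self):
        rng = np.random.default_rng(6)
        n, r = 2000, 1 / 0.05
        de = rng.random(n) < 0.2
        m1 = np.full(n, 200.0)
        m2 = np.where(de, 800.0, 200.0)
        c1 = rng.negative_binomial(r, r / (r + m1[:, None]), (n, 3))
        c2 = rng.negative_binomial(r, r / (r + m2[:, None]), (n, 3))
        counts = pd.DataFrame(np.hstack([c1, c2]), columns=list(GROUPS_3V3))
        res = nb_test(counts, GROUPS_3V3, ("g1", "g2"))
        assert res.loc[de, "significant"].mean() >= 0.9
        assert res.loc[~de, "significant"].mean() <= 0.05

    def test_lfc_sign_matches_normalized_mean_ratio(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.poisson(100, (300, 6)), columns=list(GROUPS_3V3))
        res = nb_test(counts, GROUPS_3V3, ("g1", "g2"))
        from dnscape.count_stats import effective_sizes

        norm = counts / effective_sizes(counts)
        ratio = norm[[c for c, g in GROUPS_3V3.items() if g == "g1"]].mean(1) / \
            norm[[c for c, g in GROUPS_3V3.items() if g == "g2"]].mean(1)
        same = np.sign(res["log2fc"]) == np.sign(np.log2(ratio.loc[res.index]))
        assert (same | (res["log2fc"] == 0)).all()

    def test_all_zero_units_excluded_and_reported(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.poisson(50, (20, 6)), columns=list(GROUPS_3V3))
        counts.iloc[3] = 0
        counts.iloc[7] = 0
        res = nb_test(counts, GROUPS_3V3, ("g1", "g2"))
        assert len(res) == 18
        assert sorted(res.attrs["excluded"]) == [3, 7]

    def test_agrees_with_deseq2_on_strong_effects(self):
        """Independent oracle: DESeq2 calls the same strong planted effects."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(9)
        n, r = 400, 1 / 0.05
        de = np.zeros(n, bool)
        de[:80] = True
        m1 = np.full(n, 300.0)
        m2 = np.where(de, 1200.0, 300.0)
        c1 = rng.negative_binomial(r, r / (r + m1[:, None]), (n, 3))
        c2 = rng.negative_binomial(r, r / (r + m2[:, None]), (n, 3))
        counts = pd.DataFrame(np.hstack([c1, c2]), columns=list(GROUPS_3V3),
                              index=[f"u{i}" for i in range(n)])
        res = nb_test(counts, GROUPS_3V3, ("g2", "g1"))
        meta = pd.DataFrame({"condition": ["g1"] * 3 + ["g2"] * 3}, index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "g2", "g1"], quiet=True)
        stats.summary()
        ds = stats.results_df
        agree = (ds["padj"] < 0.05) == res["significant"]
        assert agree.loc[de].mean() >= 0.95
        assert np.corrcoef(ds["log2FoldChange"], res["log2fc"])[0, 1] > 0.98

    def test_interaction_contrast_recovers_ratio_of_ratios(self):
        rng = np.random.default_rng(10)
        n = 500
        groups = {f"s{i}": g for i, g in enumerate(
            ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3)}
        lfc_int = np.where(rng.random(n) < 0.1, 2.0, 0.0)
        mu = {"a": 200 * 2.0 ** lfc_int, "b": 200.0 * np.ones(n),
              "c": 200.0 * np.ones(n), "d": 200.0 * np.ones(n)}
        r = 1 / 0.05
        cols = {}
        for i, (c, g) in enumerate(groups.items()):
            m = np.broadcast_to(mu[g], n)
            cols[c] = rng.negative_binomial(r, r / (r + m))
        counts = pd.DataFrame(cols)
        res = nb_interaction_test(counts, groups, (("a", "b"), ("c", "d")))
        planted = lfc_int > 0
        assert res.loc[planted, "significant"].mean() >= 0.85
        assert abs(res.loc[planted, "log2fc"].mean() - 2.0) < 0.15
        assert res.loc[~planted, "significant"].mean() <= 0.05


class TestWindowDA:
    def _fragsets(self, rates, length=100_000, n=20_000, seed=0):
        """rates: {(genotype, digestion, rep): per-base density array or None}."""
        rng = np.random.default_rng(seed)
        sets = []
        for (gt, dig, rep), dens in rates.items():
            if dens is None:
                mids = rng.integers(100, length - 100, n)
            else:
                p = dens / dens.sum()
                mids = rng.choice(length, size=n, p=p)
            arr = np.column_stack([mids - 40, mids + 40])
            sets.append(mk_fragset(arr, length=length, genotype=gt,
                                   digestion=dig, replicate=rep))
        return sets

    def test_null_false_discoveries_controlled(self):
        total_sig = 0
        total_windows = 0
        for seed in range(5):
            rates = {(gt, dig, rep): None for gt in ("F1", "A2")
                     for dig in ("light", "heavy") for rep in (1, 2)}
            sets = self._fragsets(rates, seed=seed)
            res = window_da(sets, "hybridization", window=500)
            total_sig += int(res.windows["significant"].sum())
            total_windows += len(res.windows)
        assert total_sig <= max(5, 0.05 * total_windows * 1.5)

    def test_planted_doubled_light_region_recovered(self):
        length = 100_000
        dens = np.ones(length)
        dens[40_000:45_000] = 2.0  # light signal doubles in F1 only
        rates = {}
        for gt in ("F1", "A2"):
            for dig in ("light", "heavy"):
                for rep in (1, 2):
                    boost = dens if (gt == "F1" and dig == "light") else None
                    rates[(gt, dig, rep)] = boost
        sets = self._fragsets(rates, n=60_000, seed=3)
        res = window_da(sets, "hybridization", window=500)
        inc = res.regions.query("direction == 'increase'")
        covered = 0
        for r in inc.itertuples():
            covered += max(0, min(r.end, 45_000) - max(r.start, 40_000))
        assert covered >= 0.8 * 5_000

    def test_label_swap_flips_directions(self):
        import dataclasses

        length = 50_000
        dens = np.ones(length)
        dens[10_000:14_000] = 3.0
        rates = {}
        for dig in ("light", "heavy"):
            for rep in (1, 2):
                rates[("AD1", dig, rep)] = dens if dig == "light" else None
                rates[("F1", dig, rep)] = None
        sets = self._fragsets(rates, length=length, n=40_000, seed=4)
        swap = {"AD1": "F1", "F1": "AD1"}
        swapped = [dataclasses.replace(fs, genotype=swap[fs.genotype]) for fs in sets]
        a = window_da(sets, "polyploidization", window=500)
        b = window_da(swapped, "polyploidization", window=500)
        assert a.bp_increase > 0 and a.bp_decrease == 0
        assert b.bp_decrease > 0 and b.bp_increase == 0
        assert a.bp_increase == b.bp_decrease  # identical fragments, labels swapped
        merged = a.regions.reset_index(drop=True)
        flipped = b.regions.assign(
            direction=b.regions["direction"].map({"increase": "decrease", "decrease": "increase"})
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, flipped)

    def test_missing_digestion_rejected(self):
        sets = self._fragsets({("F1", "light", 1): None, ("F1", "light", 2): None})
        with pytest.raises(ValueError, match="digestion"):
            window_da(sets, "light_vs_heavy_within")
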