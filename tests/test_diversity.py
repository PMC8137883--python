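"""Rarefaction against the hypergeometric closed form, turnover, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from sedarich.diversity import (
    depth_richness_correlation,
    rarefied_richness,
    rarefy_counts,
    within_family_richness,
    zonal_turnover,
)

from conftest import random_table


def expected_richness(counts, depth):
    """Independent oracle: E[richness] = sum_i 1 - C(N-N_i, n)/C(N, n).

    The binomial ratio equals the hypergeometric probability of drawing
    zero reads of taxon i, evaluated stably for large totals.
    """
    from scipy.stats import hypergeom

    counts = np.asarray(counts)
    N = counts.sum()
    return float(sum(1.0 - hypergeom.pmf(0, N, c, depth) for c in counts if c > 0))


class TestRarefyCounts:
    def test_full_depth_is_identity(self):
        rng = np.random.default_rng(0)
        counts = np.array([5, 0, 12, 3])
        out = rarefy_counts(counts, counts.sum(), rng)
        assert np.array_equal(out, counts)

    def test_depth_zero_gives_empty_sample(self):
        rng = np.random.default_rng(0)
        out = rarefy_counts(np.array([5, 5]), 0, rng)
        assert out.sum() == 0

    def test_depth_above_total_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            rarefy_counts(np.array([2, 2]), 5, rng)

    def test_two_taxon_expectation(self):
        # {A:5, B:5} at depth 2: E[richness] = 2*(1 - C(8,2)/C(10,2)) = 14/9
        rng = np.random.default_rng(42)
        draws = [(rarefy_counts(np.array([5, 5]), 2, rng) > 0).sum() for _ in range(20000)]
        assert abs(np.mean(draws) - 14 / 9) < 0.02
        assert abs(expected_richness([5, 5], 2) - 14 / 9) < 1e-12

    def test_fixed_seed_reproducible(self):
        counts = np.array([40, 7, 0, 93, 11])
        a = rarefy_counts(counts, 50, np.random.default_rng(123))
        b = rarefy_counts(counts, 50, np.random.default_rng(123))
        assert np.array_equal(a, b)


class TestRarefiedRichness:
    def test_mean_matches_closed_form(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, n_taxa=10, n_samples=4, depth=400)
        rich = rarefied_richness(table, reps=100, rng=np.random.default_rng(2))
        pooled = table.sediment_pooled()
        depth = int(pooled.sum(axis=0).min())
        for sample in pooled.columns:
            exp = expected_richness(pooled[sample].to_numpy(), depth)
            # Monte-Carlo standard error of the mean at 100 reps
            se = max(np.sqrt(exp) / np.sqrt(100), 0.05)
            assert abs(rich.loc[sample, "richness"] - exp) < 3 * se

    def test_sample_at_base_depth_has_zero_variance(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, n_taxa=8, n_samples=3, depth=300)
        pooled = table.sediment_pooled()
        depth = int(pooled.sum(axis=0).min())
        base_sample = pooled.columns[pooled.sum(axis=0).to_numpy().argmin()]
        rich = rarefied_richness(table, reps=50, rng=np.random.default_rng(4))
        observed = int((pooled[base_sample] > 0).sum())
        row = rich.loc[base_sample]
        assert row["richness"] == row["ci_low"] == row["ci_high"] == observed
        assert row["depth"] == depth

    def test_mean_richness_monotone_in_depth(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, n_taxa=15, n_samples=3, depth=1000)
        pooled = table.sediment_pooled()
        max_depth = int(pooled.sum(axis=0).min())
        means = []
        for depth in np.linspace(max_depth // 10, max_depth, 5).astype(int):
            r = rarefied_richness(table, reps=100, depth=int(depth),
                                  rng=np.random.default_rng(6))
            means.append(r["richness"].mean())
        jitter = 0.3  # Monte-Carlo slack at 100 reps
        assert all(b >= a - jitter for a, b in zip(means, means[1:]))

    def test_bit_identical_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        table = random_table(rng)
        a = rarefied_richness(table, reps=20, rng=np.random.default_rng(7))
        b = rarefied_richness(table, reps=20, rng=np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)


class TestWithinFamilyRichness:
    def test_single_taxon_family_bounded_by_one(self):
        rng = np.random.default_rng(2)
        table = random_table(rng, n_taxa=9, n_samples=4, depth=3000)
        fam = table.metadata.loc["sq0", "family"]
        only = table.metadata["family"] == fam
        # shrink the family to a single member by reassigning the others
        table.metadata.loc[only & (table.metadata.index != "sq0"), "family"] = "Other"
        rich = within_family_richness(table, fam, cutoff=100, reps=20,
                                      rng=np.random.default_rng(0))
        assert (rich["richness"].dropna() <= 1).all()

    def test_below_cutoff_horizon_is_missing_not_zero(self):
        rng = np.random.default_rng(4)
        table = random_table(rng, n_taxa=6, n_samples=3, depth=500)
        fam = "FamilyX"
        table.metadata.loc["sq0", "family"] = fam
        sample = table.sample_ids("sediment")[0]
        for col in table.counts.columns:
            table.counts.loc["sq0", col] = 99 if col[0] == sample else 500
        rich = within_family_richness(table, fam, cutoff=100, reps=10,
                                      rng=np.random.default_rng(0))
        # replicates pooled: only horizons whose family total < 100 are missing
        pooled_fam = table.pooled().loc[["sq0"]].sum(axis=0)
        for s in rich.index:
            assert np.isnan(rich.loc[s, "richness"]) == (pooled_fam[s] < 100)

    def test_equal_abundance_family_matches_expectation(self):
        rng = np.random.default_rng(8)
        table = random_table(rng, n_taxa=5, n_samples=3, depth=100)
        table.metadata["family"] = "Solo"
        for col in table.counts.columns:
            table.counts[col] = 1000  # five equally abundant taxa, total 1e4 per replicate
        rich = within_family_richness(table, "Solo", cutoff=100, reps=100,
                                      rng=np.random.default_rng(1))
        from scipy.stats import hypergeom

        exp = 5 * (1 - hypergeom.pmf(0, 10000, 2000, 100))
        assert np.allclose(rich["richness"], exp, atol=3 * 0.05 + 1e-6)

    def test_unknown_family_raises(self):
        rng = np.random.default_rng(2)
        table = random_table(rng)
        with pytest.raises(KeyError):
            within_family_richness(table, "Nullaceae")


class TestZonalTurnover:
    def hand_zones(self, rows):
        return pd.DataFrame(rows, index=[f"Z{i}" for i in range(len(rows))])

    def test_identical_zones_have_zero_turnover(self):
        zones = self.hand_zones([[50, 50, 0], [50, 50, 0]])
        out = zonal_turnover(zones, reps=5, rng=0)
        assert out["total"].iloc[0] == 0.0

    def test_one_in_one_out_of_four(self):
        # {a,b,c} -> {b,c,d}: gains 1, losses 1, pooled 4, total 0.5
        zones = self.hand_zones([[40, 40, 40, 0], [0, 40, 40, 40]])
        out = zonal_turnover(zones, reps=5, rng=0)
        row = out.iloc[0]
        assert row["gains"] == 1 and row["losses"] == 1
        assert row["pooled"] == 4 and row["total"] == 0.5
        assert row["appearance"] + row["disappearance"] == pytest.approx(row["total"])

    def test_disjoint_zones_have_full_turnover(self):
        zones = self.hand_zones([[60, 60, 0, 0], [0, 0, 60, 60]])
        out = zonal_turnover(zones, reps=5, rng=0)
        assert out["total"].iloc[0] == 1.0

    def test_needs_two_zones(self):
        with pytest.raises(ValueError):
            zonal_turnover(self.hand_zones([[1, 2, 3]]))


class TestDepthRichnessCorrelation:
    def test_df_is_n_minus_two(self):
        rng = np.random.default_rng(0)
        table = random_table(rng, n_samples=6)
        rich = rarefied_richness(table, reps=10, rng=np.random.default_rng(0))
        out = depth_richness_correlation(table, rich)
        assert out.df == 4

    def test_constant_richness_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        table = random_table(rng, n_samples=5)
        rich = rarefied_richness(table, reps=10, rng=np.random.default_rng(0))
        rich["richness"] = 7.0
        out = depth_richness_correlation(table, rich)
        assert out.degenerate and out.rho == 0.0

    def test_proportional_depth_gives_rho_one(self):
        rng = np.random.default_rng(0)
        table = random_table(rng, n_samples=5)
        rich = rarefied_richness(table, reps=10, rng=np.random.default_rng(0))
        depths = table.sediment_pooled().sum(axis=0)
        rich["richness"] = depths.loc[rich.index].to_numpy(dtype=float) / 100.0
        out = depth_richness_correlation(table, rich)
        assert out.rho == pytest.approx(1.0)
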