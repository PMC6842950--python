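"""Synthetic-data generator: determinism, planted structure, censoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from snownet.simulate import (
    ORGANIC_ACIDS,
    ORGANIC_ACIDS_UP,
    SyntheticConfig,
    generate_card_hits,
    generate_chemistry,
    generate_marker_counts,
    generate_otu_series,
)


class TestConfigValidation:
    def test_driver_strength_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(driver_strength=1.5).validate()

    def test_too_many_planted_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            SyntheticConfig(n_otus=4, n_pos_pairs=6, n_neg_pairs=1).validate()

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(nb_dispersion=0.0).validate()


class TestOtuSeries:
    def test_same_seed_bitwise_identical(self, small_config):
        t1, truth1 = generate_otu_series(small_config)
        t2, truth2 = generate_otu_series(small_config)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        assert truth1.planted_pairs == truth2.planted_pairs

    def test_period_sample_counts_and_time_order(self, small_config):
        table, _ = generate_otu_series(small_config)
        assert len(table.samples_in_period("ES")) == small_config.n_samples_es
        assert len(table.samples_in_period("LS")) == small_config.n_samples_ls
        t = table.sample_meta["time_index"]
        assert (t.sort_values().to_numpy() == np.arange(len(t))).all()

    def test_pure_driver_gives_perfect_latent_rank_correlation(self):
        cfg = SyntheticConfig(seed=5, n_otus=30, n_pos_pairs=3, n_neg_pairs=2,
                              driver_strength=1.0, noise_sd=0.0)
        _, truth, latent = generate_otu_series(cfg, return_latent=True)
        for i, j, sign in truth.planted_pairs:
            rho = spearmanr(latent[i], latent[j]).statistic
            assert rho == pytest.approx(float(sign))

    def test_counts_nonnegative_integers_with_expected_depth(self, small_config):
        table, _ = generate_otu_series(small_config)
        counts = table.counts.to_numpy()
        assert np.issubdtype(counts.dtype, np.integer) and (counts >= 0).all()
        totals = counts.sum(axis=1)
        sigma = np.sqrt(small_config.depth_mean)
        assert np.all(np.abs(totals - small_config.depth_mean) < 5 * sigma)

    def test_fewer_than_four_samples_per_period_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            generate_otu_series(SyntheticConfig(n_samples_es=3))


class TestChemistry:
    def test_no_ramp_no_noise_gives_constant_acids(self):
        cfg = SyntheticConfig(seed=1, organic_acid_ramp=0.0, noise_sd=0.0,
                              lod_table={"nothing": 1e-9})
        table = generate_chemistry(cfg)
        for acid in ORGANIC_ACIDS_UP:
            assert table.values[acid].nunique() == 1

    def test_positive_ramp_correlates_with_time(self, small_config):
        from snownet.chemistry import impute_below_lod

        table = impute_below_lod(generate_chemistry(small_config))
        total = table.values[ORGANIC_ACIDS].sum(axis=1)
        t = np.arange(len(total))
        assert spearmanr(t, total).statistic > 0.9

    def test_total_acids_span_two_orders_of_magnitude(self, small_config):
        from snownet.chemistry import impute_below_lod

        table = impute_below_lod(generate_chemistry(small_config))
        total = table.values[ORGANIC_ACIDS].sum(axis=1)
        assert total.max() / total.min() >= 100

    def test_censored_cells_withhold_values_and_flag(self, small_config):
        table = generate_chemistry(small_config)
        assert table.is_censored()  # early-season acids dip below LOD
        assert table.values[table.below_lod].isna().all().all()
        assert not table.below_lod["pH"].any()

    def test_same_seed_identical(self, small_config):
        a = generate_chemistry(small_config)
        b = generate_chemistry(small_config)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestMarkerCounts:
    def test_same_seed_identical(self, small_config):
        a, _ = generate_marker_counts(small_config)
        b, _ = generate_marker_counts(small_config)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_group_imbalance_matches_design(self, small_config):
        table, _ = generate_marker_counts(small_config)
        periods = table.sample_meta["period"]
        assert (periods == "ES").sum() == 8 and (periods == "LS").sum() == 12

    def test_planted_ratio_near_two_to_log2fc(self):
        cfg = SyntheticConfig(seed=21, planted_log2fc=4.0, nb_dispersion=0.01)
        table, truth = generate_marker_counts(cfg)
        norm = table.counts.div(table.counts.sum(axis=1), axis=0)
        is_ls = (table.sample_meta["period"] == "LS").to_numpy()
        for feature, direction, lfc in truth.enriched_features:
            ratio = norm.loc[is_ls, feature].mean() / norm.loc[~is_ls, feature].mean()
            assert abs(np.log2(ratio) - lfc) < 1.5


class TestCardHits:
    def test_same_seed_identical(self, small_config):
        pd.testing.assert_frame_equal(
            generate_card_hits(small_config), generate_card_hits(small_config)
        )

    def test_hits_straddle_every_threshold(self, small_config):
        hits = generate_card_hits(small_config)
        assert (hits["e_value"] >= 1e-10).any() and (hits["e_value"] < 1e-10).any()
        assert (hits["z_score"] <= 50).any() and (hits["z_score"] > 50).any()
        assert (hits["pct_identity"] <= 60).any() and (hits["pct_identity"] > 60).any()

    def test_ls_samples_draw_from_richer_gene_pool(self, small_config):
        hits = generate_card_hits(small_config)
        meta = {"ES": set(), "LS": set()}
        for sample, sub in hits.groupby("sample"):
            period = "ES" if int(sample[1:]) <= 8 else "LS"
            meta[period] |= set(sub["gene"])
        assert len(meta["LS"]) > len(meta["ES"])

    def test_multi_hit_read_resolves_to_single_best(self):
        """Two passing hits on one read: exactly one survives best-hit."""
        from snownet.markers import filter_card_hits

        hits = pd.DataFrame(
            [
                ["r1", "s1", "MT", "gA", 1e-12, 60, 70],
                ["r1", "s1", "MT", "gB", 1e-15, 55, 65],
            ],
            columns=["read_id", "sample", "dataset", "gene", "e_value", "z_score", "pct_identity"],
        )
        out = filter_card_hits(hits)
        assert len(out) == 1 and out.iloc[0]["gene"] == "gA"
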