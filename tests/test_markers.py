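"""Marker selection, CARD filtering, differential abundance, correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from snownet.markers import (
    differential_abundance,
    feature_set_overlap,
    filter_card_hits,
    normalize_by_total,
    remove_eukaryotes,
    sample_read_totals,
    select_antibiotic_markers,
    select_plasmid_markers,
    spearman_test,
)


def make_records(rows):
    cols = ["read_id", "sample", "dataset", "period", "protein_name", "go_ids", "tax_id", "is_eukaryote"]
    return pd.DataFrame(rows, columns=cols)


class TestRemoveEukaryotes:
    def test_mixed_input_keeps_prokaryotic_reads_and_totals(self):
        rows = [
            [f"r{i}", "s1", "MG", "ES", "p", "", 1, euk]
            for i, euk in enumerate([False, False, True, True, True])
        ]
        out = remove_eukaryotes(make_records(rows))
        assert len(out) == 2
        assert sample_read_totals(out).loc[("s1", "MG")] == 2

    def test_all_true_gives_empty(self):
        rows = [["r1", "s1", "MG", "ES", "p", "", 1, True]]
        assert remove_eukaryotes(make_records(rows)).empty


class TestMarkerSelection:
    def test_plasmid_keyword_and_go_or_rule(self):
        rows = [
            ["r1", "s1", "MG", "ES", "XRE family plasmid maintenance system antidote protein", "", 1, False],
            ["r2", "s1", "MG", "ES", "Some circular DNA thing", "GO:0005727;GO:0000001", 1, False],
            ["r3", "s1", "MG", "ES", "Replication protein", "GO:0000001", 1, False],
        ]
        counts = select_plasmid_markers(make_records(rows))
        assert "XRE family plasmid maintenance system antidote protein" in counts.columns
        assert "Some circular DNA thing" in counts.columns
        assert "Replication protein" not in counts.columns

    def test_antibiotic_exact_list_and_go_matching(self):
        custom = ["Chloramphenicol acetyltransferase (EC 2.3.1.28)"]
        rows = [
            ["r1", "s1", "MG", "ES", "chloramphenicol  acetyltransferase (EC 2.3.1.28)", "", 1, False],
            ["r2", "s1", "MG", "ES", "Amidase-like", "GO:0017000", 1, False],
            ["r3", "s1", "MG", "ES", "Chloramphenicol acetyl transferase", "", 1, False],  # near miss
        ]
        counts = select_antibiotic_markers(make_records(rows), custom)
        assert counts.shape[1] == 2
        assert "Chloramphenicol acetyl transferase" not in counts.columns

    def test_empty_custom_list_falls_back_to_go_only(self, caplog):
        rows = [["r1", "s1", "MG", "ES", "Beta-lactamase", "GO:0017000", 1, False]]
        counts = select_antibiotic_markers(make_records(rows), [])
        assert counts.shape[1] == 1


def make_hits(rows):
    return pd.DataFrame(
        rows, columns=["read_id", "sample", "dataset", "gene", "e_value", "z_score", "pct_identity"]
    )


class TestFilterCardHits:
    def test_threshold_boundaries(self):
        hits = make_hits(
            [
                ["r1", "s1", "MT", "g1", 1e-9, 60, 70],  # e-value fails (not < 1e-10)
                ["r2", "s1", "MT", "g2", 1e-12, 51, 61],  # all pass
                ["r3", "s1", "MT", "g3", 1e-12, 50, 61],  # z fails (not > 50)
                ["r4", "s1", "MT", "g4", 1e-12, 51, 60],  # identity fails
            ]
        )
        out = filter_card_hits(hits)
        assert out["read_id"].tolist() == ["r2"]

    def test_best_hit_prefers_higher_z(self):
        hits = make_hits(
            [
                ["r1", "s1", "MT", "gA", 1e-12, 60, 70],
                ["r1", "s1", "MT", "gB", 1e-15, 55, 65],
            ]
        )
        out = filter_card_hits(hits)
        assert len(out) == 1 and out.iloc[0]["gene"] == "gA"

    def test_tie_break_by_evalue_then_name(self):
        hits = make_hits(
            [
                ["r1", "s1", "MT", "gB", 1e-12, 60, 70],
                ["r1", "s1", "MT", "gA", 1e-12, 60, 70],
                ["r2", "s1", "MT", "gC", 1e-20, 60, 70],
                ["r2", "s1", "MT", "gD", 1e-12, 60, 70],
            ]
        )
        out = filter_card_hits(hits).set_index("read_id")
        assert out.loc["r1", "gene"] == "gA"  # lexicographic
        assert out.loc["r2", "gene"] == "gC"  # lower e-value

    def test_idempotent_and_one_hit_per_read(self):
        from snownet.simulate import SyntheticConfig, generate_card_hits

        hits = generate_card_hits(SyntheticConfig(seed=3))
        once = filter_card_hits(hits)
        twice = filter_card_hits(once)
        pd.testing.assert_frame_equal(once, twice)
        assert not once.duplicated(subset=["sample", "dataset", "read_id"]).any()
        assert len(once) <= len(hits)


class TestNormalizeByTotal:
    def test_fraction_and_scale_invariance(self):
        counts = pd.DataFrame({"f": [5, 0]}, index=["s1", "s2"])
        totals = pd.Series({"s1": 100.0, "s2": 50.0})
        out = normalize_by_total(counts, totals)
        assert out.loc["s1", "f"] == pytest.approx(0.05)
        assert out.loc["s2", "f"] == 0.0
        doubled = normalize_by_total(counts * 2, totals * 2)
        pd.testing.assert_frame_equal(out, doubled)

    def test_zero_total_with_counts_is_error(self):
        counts = pd.DataFrame({"f": [5]}, index=["s1"])
        with pytest.raises(ValueError, match="s1"):
            normalize_by_total(counts, pd.Series({"s1": 0.0}))


class TestDifferentialAbundance:
    def test_rare_feature_dropped_before_testing(self, rng):
        abundance = pd.DataFrame(
            {
                "common": rng.random(8) + 0.5,
                "singleton": [0.3] + [0.0] * 7,
            }
        )
        labels = ["ES"] * 4 + ["LS"] * 4
        res = differential_abundance(abundance, labels, n_perm=99, seed=0)
        assert [r.feature for r in res] == ["common"]

    def test_planted_sixteen_fold_enrichment_recovered_with_sign(self):
        from snownet.markers import normalize_by_total
        from snownet.simulate import SyntheticConfig, generate_marker_counts

        cfg = SyntheticConfig(seed=11, planted_log2fc=4.0, nb_dispersion=0.05)
        table, truth = generate_marker_counts(cfg)
        norm = normalize_by_total(table.counts, table.counts.sum(axis=1).astype(float))
        res = differential_abundance(
            norm, table.sample_meta["period"].to_numpy(), n_perm=999, seed=1
        )
        by_feature = {r.feature: r for r in res}
        for feature, direction, lfc in truth.enriched_features:
            r = by_feature[feature]
            assert r.significant, feature
            assert math.copysign(1, r.log2fc) == math.copysign(1, lfc)

    def test_single_group_rejected(self, rng):
        abundance = pd.DataFrame(rng.random((4, 3)))
        with pytest.raises(ValueError):
            differential_abundance(abundance, ["ES"] * 4, n_perm=99)


class TestSpearman:
    def test_monotone_pairs_hit_plus_minus_one(self):
        x = np.arange(10.0)
        rho, _ = spearman_test(x, np.exp(x), n_perm=99, seed=0)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_test(x, -x, n_perm=99, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_permutation_p_matches_exhaustive_enumeration_n6(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho, p_mc = spearman_test(x, y, n_perm=9999, seed=2)
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        rxc, ryc = rx - rx.mean(), ry - ry.mean()
        denom = np.linalg.norm(rxc) * np.linalg.norm(ryc)
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            total += 1
            hits += abs(ryc[list(perm)] @ rxc / denom) >= abs(rho) - 1e-12
        p_exact = hits / total
        assert abs(p_mc - p_exact) < 0.02

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_test([1.0] * 6, [1, 2, 3, 4, 5, 6])


class TestFeatureSetOverlap:
    def test_identical_sets_share_everything(self):
        regions = feature_set_overlap({"a", "b"}, {"a", "b"})
        assert regions[(True, True)] == 2
        assert regions[(True, False)] == 0

    def test_disjoint_sets_have_empty_intersection(self):
        regions = feature_set_overlap({"a"}, {"b", "c"})
        assert regions[(True, True)] == 0
        assert regions[(False, True)] == 2

    def test_three_set_chain_matches_inclusion_exclusion(self):
        a = {1}
        b = {1, 2, 3}
        c = {1, 2, 3, 4, 5, 6}
        regions = feature_set_overlap(a, b, c)
        # brute-force membership tally
        for pattern, count in regions.items():
            expected = sum(
                1
                for item in a | b | c
                if tuple(item in s for s in (a, b, c)) == pattern
            )
            assert count == expected
        assert sum(regions.values()) == len(a | b | c)

    def test_more_than_four_sets_rejected(self):
        with pytest.raises(ValueError):
            feature_set_overlap({1}, {2}, {3}, {4}, {5})
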