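"""Fisher enrichments, BH, correlations, states, clustering, proximity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scarline import enrichment_stats as es
from scarline import synthetic_data as sd


def _masks_from_table(a, b, c, d):
    f = np.r_[np.ones(a + b, bool), np.zeros(c + d, bool)]
    h = np.r_[np.ones(a, bool), np.zeros(b, bool), np.ones(c, bool), np.zeros(d, bool)]
    return f, h


class TestFisher:
    def test_cross_product_example(self):
        r = es.fisher_enrichment(*_masks_from_table(10, 20, 30, 40))
        assert round(r.odds_ratio, 4) == 0.6667
        assert not r.corrected

    def test_zero_cell_haldane_correction(self):
        r = es.fisher_enrichment(*_masks_from_table(0, 20, 30, 40))
        assert r.corrected and np.isfinite(r.odds_ratio) and r.odds_ratio > 0

    def test_or_invariant_under_role_transpose(self):
        f, h = _masks_from_table(7, 13, 5, 25)
        assert es.fisher_enrichment(f, h).odds_ratio == pytest.approx(
            es.fisher_enrichment(h, f).odds_ratio
        )

    def test_independent_masks_near_unit_or(self, rng):
        ors, ps = [], []
        for _ in range(40):
            f = rng.random(400) < 0.3
            h = rng.random(400) < 0.2
            r = es.fisher_enrichment(f, h)
            ors.append(r.odds_ratio)
            ps.append(r.pvalue)
        assert abs(np.median(np.log(ors))) < 0.2
        assert (np.asarray(ps) < 0.05).mean() < 0.2

    def test_matches_cross_product_oracle_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 60, 4)
            r = es.fisher_enrichment(*_masks_from_table(a, b, c, d))
            assert r.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-12)


def _bh_oracle(p):
    """Independent min-over-tail step-up formula."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


class TestBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            es.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_pvalue_unchanged(self):
        assert es.bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            es.bh_adjust([0.1, 1.2])

    def test_matches_min_over_tail_oracle(self, rng):
        for _ in range(30):
            p = rng.random(rng.integers(1, 200))
            np.testing.assert_allclose(es.bh_adjust(p), _bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_monotone_and_bounded(self, p):
        q = es.bh_adjust(p)
        assert (q <= 1.0 + 1e-12).all() and (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 5.0, -1.0])
        r = es.change_correlation(x, 2 * x)
        assert r.r == pytest.approx(1.0)

    def test_missing_pairs_dropped_and_counted(self):
        x = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.0, np.nan, 8.0, 10.0])
        r = es.change_correlation(x, y)
        assert r.n == 3 and r.n_dropped == 2

    def test_refuses_tiny_samples(self):
        with pytest.raises(ValueError, match="at least 3"):
            es.change_correlation([1.0, 2.0], [2.0, 4.0])

    def test_independent_changes_near_zero(self, rng):
        r = es.change_correlation(rng.normal(size=500), rng.normal(size=500))
        assert abs(r.r) < 3 / np.sqrt(500)


class TestChromatinStates:
    def test_all_low_is_quiescent(self):
        sig = pd.DataFrame({"H3K4me3": [0.0], "H3K27me3": [0.0], "H3K9me3": [0.0]})
        states, _ = es.assign_chromatin_states(sig, thresholds={m: 1.0 for m in sig})
        assert states.iloc[0] == "quiescent"

    def test_bivalent_precedence_over_heterochromatic(self):
        sig = pd.DataFrame({"H3K4me3": [5.0], "H3K27me3": [5.0], "H3K9me3": [5.0]})
        states, _ = es.assign_chromatin_states(sig, thresholds={m: 1.0 for m in sig})
        assert states.iloc[0] == "bivalent"

    def test_missing_mark_column_is_configuration_error(self):
        with pytest.raises(KeyError):
            es.assign_chromatin_states(pd.DataFrame({"H3K4me3": [1.0]}))

    def test_states_partition_the_feature_set(self):
        sig = sd.simulate_promoter_signals(n=500, seed=4)
        states, _ = es.assign_chromatin_states(sig[["H3K4me3", "H3K27me3", "H3K9me3"]])
        assert len(states) == 500
        assert set(states.unique()).issubset(set(es.STATE_PRECEDENCE))

    def test_planted_classes_recovered(self):
        sig = sd.simulate_promoter_signals(n=2_000, seed=5)
        states, _ = es.assign_chromatin_states(sig[["H3K4me3", "H3K27me3", "H3K9me3"]])
        acc = (states.to_numpy() == sig["true_state"].to_numpy()).mean()
        assert acc >= 0.95


class TestClustering:
    def test_duplicated_rows_share_cluster(self):
        df, _ = sd.simulate_change_matrix(n_features=30, seed=7)
        df2 = pd.concat([df, df.iloc[[0]].rename(index={df.index[0]: "dup"})])
        ca = es.cluster_changes(df2, k=3)
        assert ca.labels[df.index[0]] == ca.labels["dup"]

    def test_single_feature_single_cluster(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["only"])
        ca = es.cluster_changes(df, k=1)
        assert ca.labels.tolist() == [1]

    def test_constant_column_dropped_with_warning(self):
        df, _ = sd.simulate_change_matrix(n_features=20, seed=8)
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            ca = es.cluster_changes(df, k=2)
        assert "flat" in ca.dropped_columns

    def test_row_permutation_invariance(self):
        from sklearn.metrics import adjusted_rand_score

        df, _ = sd.simulate_change_matrix(n_features=120, seed=9)
        ca1 = es.cluster_changes(df, k=3)
        perm = np.random.default_rng(1).permutation(len(df))
        ca2 = es.cluster_changes(df.iloc[perm], k=3)
        joined = pd.concat([ca1.labels.rename("a"), ca2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == pytest.approx(1.0)

    def test_planted_groups_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        df, truth = sd.simulate_change_matrix(seed=10)
        ca = es.cluster_changes(df, k=3)
        assert adjusted_rand_score(truth, ca.labels.to_numpy()) > 0.9


class TestProximity:
    def _genes(self, tss_positions, flags):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * len(tss_positions),
                "start": tss_positions,
                "end": [t + 2_000 for t in tss_positions],
                "name": [f"g{i}" for i in range(len(tss_positions))],
                "strand": ["+"] * len(tss_positions),
                "upregulated": flags,
            }
        )

    def test_radius_rule_boundaries(self):
        repeats = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [109_999, 1_000_000],
                "end": [110_500, 1_000_400],
                "derepressed": [True, True],
            }
        )
        genes = self._genes([100_000, 989_999 - 2_000 + 2_000], [True, True])
        genes.loc[1, "start"] = 989_999  # TSS 10,001 bp left of second repeat
        genes.loc[1, "end"] = 991_999
        _, per_gene = es.proximity_enrichment(genes, repeats)
        assert per_gene.loc[0, "nearest_repeat_bp"] == 9_999
        assert bool(per_gene.loc[0, "repeat_proximal"]) is True
        assert per_gene.loc[1, "nearest_repeat_bp"] == 10_001
        assert bool(per_gene.loc[1, "repeat_proximal"]) is False

    def test_minus_strand_tss_anchor(self):
        genes = self._genes([50_000], [True])
        genes.loc[0, "strand"] = "-"  # TSS at end-1 = 51,999
        repeats = pd.DataFrame(
            {"chrom": ["chr1"], "start": [60_000], "end": [60_500], "derepressed": [True]}
        )
        _, per_gene = es.proximity_enrichment(genes, repeats)
        assert per_gene.loc[0, "nearest_repeat_bp"] == 60_000 - 51_999

    def test_planted_association_vs_shuffled_null(self, rng):
        n = 300
        tss = np.arange(n) * 50_000 + 10_000
        up = rng.random(n) < 0.3
        # plant repeats near most upregulated genes, far otherwise
        rep_rows = []
        for i in np.flatnonzero(up):
            if rng.random() < 0.8:
                rep_rows.append(("chr1", tss[i] + 3_000, tss[i] + 3_400, True))
        for i in np.flatnonzero(~up)[:20]:
            rep_rows.append(("chr1", tss[i] + 3_000, tss[i] + 3_400, True))
        repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "derepressed"])
        genes = self._genes(list(tss), list(up))
        enr, _ = es.proximity_enrichment(genes, repeats)
        assert enr.odds_ratio > 1 and enr.pvalue < 0.001
        shuffled = genes.copy()
        shuffled["upregulated"] = rng.permutation(up)
        enr0, _ = es.proximity_enrichment(shuffled, repeats)
        assert enr0.pvalue > 0.001 or abs(np.log(enr0.odds_ratio)) < abs(
            np.log(enr.odds_ratio)
        )
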