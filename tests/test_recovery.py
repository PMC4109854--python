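"""Recovery AUC, NES normalization, leading-edge target selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regulonscan.ranking import build_database
from regulonscan.recovery import (RecoveryParams, collection_background,
                                  compute_recovery_auc, normalize_nes,
                                  recovery_curve, run_enrichment,
                                  select_targets_leading_edge)


def naive_auc(ranks, G, s, top_fraction):
    """O(G*s) oracle: walk the ranking and accumulate the recovery curve."""
    T = int(np.ceil(top_fraction * G))
    rankset = set(int(r) for r in ranks)
    c, total = 0, 0
    for k in range(1, T + 1):
        if k in rankset:
            c += 1
        total += c
    return total / (T * s)


def make_column(G, gene_ranks, seed=0):
    """A permutation of 1..G assigning the given genes the given ranks."""
    rng = np.random.default_rng(seed)
    ranks = np.zeros(G, dtype=np.int32)
    used = set(gene_ranks.values())
    free = [r for r in range(1, G + 1) if r not in used]
    rng.shuffle(free)
    it = iter(free)
    for g in range(G):
        ranks[g] = gene_ranks.get(g, 0) or next(it)
    return ranks


class TestAUC:
    def test_set_outside_top_fraction_is_zero(self):
        universe = [f"g{i}" for i in range(100)]
        col = np.arange(1, 101, dtype=np.int32)
        auc = compute_recovery_auc(col, universe, ["g98", "g99"],
                                   RecoveryParams(top_fraction=0.03))
        assert auc == 0.0

    def test_two_genes_at_top_of_ranking(self):
        # s=2 at ranks 1,2 with T=10: sum c = 1 + 2*9 = 19 -> AUC 0.95
        universe = [f"g{i}" for i in range(100)]
        col = np.arange(1, 101, dtype=np.int32)
        auc = compute_recovery_auc(col, universe, ["g0", "g1"],
                                   RecoveryParams(top_fraction=0.1))
        assert auc == pytest.approx(0.95)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        G = int(rng.integers(200, 1500))
        s = int(rng.integers(2, 40))
        top = float(rng.choice([0.01, 0.03, 0.1]))
        universe = [f"g{i}" for i in range(G)]
        col = rng.permutation(np.arange(1, G + 1)).astype(np.int32)
        members = rng.choice(G, size=s, replace=False)
        auc = compute_recovery_auc(col, universe,
                                   [f"g{i}" for i in members],
                                   RecoveryParams(top_fraction=top))
        assert auc == pytest.approx(
            naive_auc(col[members], G, s, top), abs=1e-12)

    def test_unknown_genes_dropped_with_warning(self):
        universe = [f"g{i}" for i in range(50)]
        col = np.arange(1, 51, dtype=np.int32)
        with pytest.warns(UserWarning, match="dropped"):
            auc = compute_recovery_auc(col, universe, ["g0", "nope"],
                                       RecoveryParams(top_fraction=0.1))
        assert auc > 0

    def test_empty_effective_set_is_error(self):
        universe = [f"g{i}" for i in range(50)]
        col = np.arange(1, 51, dtype=np.int32)
        with pytest.raises(ValueError, match="no usable genes"), \
                pytest.warns(UserWarning):
            compute_recovery_auc(col, universe, ["nope"], RecoveryParams())

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_improving_a_rank_never_decreases_auc(self, seed):
        rng = np.random.default_rng(seed)
        G, s = 300, 10
        ranks = rng.choice(np.arange(1, G + 1), size=s, replace=False)
        T = 9  # 3% of 300
        from regulonscan.recovery import _auc_from_ranks
        base = _auc_from_ranks(ranks, T, s)
        i = rng.integers(0, s)
        improved = ranks.copy()
        improved[i] = rng.integers(1, ranks[i] + 1)
        # keep distinctness irrelevant: oracle formula only needs ranks
        assert _auc_from_ranks(improved, T, s) >= base - 1e-12


class TestNES:
    def test_forced_example(self):
        nes = normalize_nes([0.1, 0.2, 0.3])
        np.testing.assert_allclose(nes, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_degenerate_collection(self):
        with pytest.warns(UserWarning, match="degenerate"):
            nes = normalize_nes([0.2, 0.2, 0.2])
        np.testing.assert_array_equal(nes, np.zeros(3))

    def test_zscore_identities_on_random_aucs(self):
        rng = np.random.default_rng(0)
        aucs = rng.random(50)
        nes = normalize_nes(aucs)
        assert nes.mean() == pytest.approx(0.0, abs=1e-12)
        assert nes.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_too_few_features(self):
        with pytest.raises(ValueError, match=">= 3"):
            normalize_nes([0.1, 0.2])


class TestLeadingEdge:
    def make_curves(self, depth=600, s=4, n_flat=10):
        # the collection background includes the candidate itself, so a few
        # flat co-features keep the envelope essentially flat
        flat = recovery_curve(np.array([10_000]), depth, s, "flat", 1000)
        signal = recovery_curve(np.array([1, 2, 3, 500]), depth, s,
                                "signal", 1000)
        return signal, [flat] * n_flat

    def test_toy_max_difference_at_rank_three(self):
        signal, flats = self.make_curves()
        background = collection_background(flats + [signal])
        member_ranks = {"a": 1, "b": 2, "c": 3, "d": 500}
        k_star, targets = select_targets_leading_edge(
            signal, background, member_ranks, rank_threshold=400)
        assert k_star == 3
        assert [g for g, _ in targets] == ["a", "b", "c"]

    def test_signal_below_background_selects_nothing(self):
        signal, flats = self.make_curves()
        background = collection_background(flats + [signal]) + 10.0
        k_star, targets = select_targets_leading_edge(
            signal, background, {"a": 1}, rank_threshold=400)
        assert (k_star, targets) == (0, [])

    def test_targets_subset_of_input_with_ranks_below_kstar(self):
        rng = np.random.default_rng(1)
        depth = 500
        curves = [recovery_curve(
            np.sort(rng.choice(np.arange(1, 1001), 20, replace=False)),
            depth, 20, f"f{i}", 1000) for i in range(6)]
        background = collection_background(curves)
        for c in curves:
            member_ranks = {f"g{r}": int(r) for r in
                            np.where(np.diff(np.concatenate([[0], c.counts])))[0] + 1}
            k_star, targets = select_targets_leading_edge(
                c, background, member_ranks, depth)
            for g, r in targets:
                assert r <= k_star
                assert g in member_ranks

    def test_background_needs_three_features(self):
        signal, _ = self.make_curves()
        with pytest.raises(ValueError, match=">= 3"):
            collection_background([signal, signal])


class TestRunEnrichment:
    def build_dbs(self, G=200, seed=0):
        rng = np.random.default_rng(seed)
        planted = np.arange(G)
        cols = {}
        for i in range(8):
            cols[f"m{i}"] = rng.permutation(np.arange(1, G + 1)).astype(np.int32)
        # feature m0 puts genes 0..9 at ranks 1..10
        cols["m0"] = make_column(G, {g: g + 1 for g in range(10)}, seed=seed)
        universe = [f"g{i}" for i in range(G)]
        return build_database(cols, universe, "motifs")

    def test_planted_feature_reported_with_targets(self):
        db = self.build_dbs()
        res = run_enrichment(db, [f"g{i}" for i in range(10)],
                             RecoveryParams(top_fraction=0.1,
                                            nes_threshold=2.0,
                                            rank_threshold=100))
        assert res and res[0].feature_id == "m0"
        assert res[0].nes >= 2.0
        assert res[0].collection == "motifs"
        targets = res[0].target_genes
        assert set(targets) <= {f"g{i}" for i in range(10)}
        assert len(targets) >= 5

    def test_identical_columns_in_two_collections_same_auc(self):
        db_m = self.build_dbs(seed=1)
        db_t = build_database(
            {f: db_m.ranks[:, i].copy() for i, f in enumerate(db_m.features)},
            db_m.universe, "tracks")
        params = RecoveryParams(top_fraction=0.1, nes_threshold=-np.inf,
                                rank_threshold=100)
        gene_set = [f"g{i}" for i in range(10)]
        res = run_enrichment([db_m, db_t], gene_set, params)
        by_coll = {}
        for r in res:
            by_coll.setdefault(r.collection, {})[r.feature_id] = r
        for f in db_m.features:
            assert by_coll["motifs"][f].auc == by_coll["tracks"][f].auc
            assert by_coll["motifs"][f].nes == pytest.approx(
                by_coll["tracks"][f].nes)

    def test_results_sorted_by_nes_descending(self):
        db = self.build_dbs(seed=2)
        res = run_enrichment(db, [f"g{i}" for i in range(10)],
                             RecoveryParams(top_fraction=0.1,
                                            nes_threshold=-np.inf,
                                            rank_threshold=100))
        nes = [r.nes for r in res]
        assert nes == sorted(nes, reverse=True)
        assert len(res) == len(db.features)
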