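"""Order-statistic aggregation and ranking-database construction."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regulonscan.ranking import (RankingDatabase, aggregate_species_ranks,
                                 aggregate_species_ranks_many,
                                 build_database, build_motif_ranking,
                                 build_track_ranking, gene_peak_scores,
                                 rank_genes_from_species_scores,
                                 read_peak_bed)
from regulonscan.search_space import Region


def mc_order_statistic(ratios, n_draws, seed):
    """Monte-Carlo oracle: P(U_(i) <= r_(i) for all i) for iid uniforms."""
    rng = np.random.default_rng(seed)
    r = np.sort(np.asarray(ratios))
    draws = np.sort(rng.random((n_draws, r.size)), axis=1)
    hits = np.all(draws <= r, axis=1)
    p_hat = hits.mean()
    se = np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_draws)
    return p_hat, se


class TestOrderStatistics:
    def test_single_ratio_is_identity(self):
        assert aggregate_species_ranks([0.25]) == pytest.approx(0.25)

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_all_ones_is_certain(self, k):
        assert aggregate_species_ranks([1.0] * k) == pytest.approx(1.0)

    def test_k2_closed_form(self):
        # Q = 2*r1*r2 - r1^2
        assert aggregate_species_ranks([0.1, 0.5]) == pytest.approx(0.09)
        rng = np.random.default_rng(0)
        for _ in range(50):
            r1, r2 = np.sort(rng.random(2))
            assert aggregate_species_ranks([r1, r2]) == \
                pytest.approx(2 * r1 * r2 - r1 ** 2, rel=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_matches_monte_carlo(self, k):
        rng = np.random.default_rng(k)
        ratios = np.sort(rng.random(k))
        q = aggregate_species_ranks(ratios)
        p_hat, se = mc_order_statistic(ratios, n_draws=200_000, seed=k + 100)
        assert abs(q - p_hat) <= 3 * se + 1e-9

    def test_unsorted_input_sorted_internally(self):
        assert aggregate_species_ranks([0.5, 0.1]) == \
            aggregate_species_ranks([0.1, 0.5])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_species_ranks([])
        with pytest.raises(ValueError):
            aggregate_species_ranks([0.0, 0.5])
        with pytest.raises(ValueError):
            aggregate_species_ranks([0.5, 1.5])

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
           st.integers(0, 4), st.floats(0.01, 0.2))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_each_ratio(self, ratios, which, bump):
        """Improving (lowering) any ratio never increases Q."""
        q = aggregate_species_ranks(ratios)
        idx = which % len(ratios)
        better = list(ratios)
        better[idx] = max(1e-6, better[idx] - bump)
        assert aggregate_species_ranks(better) <= q + 1e-12

    def test_vectorised_form_matches_scalar(self):
        rng = np.random.default_rng(7)
        R = rng.random((4, 200))
        R[rng.random((4, 200)) < 0.4] = np.nan
        qv = aggregate_species_ranks_many(R)
        for g in range(200):
            col = R[~np.isnan(R[:, g]), g]
            expect = aggregate_species_ranks(col) if col.size else 1.0
            assert qv[g] == pytest.approx(expect, rel=1e-12)


class TestMotifRanking:
    def test_three_genes_one_species(self):
        scores = pd.DataFrame({
            "gene_id": ["a", "b", "c"], "species_id": ["sp0"] * 3,
            "region": [0, 0, 0], "score": [5.0, 2.0, 0.0]})
        ranks = build_motif_ranking(scores, ["a", "b", "c"], seed=0)
        assert list(ranks) == [1, 2, 3]

    def test_consistent_gene_beats_inconsistent(self):
        # A is 1st in both species; B is 1st in one and last in the other
        rows = []
        for sp, order in [("sp0", ["A", "B", "C", "D"]),
                          ("sp1", ["A", "C", "D", "B"])]:
            for rank, g in enumerate(order):
                rows.append((g, sp, 0, 10.0 - rank))
        scores = pd.DataFrame(rows, columns=["gene_id", "species_id",
                                             "region", "score"])
        ranks = build_motif_ranking(scores, ["A", "B", "C", "D"], seed=0)
        assert ranks[0] == 1  # A first
        # direct q comparison: A=(0.25,0.25) beats B=(0.5,1.0)
        qa = aggregate_species_ranks([0.25, 0.25])
        qb = aggregate_species_ranks([0.5, 1.0])
        assert qa < qb
        assert ranks[0] < ranks[1]

    def test_multiple_regions_gene_keeps_best(self):
        scores = pd.DataFrame({
            "gene_id": ["a", "a", "b"], "species_id": ["sp0"] * 3,
            "region": [0, 1, 0], "score": [1.0, 9.0, 5.0]})
        ranks = build_motif_ranking(scores, ["a", "b"], seed=0)
        assert ranks[0] < ranks[1]  # a's best region (9.0) wins

    def test_unknown_gene_rejected(self):
        scores = pd.DataFrame({"gene_id": ["zz"], "species_id": ["sp0"],
                               "region": [0], "score": [1.0]})
        with pytest.raises(ValueError, match="not in universe"):
            build_motif_ranking(scores, ["a"], seed=0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_permutation_and_determinism(self, seed):
        rng = np.random.default_rng(seed)
        G = 40
        scores = rng.random((3, G))
        scores[scores < 0.3] = 0.0
        r1 = rank_genes_from_species_scores(scores, seed=seed)
        r2 = rank_genes_from_species_scores(scores.copy(), seed=seed)
        assert np.array_equal(r1, r2)
        assert sorted(r1) == list(range(1, G + 1))
        r3 = rank_genes_from_species_scores(scores, seed=seed + 999)
        assert sorted(r3) == list(range(1, G + 1))

    def test_all_zero_genes_queued_randomly_at_the_end(self):
        scores = np.zeros((2, 10))
        scores[:, :3] = [[9, 5, 2], [8, 6, 1]]
        ranks = rank_genes_from_species_scores(scores, seed=3)
        assert set(ranks[:3]) == {1, 2, 3}
        tail1 = rank_genes_from_species_scores(scores, seed=3)[3:]
        tail2 = rank_genes_from_species_scores(scores, seed=4)[3:]
        assert not np.array_equal(tail1, tail2)  # seed moves the tail

    def test_missing_species_reduces_k(self):
        # gene b has data only in sp0 where it ranks 1st of 2
        scores = np.array([[1.0, 5.0], [2.0, np.nan]])
        ranks = rank_genes_from_species_scores(scores, seed=0)
        assert sorted(ranks) == [1, 2]
        # q(b) from a single ratio 0.5; q(a) from (1.0, 0.5)
        qa = aggregate_species_ranks([1.0, 0.5])
        qb = aggregate_species_ranks([0.5])
        assert (ranks[1] < ranks[0]) == (qb < qa)


def region(gid, start, end, chrom="chr1"):
    return Region(chrom, start, end, gid)


class TestTrackRanking:
    def setup_method(self):
        self.space = {
            "X": [region("X", 100, 600)],
            "Y": [region("Y", 1000, 1500)],
            "Z": [region("Z", 2000, 2500)],
        }
        self.universe = ["X", "Y", "Z"]

    def test_stronger_peak_ranks_first(self):
        peaks = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [150, 1100],
            "end": [250, 1200], "signalValue": [80.0, 20.0]})
        ranks = build_track_ranking(peaks, self.space, self.universe, seed=0)
        assert ranks[0] == 1 and ranks[1] == 2 and ranks[2] == 3

    def test_no_overlap_gives_seeded_random_permutation(self):
        peaks = pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [10],
                              "signalValue": [5.0]})
        r1 = build_track_ranking(peaks, self.space, self.universe, seed=5)
        r2 = build_track_ranking(peaks, self.space, self.universe, seed=5)
        r3 = build_track_ranking(peaks, self.space, self.universe, seed=6)
        assert np.array_equal(r1, r2)
        assert sorted(r1) == [1, 2, 3] and sorted(r3) == [1, 2, 3]
        assert not np.array_equal(r1, r3)

    def test_shared_peak_scores_both_genes(self):
        space = {"A": [region("A", 0, 300)], "B": [region("B", 250, 700)]}
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [200],
                              "end": [350], "signalValue": [42.0]})
        scores = gene_peak_scores(peaks, space)
        assert scores == {"A": 42.0, "B": 42.0}

    def test_gene_scores_match_brute_force_on_toy(self):
        rng = np.random.default_rng(0)
        space = {f"g{i}": [region(f"g{i}", i * 1000, i * 1000 + 500)]
                 for i in range(5)}
        peaks = pd.DataFrame({
            "chrom": ["chr1"] * 30,
            "start": (starts := rng.integers(0, 5500, 30)),
            "end": starts + rng.integers(50, 400, 30),
            "signalValue": rng.uniform(1, 100, 30).round(2)})
        scores = gene_peak_scores(peaks, space)
        for gid, regs in space.items():
            r = regs[0]
            best = 0.0
            for p in peaks.itertuples(index=False):
                if p.start < r.end and p.end > r.start:
                    best = max(best, p.signalValue)
            assert scores[gid] == pytest.approx(best)

    def test_malformed_bed_lines_skipped_with_count(self):
        text = ("chr1\t100\t200\tp1\t0\t.\t55.5\n"
                "chr1\tnot_an_int\t300\n"
                "chr1\t400\t300\tp_bad_interval\t0\t.\t9\n"
                "chr1\t500\t600\tp2\t7\n")
        df = read_peak_bed(io.StringIO(text))
        assert len(df) == 2
        assert df.attrs["n_skipped"] == 2
        assert df["signalValue"].tolist() == [55.5, 7.0]  # col7 else col5


class TestDatabasePersistence:
    def make_db(self):
        rng = np.random.default_rng(0)
        cols = {f"m{i}": rng.permutation(np.arange(1, 21)).astype(np.int32)
                for i in range(4)}
        return build_database(cols, [f"g{i}" for i in range(20)], "motifs",
                              {"seed": 0})

    def test_column_permutation_validated(self):
        with pytest.raises(ValueError, match="permutation"):
            RankingDatabase(universe=["a", "b"], features=["m"],
                            collection="motifs",
                            ranks=np.array([[1], [1]]))

    def test_save_load_roundtrip_and_determinism(self, tmp_path):
        db = self.make_db()
        p1, m1 = db.save(tmp_path / "one")
        p2, m2 = db.save(tmp_path / "two")
        assert p1.read_bytes() == p2.read_bytes()
        assert m1.read_text().replace("one", "x") == \
            m2.read_text().replace("two", "x")
        back = RankingDatabase.load(tmp_path / "one")
        assert back.universe == db.universe
        assert back.features == db.features
        assert np.array_equal(back.ranks, db.ranks)
        assert back.universe_sha256 == db.universe_sha256

    def test_tsv_export(self, tmp_path):
        db = self.make_db()
        out = tmp_path / "db.tsv"
        db.export_tsv(out)
        frame = pd.read_csv(out, sep="\t", index_col=0)
        assert list(frame.columns) == db.features
        assert np.array_equal(frame.to_numpy(), db.ranks)
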