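import itertools

import numpy as np
import pandas as pd
import pytest

from intercov.compare import (ScoreTable, classify_pairs, density_summary,
                              export_scores, import_external_scores,
                              links_needed, rank_pairs, read_score_tsv,
                              top_class_pairs, top_overlap)

SEGMENTS = [("A", 0, 3), ("B", 3, 6)]


def table_from_scores(pair_scores, segments=SEGMENTS, method="m"):
    L = segments[-1][2]
    scores = np.zeros((L, L))
    for (i, j), s in pair_scores.items():
        scores[i, j] = scores[j, i] = s
    return ScoreTable(method, scores, segments)


def random_table(seed, segments=SEGMENTS, method="m"):
    L = segments[-1][2]
    rng = np.random.default_rng(seed)
    m = rng.random((L, L))
    scores = (m + m.T) / 2
    np.fill_diagonal(scores, 0.0)
    return ScoreTable(method, scores, segments)


def brute_force_links_needed(ranked, target_class, n):
    count = 0
    for k, cls in enumerate(ranked["cls"], start=1):
        if target_class == "both" or \
                (target_class == "intra" and cls.startswith("intra")) or \
                cls == target_class:
            count += 1
        if count >= n:
            return k
    raise AssertionError("not enough links")


class TestClassifyPairs:
    def test_intra_and_inter(self):
        segments = [("A", 0, 30), ("B", 30, 70)]
        classes = classify_pairs(segments, 70)
        assert classes[5, 10] == "intra:A"
        assert classes[5, 40] == "inter"
        assert classes[29, 30] == "inter"     # half-open boundary
        assert classes[30, 31] == "intra:B"

    def test_uncovered_position_errors(self):
        with pytest.raises(ValueError, match="outside"):
            classify_pairs([("A", 0, 3)], 5)


class TestRankPairs:
    def test_descending_order(self):
        t = table_from_scores({(0, 1): 3, (0, 2): 1, (1, 2): 2},
                              segments=[("A", 0, 2), ("B", 2, 3)])
        r = rank_pairs(t)
        assert list(zip(r["i"], r["j"])) == [(0, 1), (1, 2), (0, 2)]
        assert r["rank"].tolist() == [1, 2, 3]

    def test_tie_break_lexicographic(self):
        t = table_from_scores({}, segments=[("A", 0, 2), ("B", 2, 3)])
        r = rank_pairs(t)
        assert list(zip(r["i"], r["j"])) == [(0, 1), (0, 2), (1, 2)]

    def test_matches_sort_oracle(self):
        t = random_table(5)
        r = rank_pairs(t)
        oracle = sorted(
            ((t.scores[i, j], i, j) for i in range(6)
             for j in range(i + 1, 6)),
            key=lambda x: (-x[0], x[1], x[2]))
        assert list(zip(r["i"], r["j"])) == [(i, j) for _, i, j in oracle]

    def test_nan_rejected(self):
        t = random_table(0)
        t.scores[0, 1] = t.scores[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            rank_pairs(t)


class TestLinksNeeded:
    def test_counting_example(self):
        ranked = pd.DataFrame({
            "rank": [1, 2, 3], "i": [0, 0, 1], "j": [3, 1, 4],
            "score": [3.0, 2.0, 1.0],
            "cls": ["inter", "intra:A", "inter"]})
        assert links_needed(ranked, "inter", 2) == 3

    def test_insufficient_links_reports_count(self):
        ranked = rank_pairs(random_table(1))
        with pytest.raises(ValueError, match="9"):
            links_needed(ranked, "inter", 10)   # only 3*3=9 inter pairs

    def test_interprotein_target_at_known_overall_rank(self):
        # construct a ranking where the 100th inter pair sits at overall
        # rank 565, and (second method) at rank 816
        for target_rank, n_inter in [(565, 100), (816, 100)]:
            segments = [("A", 0, 40), ("B", 40, 80)]
            L = 80
            classes = classify_pairs(segments, L)
            iu = list(zip(*np.triu_indices(L, k=1)))
            inter_pairs = [p for p in iu if classes[p] == "inter"]
            intra_pairs = [p for p in iu if classes[p] != "inter"]
            scores = {}
            score = 10_000.0
            # 99 inter + (target_rank - 100) intra above, then the 100th
            for p in inter_pairs[:n_inter - 1]:
                scores[p] = score
                score -= 1
            for p in intra_pairs[:target_rank - n_inter]:
                scores[p] = score
                score -= 1
            scores[inter_pairs[n_inter - 1]] = score
            t = table_from_scores(scores, segments)
            ranked = rank_pairs(t)
            assert links_needed(ranked, "inter", n_inter) == target_rank

    def test_monotone_in_n_and_class_nesting(self):
        ranked = rank_pairs(random_table(7))
        ks = [links_needed(ranked, "inter", n) for n in range(1, 10)]
        assert ks == sorted(ks)
        for n in range(1, 10):
            assert links_needed(ranked, "both", n) <= \
                links_needed(ranked, "inter", n)

    def test_matches_brute_force_for_all_n(self):
        ranked = rank_pairs(random_table(11))
        for cls in ["inter", "intra", "both"]:
            total = sum(
                1 for c in ranked["cls"]
                if cls == "both" or (cls == "intra" and c.startswith("intra"))
                or c == cls)
            for n in range(1, total + 1):
                assert links_needed(ranked, cls, n) == \
                    brute_force_links_needed(ranked, cls, n)


class TestTopOverlap:
    def test_identical_tables_full_overlap(self):
        t = random_table(2)
        ranked = {"a": rank_pairs(t), "b": rank_pairs(t)}
        out = top_overlap(ranked, "inter", 3)
        expected = set(
            (r.i, r.j) for r in
            top_class_pairs(rank_pairs(t), "inter", 3).itertuples())
        assert set(out["overlap"]) == expected
        assert len(out["overlap"]) == 3

    def test_disjoint_top_sets_empty_overlap(self):
        # method a scores pair (0,3) highest; method b scores (2,5)
        a = table_from_scores({(0, 3): 9.0, (2, 5): 1.0, (1, 4): 0.5})
        b = table_from_scores({(2, 5): 9.0, (0, 3): 1.0, (1, 4): 0.5})
        out = top_overlap({"a": rank_pairs(a), "b": rank_pairs(b)},
                          "inter", 1)
        assert out["overlap"] == []
        assert len(out["union_report"]) == 2

    def test_four_tables_known_intersection(self):
        # three inter pairs shared at the top of all four methods, each
        # method adding one private pair
        shared = {(0, 3): 9.0, (1, 4): 8.0, (2, 5): 7.0}
        privates = [(0, 4), (0, 5), (1, 3), (1, 5)]
        ranked = {}
        for k, private in enumerate(privates):
            scores = dict(shared)
            scores[private] = 8.5
            ranked[f"m{k}"] = rank_pairs(table_from_scores(scores))
        out = top_overlap(ranked, "inter", 4)
        assert sorted(out["overlap"]) == sorted(shared)

    def test_monotone_in_n(self):
        tables = {"a": rank_pairs(random_table(3)),
                  "b": rank_pairs(random_table(4))}
        sizes = [len(top_overlap(tables, "inter", n)["overlap"])
                 for n in range(1, 10)]
        assert sizes == sorted(sizes)

    def test_brute_force_equivalence(self):
        tables = {"a": rank_pairs(random_table(8)),
                  "b": rank_pairs(random_table(9))}
        for n in range(1, 10):
            out = top_overlap(tables, "inter", n)
            brute = None
            for name, ranked in tables.items():
                k = brute_force_links_needed(ranked, "inter", n)
                top = {(r.i, r.j) for r in ranked.iloc[:k].itertuples()
                       if r.cls == "inter"}
                brute = top if brute is None else brute & top
            assert set(out["overlap"]) == brute


class TestDensitySummary:
    def test_counts_conserved(self):
        t = random_table(6)
        d = density_summary(t)
        L = t.L
        assert d["classes"]["inter+intra"]["count"] == L * (L - 1) // 2
        assert d["classes"]["inter"]["count"] + \
            d["classes"]["intra"]["count"] == L * (L - 1) // 2

    def test_inter_count_is_product_of_segment_lengths(self):
        t = random_table(6, segments=[("A", 0, 4), ("B", 4, 9)])
        d = density_summary(t)
        assert d["classes"]["inter"]["count"] == 4 * 5

    def test_quantiles_match_sort_oracle(self):
        t = random_table(10)
        d = density_summary(t)
        iu = np.triu_indices(t.L, k=1)
        vals = np.sort(t.scores[iu])
        for p, v in d["classes"]["inter+intra"]["quantiles"].items():
            assert v == pytest.approx(np.percentile(vals, float(p)))


class TestProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(0, 10_000), st.integers(2, 5), st.integers(1, 8))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_class_counts_and_links_monotonicity(self, seed, la, lb):
        segments = [("A", 0, la), ("B", la, la + lb)]
        t = random_table(seed, segments=segments)
        L = la + lb
        from intercov.compare import classify_pairs
        iu = np.triu_indices(L, k=1)
        classes = classify_pairs(segments, L)[iu]
        n_inter = sum(c == "inter" for c in classes)
        assert len(classes) == L * (L - 1) // 2
        assert n_inter == la * lb
        ranked = rank_pairs(t)
        prev = 0
        for n in range(1, n_inter + 1):
            k = links_needed(ranked, "inter", n)
            assert k >= prev and k >= links_needed(ranked, "both", n)
            prev = k


class TestScoreIO:
    def test_roundtrip_preserves_ranking(self, tmp_path):
        t = random_table(12, method="zscore")
        path = tmp_path / "scores.tsv"
        export_scores(t, path, reference="ACDEFG")
        back = read_score_tsv(path, SEGMENTS)
        assert back.method == "zscore"
        r1 = rank_pairs(t)
        r2 = rank_pairs(back)
        assert list(zip(r1["i"], r1["j"])) == list(zip(r2["i"], r2["j"]))

    def test_import_complete_external_file(self, tmp_path):
        path = tmp_path / "ext.tsv"
        lines = ["# method: psicov", "i\tj\tscore"]
        for i in range(1, 5):
            for j in range(i + 1, 5):
                lines.append(f"{i}\t{j}\t{i * 10 + j}")
        path.write_text("\n".join(lines) + "\n")
        t = import_external_scores(path, [("A", 0, 2), ("B", 2, 4)], 4)
        assert t.method == "psicov"
        assert t.scores[0, 1] == 12
        assert t.scores[1, 0] == 12

    def test_conflicting_duplicates_rejected(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("i\tj\tscore\n5\t2\t1.0\n2\t5\t2.0\n")
        with pytest.raises(ValueError, match="conflicting"):
            import_external_scores(path, [("A", 0, 3), ("B", 3, 5)], 5)

    def test_missing_pairs_need_sparse_flag(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("i\tj\tscore\n1\t2\t3.0\n")
        segs = [("A", 0, 2), ("B", 2, 4)]
        with pytest.raises(ValueError, match="sparse"):
            import_external_scores(path, segs, 4)
        t = import_external_scores(path, segs, 4, sparse=True)
        ranked = rank_pairs(t)
        assert (ranked.iloc[0]["i"], ranked.iloc[0]["j"]) == (0, 1)
        assert np.isneginf(ranked.iloc[-1]["score"])

    def test_out_of_range_positions_rejected(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("i\tj\tscore\n1\t9\t3.0\n")
        with pytest.raises(ValueError, match="out of range"):
            import_external_scores(path, [("A", 0, 2), ("B", 2, 4)], 4)
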