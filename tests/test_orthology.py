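import itertools

import numpy as np
import pytest

from netsel.orthology import (
    HitRecord,
    OrthologyCall,
    Thresholds,
    best_hit,
    classify_orthologs,
    filter_hits,
    presence_flags,
    presence_matrix,
)


def make_hit(query="g1", subject="h1", score=200.0, length=100, identity=50.0,
             similarity=60.0, coverage=0.8):
    return HitRecord(query, subject, score, length, identity, similarity, coverage)


class TestFilterHits:
    def test_strict_boundaries(self):
        kept = filter_hits([
            make_hit(score=151, length=51),
            make_hit(score=150, length=300),
            make_hit(score=300, length=50),
        ])
        assert len(kept) == 1
        assert kept[0].score == 151

    def test_empty_input(self):
        assert filter_hits([]) == []

    def test_matches_predicate_scan(self):
        rng = np.random.default_rng(0)
        hits = [
            make_hit(score=float(s), length=int(l))
            for s, l in zip(rng.uniform(100, 200, 100), rng.integers(20, 80, 100))
        ]
        kept = filter_hits(hits)
        expected = [h for h in hits if h.score > 150 and h.alignment_length > 50]
        assert kept == expected

    def test_order_preserved(self):
        hits = [make_hit(subject=f"h{i}", score=200 + i) for i in range(5)]
        assert [h.subject for h in filter_hits(hits)] == [f"h{i}" for i in range(5)]


class TestBestHit:
    def test_single_and_score_ordering(self):
        only = make_hit()
        assert best_hit([only]) is only
        lo, hi = make_hit(score=180), make_hit(score=200, subject="h2")
        assert best_hit([lo, hi]) is hi

    def test_tie_break_stable_under_permutation(self):
        hits = [
            make_hit(subject="hB", score=200, similarity=70),
            make_hit(subject="hA", score=200, similarity=70),
            make_hit(subject="hC", score=200, similarity=75),
        ]
        winners = {best_hit(list(p)).subject for p in itertools.permutations(hits)}
        assert winners == {"hC"}  # higher similarity wins, then lexicographic

    def test_empty_and_mixed_queries(self):
        assert best_hit([]) is None
        with pytest.raises(ValueError, match="multiple queries"):
            best_hit([make_hit(query="a"), make_hit(query="b")])


class TestClassify:
    def test_reciprocal_pair_is_ortholog(self):
        ab = [make_hit("gA", "gB")]
        ba = [make_hit("gB", "gA")]
        (call,) = classify_orthologs(ab, ba)
        assert call.verdict == "ortholog_rbh"

    def test_fallback_thresholds(self):
        ab = [make_hit("gA", "gB", score=200, identity=35, similarity=45)]
        ba = [make_hit("gB", "gX", score=500)]  # best hit elsewhere
        (call,) = classify_orthologs(ab, ba)
        assert call.verdict == "homolog_fallback"

    def test_below_thresholds_is_non_homolog(self):
        ab = [make_hit("gA", "gB", score=200, identity=25, similarity=35)]
        ba = [make_hit("gB", "gX", score=500)]
        (call,) = classify_orthologs(ab, ba)
        assert call.verdict == "non_homolog"

    def test_no_surviving_hit_is_absent(self):
        ab = [make_hit("gA", "gB", score=100)]
        (call,) = classify_orthologs(ab, [], queries=["gA"])
        assert call.verdict == "absent"

    def test_toy_genome_pair_matches_hand_trace(self):
        """Six genes exercising every rule branch, verdicts traced by hand."""
        ab = [
            make_hit("g1", "h1", score=400),                     # rbh
            make_hit("g2", "h2", score=300, identity=35, similarity=45),  # fallback
            make_hit("g3", "h3", score=200, identity=20, similarity=30),  # non-homolog
            make_hit("g4", "h4", score=120),                     # filtered -> absent
            make_hit("g5", "h5", score=250),                     # rbh
        ]
        ba = [
            make_hit("h1", "g1", score=390),
            make_hit("h2", "g9", score=600),
            make_hit("h3", "g9", score=600),
            make_hit("h5", "g5", score=240),
        ]
        calls = classify_orthologs(ab, ba, queries=["g1", "g2", "g3", "g4", "g5", "g6"])
        verdicts = {c.gene: c.verdict for c in calls}
        assert verdicts == {
            "g1": "ortholog_rbh",
            "g2": "homolog_fallback",
            "g3": "non_homolog",
            "g4": "absent",
            "g5": "ortholog_rbh",
            "g6": "absent",
        }

    def test_raising_thresholds_never_rescues(self):
        """Monotonicity: stricter thresholds can only demote verdicts."""
        ab = [make_hit("gA", "gB", score=200, identity=35, similarity=45)]
        ba = [make_hit("gB", "gX", score=500)]
        base = classify_orthologs(ab, ba)[0].verdict
        assert base == "homolog_fallback"
        stricter = classify_orthologs(
            ab, ba, Thresholds(identity=36.0)
        )[0].verdict
        assert stricter == "non_homolog"

    def test_permutation_invariance(self):
        ab = [
            make_hit("gA", "gB", score=250),
            make_hit("gA", "gC", score=250),
            make_hit("gA", "gD", score=240),
        ]
        ba = [make_hit("gB", "gA", score=250), make_hit("gC", "gZ", score=400)]
        verdicts = set()
        for perm in itertools.permutations(ab):
            verdicts.add(classify_orthologs(list(perm), ba)[0].verdict)
        assert len(verdicts) == 1

    def test_malformed_id_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            make_hit(query="bad id")


class TestPresenceMatrix:
    def test_all_absent_gives_zero_matrix(self):
        calls = [OrthologyCall("g1", "sp1", "absent"),
                 OrthologyCall("g2", "sp1", "non_homolog")]
        matrix = presence_matrix(calls)
        assert (matrix.to_numpy() == 0).all()

    def test_paralogous_calls_counted(self):
        calls = [
            OrthologyCall("g1", "sp1", "ortholog_rbh"),
            OrthologyCall("g1", "sp1", "homolog_fallback"),
            OrthologyCall("g1", "sp2", "ortholog_rbh"),
        ]
        matrix = presence_matrix(calls)
        assert matrix.loc["g1", "sp1"] == 2
        assert matrix.loc["g1", "sp2"] == 1
        flags = presence_flags(matrix)
        assert flags.loc["g1", "sp1"] == 1

    def test_matches_tally_oracle(self):
        rng = np.random.default_rng(1)
        verdicts = ["ortholog_rbh", "homolog_fallback", "non_homolog", "absent"]
        calls = [
            OrthologyCall(f"g{rng.integers(3)}", f"sp{rng.integers(2)}",
                          verdicts[rng.integers(4)])
            for _ in range(60)
        ]
        matrix = presence_matrix(calls)
        for gene in matrix.index:
            for genome in matrix.columns:
                expected = sum(
                    1 for c in calls
                    if c.gene == gene and c.target_genome == genome
                    and c.verdict in ("ortholog_rbh", "homolog_fallback")
                )
                assert matrix.loc[gene, genome] == expected
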