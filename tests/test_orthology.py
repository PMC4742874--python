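"""Reciprocal-best-hit calling, semen cross-referencing and Venn regions."""

import numpy as np
import pandas as pd
import pytest

from spermatophore.orthology import (
    BLAST_COLUMNS,
    HitTableParseError,
    OrthologyParams,
    best_hits,
    intersect_sets,
    rbh,
    read_hit_table,
    semen_crossref,
)


def hits(rows):
    """rows: (query, subject, evalue, bitscore)."""
    return pd.DataFrame(
        [
            {
                "qseqid": q, "sseqid": s, "pident": 90.0, "length": 100,
                "mismatch": 5, "gapopen": 1, "qstart": 1, "qend": 100,
                "sstart": 1, "send": 100, "evalue": e, "bitscore": b,
            }
            for q, s, e, b in rows
        ],
        columns=BLAST_COLUMNS,
    )


class TestBestHits:
    def test_single_surviving_hit(self):
        assert best_hits(hits([("q", "s", 1e-20, 100)])) == {"q": "s"}

    def test_threshold_is_exclusive(self):
        assert best_hits(hits([("q", "s", 1e-9, 100)])) == {}
        assert best_hits(hits([("q", "s", 1e-10, 100)])) == {}
        assert best_hits(hits([("q", "s", 0.99e-10, 100)])) == {"q": "s"}

    def test_tie_break_by_bitscore_then_subject(self):
        assert best_hits(hits([("q", "a", 1e-30, 180), ("q", "b", 1e-30, 200)])) == {"q": "b"}
        assert best_hits(hits([("q", "b", 1e-30, 200), ("q", "a", 1e-30, 200)])) == {"q": "a"}

    def test_hsp_rows_collapse_to_best_per_pair(self):
        table = hits([("q", "s", 1e-30, 100), ("q", "s", 1e-50, 90), ("q", "t", 1e-40, 100)])
        assert best_hits(table) == {"q": "s"}

    def test_self_hits_dropped(self):
        assert best_hits(hits([("q", "q", 1e-80, 500), ("q", "s", 1e-20, 100)])) == {"q": "s"}

    def test_filtered_best_does_not_shadow_weaker_survivor(self):
        # the nominally best hit is above threshold; the surviving hit wins
        table = hits([("q", "gone", 1e-5, 900), ("q", "kept", 1e-15, 80)])
        assert best_hits(table) == {"q": "kept"}


def brute_force_rbh(forward, reverse, e_threshold):
    """Independent oracle: double loop over queries and subjects."""

    def best_of(table, query):
        cand = [
            r
            for _, r in table.iterrows()
            if r["qseqid"] == query and r["evalue"] < e_threshold and r["qseqid"] != r["sseqid"]
        ]
        if not cand:
            return None
        cand.sort(key=lambda r: (r["evalue"], -r["bitscore"], r["sseqid"]))
        return cand[0]["sseqid"]

    pairs = []
    for q in sorted(set(forward["qseqid"])):
        b = best_of(forward, q)
        if b is not None and best_of(reverse, b) == q:
            pairs.append((q, b))
    return sorted(pairs)


def random_instance(rng, n=20):
    queries = [f"q{i}" for i in range(n)]
    subjects = [f"s{i}" for i in range(n)]
    e_pool = [1e-40, 1e-30, 1e-30, 1e-20, 1e-12, 1e-9, 1e-6]

    def table(qs, ss):
        rows = []
        for q in qs:
            for s in rng.choice(ss, size=rng.integers(0, 5), replace=False):
                rows.append((q, s, float(rng.choice(e_pool)), float(rng.choice([100, 150, 150, 200]))))
        return hits(rows)

    return table(queries, subjects), table(subjects, queries)


class TestRBH:
    def test_planted_pair_and_one_way_decoy(self):
        fwd = hits([("g", "x", 1e-30, 200), ("g2", "y", 1e-30, 200)])
        rev = hits([("x", "g", 1e-30, 200), ("y", "g", 1e-25, 300)])
        assert rbh(fwd, rev) == [("g", "x")]

    def test_matches_brute_force_on_random_instances(self, rng):
        params = OrthologyParams()
        for _ in range(50):
            fwd, rev = random_instance(rng)
            got = rbh(fwd, rev, params)
            assert got == brute_force_rbh(fwd, rev, params.e_threshold)
            # symmetry: swapping tables swaps pair order
            swapped = rbh(rev, fwd, params)
            assert sorted((b, a) for a, b in got) == swapped
            # one-to-one matching
            assert len({a for a, _ in got}) == len(got)
            assert len({b for _, b in got}) == len(got)

    def test_shrinking_threshold_never_adds_pairs(self, rng):
        for _ in range(20):
            fwd, rev = random_instance(rng)
            loose = set(rbh(fwd, rev, OrthologyParams(1e-10)))
            tight = set(rbh(fwd, rev, OrthologyParams(1e-25)))
            assert tight <= loose


class TestSemenCrossref:
    def test_classes(self):
        pairs = [("a", "x"), ("b", "y"), ("c", "z"), ("d", "w")]
        calls = semen_crossref(
            pairs, sfp_list=["x", "z"], sperm_list=["y", "z"],
            all_query_ids=["a", "b", "c", "d", "e"],
        ).set_index("protein_id")
        assert calls.at["a", "semen_class"] == "SFP"
        assert calls.at["b", "semen_class"] == "sperm"
        assert calls.at["c", "semen_class"] == "both"
        assert calls.at["d", "semen_class"] == "neither"
        assert calls.at["e", "semen_class"] == "no_ortholog"
        assert pd.isna(calls.at["e", "ortholog_id"]) or calls.at["e", "ortholog_id"] is None


class TestIntersectSets:
    def test_identical_and_disjoint(self):
        s = {"A": set("abcde"), "B": set("abcde")}
        regions = intersect_sets(s)
        assert regions["A&B"] == 5 and regions["A"] == 0 and regions["B"] == 0
        regions = intersect_sets({"A": {"a"}, "B": {"b"}})
        assert regions == {"A": 1, "B": 1, "A&B": 0}

    def test_matches_membership_enumeration(self, rng):
        universe = [f"id{i}" for i in range(100)]
        named = {
            name: set(rng.choice(universe, size=rng.integers(5, 60), replace=False))
            for name in "ABCDE"
        }
        regions = intersect_sets(named)
        # oracle: per-id membership patterns
        expected: dict = {}
        for item in set().union(*named.values()):
            key = "&".join(n for n in "ABCDE" if item in named[n])
            expected[key] = expected.get(key, 0) + 1
        for key, count in expected.items():
            assert regions[key] == count
        assert sum(regions.values()) == len(set().union(*named.values()))

    def test_too_many_sets_rejected(self):
        with pytest.raises(ValueError):
            intersect_sets({str(i): {i} for i in range(7)})


class TestHitTableIO:
    def test_round_trip_and_comments(self, tmp_path):
        table = hits([("q", "s", 1e-30, 200.5)])
        path = tmp_path / "hits.tsv"
        lines = "# a comment line\n" + "\t".join(
            str(v) for v in table.iloc[0]
        ) + "\n"
        path.write_text(lines)
        parsed = read_hit_table(path)
        assert len(parsed) == 1
        assert parsed.at[0, "evalue"] == 1e-30
        assert parsed.at[0, "bitscore"] == 200.5

    def test_malformed_rows_carry_line_numbers(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q\ts\tonly_three\n")
        with pytest.raises(HitTableParseError, match="line 1"):
            read_hit_table(path)
        path.write_text(
            "\t".join(["q", "s", "90", "100", "5", "1", "1", "100", "1", "100", "not_a_number", "200"]) + "\n"
        )
        with pytest.raises(HitTableParseError, match="evalue"):
            read_hit_table(path)
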