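"""Fingerprint construction, window search, statistics and identification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axokit import (
    CANONICAL_RESIDUES,
    CLASS_LABELS,
    DEFAULT_SCHEME,
    Fingerprint,
    FingerprintPosition,
    ProteomeDB,
    ResidueClassScheme,
    SearchPolicy,
    ValidationError,
    compile_pattern,
    cross_verify,
    expected_random_matches,
    fingerprint_from_classes,
    identify_protein,
    refine_policy,
    relax_fingerprint,
    score_candidate,
    search_pattern,
)
from axokit.fingerprint import MatchHit

from conftest import brute_force_search, random_db, random_pattern


# --------------------------------------------------------------------------
# Scheme and pattern compilation
# --------------------------------------------------------------------------

class TestScheme:
    def test_default_scheme_partitions_canonical_alphabet(self):
        union = set()
        for label in CLASS_LABELS:
            members = DEFAULT_SCHEME.classes[label]
            assert not union & members
            union |= members
        assert union == set(CANONICAL_RESIDUES)
        assert DEFAULT_SCHEME.classes["LARGE"] == set("WYRFH")
        assert DEFAULT_SCHEME.classes["GLY"] == {"G"}

    def test_overlapping_classes_rejected(self):
        with pytest.raises(ValidationError):
            ResidueClassScheme(
                classes={
                    "LARGE": frozenset("WYRFHG"),
                    "MIDDLE": frozenset("LQNIMK"),
                    "SMALL": frozenset("PVSTCEDA"),
                    "GLY": frozenset("G"),
                }
            )

    def test_incomplete_cover_rejected(self):
        with pytest.raises(ValidationError):
            ResidueClassScheme(
                classes={
                    "LARGE": frozenset("WYRFH"),
                    "MIDDLE": frozenset("LQNIMK"),
                    "SMALL": frozenset("PVSTCED"),  # A missing
                    "GLY": frozenset("G"),
                }
            )


class TestCompilePattern:
    def test_class_labels_expand_to_residue_sets(self):
        fp = fingerprint_from_classes(["LARGE", "GLY", "SMALL"])
        assert compile_pattern(fp) == [
            frozenset("WYRFH"),
            frozenset("G"),
            frozenset("PVSTCEDA"),
        ]

    def test_wildcard_allows_all_20(self):
        fp = fingerprint_from_classes(["WILDCARD"])
        assert compile_pattern(fp) == [frozenset(CANONICAL_RESIDUES)]

    def test_union_position(self):
        fp = fingerprint_from_classes([{"LARGE", "MIDDLE"}])
        (allowed,) = compile_pattern(fp)
        assert allowed == frozenset("WYRFH") | frozenset("LQNIMK")
        assert len(allowed) == 11

    def test_unknown_class_label_rejected(self):
        with pytest.raises(ValidationError):
            FingerprintPosition(frozenset(["HUGE"]))

    def test_empty_fingerprint_rejected(self):
        with pytest.raises(ValidationError):
            Fingerprint(positions=())


# --------------------------------------------------------------------------
# Window search
# --------------------------------------------------------------------------

LGS = compile_pattern(fingerprint_from_classes(["LARGE", "GLY", "SMALL"]))


class TestSearchPattern:
    def test_exact_match_found(self):
        db = ProteomeDB({"s1": "AWGSA"})
        hits = search_pattern(LGS, db)
        assert [(h.seq_id, h.start, h.end, h.n_mismatches) for h in hits] == [
            ("s1", 1, 4, 0)
        ]
        assert hits[0].matched_subsequence == "WGS"

    def test_one_mismatch_tolerated(self):
        db = ProteomeDB({"s1": "AWGSA"})
        pattern = compile_pattern(fingerprint_from_classes(["LARGE", "GLY", "GLY"]))
        assert search_pattern(pattern, db) == []
        hits = search_pattern(pattern, db, max_mismatches=1)
        assert [(h.seq_id, h.start, h.n_mismatches) for h in hits] == [("s1", 1, 1)]

    def test_no_match_is_empty_not_error(self):
        db = ProteomeDB({"s1": "GGGGGGGG"})
        pattern = compile_pattern(fingerprint_from_classes(["LARGE"] * 3))
        assert search_pattern(pattern, db) == []

    def test_pattern_longer_than_sequences_is_empty(self):
        db = ProteomeDB({"s1": "AWG"})
        assert search_pattern([frozenset("A")] * 10, db) == []

    def test_noncanonical_letter_counts_as_mismatch_even_for_wildcard(self):
        db = ProteomeDB({"s1": "AXGSA"})
        wildcard = compile_pattern(fingerprint_from_classes(["WILDCARD"] * 3))
        hits = search_pattern(wildcard, db, max_mismatches=0)
        # windows containing X (starts 0, 1, 2) all miss; only GSA matches
        assert [(h.seq_id, h.start) for h in hits] == [("s1", 2)]

    def test_hits_carry_policy_sorted_order(self, rng):
        db = random_db(rng, n_sequences=5, length=80)
        pattern = random_pattern(rng, 3, 5)
        hits = search_pattern(pattern, db, max_mismatches=2)
        keys = [h.sort_key() for h in hits]
        assert keys == sorted(keys)

    def test_matches_brute_force_oracle_on_random_cases(self, rng):
        for _ in range(20):
            db = random_db(rng, n_sequences=8, length=60)
            pattern = random_pattern(rng)
            m = int(rng.integers(0, 3))
            got = sorted(
                (h.seq_id, h.start, h.n_mismatches)
                for h in search_pattern(pattern, db, max_mismatches=m)
            )
            assert got == brute_force_search(pattern, db.records, m)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        m=st.integers(0, 2),
        length=st.integers(10, 60),
    )
    def test_matches_brute_force_oracle_property(self, seed, m, length):
        gen = np.random.default_rng(seed)
        db = random_db(gen, n_sequences=3, length=length)
        pattern = random_pattern(gen)
        got = sorted(
            (h.seq_id, h.start, h.n_mismatches)
            for h in search_pattern(pattern, db, max_mismatches=m)
        )
        assert got == brute_force_search(pattern, db.records, m)

    def test_hit_sets_nested_in_mismatch_tolerance(self, rng):
        db = random_db(rng, n_sequences=10, length=100)
        pattern = random_pattern(rng, 4, 8)
        previous = set()
        for m in range(3):
            current = {
                (h.seq_id, h.start) for h in search_pattern(pattern, db, max_mismatches=m)
            }
            assert previous <= current
            previous = current

    def test_enlarging_an_allowed_set_never_removes_hits(self, rng):
        db = random_db(rng, n_sequences=10, length=100)
        pattern = random_pattern(rng, 4, 8)
        base = {(h.seq_id, h.start) for h in search_pattern(pattern, db, max_mismatches=1)}
        widened = list(pattern)
        widened[0] = frozenset(CANONICAL_RESIDUES)
        more = {(h.seq_id, h.start) for h in search_pattern(widened, db, max_mismatches=1)}
        assert base <= more

    def test_within_class_substitution_leaves_hits_unchanged(self, rng):
        db = random_db(rng, n_sequences=10, length=100)
        pattern = random_pattern(rng, 4, 8)
        # replace every residue with a random member of its own size class
        mutated = {}
        for seq_id, seq in db.records.items():
            out = []
            for r in seq:
                members = sorted(DEFAULT_SCHEME.classes[DEFAULT_SCHEME.class_of(r)])
                out.append(members[rng.integers(0, len(members))])
            mutated[seq_id] = "".join(out)
        before = {
            (h.seq_id, h.start, h.n_mismatches)
            for h in search_pattern(pattern, db, max_mismatches=2)
        }
        after = {
            (h.seq_id, h.start, h.n_mismatches)
            for h in search_pattern(pattern, ProteomeDB(mutated), max_mismatches=2)
        }
        assert before == after


# --------------------------------------------------------------------------
# Expected random matches
# --------------------------------------------------------------------------

class TestExpectedRandomMatches:
    def test_uniform_single_sequence(self):
        # 3 windows x P(LARGE) P(GLY) P(SMALL) = 3 x 0.25 x 0.05 x 0.40
        db = ProteomeDB({"s1": "AAAAA"})
        assert expected_random_matches(LGS, db, "UNIFORM") == pytest.approx(0.015)

    def test_all_wildcard_counts_windows(self):
        db = ProteomeDB({"a": "A" * 10, "b": "A" * 3, "c": "A" * 2})
        wildcard = compile_pattern(fingerprint_from_classes(["WILDCARD"] * 3))
        # max(0, len-k+1) summed: 8 + 1 + 0
        assert expected_random_matches(wildcard, db, "UNIFORM") == pytest.approx(9.0)

    def test_empty_db_gives_zero(self):
        assert expected_random_matches(LGS, ProteomeDB({}), "UNIFORM") == 0.0

    def test_mismatch_levels_match_subset_enumeration(self):
        # independent oracle: explicit sum over mismatching position subsets
        db = ProteomeDB({"s1": "A" * 30})
        pattern = compile_pattern(
            fingerprint_from_classes(["LARGE", "MIDDLE", "GLY", "SMALL", "LARGE"])
        )
        p = [len(s) / 20.0 for s in pattern]
        n_windows = 30 - 5 + 1
        for m in range(3):
            exact = 0.0
            for miss in range(m + 1):
                for subset in itertools.combinations(range(5), miss):
                    term = 1.0
                    for i in range(5):
                        term *= (1 - p[i]) if i in subset else p[i]
                    exact += term
            assert expected_random_matches(
                pattern, db, "UNIFORM", max_mismatches=m
            ) == pytest.approx(n_windows * exact, rel=1e-12)

    def test_empirical_composition_reflects_database(self):
        db = ProteomeDB({"s1": "WWWWGGGG"})  # only W and G present
        pattern = compile_pattern(fingerprint_from_classes(["LARGE"]))
        # P(LARGE) under the empirical composition is 0.5 (W only)
        assert expected_random_matches(pattern, db, "EMPIRICAL") == pytest.approx(
            8 * 0.5
        )

    def test_monte_carlo_calibration_small(self, rng):
        observed = []
        for _ in range(400):
            db = random_db(rng, n_sequences=2, length=60, prefix="mc")
            observed.append(len(search_pattern(LGS, db)))
        expected = 2 * (60 - 3 + 1) * 0.005
        se = np.std(observed, ddof=1) / np.sqrt(len(observed))
        assert abs(np.mean(observed) - expected) < 3 * se + 1e-12


# --------------------------------------------------------------------------
# Policy refinement, relaxation, scoring
# --------------------------------------------------------------------------

class TestRefinePolicy:
    @pytest.mark.parametrize(
        "n_hits,relax,db_left,expected",
        [
            (500, True, True, "STRICTEN"),
            (0, True, True, "RELAX"),
            (0, False, True, "ESCALATE_DB"),
            (0, False, False, "ACCEPT"),  # exhausted: loop terminates
            (3, True, True, "ACCEPT"),
            (20, True, True, "ACCEPT"),
            (21, True, True, "STRICTEN"),
        ],
    )
    def test_actions(self, n_hits, relax, db_left, expected):
        policy = SearchPolicy(max_hits=20)
        assert refine_policy(n_hits, policy, relax, db_left) == expected

    def test_negative_hits_rejected(self):
        with pytest.raises(ValidationError):
            refine_policy(-1, SearchPolicy())


class TestRelaxFingerprint:
    def test_nonconfident_positions_widen_to_adjacent_classes(self):
        fp = fingerprint_from_classes(
            ["LARGE", "GLY", "MIDDLE"], confident=[False, False, True]
        )
        relaxed = relax_fingerprint(fp)
        assert relaxed.positions[0].allowed_classes == {"LARGE", "MIDDLE"}
        assert relaxed.positions[1].allowed_classes == {"GLY", "SMALL"}
        assert relaxed.positions[2].allowed_classes == {"MIDDLE"}  # confident kept

    def test_relaxation_only_grows_sets(self):
        fp = fingerprint_from_classes(
            ["SMALL", "MIDDLE"], confident=[False, False]
        )
        relaxed = relax_fingerprint(fp)
        for before, after in zip(fp.positions, relaxed.positions):
            assert before.allowed_classes <= after.allowed_classes


class TestScoreCandidate:
    def test_exact_source_window_scores_zero(self):
        fp = fingerprint_from_classes(["LARGE", "GLY", "SMALL"])
        flags, count = score_candidate(fp, "WGS")
        assert flags == [False, False, False] and count == 0

    def test_cross_class_substitution_scores_one(self):
        fp = fingerprint_from_classes(["LARGE", "GLY", "SMALL"])
        flags, count = score_candidate(fp, "GGS")  # W->G at a LARGE position
        assert flags == [True, False, False] and count == 1

    def test_within_class_substitution_indistinguishable(self):
        fp = fingerprint_from_classes(["MIDDLE", "GLY"])
        assert score_candidate(fp, "LG")[1] == 0
        assert score_candidate(fp, "IG")[1] == 0  # L->I stays MIDDLE

    def test_length_mismatch_rejected(self):
        fp = fingerprint_from_classes(["LARGE", "GLY"])
        with pytest.raises(ValidationError):
            score_candidate(fp, "WGS")


# --------------------------------------------------------------------------
# Cross-verification and identification
# --------------------------------------------------------------------------

def _hit(seq_id, start=0, nm=0, e=1e-3):
    return MatchHit(seq_id, start, start + 3, nm, e, "WGS")


class TestCrossVerify:
    def test_agreeing_regions_identify(self):
        consensus, status, note = cross_verify(
            {"r1": [_hit("P"), _hit("Q", nm=1)], "r2": [_hit("P", start=5)]}
        )
        assert (consensus, status) == ("P", "IDENTIFIED")
        assert note == ""

    def test_disagreeing_regions_conflict(self):
        consensus, status, _ = cross_verify({"r1": [_hit("P")], "r2": [_hit("Q")]})
        assert (consensus, status) == (None, "CONFLICT")

    def test_no_hits_unresolved(self):
        consensus, status, _ = cross_verify({"r1": [], "r2": []})
        assert (consensus, status) == (None, "UNRESOLVED")

    def test_single_region_notes_provenance(self):
        consensus, status, note = cross_verify({"r1": [_hit("P")], "r2": []})
        assert (consensus, status, note) == ("P", "IDENTIFIED", "single-region")

    def test_tied_top_hits_do_not_identify(self):
        consensus, status, _ = cross_verify({"r1": [_hit("P"), _hit("Q")]})
        assert status == "UNRESOLVED" and consensus is None


class TestIdentifyProtein:
    @staticmethod
    def _db():
        return ProteomeDB(
            {
                "target": "AAAA" + "WGSLK" + "AAAA" + "RGPQM" + "AAAA",
                "decoy": "GGGGGGGGGGGGGGGGGGGG",
            },
            name="toy",
        )

    def test_two_agreeing_regions_identified(self):
        fps = [
            fingerprint_from_classes(
                ["LARGE", "GLY", "SMALL", "MIDDLE", "MIDDLE"], region_id="r1"
            ),
            fingerprint_from_classes(
                ["LARGE", "GLY", "SMALL", "MIDDLE", "MIDDLE"], region_id="r2"
            ),
        ]
        policy = SearchPolicy(database_chain=("toy",))
        report = identify_protein(fps, policy, {"toy": self._db()})
        assert report.status == "IDENTIFIED"
        assert report.consensus_candidate == "target"
        assert report.databases_searched == ["toy"]

    def test_unmatchable_region_escalates_then_unresolved(self):
        # all-GLY pattern of length 6 matches nothing in either G-free db
        fp = fingerprint_from_classes(["GLY"] * 6, region_id="r1")
        small = ProteomeDB({"a": "WWWWWWWW"}, name="small")
        big = ProteomeDB({"b": "PPPPPPPPLLLL", "c": "WWWWLLLLPPPP"}, name="big")
        policy = SearchPolicy(database_chain=("small", "big"), relax_budget=0)
        report = identify_protein([fp], policy, {"small": small, "big": big})
        assert report.status == "UNRESOLVED"
        assert report.databases_searched == ["small", "big"]

    def test_conflicting_regions_discarded(self):
        db = ProteomeDB({"p1": "WGSWW", "p2": "PPGPP"}, name="toy")
        fps = [
            fingerprint_from_classes(["LARGE", "GLY", "SMALL"], region_id="r1"),
            fingerprint_from_classes(["SMALL", "GLY", "SMALL"], region_id="r2"),
        ]
        policy = SearchPolicy(database_chain=("toy",))
        report = identify_protein(fps, policy, {"toy": db})
        assert report.status == "CONFLICT"
        assert report.consensus_candidate is None

    def test_relaxation_rescues_a_misread_position(self):
        # the MIDDLE call at position 3 is a misread of a true SMALL residue;
        # the non-confident flag lets relaxation widen it
        db = ProteomeDB({"target": "AAWGSPAA" + "A" * 20}, name="toy")
        fp = fingerprint_from_classes(
            ["LARGE", "GLY", "SMALL", "MIDDLE"],
            confident=[True, True, True, False],
            region_id="r1",
        )
        policy = SearchPolicy(max_mismatches=0, database_chain=("toy",), relax_budget=1)
        report = identify_protein([fp], policy, {"toy": db})
        assert report.status == "IDENTIFIED"
        assert report.consensus_candidate == "target"
        assert any("relaxed" in n for n in report.notes)

    def test_overlong_hit_list_truncated_to_max_hits(self, rng):
        db = random_db(rng, n_sequences=30, length=50)
        fp = fingerprint_from_classes(["WILDCARD"] * 3, region_id="r1")
        policy = SearchPolicy(max_hits=5, database_chain=("r",))
        report = identify_protein([fp], policy, {"r": db})
        assert len(report.region_hits["r1"]) == 5
        assert any("truncated" in n for n in report.notes)

    def test_empty_fingerprint_list_rejected(self):
        with pytest.raises(ValidationError):
            identify_protein([], SearchPolicy(), {})

    def test_mixed_chains_rejected(self):
        fps = [
            fingerprint_from_classes(["GLY"], chain_label="A"),
            fingerprint_from_classes(["GLY"], chain_label="B"),
        ]
        with pytest.raises(ValidationError):
            identify_protein(fps, SearchPolicy(), {"toy": self._db()})
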