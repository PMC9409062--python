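"""Overlap-conflict detection and keep/discard resolution."""

import random

import pytest

from phagepipe.annotation_transfer import ProfileHit, assign_phrog
from phagepipe.consensus import ConsensusOrf
from phagepipe.curation import (
    classify_affiliation_strength,
    curate_genome,
    find_overlaps,
    orf_feature_id,
    resolve_conflict,
)
from phagepipe.errors import ContractError
from phagepipe.io_formats import TrnaRecord


def make_orf(start, end, strand="+", genome="g"):
    return ConsensusOrf(
        genome_id=genome, strand=strand,
        stop_anchor=end if strand == "+" else start,
        supporting_callers=frozenset({"Phanotate"}),
        selected_start=start, selected_end=end,
        variants={"Phanotate": (start, end)},
    )


def assignment(prob, evalue, query="q"):
    return assign_phrog(
        ProfileHit(query, "phrog_x", "phrog", prob, evalue, 0.9, "p", "other")
    )


class TestFindOverlaps:
    def test_mutually_overlapping_trio_is_one_conflict(self, curation_cases):
        case = curation_cases["weak_pair_trio"]
        conflicts = find_overlaps(case.orfs, case.trnas)
        orf_orf = [c for c in conflicts if c.kind == "orf-orf"]
        assert len(orf_orf) == 1
        assert len(orf_orf[0].members) == 3

    def test_contained_trna_reported(self, curation_cases):
        case = curation_cases["trna_overlap"]
        conflicts = find_overlaps(case.orfs, case.trnas)
        assert [c.kind for c in conflicts] == ["orf-trna"]

    def test_small_overlap_below_threshold_ignored(self):
        a, b = make_orf(1, 300), make_orf(298, 600)
        assert find_overlaps([a, b]) == []

    def test_wraparound_overlap_detected_on_circular_genome(self):
        a = make_orf(4801, 5100)  # spans origin of a 5000 bp genome
        b = make_orf(1, 150)
        conflicts = find_overlaps([a, b], genome_length=5000, circular=True)
        assert len(conflicts) == 1

    def test_opposite_strand_trna_not_a_conflict(self):
        orf = make_orf(100, 699)
        trna = TrnaRecord("g", 200, 275, "-", "Val")
        assert find_overlaps([orf], [trna]) == []


class TestStrengthClassification:
    @pytest.mark.parametrize(
        "prob,evalue,expected",
        [
            (99.5, 1.4e-18, "strong"),
            (23.5, 7.4, "weak"),
            (55, 1.1, "weak"),
            (69.9, 1e-10, "weak"),   # probability below 70
            (90, 2e-4, "weak"),      # evalue above 1e-4
            (70.0, 1e-4, "strong"),  # boundary: not below / not above
        ],
    )
    def test_weak_rule(self, prob, evalue, expected):
        assert classify_affiliation_strength(assignment(prob, evalue)) == expected

    def test_no_hit_is_weak(self):
        assert classify_affiliation_strength(None) == "weak"


class TestCurateGenome:
    def test_no_overlaps_all_kept_with_no_conflict_rule(self):
        orfs = [make_orf(1, 300), make_orf(400, 699)]
        assignments = {
            orf_feature_id(o): assignment(99, 1e-10) for o in orfs
        }
        kept, decisions = curate_genome(orfs, [], assignments)
        assert len(kept) == 2
        assert all(d.rule == "no-conflict" and d.action == "keep"
                   for d in decisions)

    def test_worked_examples_give_exactly_three_discards(self, curation_cases):
        all_discards = []
        for case in curation_cases.values():
            _kept, decisions = curate_genome(
                case.orfs, case.trnas, case.assignments
            )
            all_discards += [
                case.orf_names[d.feature_id]
                for d in decisions if d.action == "discard"
            ]
        assert sorted(all_discards) == ["gp_014", "gp_016", "gp_222"]

    def test_all_strong_trio_kept(self, curation_cases):
        case = curation_cases["all_strong_trio"]
        kept, decisions = curate_genome(case.orfs, case.trnas, case.assignments)
        assert len(kept) == 3
        assert {d.rule for d in decisions} == {"all-strong-keep"}

    def test_all_weak_conflict_kept_and_flagged(self):
        orfs = [make_orf(1, 600), make_orf(100, 500)]
        assignments = {orf_feature_id(o): assignment(30, 5.0) for o in orfs}
        kept, decisions = curate_genome(orfs, [], assignments)
        assert len(kept) == 2
        assert {d.rule for d in decisions} == {"all-weak-review"}

    def test_structure_rescue_saves_weak_overlapper(self):
        strong, weak = make_orf(1, 900), make_orf(100, 699)
        assignments = {
            orf_feature_id(strong): assignment(99, 1e-12),
            orf_feature_id(weak): assignment(30, 5.0),
        }
        kept, _d = curate_genome(
            orfs=[strong, weak], trnas=[], assignments=assignments,
            pdb_rescue={orf_feature_id(weak): True},
        )
        assert len(kept) == 2

    def test_missing_assignment_is_contract_error(self):
        orfs = [make_orf(1, 300)]
        with pytest.raises(ContractError):
            curate_genome(orfs, [], {})

    def test_audit_is_exhaustive_and_order_independent(self, curation_cases):
        case = curation_cases["weak_pair_trio"]
        kept1, d1 = curate_genome(case.orfs, case.trnas, case.assignments)
        shuffled = list(reversed(case.orfs))
        kept2, d2 = curate_genome(shuffled, case.trnas, case.assignments)
        assert len(d1) == len(case.orfs)
        key = lambda o: orf_feature_id(o)
        assert sorted(map(key, kept1)) == sorted(map(key, kept2))
        assert {(d.feature_id, d.action) for d in d1} == \
               {(d.feature_id, d.action) for d in d2}

    @pytest.mark.parametrize("seed", range(5))
    def test_strong_orf_never_discarded_under_fuzzing(self, seed):
        rng = random.Random(seed)
        orfs, assignments = [], {}
        pos = 1
        for _ in range(40):
            length = 3 * rng.randrange(40, 400)
            start = pos + rng.randrange(-min(pos - 1, length), 50)
            start = max(1, start)
            orf = make_orf(start, start + length - 1)
            if any(orf_feature_id(orf) == orf_feature_id(o) for o in orfs):
                continue
            orfs.append(orf)
            strong = rng.random() < 0.5
            assignments[orf_feature_id(orf)] = (
                assignment(rng.uniform(80, 100), 10 ** rng.uniform(-30, -5))
                if strong else
                assignment(rng.uniform(0, 65), 10 ** rng.uniform(-3, 1))
            )
            pos = start + rng.randrange(0, length)
        kept, decisions = curate_genome(orfs, [], assignments)
        kept_ids = {orf_feature_id(o) for o in kept}
        for oid, a in assignments.items():
            if classify_affiliation_strength(a) == "strong":
                assert oid in kept_ids

    def test_matches_rule_by_rule_oracle(self, curation_cases):
        # independent re-application of the stated rules, feature by feature
        from phagepipe.curation import find_overlaps, classify_affiliation_strength
        case = curation_cases["weak_pair_trio"]
        kept, _d = curate_genome(case.orfs, case.trnas, case.assignments)
        conflicts = find_overlaps(case.orfs, case.trnas)
        expect_discard = set()
        for c in conflicts:
            sts = {m: classify_affiliation_strength(case.assignments[m])
                   for m in c.members}
            if "strong" in sts.values():
                expect_discard |= {m for m, s in sts.items() if s == "weak"}
        got_kept = {orf_feature_id(o) for o in kept}
        assert got_kept == {orf_feature_id(o) for o in case.orfs} - expect_discard
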