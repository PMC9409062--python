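"""Stop-anchor merging, agreement statistics and the keep policy."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagepipe.consensus import (
    OrfPrediction,
    agreement_stats,
    consensus_keep_policy,
    flag_outlier_callers,
    merge_predictions,
)
from phagepipe.errors import ConfigurationError, ValidationError
from phagepipe.synthetic_data import DEFAULT_CALLERS

CALLERS = ["a", "b", "c", "d"]


def orf(caller, strand, start, end, genome="g"):
    return OrfPrediction(genome, caller, strand, start, end)


class TestMergePredictions:
    def test_identical_orf_from_four_callers_merges_to_one(self):
        preds = [orf(c, "+", 100, 399) for c in CALLERS]
        merged = merge_predictions(preds, CALLERS)
        assert len(merged) == 1
        assert merged[0].supporting_callers == frozenset(CALLERS)
        assert (merged[0].selected_start, merged[0].selected_end) == (100, 399)

    def test_longest_start_variant_selected(self):
        # same stop anchor, disagreeing starts: the longest extent wins
        merged = merge_predictions(
            [orf("a", "+", 100, 399), orf("b", "+", 130, 399)], CALLERS
        )
        assert len(merged) == 1
        assert merged[0].length == 300
        assert merged[0].variants == {"a": (100, 399), "b": (130, 399)}

    def test_same_coordinates_opposite_strands_stay_distinct(self):
        merged = merge_predictions(
            [orf("a", "+", 100, 399), orf("b", "-", 100, 399)], CALLERS
        )
        assert len(merged) == 2

    def test_wrap_around_anchor_reduced_modulo_genome_length(self):
        # a gene spanning the origin of a 1000 bp circular genome
        merged = merge_predictions(
            [orf("a", "+", 901, 1050), orf("b", "+", 3, 50)],
            CALLERS,
            genome_length=1000,
        )
        assert len(merged) == 1
        assert merged[0].stop_anchor == 50

    def test_unknown_caller_rejected(self):
        with pytest.raises(ConfigurationError):
            merge_predictions([orf("zzz", "+", 1, 300)], CALLERS)

    def test_equal_length_tie_breaks_by_caller_order(self):
        # same stop, same length, different (hypothetical) starts cannot
        # happen on one strand; the tie rule picks the earliest caller
        merged = merge_predictions(
            [orf("b", "+", 100, 399), orf("a", "+", 100, 399)], CALLERS
        )
        assert merged[0].variants["a"] == (100, 399)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_grouping_oracle(self, seed):
        rng = random.Random(seed)
        preds = []
        for _ in range(1200):
            caller = rng.choice(CALLERS)
            strand = rng.choice("+-")
            start = rng.randrange(1, 5000)
            length = 3 * rng.randrange(20, 200)
            preds.append(orf(caller, strand, start, start + length - 1))
        merged = merge_predictions(preds, CALLERS)
        # oracle: plain dict-of-lists grouping by (strand, stop anchor)
        groups = {}
        for p in preds:
            key = (p.strand, p.end if p.strand == "+" else p.start)
            groups.setdefault(key, []).append(p)
        assert len(merged) == len(groups)
        by_key = {(m.strand, m.stop_anchor): m for m in merged}
        for key, members in groups.items():
            m = by_key[key]
            assert m.supporting_callers == {p.caller for p in members}
            assert m.length == max(p.length for p in members)

    def test_adding_a_caller_never_decreases_union(self):
        rng = random.Random(7)
        base = [
            orf(rng.choice(CALLERS[:3]), "+", s, s + 299)
            for s in rng.sample(range(1, 10000), 50)
        ]
        extra = [
            orf("d", "+", s, s + 299) for s in rng.sample(range(1, 10000), 30)
        ]
        n_before = len(merge_predictions(base, CALLERS))
        n_after = len(merge_predictions(base + extra, CALLERS))
        assert n_after >= n_before

    def test_non_codon_length_rejected(self):
        with pytest.raises(ValidationError):
            orf("a", "+", 1, 100)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(CALLERS),
                st.sampled_from("+-"),
                st.integers(min_value=1, max_value=3000),
                st.integers(min_value=20, max_value=200),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_merge_invariants_hold_on_arbitrary_inputs(self, raw):
        preds = [
            orf(caller, strand, start, start + 3 * ncodons - 1)
            for caller, strand, start, ncodons in raw
        ]
        merged = merge_predictions(preds, CALLERS)
        # one consensus ORF per distinct key; selected extent is maximal;
        # permuting the input changes nothing
        keys = [(m.strand, m.stop_anchor) for m in merged]
        assert len(keys) == len(set(keys))
        assert keys == sorted(keys)
        for m in merged:
            assert m.supporting_callers
            assert m.length == max(
                e - s + 1 for s, e in m.variants.values()
            )
        permuted = merge_predictions(list(reversed(preds)), CALLERS)
        assert [
            (m.strand, m.stop_anchor, m.supporting_callers, m.length)
            for m in merged
        ] == [
            (m.strand, m.stop_anchor, m.supporting_callers, m.length)
            for m in permuted
        ]


class TestAgreementStats:
    def test_subset_counts_sum_to_union(self, agreement_statistics):
        s = agreement_statistics
        assert sum(s.per_subset_counts.values()) == s.n_union

    def test_per_caller_totals_recovered(self, agreement_statistics):
        s = agreement_statistics
        for c in s.callers:
            assert s.per_caller_totals[c] == sum(
                n for sub, n in s.per_subset_counts.items() if c in sub
            )

    def test_single_caller_is_one_subset_at_100_percent(self):
        merged = merge_predictions(
            [orf("a", "+", s, s + 299) for s in (1, 400, 800)], ["a"]
        )
        s = agreement_stats(merged, ["a"])
        assert s.n_union == 3
        assert s.shared_percent() == 100.0


class TestFlagOutliers:
    def test_perfect_agreement_flags_nobody(self):
        merged = merge_predictions(
            [orf(c, "+", 1, 300) for c in CALLERS], CALLERS
        )
        flags = flag_outlier_callers(agreement_stats(merged, CALLERS))
        assert all(not flagged for _c, _f, flagged in flags)
        assert all(f == 0.0 for _c, f, _fl in flags)

    def test_threshold_100_never_flags(self, agreement_statistics):
        flags = flag_outlier_callers(agreement_statistics, 100.0)
        assert all(not flagged for _c, _f, flagged in flags)

    def test_caller_with_zero_predictions_reports_zero(self):
        merged = merge_predictions([orf("a", "+", 1, 300)], CALLERS)
        flags = dict(
            (c, (f, fl))
            for c, f, fl in flag_outlier_callers(
                agreement_stats(merged, CALLERS)
            )
        )
        assert flags["b"] == (0.0, False)


class TestKeepPolicy:
    def test_orf_supported_only_by_excluded_caller_dropped(self):
        merged = merge_predictions(
            [orf("a", "+", 1, 300), orf("b", "+", 400, 699)], CALLERS
        )
        kept = consensus_keep_policy(merged, ["b", "c", "d"])
        assert len(kept) == 1
        assert kept[0].supporting_callers == frozenset({"b"})

    def test_included_all_is_identity(self, agreement_consensus):
        kept = consensus_keep_policy(agreement_consensus, list(DEFAULT_CALLERS))
        assert len(kept) == len(agreement_consensus)

    def test_empty_included_rejected(self, agreement_consensus):
        with pytest.raises(ConfigurationError):
            consensus_keep_policy(agreement_consensus, [])
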