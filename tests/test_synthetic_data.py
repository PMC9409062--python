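"""Generators: determinism, statistical targets and the recount oracle."""

import numpy as np
import pytest

from phagepipe.annotation_transfer import SINGLETON, assign_phrog, select_best_hit
from phagepipe.consensus import agreement_stats, merge_predictions
from phagepipe.errors import ConfigurationError
from phagepipe.synthetic_data import (
    DEFAULT_CALLERS,
    SEAO1_AGREEMENT_CELLS,
    build_agreement_fixture,
    load_acr_candidates,
    load_curation_cases,
    load_marker_content,
    make_caller_outputs,
    make_genome,
    make_hit_table,
)

STOPS = {"TAA", "TAG", "TGA"}


class TestMakeGenome:
    def test_same_seed_identical_output(self):
        g1, o1 = make_genome(12000, seed=4)
        g2, o2 = make_genome(12000, seed=4)
        assert g1.sequence == g2.sequence
        assert o1 == o2

    def test_terminal_repeat_construction(self):
        g, _ = make_genome(20000, terminal_repeat=77, seed=1)
        assert g.length == 20077
        assert g.sequence[:77] == g.sequence[-77:]

    def test_planted_orfs_are_valid_genes(self):
        g, orfs = make_genome(15000, seed=2)
        comp = str.maketrans("ACGT", "TGCA")
        for orf in orfs:
            assert orf.length % 3 == 0
            sub = g.sequence[orf.start - 1 : orf.end]
            if orf.strand == "-":
                sub = sub.translate(comp)[::-1]
            assert sub[:3] == "ATG"
            assert sub[-3:] in STOPS
            # no premature in-frame stop
            assert all(
                sub[i : i + 3] not in STOPS for i in range(3, len(sub) - 3, 3)
            )

    def test_exactly_one_terminase_label(self):
        _g, orfs = make_genome(15000, seed=2)
        assert sum(
            1 for o in orfs if o.label == "terminase small subunit"
        ) == 1

    def test_gc_content_concentrates(self):
        g, _ = make_genome(50000, gc=0.52, seed=6)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / g.length
        assert abs(gc - 0.52) <= 0.02

    def test_oversized_repeat_rejected(self):
        with pytest.raises(ConfigurationError):
            make_genome(2000, terminal_repeat=1500, seed=0)


class TestMakeCallerOutputs:
    def test_perfect_callers_agree_completely(self):
        _g, orfs = make_genome(20000, seed=7)
        outputs = make_caller_outputs(orfs, 20000, seed=7)
        merged = merge_predictions(
            [p for v in outputs.values() for p in v], DEFAULT_CALLERS
        )
        stats = agreement_stats(merged, DEFAULT_CALLERS)
        assert stats.n_union == len(orfs)
        assert stats.shared_percent() == 100.0

    def test_start_jitter_preserves_stop_anchor_consensus(self):
        _g, orfs = make_genome(20000, seed=8)
        outputs = make_caller_outputs(
            orfs, 20000, start_jitter=1.0, seed=8
        )
        merged = merge_predictions(
            [p for v in outputs.values() for p in v], DEFAULT_CALLERS
        )
        assert len(merged) == len(orfs)

    def test_fp_heavy_caller_has_highest_unique_fraction(self):
        _g, orfs = make_genome(30000, seed=9)
        fp = {c: 0.0 for c in DEFAULT_CALLERS}
        fp["Glimmer"] = 0.5
        uniques = []
        for seed in range(5):
            outputs = make_caller_outputs(orfs, 30000, fp_rate=fp, seed=seed)
            merged = merge_predictions(
                [p for v in outputs.values() for p in v], DEFAULT_CALLERS
            )
            stats = agreement_stats(merged, DEFAULT_CALLERS)
            others = max(
                stats.unique_percent(c)
                for c in DEFAULT_CALLERS if c != "Glimmer"
            )
            uniques.append(stats.unique_percent("Glimmer") > others)
        assert all(uniques)


class TestAgreementFixture:
    def test_recount_oracle_matches_cells_exactly(self):
        preds = build_agreement_fixture(SEAO1_AGREEMENT_CELLS)
        # independent recount: group emitted predictions by stop anchor
        support = {}
        for caller, plist in preds.items():
            for p in plist:
                support.setdefault((p.strand, p.end), set()).add(caller)
        recount = {}
        for callers in support.values():
            key = frozenset(callers)
            recount[key] = recount.get(key, 0) + 1
        assert recount == SEAO1_AGREEMENT_CELLS

    def test_arbitrary_feasible_cells_realized(self):
        cells = {
            frozenset({"a"}): 3,
            frozenset({"a", "b"}): 2,
            frozenset({"b", "c"}): 1,
        }
        preds = build_agreement_fixture(cells, callers=["a", "b", "c"])
        merged = merge_predictions(
            [p for v in preds.values() for p in v], ["a", "b", "c"]
        )
        stats = agreement_stats(merged, ["a", "b", "c"])
        for subset, n in cells.items():
            assert stats.subset_count(subset) == n
        assert stats.n_union == 6

    def test_infeasible_intersection_rejected(self):
        with pytest.raises(ConfigurationError, match="intersection"):
            build_agreement_fixture(
                {frozenset({"a", "b"}): 10},
                callers=["a", "b"],
                per_caller_totals={"a": 5, "b": 12},
                full_intersection=10,
            )

    def test_total_mismatch_rejected(self):
        with pytest.raises(ConfigurationError, match="requested total"):
            build_agreement_fixture(
                {frozenset({"a"}): 3},
                callers=["a", "b"],
                per_caller_totals={"a": 4, "b": 0},
            )


class TestMakeHitTable:
    def _pct_affiliated(self, hits):
        n = sum(
            1
            for h in hits
            if assign_phrog(h).family_id != SINGLETON
        )
        return n / len(hits)

    def test_strong_only_no_singletons(self):
        hits = make_hit_table([f"q{i}" for i in range(50)],
                              affiliated_fraction=1.0, seed=1)
        assert self._pct_affiliated(hits) == 1.0

    def test_weak_only_all_singletons(self):
        hits = make_hit_table([f"q{i}" for i in range(50)],
                              affiliated_fraction=0.0, seed=1)
        assert self._pct_affiliated(hits) == 0.0

    def test_mixed_fraction_within_tolerance(self):
        hits = make_hit_table([f"q{i}" for i in range(600)],
                              affiliated_fraction=0.6, seed=2)
        assert abs(self._pct_affiliated(hits) - 0.6) <= 0.05


class TestPackagedFixtures:
    def test_acr_table_covers_ten_genomes(self):
        candidates = load_acr_candidates()
        assert len(candidates) == 28
        assert len({c.genome_id for c in candidates}) == 10

    def test_marker_content_has_exactly_one_integrase_genome(self):
        content = load_marker_content()
        assert len(content) == 10
        with_int = [
            g for g, assigns in content.items()
            if any(a.family_id == "phrog_216" for a in assigns)
        ]
        assert with_int == ["Salfasec13b"]

    def test_curation_cases_parse_into_three_scenarios(self):
        cases = load_curation_cases()
        assert set(cases) == {
            "weak_pair_trio", "all_strong_trio", "trna_overlap"
        }
        assert len(cases["weak_pair_trio"].orfs) == 3
        assert len(cases["trna_overlap"].trnas) == 1
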