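"""Cluster extraction, pattern classification, and the TDRL engine."""

import itertools

import pytest

from conftest import tdrl_min_rounds_oracle, tdrl_successor_states
from mitoarch.gene_order import GeneOrder, classify_pattern, extract_cluster
from mitoarch.tdrl import (
    AlphabetMismatchError,
    BlockRangeError,
    GeneLossError,
    REARRANGEMENT_SCENARIOS,
    TDRLRound,
    TDRLScenario,
    apply_tdrl,
    minimal_scenarios,
    verify_scenario,
)


class TestClusterExtraction:
    def test_deep_water_record_is_wncyaa(self, tanakae):
        order = extract_cluster(tanakae)
        assert tuple(order.letters) == tuple("WNCYAA")
        assert classify_pattern(order) == "WNCYAA"

    def test_shallow_water_record_is_wyanc(self, chefuensis):
        order = extract_cluster(chefuensis)
        assert tuple(order.letters) == tuple("WYANC")
        assert classify_pattern(order) == "WYANC"

    def test_empty_cluster(self, tanakae):
        from mitoarch.records import MitogenomeRecord

        keep = {"ND2", "COXI"}
        rec = MitogenomeRecord(
            species_id="x",
            genome_length=tanakae.genome_length,
            features=[f for f in tanakae.features if f.name in keep],
        )
        assert extract_cluster(rec).letters == ()

    def test_missing_anchor_raises(self, tanakae):
        from mitoarch.records import MitogenomeRecord

        rec = MitogenomeRecord(
            species_id="x",
            genome_length=tanakae.genome_length,
            features=[f for f in tanakae.features if f.name != "ND2"],
        )
        with pytest.raises(KeyError):
            extract_cluster(rec)

    @pytest.mark.parametrize(
        "letters,label",
        [
            ("WANCY", "WANCY"),
            ("WYANC", "WYANC"),
            ("WNCYAC", "WNCYAC"),
            ("WNCYAA", "WNCYAA"),
            ("YW", "OTHER"),
            ("WANC", "OTHER"),
        ],
    )
    def test_classification_is_exact_match(self, letters, label):
        assert classify_pattern(GeneOrder.from_string(letters)) == label


class TestReplay:
    def test_identity_with_zero_rounds(self):
        assert apply_tdrl("WANCY", []) == tuple("WANCY")

    @pytest.mark.parametrize("label", ["WYANC", "WNCYAC", "WNCYAA"])
    def test_study_reconstructions_replay_to_their_patterns(self, label):
        scenario = REARRANGEMENT_SCENARIOS[label]
        derived = apply_tdrl(scenario.source, scenario.rounds)
        assert classify_pattern(derived) == label
        assert verify_scenario(scenario)

    def test_wrong_derived_fails_verification(self):
        s = REARRANGEMENT_SCENARIOS["WYANC"]
        bad = TDRLScenario(s.source, s.rounds, tuple("WANCY"))
        assert not verify_scenario(bad)

    def test_deleting_all_copies_of_a_gene_is_rejected(self):
        rounds = [TDRLRound((1, 5), frozenset({1, 6}))]  # both W copies
        with pytest.raises(GeneLossError):
            apply_tdrl("WANCY", rounds)
        assert not verify_scenario(
            TDRLScenario(tuple("WANCY"), tuple(rounds), tuple("ANCY"))
        )

    def test_out_of_range_block_and_loss(self):
        with pytest.raises(BlockRangeError):
            apply_tdrl("WANCY", [TDRLRound((2, 6), frozenset())])
        with pytest.raises(BlockRangeError):
            apply_tdrl("WANCY", [TDRLRound((1, 5), frozenset({11}))])

    def test_deletions_never_reorder(self):
        # any scenario's derived order embeds in the duplicated expansion
        for label, s in REARRANGEMENT_SCENARIOS.items():
            seq = s.source
            for rnd in s.rounds:
                i, j = rnd.block
                post = seq[:j] + seq[i - 1:j] + seq[j:]
                seq = tuple(
                    x for k, x in enumerate(post, 1) if k not in rnd.losses
                )
                # kept order is a subsequence of post by construction
                it = iter(post)
                assert all(ch in it for ch in seq)
            assert seq == s.derived


class TestMinimalSearch:
    @pytest.mark.parametrize(
        "target,rounds",
        [("WANCY", 0), ("WYANC", 1), ("WNCYAC", 1), ("WNCYAA", 2)],
    )
    def test_minimum_rounds_for_study_patterns(self, target, rounds):
        found = minimal_scenarios("WANCY", target, max_rounds=2)
        assert found and found[0].n_rounds == rounds
        assert all(s.n_rounds == rounds for s in found)
        assert all(verify_scenario(s) for s in found)

    def test_whole_cluster_study_scenario_is_found(self):
        found = minimal_scenarios("WANCY", "WNCYAC", max_rounds=2)
        assert REARRANGEMENT_SCENARIOS["WNCYAC"].rounds in [s.rounds for s in found]

    def test_alphabet_mismatch(self):
        with pytest.raises(AlphabetMismatchError):
            minimal_scenarios("WANCY", "WANC")

    def test_sorted_by_total_losses(self):
        found = minimal_scenarios("WANCY", "WYANC", max_rounds=2)
        losses = [s.total_losses for s in found]
        assert losses == sorted(losses)

    def test_exhaustive_agreement_with_state_oracle_two_letters(self):
        # full 2-round equivalence against raw subset enumeration
        src = tuple("WA")
        reach1 = tdrl_successor_states(src)
        reach2 = set().union(*(tdrl_successor_states(s) for s in reach1))
        for target in sorted(reach2 | reach1 | {src}):
            oracle = tdrl_min_rounds_oracle(src, target, 2)
            found = minimal_scenarios(src, target, max_rounds=2)
            assert found, target
            assert found[0].n_rounds == oracle

    def test_agreement_with_state_oracle_three_letters(self):
        # every 1-round target plus a deterministic sample of 2-round targets
        src = tuple("WAN")
        reach1 = tdrl_successor_states(src)
        reach2 = set().union(*(tdrl_successor_states(s) for s in reach1))
        targets = sorted(reach1) + sorted(reach2 - reach1 - {src})[::17]
        for target in targets:
            oracle = tdrl_min_rounds_oracle(src, target, 2)
            found = minimal_scenarios(src, target, max_rounds=2)
            assert found, target
            assert found[0].n_rounds == oracle

    def test_agreement_with_state_oracle_four_letters_one_round(self):
        src = tuple("WANC")
        for target in sorted(tdrl_successor_states(src)):
            found = minimal_scenarios(src, target, max_rounds=1)
            oracle = tdrl_min_rounds_oracle(src, target, 1)
            assert found and found[0].n_rounds == oracle

    def test_unreachable_within_budget_returns_empty(self):
        # 'WWWWA...' style targets needing more copies than one round allows
        src = tuple("WA")
        target = tuple("WWWWWWWWWA")  # needs >= 3 doublings of W
        assert minimal_scenarios(src, target, max_rounds=2) == []

    def test_relabeling_invariance(self):
        # letter identity is arbitrary: scenario structure must be preserved
        # under alphabet permutation, so one source per length is exhaustive
        mapping = dict(zip("WANCY", "YCNAW"))
        for target in ("WYANC", "WNCYAA"):
            a = minimal_scenarios("WANCY", target, max_rounds=2)
            b = minimal_scenarios(
                "".join(mapping[x] for x in "WANCY"),
                "".join(mapping[x] for x in target),
                max_rounds=2,
            )
            assert [(s.rounds) for s in a] == [(s.rounds) for s in b]

    def test_single_block_copy_targets_need_one_round(self):
        # any subsequence-with-duplicates of a one-block expansion
        src = tuple("WANC")
        for i, j in itertools.combinations(range(1, 6), 2):
            post = src[:j - 1] + src[i - 1:j - 1] + src[j - 1:]
            target = post  # keep everything
            if target == src:
                continue
            found = minimal_scenarios(src, target, max_rounds=2)
            assert found and found[0].n_rounds == 1


class TestCanonicalization:
    def test_postponable_deletion_is_deferred(self):
        from mitoarch.tdrl import canonicalize_rounds

        # delete the trailing Y copy in round 1 even though round 2 only
        # duplicates the front block: canonical form defers it to round 2
        rounds = (
            TDRLRound((1, 5), frozenset({10})),
            TDRLRound((1, 2), frozenset({2, 3})),
        )
        canon = canonicalize_rounds(tuple("WANCY"), rounds)
        assert canon[0].losses == frozenset()
        assert apply_tdrl("WANCY", canon) == apply_tdrl("WANCY", rounds)

    def test_canonical_forms_are_unique_in_search_output(self):
        found = minimal_scenarios("WANCY", "WNCYAA", max_rounds=2)
        assert len({s.rounds for s in found}) == len(found)
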