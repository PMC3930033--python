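"""Unit ranking, rank-based read assignment, and dataset summaries."""

import numpy as np
import pytest

from genomescreen import (
    ReadAlignment,
    SpeciesAlignmentSet,
    assign_reads,
    make_role_map,
    rank_units,
    summarize,
)


def make_set(alignments, sampled_count, dataset_id="lane", max_mismatches=2):
    return SpeciesAlignmentSet(dataset_id, alignments, sampled_count,
                               max_mismatches)


def aln(read_id, unit_id, mismatches=0, length=36):
    return ReadAlignment(read_id, unit_id, mismatches, length)


def counts_to_alignments(counts):
    alignments = []
    for unit_id, n in counts.items():
        alignments += [aln(f"{unit_id}_{i}", unit_id) for i in range(n)]
    return alignments


class TestRankUnits:
    def test_strict_ordering_by_count(self):
        aset = make_set(counts_to_alignments(
            {"human": 900, "mouse": 130, "phix": 50}), 1200)
        assert rank_units(aset).order == ("human", "mouse", "phix")

    def test_tie_breaks_lexicographically(self):
        aset = make_set(counts_to_alignments({"b": 10, "a": 10}), 30)
        assert rank_units(aset).order == ("a", "b")

    def test_tie_breaks_target_first(self):
        aset = make_set(counts_to_alignments({"a": 10, "zebra": 10}), 30)
        assert rank_units(aset, target_units={"zebra"}).order == ("zebra", "a")

    def test_ranking_covers_exactly_aligned_units(self):
        aset = make_set(counts_to_alignments({"a": 5, "b": 3, "c": 1}), 20)
        assert sorted(rank_units(aset).order) == ["a", "b", "c"]

    def test_simulated_fractions_rank_descending(self, rng):
        fractions = {"target": 0.8, "mouse": 0.13, "phix": 0.07}
        units = list(fractions)
        draws = rng.choice(len(units), size=2000,
                           p=list(fractions.values()))
        alignments = [aln(f"r{i}", units[d]) for i, d in enumerate(draws)]
        aset = make_set(alignments, 2000)
        assert rank_units(aset).order == ("target", "mouse", "phix")


class TestAssignReads:
    def test_shared_read_goes_to_higher_ranked_unit(self):
        aset = make_set(
            counts_to_alignments({"human": 10, "mouse": 2})
            + [aln("shared", "human"), aln("shared", "mouse")], 20)
        ranking = rank_units(aset)
        assert assign_reads(aset, ranking)["shared"] == "human"

    def test_unique_read_keeps_its_unit(self):
        aset = make_set(
            counts_to_alignments({"human": 10})
            + [aln("solo", "mouse")], 20)
        assignments = assign_reads(aset, rank_units(aset))
        assert assignments["solo"] == "mouse"

    def test_assignment_matches_argmax_by_rank_brute_force(self, rng):
        """500 reads with random alignment subsets over 4 ranked units."""
        units = ["u1", "u2", "u3", "u4"]
        alignments = []
        subsets = {}
        for i in range(500):
            size = int(rng.integers(1, 5))
            chosen = sorted(rng.choice(units, size=size, replace=False))
            subsets[f"r{i}"] = chosen
            alignments += [aln(f"r{i}", u) for u in chosen]
        aset = make_set(alignments, 500)
        ranking = rank_units(aset)
        assignments = assign_reads(aset, ranking)
        rank = {u: i for i, u in enumerate(ranking.order)}
        for read_id, chosen in subsets.items():
            assert assignments[read_id] == min(chosen, key=rank.__getitem__)

    def test_rank_dominance(self, rng):
        """No read aligning to two units is assigned to the lower-ranked."""
        alignments = counts_to_alignments({"a": 50, "b": 20})
        both = [aln(f"s{i}", "a") for i in range(10)] + \
               [aln(f"s{i}", "b") for i in range(10)]
        aset = make_set(alignments + both, 100)
        ranking = rank_units(aset)
        assignments = assign_reads(aset, ranking)
        for i in range(10):
            assert assignments[f"s{i}"] == "a"


class TestSummarize:
    ROLES = {"human": "target", "mouse": "other", "phix": "control"}

    def test_error_free_target_rate_zero(self):
        aset = make_set(counts_to_alignments({"human": 100}), 120)
        assignments = assign_reads(aset, rank_units(aset))
        s = summarize(aset, assignments, self.ROLES)
        human = next(u for u in s.unit_summaries if u.unit_id == "human")
        assert human.assigned_count == 100
        assert human.assigned_error_rate == 0.0
        assert s.unmapped_count == 20

    def test_one_mismatch_per_read_closed_form(self):
        alignments = [aln(f"r{i}", "human", mismatches=1) for i in range(50)]
        aset = make_set(alignments, 50)
        assignments = assign_reads(aset, rank_units(aset))
        s = summarize(aset, assignments, self.ROLES)
        human = next(u for u in s.unit_summaries if u.unit_id == "human")
        assert human.assigned_error_rate == pytest.approx(1 / 36)

    def test_conservation_invariant(self, rng):
        alignments = counts_to_alignments(
            {"human": 700, "mouse": 150, "phix": 50})
        aset = make_set(alignments, 1000)
        assignments = assign_reads(aset, rank_units(aset))
        s = summarize(aset, assignments, self.ROLES)
        assert sum(u.assigned_count for u in s.unit_summaries) \
            + s.unmapped_count == s.sampled_count

    def test_assigned_never_exceeds_aligned(self):
        alignments = (counts_to_alignments({"human": 30, "mouse": 10})
                      + [aln("x1", "human"), aln("x1", "mouse")])
        aset = make_set(alignments, 60)
        assignments = assign_reads(aset, rank_units(aset))
        s = summarize(aset, assignments, self.ROLES)
        for u in s.unit_summaries:
            assert u.assigned_count <= u.aligned_count

    def test_error_rate_uses_assigned_reads_only(self):
        """A shared read's mismatches count toward the unit it is assigned
        to, not every unit it aligns to."""
        alignments = (counts_to_alignments({"human": 10})
                      + [aln("sh", "human", 0), aln("sh", "mouse", 2)])
        aset = make_set(alignments, 12)
        assignments = assign_reads(aset, rank_units(aset))
        s = summarize(aset, assignments, self.ROLES)
        mouse = next(u for u in s.unit_summaries if u.unit_id == "mouse")
        assert mouse.assigned_count == 0
        assert mouse.assigned_error_rate == 0.0

    def test_role_map_must_cover_aligned_units(self):
        aset = make_set(counts_to_alignments({"elephant": 5}), 5)
        assignments = assign_reads(aset, rank_units(aset))
        with pytest.raises(ValueError, match="elephant"):
            summarize(aset, assignments, self.ROLES)

    def test_simulated_substitution_rate_recovered(self, rng):
        """Binomial mismatches at per-base rate 0.005 over 36 bases."""
        rate, n_reads, length = 0.005, 5000, 36
        mismatches = rng.binomial(length, rate, size=n_reads)
        keep = mismatches <= 2  # the aligner's ceiling
        alignments = [aln(f"r{i}", "human", int(m), length)
                      for i, m in enumerate(mismatches[keep])]
        aset = make_set(alignments, n_reads)
        assignments = assign_reads(aset, rank_units(aset))
        s = summarize(aset, assignments, self.ROLES)
        human = next(u for u in s.unit_summaries if u.unit_id == "human")
        se = np.sqrt(rate * (1 - rate) / (keep.sum() * length))
        assert abs(human.assigned_error_rate - rate) <= 3 * se


class TestRoleMap:
    def test_roles_assigned(self):
        roles = make_role_map(["human", "mouse", "phix"], "human", ["phix"])
        assert roles == {"human": "target", "mouse": "other",
                         "phix": "control"}

    def test_no_target_allowed(self):
        roles = make_role_map(["human", "phix"], None, ["phix"])
        assert roles["human"] == "other"

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="not in panel"):
            make_role_map(["human"], "dog", [])
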