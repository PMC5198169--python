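"""Markov genome simulation, HGT planting, and truth-based scoring."""

import numpy as np
import pytest

from blsomhgt.composition import SequenceRecord
from blsomhgt.pipeline import ContigAssignment
from blsomhgt.synthetic import (
    GenomeModel,
    PackingError,
    evaluate,
    plant_hgt,
    reference_models,
    scenario,
    simulate_genome,
)
from helpers import make_assignment
from blsomhgt.synthetic import PlantedTruth


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        m = GenomeModel("m", 0, np.array([0.25, 0.25, 0.25, 0.25]))
        assert simulate_genome(m, 2000, 7) == simulate_genome(m, 2000, 7)

    def test_degenerate_model_all_a(self):
        m = GenomeModel("a", 0, np.array([1.0, 0.0, 0.0, 0.0]))
        assert simulate_genome(m, 50, 1) == "A" * 50

    def test_gc_content_within_binomial_bound(self):
        n = 100_000
        m = GenomeModel("half", 0, np.array([0.25, 0.25, 0.25, 0.25]))
        seq = simulate_genome(m, n, 3)
        gc = (seq.count("G") + seq.count("C")) / n
        assert abs(gc - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_order1_follows_transition_matrix(self):
        # chain that almost always repeats the current base
        t = np.full((4, 4), 0.02)
        np.fill_diagonal(t, 0.94)
        m = GenomeModel("sticky", 1, t)
        seq = simulate_genome(m, 20_000, 5)
        repeats = sum(a == b for a, b in zip(seq, seq[1:])) / (len(seq) - 1)
        assert repeats == pytest.approx(0.94, abs=0.02)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GenomeModel("bad", 0, np.array([0.5, 0.5, 0.5, 0.5]))
        with pytest.raises(ValueError):
            GenomeModel("bad", 2, np.zeros((4, 4)))

    def test_symmetric_chains_have_gc_half(self):
        for genera in reference_models().values():
            for m in genera.values():
                if m.order == 1:
                    assert m.gc == pytest.approx(0.5, abs=1e-12)


class TestPlantHGT:
    @pytest.fixture()
    def host(self):
        m = GenomeModel("host", 0, np.array([0.325, 0.175, 0.175, 0.325]))
        return [
            SequenceRecord(id=f"c{i}", sequence=simulate_genome(m, 20_000, 100 + i))
            for i in range(4)
        ]

    def test_zero_inserts_is_identity(self, host):
        chimeric, truth = plant_hgt(host, [("P", "g", GenomeModel("d", 0, np.array([0.25] * 4)))],
                                    0, (1000, 2000), 5)
        assert truth == []
        assert [r.sequence for r in chimeric] == [r.sequence for r in host]

    def test_single_insert_changes_only_its_interval(self, host):
        donor = GenomeModel("d", 0, np.array([0.05, 0.45, 0.45, 0.05]))
        chimeric, truth = plant_hgt(host, [("P", "g", donor)], 1, (3000, 3000), 5)
        (t,) = truth
        pairs = {r.id: r for r in host}
        changed = [r for r in chimeric if r.sequence != pairs[r.id].sequence]
        assert [r.id for r in changed] == [t.contig_id]
        orig, chim = pairs[t.contig_id].sequence, changed[0].sequence
        assert chim[: t.insert_start] == orig[: t.insert_start]
        assert chim[t.insert_end:] == orig[t.insert_end:]
        assert len(chim) == len(orig)

    def test_inserted_intervals_shift_gc(self, host):
        donor = GenomeModel("gc65", 0, np.array([0.175, 0.325, 0.325, 0.175]))
        chimeric, truth = plant_hgt(host, [("P", "g", donor)], 20, (1000, 2000), 6)
        def gc(s):
            return (s.count("G") + s.count("C")) / len(s)
        by_id = {r.id: r.sequence for r in chimeric}
        inside = [gc(by_id[t.contig_id][t.insert_start:t.insert_end]) for t in truth]
        masks = {cid: np.zeros(len(s), dtype=bool) for cid, s in by_id.items()}
        for t in truth:
            masks[t.contig_id][t.insert_start:t.insert_end] = True
        outside = [
            gc("".join(c for c, m in zip(by_id[cid], masks[cid]) if not m))
            for cid in by_id
        ]
        assert np.mean(inside) > np.mean(outside)

    def test_inserts_do_not_overlap(self, host):
        donor = GenomeModel("d", 0, np.array([0.25] * 4))
        _, truth = plant_hgt(host, [("P", "g", donor)], 25, (1500, 2500), 7)
        by_contig = {}
        for t in truth:
            by_contig.setdefault(t.contig_id, []).append((t.insert_start, t.insert_end))
        for ivs in by_contig.values():
            ivs.sort()
            assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(ivs, ivs[1:]))

    def test_infeasible_packing_raises(self, host):
        donor = GenomeModel("d", 0, np.array([0.25] * 4))
        with pytest.raises(PackingError):
            plant_hgt(host, [("P", "g", donor)], 50, (15_000, 15_000), 8)

    def test_insert_longer_than_contig_rejected(self, host):
        donor = GenomeModel("d", 0, np.array([0.25] * 4))
        with pytest.raises(ValueError):
            plant_hgt(host, [("P", "g", donor)], 1, (30_000, 30_000), 9)


class TestEvaluate:
    def hand_case(self):
        """Three contigs, hand-enumerated outcomes.

        c1: one truth insert fully covered by one candidate called PhyX -> TP.
        c2: truth insert, candidate called PhyX but donor is PhyY -> TP at
            segment level (position is right), contig phylum wrong.
        c3: no truth; one candidate -> FP.
        """
        truth = [
            PlantedTruth("c1", 0, 5000, "PhyX"),
            PlantedTruth("c2", 0, 5000, "PhyY"),
        ]
        asg = [
            make_assignment("c1", True, "PhyX"),
            make_assignment("c2", True, "PhyX"),
            make_assignment("c3", True, "PhyX"),
            make_assignment("c3", False, start=1000),
        ]
        calls = [
            ContigAssignment("c1", 1, 1, {"PhyX": 1}, 1.0, assigned_phylum="PhyX"),
            ContigAssignment("c2", 1, 1, {"PhyX": 1}, 1.0, assigned_phylum="PhyX"),
            ContigAssignment("c3", 2, 1, {"PhyX": 1}, 1.0, assigned_phylum="PhyX"),
        ]
        return asg, calls, truth

    def test_hand_computed_metrics(self):
        asg, calls, truth = self.hand_case()
        rep = evaluate(asg, calls, truth)
        assert (rep.tp, rep.fp, rep.fn) == (2, 1, 0)
        assert rep.segment_recall == 1.0
        assert rep.segment_precision == pytest.approx(2 / 3)
        assert rep.contig_accuracy == pytest.approx(1 / 2)  # c2 is wrong

    def test_conservation_tp_fp_candidates(self):
        asg, calls, truth = self.hand_case()
        rep = evaluate(asg, calls, truth)
        assert rep.tp + rep.fp == sum(a.is_hgt_candidate for a in asg)

    def test_zero_candidates(self):
        truth = [PlantedTruth("c1", 0, 5000, "PhyX")]
        asg = [make_assignment("c1", False)]
        rep = evaluate(asg, [], truth)
        assert rep.segment_recall == 0.0
        assert rep.segment_precision is None

    def test_exact_recovery_scores_one(self):
        truth = [PlantedTruth("c1", 0, 5000, "PhyX")]
        asg = [make_assignment("c1", True, "PhyX")]
        calls = [ContigAssignment("c1", 1, 1, {"PhyX": 1}, 1.0, assigned_phylum="PhyX")]
        rep = evaluate(asg, calls, truth)
        assert rep.segment_recall == rep.segment_precision == rep.contig_accuracy == 1.0

    def test_unknown_contigs_rejected(self):
        truth = [PlantedTruth("nope", 0, 5000, "PhyX")]
        asg = [make_assignment("c1", True, "PhyX")]
        with pytest.raises(ValueError, match="unknown contigs"):
            evaluate(asg, [], truth)


class TestScenario:
    def test_regenerates_identically_from_seed(self):
        a = scenario(11, n_contigs=2, contig_len=12_000, reference_len=30_000,
                     n_inserts=3, insert_len=(1000, 2000))
        b = scenario(11, n_contigs=2, contig_len=12_000, reference_len=30_000,
                     n_inserts=3, insert_len=(1000, 2000))
        assert [r.sequence for r in a.host_records] == [r.sequence for r in b.host_records]
        assert [r.sequence for r in a.ref_records] == [r.sequence for r in b.ref_records]
        assert [(t.contig_id, t.insert_start, t.phylum) for t in a.truth] == [
            (t.contig_id, t.insert_start, t.phylum) for t in b.truth
        ]

    def test_structure_of_reference_collection(self):
        sc = scenario(11, n_contigs=2, contig_len=12_000, reference_len=30_000, n_inserts=2)
        assert len(sc.ref_records) == 12  # 3 pseudo-phyla x 4 pseudo-genera
        assert all(len(r) >= 10_000 for r in sc.ref_records)
        phyla = {r.phylum for r in sc.ref_records}
        assert len(phyla) == 3
        assert all(r.genus is not None for r in sc.ref_records)

    def test_insert_lengths_within_range(self):
        sc = scenario(11, n_contigs=3, contig_len=30_000, n_inserts=5,
                      reference_len=30_000, insert_len=(2000, 4000))
        for t in sc.truth:
            assert 2000 <= t.insert_end - t.insert_start <= 4000
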