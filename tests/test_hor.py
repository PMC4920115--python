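import pytest

from conftest import run_spec
from tandemhor.cluster import ClusterAssignment, ThresholdSelection
from tandemhor.hor import (
    ClusterDistances,
    ReadClassification,
    classify_read,
    estimate_period,
    evaluate_regularity,
    hor_consensus,
    _majority_consensus,
)
from tandemhor.io import MonomerHitRecord, Read
from tandemhor.simulate import Anomaly, SyntheticReadSpec, make_monomer_family


def _hits(starts, span=171, strands=None, read_id="r1", gaps=None):
    """Build hits at given starts; ends default to start+span."""
    strands = strands or ["+"] * len(starts)
    ends = [s + span for s in starts]
    if gaps is not None:  # shrink ends so that start[k+1]-end[k] == gaps[k]
        ends = [starts[k + 1] - gaps[k] for k in range(len(gaps))] + [starts[-1] + span]
    return [
        MonomerHitRecord(read_id, s, e, st, "m", 1.0)
        for s, e, st in zip(starts, ends, strands)
    ]


def _assignment(labels, read_id="r1", threshold=0.98):
    sizes = {}
    for lab in labels:
        sizes[lab] = sizes.get(lab, 0) + 1
    return ClusterAssignment(
        read_id=read_id,
        threshold=threshold,
        labels=dict(enumerate(labels)),
        cluster_sizes=sizes,
    )


def perfect_tandem(k=4, copies=2, span=171):
    """k-monomer unit repeated `copies` times, zero gaps."""
    starts = [u * k * span + m * span for u in range(copies) for m in range(k)]
    labels = [chr(ord("A") + m) for _ in range(copies) for m in range(k)]
    return _hits(starts, span=span), _assignment(labels)


class TestEvaluateRegularity:
    def test_perfect_two_copy_tetramer_all_pass(self):
        hits, assignment = perfect_tandem(k=4, copies=2)
        rep = evaluate_regularity(hits, assignment)
        assert (rep.condition1, rep.condition2, rep.condition3, rep.condition4) == (
            True,
            True,
            True,
            True,
        )
        assert rep.regular
        assert rep.distances.median_d == 684.0
        assert rep.failing_monomers == []

    def test_deleted_monomer_breaks_condition1(self):
        hits, assignment = perfect_tandem(k=4, copies=2)
        # drop the 6th monomer (unit 1, monomer B): its cluster becomes singleton
        del hits[5]
        labels = ["A", "B", "C", "D", "A", "C", "D"]
        rep = evaluate_regularity(hits, _assignment(labels))
        assert not rep.condition1
        assert not rep.regular
        assert 1 in rep.failing_monomers  # the surviving singleton B member

    def test_strand_flip_breaks_condition4(self):
        hits, assignment = perfect_tandem(k=4, copies=2)
        strands = ["+"] * 8
        strands[5] = "-"
        flipped = _hits([h.start for h in hits], strands=strands)
        rep = evaluate_regularity(flipped, assignment)
        assert not rep.condition4
        assert 5 in rep.failing_monomers

    def test_ratio_arithmetic_exact_band(self):
        # one cluster with distances {1000, 1050, 950}: ratios 1.0/1.05/0.95
        starts = [0, 1000, 2050, 3000]
        hits = _hits(starts, span=171)
        rep = evaluate_regularity(hits, _assignment(["A"] * 4))
        assert rep.condition2  # 1.05 and 0.95 sit on the closed boundary

    def test_ratio_1_06_fails(self):
        starts = [0, 1000, 2060, 3060]  # distances 1000, 1060, 1000 -> 1.06
        hits = _hits(starts, gaps=[0, 0, 0])  # contiguous: only cond2 can fail
        rep = evaluate_regularity(hits, _assignment(["A"] * 4))
        assert not rep.condition2
        assert rep.condition3
        assert set(rep.failing_monomers) == {1, 2}

    def test_stretch_to_1_10_fails(self):
        hits, assignment = perfect_tandem(k=4, copies=4)
        # stretch the last unit's positions so one cluster distance is 1.10x
        # the pooled median (which stays at the unstretched unit length)
        shift = int(684 * 0.10)
        moved = [h.start + (shift if i >= 12 else 0) for i, h in enumerate(hits)]
        rep = evaluate_regularity(
            _hits(moved), _assignment([assignment.labels[i] for i in range(16)])
        )
        assert not rep.condition2

    def test_gap_5_passes_gap_6_fails(self):
        hits5 = _hits([0, 176], gaps=[5])
        assert evaluate_regularity(hits5, _assignment(["A", "A"])).condition3
        hits6 = _hits([0, 177], gaps=[6])
        rep = evaluate_regularity(hits6, _assignment(["A", "A"]))
        assert not rep.condition3
        assert rep.failing_monomers == [0, 1]

    def test_negative_gap_tolerated(self):
        a = MonomerHitRecord("r1", 0, 171, "+", "m", 1.0)
        b = MonomerHitRecord("r1", 168, 339, "+", "m", 1.0)  # 3 bp overlap
        assert evaluate_regularity([a, b], _assignment(["A", "A"])).condition3

    def test_300bp_insert_breaks_condition3(self):
        hits = _hits([0, 471], span=171)  # 300 bp of unmatched sequence between
        rep = evaluate_regularity(hits, _assignment(["A", "A"]))
        assert not rep.condition3

    def test_too_few_hits_rejected(self):
        with pytest.raises(ValueError):
            evaluate_regularity(_hits([0]), _assignment(["A"]))

    def test_unsorted_hits_rejected(self):
        hits, assignment = perfect_tandem()
        with pytest.raises(ValueError):
            evaluate_regularity(list(reversed(hits)), assignment)


class TestEstimatePeriod:
    def test_twelve_monomer_unit(self):
        hits, assignment = perfect_tandem(k=12, copies=2)
        dist = ClusterDistances.from_hits(hits, assignment)
        assert dist.median_d == 2052.0
        assert estimate_period(dist, hits) == 12

    def test_dimer(self):
        hits, assignment = perfect_tandem(k=2, copies=3)
        dist = ClusterDistances.from_hits(hits, assignment)
        assert dist.median_d == 342.0
        assert estimate_period(dist, hits) == 2

    def test_six_monomer_fixture_cross_check(self):
        read, truth, result = run_spec(
            SyntheticReadSpec(seed=61, period_k=6, n_units=3, read_error_rate=0.0)
        )
        assert result.classification.hor_period == 6
        # independent count: monomers between consecutive same-cluster hits
        fam = [p.family_index for p in truth.monomers]
        gap_counts = {
            fam.index(f, i + 1) - i
            for i, f in enumerate(fam)
            if f in fam[i + 1 :]
        }
        assert gap_counts == {6}

    def test_no_multimember_cluster_rejected(self):
        hits = _hits([0, 171])
        dist = ClusterDistances.from_hits(hits, _assignment(["A", "B"]))
        with pytest.raises(ValueError):
            estimate_period(dist, hits)


class TestClassification:
    def test_perfect_dimer_regular_period_2(self):
        _, truth, result = run_spec(
            SyntheticReadSpec(seed=71, period_k=2, n_units=4, read_error_rate=0.0)
        )
        c = result.classification
        assert c.label == "regular" and c.hor_period == 2

    def test_monomeric_read_no_hor(self):
        _, truth, result = run_spec(
            SyntheticReadSpec(
                seed=72, period_k=8, n_units=1, between_cluster_divergence=0.25
            )
        )
        c = result.classification
        assert c.label == "no-HOR" and c.monomeric_flag
        assert truth.expected_monomeric

    def test_single_copy_hor_no_hor(self):
        _, truth, result = run_spec(
            SyntheticReadSpec(seed=73, period_k=12, n_units=1, read_error_rate=0.0)
        )
        c = result.classification
        assert c.label == "no-HOR" and not c.monomeric_flag
        assert c.no_hor_reason in ("single-copy-or-incomplete", "single-monomer-period")

    def test_monomer_reuse_within_unit_is_irregular(self):
        # unit = A B A C (re-used near-identical monomer): uneven same-cluster
        # spacing must fail condition 2
        spec = SyntheticReadSpec(seed=74, period_k=3, n_units=2, read_error_rate=0.0)
        fam = make_monomer_family(spec)
        unit = fam[0] + fam[1] + fam[0] + fam[2]
        read = Read(id="reuse", sequence="TT" + unit * 3 + "GG")
        from tandemhor.detect import MonomerModel
        from tandemhor.pipeline import PipelineConfig, process_read

        models = [MonomerModel(f"m{i}", s) for i, s in enumerate(fam)]
        result = process_read(
            read, models=models, config=PipelineConfig(min_read_length=0)
        )
        assert result.classification.label == "irregular"
        assert not result.classification.inversion_flag

    def test_inversion_flag_requires_irregular(self):
        with pytest.raises(ValueError):
            ReadClassification(read_id="r", label="regular", inversion_flag=True)

    def test_monomeric_flag_requires_no_hor(self):
        with pytest.raises(ValueError):
            ReadClassification(read_id="r", label="regular", monomeric_flag=True)

    def test_fewer_than_two_hits_is_no_hor(self):
        read = Read(id="r", sequence="ACGT" * 100)
        c = classify_read(read, [], None, None, None)
        assert c.label == "no-HOR" and c.no_hor_reason == "too-few-monomers"


class TestConsensus:
    def test_three_identical_members(self):
        assert _majority_consensus(["ACGTAC"] * 3) == "ACGTAC"

    def test_single_substitution_outvoted(self):
        base = "ACGTACGTAC"
        mutant = "ACGTTCGTAC"
        assert _majority_consensus([base, mutant, base]) == base
        # and with the mutant as reference the majority still wins
        assert _majority_consensus([mutant, base, base]) == base

    def test_regular_dimer_consensus_shapes(self):
        read, truth, result = run_spec(
            SyntheticReadSpec(seed=81, period_k=2, n_units=3, read_error_rate=0.0)
        )
        assert result.classification.label == "regular"
        names = [rid for rid, _ in result.consensus]
        assert names[-1].endswith("/unit")
        unit_seq = result.consensus[-1][1]
        assert 2 * 171 - 10 <= len(unit_seq) <= 2 * 171 + 10
        assert len(result.consensus) == 3  # 2 cluster consensi + unit

    def test_non_regular_rejected(self):
        read, truth, result = run_spec(
            SyntheticReadSpec(
                seed=82,
                period_k=4,
                n_units=3,
                anomalies=(Anomaly("inversion", unit=1, monomer=1),),
            )
        )
        assert result.classification.label == "irregular"
        with pytest.raises(ValueError):
            hor_consensus(read, result.hits, None, result.classification)


class TestRegularInvariant:
    def test_regular_iff_all_conditions(self):
        hits, assignment = perfect_tandem(k=3, copies=3)
        rep = evaluate_regularity(hits, assignment)
        assert rep.regular == (
            rep.condition1 and rep.condition2 and rep.condition3 and rep.condition4
        )
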