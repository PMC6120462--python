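"""Motif scanning, Rossmann check and the candidate-selection criteria."""

import pytest

from iredmine.align import PositionMap
from iredmine.discovery import (
    CandidateVerdict,
    check_rossmann,
    evaluate_residue_criteria,
    run_filter,
    scan_gxgxxg,
)
from iredmine.seqio import SequenceRecord
from iredmine.simulate import FamilyConfig, generate_family


def rec(seq, sid="s"):
    return SequenceRecord(sid, seq)


class TestMotif:
    def test_single_hit_with_position_and_text(self):
        hits = scan_gxgxxg(rec("MGAGAAGKV"))
        assert [(h.start, h.matched_text) for h in hits] == [(2, "GAGAAG")]

    def test_no_hit(self):
        assert scan_gxgxxg(rec("AAAAAA")) == []

    def test_overlapping_hits_are_all_reported(self):
        hits = scan_gxgxxg(rec("GAGAAGAGAAG"))
        assert [h.start for h in hits] == [1, 6]


class TestRossmann:
    @pytest.fixture()
    def scaffold(self):
        fam = generate_family(FamilyConfig(n_taxa=4, seed=3))
        return fam.reference

    def test_planted_full_length_scaffold_passes(self, scaffold):
        ok, hit = check_rossmann(scaffold)
        assert ok
        assert hit.start == 15

    def test_truncation_excluded_by_min_length(self, scaffold):
        truncated = rec(scaffold.residues[:120])
        ok, hit = check_rossmann(truncated)
        assert not ok
        assert hit is not None  # motif still present, length is the failure

    def test_ablated_motif_fails(self, scaffold):
        seq = list(scaffold.residues)
        for g in (15, 17, 20):
            seq[g - 1] = "A"
        ok, hit = check_rossmann(rec("".join(seq)))
        assert not ok and hit is None

    def test_motif_outside_window_fails(self):
        seq = "A" * 100 + "GAGAAG" + "A" * 160
        ok, _ = check_rossmann(rec(seq), window=60, min_len=250)
        assert not ok

    def test_record_with_unknown_residues_fails(self):
        ok, _ = check_rossmann(rec("GAGAAG" + "X" * 280))
        assert not ok


def make_posmap(**residue_at):
    # identity map over the key positions used by the criteria
    return PositionMap("REF", "cand", {p: p for p in (111, 137, 187, 191)})


def candidate_with(res111="S", res137="L", res187="D", res191="L"):
    seq = ["A"] * 200
    seq[110], seq[136], seq[186], seq[190] = res111, res137, res187, res191
    return SequenceRecord("cand", "".join(seq))


class TestResidueCriteria:
    def test_aspartate_donor_with_apolar_flanks_passes(self):
        v = evaluate_residue_criteria(candidate_with(), make_posmap())
        assert v.donor_ok and v.polar_111_ok
        assert v.donor_residue == "D" and v.flank_137 == "L" and v.flank_191 == "L"

    def test_tyrosine_donor_waives_flank_rule(self):
        v = evaluate_residue_criteria(
            candidate_with(res187="Y", res137="S", res191="T"), make_posmap()
        )
        assert v.donor_ok

    def test_acidic_donor_with_polar_flank_fails(self):
        v = evaluate_residue_criteria(candidate_with(res191="S"), make_posmap())
        assert not v.donor_ok
        assert "apolar_flank" in v.failure_reasons

    def test_non_donor_residue_fails(self):
        v = evaluate_residue_criteria(candidate_with(res187="K"), make_posmap())
        assert not v.donor_ok
        assert "donor_residue" in v.failure_reasons

    def test_apolar_111_fails_polar_criterion(self):
        v = evaluate_residue_criteria(candidate_with(res111="A"), make_posmap())
        assert not v.polar_111_ok
        assert "polar_111" in v.failure_reasons

    def test_unaligned_key_position_fails_not_errors(self):
        pm = PositionMap("REF", "cand", {111: 111, 137: 137, 187: None, 191: 191})
        v = evaluate_residue_criteria(candidate_with(), pm)
        assert not v.donor_ok
        assert "donor_residue:unaligned" in v.failure_reasons

    def test_missing_position_definition_is_an_error(self):
        pm = PositionMap("REF", "cand", {111: 111})
        with pytest.raises(ValueError, match="lacks reference position"):
            evaluate_residue_criteria(candidate_with(), pm)


class TestRunFilter:
    def test_planted_truth_recovered(self, family):
        passing, report, _ = run_filter(family.records, family.templates, family.reference)
        truth_pos = {r.id for r in family.records if family.truth[r.id].is_positive}
        assert set(report.passing_ids()) == truth_pos
        for v in report.verdicts:
            row = family.truth[v.id]
            if row.is_positive:
                assert v.overall_pass
            elif row.negative_mode == "distant_outgroup":
                assert "evalue" in v.failure_reasons
            else:
                assert v.failure_reasons == row.expected_failures

    def test_templates_pass_against_themselves(self, positives_only):
        fam = positives_only
        passing, report, _ = run_filter(
            fam.templates, fam.templates, fam.reference
        )
        assert report.n_pass_all == len(fam.templates)
        assert all(v.best_e_value < 1e-50 for v in report.verdicts)

    def test_zero_threshold_degenerate_gate(self, positives_only):
        fam = positives_only
        _, report, _ = run_filter(
            fam.records, fam.templates, fam.reference, evalue_threshold=0.0
        )
        assert report.n_pass_evalue == 0
        assert report.n_pass_all == 0

    def test_relaxing_threshold_is_monotone(self, family):
        counts = []
        for thr in (1e-100, 1e-50, 1e-10, 1.0):
            _, report, _ = run_filter(
                family.records, family.templates, family.reference, evalue_threshold=thr
            )
            counts.append(report.n_pass_all)
        assert counts == sorted(counts)

    def test_criterion_toggle_changes_only_its_contribution(self, family):
        _, on, _ = run_filter(family.records, family.templates, family.reference)
        _, off, _ = run_filter(
            family.records, family.templates, family.reference, enforce_polar_111=False
        )
        for v_on, v_off in zip(on.verdicts, off.verdicts):
            assert v_on.passed_evalue == v_off.passed_evalue
            assert v_on.has_rossmann == v_off.has_rossmann
            assert v_on.donor_ok == v_off.donor_ok
        # the record built to violate only the polar-111 rule passes once
        # that rule is disabled
        neg = next(v for v in on.verdicts if v.id.startswith("NEG_break_111"))
        assert not neg.overall_pass
        assert off.verdict(neg.id).overall_pass

    def test_empty_candidate_set_gives_empty_report(self, positives_only):
        fam = positives_only
        passing, report, posmaps = run_filter([], fam.templates, fam.reference)
        assert passing == [] and report.n_input == 0 and posmaps == {}

    def test_pass_verdicts_are_auditable(self, family):
        _, report, _ = run_filter(family.records, family.templates, family.reference)
        for v in report.verdicts:
            if v.overall_pass:
                assert v.res_111 in "ST"
                assert v.donor_residue in "DEY"
                if v.donor_residue in "DE":
                    assert v.flank_137 in "AILMFV" and v.flank_191 in "AILMFV"
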