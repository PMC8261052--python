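"""Signature screening: verdict assignment for MerA/MerB candidates."""

import pytest

from merscreen.alnmap import Alignment, build_map
from merscreen.screen import (
    HomologRecord,
    ScreenError,
    screen_dataset,
    screen_sequence,
)
from merscreen.sigdb import builtin_profile
from merscreen.synthetic_data import SimulationConfig, simulate_cohort, toy_profile

MERA = builtin_profile("MerA")
MERB = builtin_profile("MerB")

# Full-coordinate scaffolds: alanine backbones carrying the canonical
# signature residues at the literature positions.
_MERA_CANON = {207: "C", 212: "C", 264: "Y", 605: "Y", 628: "C", 629: "C"}
_MERB_CANON = {96: "C", 99: "D", 117: "C", 159: "C"}


def scaffold(canon: dict[int, str], length: int, overrides: dict[int, str] | None = None) -> str:
    residues = ["A"] * length
    for pos, aa in {**canon, **(overrides or {})}.items():
        residues[pos - 1] = aa
    return "".join(residues)


def mera_aln(query: str) -> Alignment:
    ref = scaffold(_MERA_CANON, 640)
    return Alignment(((MERA.reference_id, ref), ("q", query)))


def merb_aln(query: str) -> Alignment:
    ref = scaffold(_MERB_CANON, 220)
    return Alignment(((MERB.reference_id, ref), ("q", query)))


def verdict_a(query: str, domain: str = "Bacteria"):
    aln = mera_aln(query)
    amap = build_map(aln, MERA.reference_id)
    record = HomologRecord("q", "g1", domain, sequence=query.replace("-", ""))
    return screen_sequence(record, aln, amap, MERA)


def verdict_b(query: str, domain: str = "Bacteria"):
    aln = merb_aln(query)
    amap = build_map(aln, MERB.reference_id)
    record = HomologRecord("q", "g1", domain, sequence=query.replace("-", ""))
    return screen_sequence(record, aln, amap, MERB)


class TestMerA:
    def test_canonical_bacterial_sequence(self):
        v = verdict_a(scaffold(_MERA_CANON, 640))
        assert v.status == "canonical"
        assert not v.variant_labels

    def test_phenylalanine_at_605_in_bacterium_is_variant(self):
        v = verdict_a(scaffold(_MERA_CANON, 640, {605: "F"}))
        assert v.status == "variant"
        assert v.variant_labels == {"605-variant"}

    def test_tyrosine_at_605_in_archaeon_is_variant(self):
        v = verdict_a(scaffold(_MERA_CANON, 640, {605: "Y"}), domain="Archaea")
        assert v.status == "variant"
        assert v.variant_labels == {"605-variant"}

    def test_archaeal_canonical_is_phenylalanine(self):
        v = verdict_a(scaffold(_MERA_CANON, 640, {605: "F"}), domain="Archaea")
        assert v.status == "canonical"

    def test_third_residue_at_605_rejects(self):
        v = verdict_a(scaffold(_MERA_CANON, 640, {605: "W"}))
        assert v.status == "reject"

    def test_broken_vicinal_pair_rejects_jointly(self):
        v = verdict_a(scaffold(_MERA_CANON, 640, {628: "S"}))
        assert v.status == "reject"
        outcomes = {r.ref_position: r.outcome for r in v.per_position_report}
        assert outcomes[628].startswith("fail")
        assert outcomes[629] == "fail:paired-position"

    def test_gap_at_essential_position_rejects(self):
        query = scaffold(_MERA_CANON, 640)
        query = query[:206] + "-" + query[207:]
        v = verdict_a(query)
        assert v.status == "reject"
        outcomes = {r.ref_position: r.outcome for r in v.per_position_report}
        assert outcomes[207] == "fail:gap-at-essential"

    def test_x_at_signature_position_is_ambiguous_not_reject(self):
        v = verdict_a(scaffold(_MERA_CANON, 640, {264: "X"}))
        assert v.status == "ambiguous"

    def test_gap_at_variant_eligible_position_is_ambiguous(self):
        query = scaffold(_MERA_CANON, 640)
        query = query[:604] + "-" + query[605:]
        v = verdict_a(query)
        assert v.status == "ambiguous"

    def test_truncated_sequence_missing_cterm_rejects(self):
        # Candidate aligned only over the N-terminal half: C-terminal
        # signature columns are gaps -> reject (missing region).
        query = scaffold(_MERA_CANON, 640)[:300] + "-" * 340
        v = verdict_a(query)
        assert v.status == "reject"

    def test_unknown_domain_accepts_either_605_residue_with_warning(self):
        v = verdict_a(scaffold(_MERA_CANON, 640, {605: "F"}), domain=None)
        assert v.status == "canonical"
        assert any("unknown domain" in w for w in v.warnings)

    def test_plasmid_records_use_bacterial_rules(self):
        v = verdict_a(
            scaffold(_MERA_CANON, 640, {605: "F"}), domain="Plasmid:Bacteria"
        )
        assert v.status == "variant"


class TestMerB:
    def test_canonical(self):
        assert verdict_b(scaffold(_MERB_CANON, 220)).status == "canonical"

    def test_alanine_at_96_rejects(self):
        assert verdict_b(scaffold(_MERB_CANON, 220, {96: "A"})).status == "reject"

    def test_serine_at_99_is_99ser_variant(self):
        v = verdict_b(scaffold(_MERB_CANON, 220, {99: "S"}))
        assert v.status == "variant"
        assert v.variant_labels == {"99Ser"}

    def test_any_substitution_at_117_is_117alt(self):
        for aa in "AGSV":
            v = verdict_b(scaffold(_MERB_CANON, 220, {117: aa}))
            assert v.status == "variant"
            assert v.variant_labels == {"117alt"}

    def test_unexpected_residue_at_99_flagged_not_rejected(self):
        v = verdict_b(scaffold(_MERB_CANON, 220, {99: "K"}))
        assert v.status == "variant"
        assert v.variant_labels == {"unclassified-99"}
        assert any("unclassified-99" in w for w in v.warnings)


class TestDataset:
    def test_record_absent_from_alignment_is_error_not_reject(self):
        aln = mera_aln(scaffold(_MERA_CANON, 640))
        amap = build_map(aln, MERA.reference_id)
        with pytest.raises(ScreenError):
            screen_sequence(
                HomologRecord("ghost", "g", "Bacteria"), aln, amap, MERA
            )

    def test_empty_dataset_gives_zero_summary(self):
        aln = mera_aln(scaffold(_MERA_CANON, 640))
        verdicts, summary = screen_dataset([], aln, MERA)
        assert verdicts == []
        assert summary["total"] == 0
        assert all(summary[s] == 0 for s in ("canonical", "variant", "reject"))

    def test_reference_screens_canonical(self):
        ref = scaffold(_MERA_CANON, 640)
        aln = Alignment(((MERA.reference_id, ref), ("copy", ref)))
        verdicts, summary = screen_dataset(
            [HomologRecord("copy", "g", "Bacteria", sequence=ref)], aln, MERA
        )
        assert summary["canonical"] == 1

    def test_summary_partitions_input(self, dense_cohort):
        c = dense_cohort
        verdicts, summary = screen_dataset(c.records_A, c.aln_A, toy_profile("MerA"))
        statuses = ("canonical", "variant", "ambiguous", "reject")
        assert sum(summary[s] for s in statuses) == summary["total"] == len(verdicts)

    def test_planted_truth_recovered_exactly(self, dense_cohort):
        c = dense_cohort
        for records, aln, profile in [
            (c.records_A, c.aln_A, toy_profile("MerA")),
            (c.records_B, c.aln_B, toy_profile("MerB")),
        ]:
            verdicts, _ = screen_dataset(records, aln, profile)
            assert [v.protein_id for v in verdicts] == [
                r.protein_id for r in records
            ]  # order preserved
            for v in verdicts:
                assert v.status == c.truth.protein_status[v.protein_id]
                assert v.variant_labels == c.truth.protein_labels[v.protein_id]

    def test_adding_unrelated_row_never_changes_verdicts(self):
        query = scaffold(_MERA_CANON, 640, {605: "F"})
        aln1 = mera_aln(query)
        v1 = verdict_a(query)
        rows = aln1.rows + (("unrelated", "W" * aln1.length),)
        aln2 = Alignment(rows)
        amap2 = build_map(aln2, MERA.reference_id)
        record = HomologRecord("q", "g1", "Bacteria")
        v2 = screen_sequence(record, aln2, amap2, MERA)
        assert (v1.status, v1.variant_labels) == (v2.status, v2.variant_labels)

    def test_determinism(self, dense_cohort):
        c = dense_cohort
        v1, s1 = screen_dataset(c.records_A, c.aln_A, toy_profile("MerA"))
        v2, s2 = screen_dataset(c.records_A, c.aln_A, toy_profile("MerA"))
        assert v1 == v2 and s1 == s2
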