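"""Signature screening of candidate MerA/MerB homologs.

Each candidate protein, taken as a row of a reference-anchored multiple
alignment, is inspected at every signature position of a profile and
assigned one of four verdicts:

* ``canonical`` — every position carries an accepted canonical residue;
* ``variant``   — one or more positions carry a residue with a named
  variant class (e.g. F at MerA position 605 in a bacterium, S at MerB
  position 99) and nothing disqualifies the call;
* ``ambiguous`` — a position could not be read (X, a non-standard
  character, or a gap/absence at a variant-eligible position);
* ``reject``    — an essential position failed: wrong residue where any
  other residue invalidates the call, a gap, or a missing position.

Verdict precedence is reject > ambiguous > variant > canonical: a record
whose essential positions all hold but which cannot be fully read is
reported ambiguous even if it also carries a variant label (the label is
retained on the verdict for auditing).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .alnmap import GAP, MISSING, Alignment, AlignmentMap, build_map, residue_at
from .sigdb import AMBIGUOUS_RESIDUE, AMINO_ACIDS, SignaturePosition, SignatureProfile

__all__ = [
    "HomologRecord",
    "PositionReport",
    "ScreenVerdict",
    "ScreenError",
    "screen_sequence",
    "screen_dataset",
    "STATUSES",
]

STATUSES = ("canonical", "variant", "ambiguous", "reject")

#: Domains evaluated under bacterial signature rules.
_DOMAIN_ALIASES = {"Plasmid:Bacteria": "Bacteria"}


class ScreenError(ValueError):
    """Screening request is invalid (distinct from a reject verdict)."""


@dataclass(frozen=True)
class HomologRecord:
    """One candidate protein with its genome and taxonomy context."""

    protein_id: str
    genome_id: str
    domain: str | None = None
    phylum: str = "unclassified"
    class_: str | None = None
    deposit_type: str = "isolate"
    sequence: str = ""


@dataclass(frozen=True)
class PositionReport:
    """Outcome of one signature position for one record."""

    ref_position: int
    observed: str
    outcome: str  # canonical | variant:<label> | ambiguous:<reason> | fail:<reason>


@dataclass(frozen=True)
class ScreenVerdict:
    protein_id: str
    status: str
    variant_labels: frozenset[str] = frozenset()
    per_position_report: tuple[PositionReport, ...] = ()
    warnings: tuple[str, ...] = ()


def _classify_position(
    pos: SignaturePosition, observed: str
) -> tuple[str, str | None, str | None]:
    """Return (kind, variant_label, warning) for one observed residue.

    kind is one of canonical / variant / ambiguous / fail.
    """
    if observed == MISSING:
        if pos.essential:
            return "fail", None, None
        return "ambiguous", None, None
    if observed == GAP:
        # The named variants are defined by observed residues, not absences.
        if pos.essential:
            return "fail", None, None
        return "ambiguous", None, None
    if observed == AMBIGUOUS_RESIDUE:
        return "ambiguous", None, None
    if observed not in AMINO_ACIDS:
        return "ambiguous", None, None
    if observed in pos.canonical_residues:
        return "canonical", None, None
    for rule in pos.variant_rules:
        if rule.residues is None or observed in rule.residues:
            warning = (
                f"position {pos.ref_position}: residue {observed} flagged "
                f"{rule.label}" if rule.warn else None
            )
            return "variant", rule.label, warning
    if pos.reject_on_other:
        return "fail", None, None
    return "ambiguous", None, None


_OUTCOME_REASON = {
    MISSING: "missing-position",
    GAP: "gap-at-essential",
}


def screen_sequence(
    record: HomologRecord,
    aln: Alignment,
    amap: AlignmentMap,
    profile: SignatureProfile,
) -> ScreenVerdict:
    """Evaluate one candidate against every position of a profile."""
    if record.protein_id not in aln:
        raise ScreenError(
            f"record {record.protein_id!r} has no row in the alignment"
        )
    domain = _DOMAIN_ALIASES.get(record.domain, record.domain)
    warnings: list[str] = []
    if domain is None and profile.domain_conditional:
        warnings.append(
            f"{record.protein_id}: unknown domain; domain-conditional "
            "positions evaluated against the union of canonical residues"
        )

    kinds: dict[int, str] = {}
    labels: set[str] = set()
    reports: list[PositionReport] = []
    for base in profile.positions:
        pos = profile.position_for(base.ref_position, domain)
        observed = residue_at(aln, amap, record.protein_id, pos.ref_position)
        kind, label, warning = _classify_position(pos, observed)
        kinds[pos.ref_position] = kind
        if label is not None:
            labels.add(label)
        if warning is not None:
            warnings.append(f"{record.protein_id}: {warning}")
        if kind == "fail":
            reason = _OUTCOME_REASON.get(observed, "unexpected-residue")
            outcome = f"fail:{reason}"
        elif kind == "variant":
            outcome = f"variant:{label}"
        elif kind == "ambiguous":
            outcome = "ambiguous"
        else:
            outcome = "canonical"
        reports.append(PositionReport(pos.ref_position, observed, outcome))

    # Paired positions (vicinal cysteines) fail jointly.
    for a, b in profile.paired_positions:
        if kinds.get(a) == "fail" or kinds.get(b) == "fail":
            kinds[a] = kinds[b] = "fail"
            reports = [
                PositionReport(r.ref_position, r.observed, "fail:paired-position")
                if r.ref_position in (a, b) and not r.outcome.startswith("fail")
                else r
                for r in reports
            ]

    if any(k == "fail" for k in kinds.values()):
        status = "reject"
    elif any(k == "ambiguous" for k in kinds.values()):
        status = "ambiguous"
    elif labels:
        status = "variant"
    else:
        status = "canonical"
    return ScreenVerdict(
        protein_id=record.protein_id,
        status=status,
        variant_labels=frozenset(labels),
        per_position_report=tuple(reports),
        warnings=tuple(warnings),
    )


def screen_dataset(
    records: list[HomologRecord],
    aln: Alignment,
    profile: SignatureProfile,
    amap: AlignmentMap | None = None,
) -> tuple[list[ScreenVerdict], dict[str, int]]:
    """Screen a batch of records; order-preserving.

    Returns the verdict list and a summary whose status and per-label
    counts partition the input (``total`` equals ``len(records)``).
    """
    if amap is None:
        amap = build_map(aln, profile.reference_id)
    verdicts = [screen_sequence(r, aln, amap, profile) for r in records]
    summary: Counter[str] = Counter()
    for v in verdicts:
        summary[v.status] += 1
        for label in v.variant_labels:
            summary[f"label:{label}"] += 1
    out = {status: summary.get(status, 0) for status in STATUSES}
    out.update({k: n for k, n in sorted(summary.items()) if k.startswith("label:")})
    out["total"] = len(verdicts)
    return verdicts, out
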