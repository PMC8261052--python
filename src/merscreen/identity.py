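"""Within-genome pairwise percent identity of homolog copies.

Genomes carrying several MerA (or MerB) copies are examined for recent
gene duplication by computing percent identity over a global
(end-to-end) Needleman–Wunsch alignment of each unordered pair of
copies. Identity = 100 x identical columns / total alignment columns;
gap-aligned columns (end gaps included) count in the denominator and
never as identical. An alternative mode computes identity directly on
rows of a supplied multiple alignment instead of re-aligning each pair.

Scoring is identity-oriented by default — match +1, mismatch 0, linear
gap -1 — because the quantity of interest is percent identity, not
substitution-matrix similarity. Traceback ties break deterministically:
diagonal, then up (gap in the second sequence), then left.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .alnmap import GAP

__all__ = [
    "Scoring",
    "PairwiseIdentity",
    "IdentityError",
    "global_align",
    "percent_identity",
    "aligned_row_identity",
    "within_genome_identity",
    "flag_duplications",
]


class IdentityError(ValueError):
    """Invalid identity-computation request."""


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -1.0


@dataclass(frozen=True)
class PairwiseIdentity:
    genome_id: str
    protein_id_a: str
    protein_id_b: str
    aligned_columns: int
    identical_columns: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identical_columns / self.aligned_columns


def global_align(
    a: str, b: str, scoring: Scoring = Scoring()
) -> tuple[str, str, float]:
    """End-to-end dynamic-programming alignment of two sequences.

    Returns the two gapped rows and the optimal score. Deterministic
    under the fixed tie-break diagonal > up > left.
    """
    if not a or not b:
        raise IdentityError("global_align requires nonempty sequences")
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=float)
    score[0, :] = np.arange(m + 1) * scoring.gap
    score[:, 0] = np.arange(n + 1) * scoring.gap
    sub = np.where(
        np.frombuffer(a.encode(), dtype=np.uint8)[:, None]
        == np.frombuffer(b.encode(), dtype=np.uint8)[None, :],
        scoring.match,
        scoring.mismatch,
    )
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + scoring.gap
        row = score[i]
        row[0] = i * scoring.gap
        for j in range(1, m + 1):
            row[j] = max(diag[j - 1], up[j - 1], row[j - 1] + scoring.gap)

    # Traceback with fixed preference order.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + scoring.gap:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])


def _column_counts(row_a: str, row_b: str, skip_shared_gaps: bool) -> tuple[int, int]:
    aligned = identical = 0
    for x, y in zip(row_a, row_b):
        if skip_shared_gaps and x == GAP and y == GAP:
            continue
        aligned += 1
        if x == y and x != GAP:
            identical += 1
    return aligned, identical


def percent_identity(a: str, b: str, scoring: Scoring = Scoring()) -> float:
    """Percent identity of a fresh pairwise global alignment."""
    row_a, row_b, _ = global_align(a, b, scoring)
    aligned, identical = _column_counts(row_a, row_b, skip_shared_gaps=False)
    return 100.0 * identical / aligned


def aligned_row_identity(row_a: str, row_b: str) -> float:
    """Percent identity computed on rows of an existing alignment.

    Columns gapped in both rows are dropped (they carry no signal for
    this pair); columns gapped in one row count as non-identical.
    """
    aligned, identical = _column_counts(row_a, row_b, skip_shared_gaps=True)
    if aligned == 0:
        raise IdentityError("rows share no non-gap columns")
    return 100.0 * identical / aligned


def within_genome_identity(
    groups: dict[str, dict[str, str]], scoring: Scoring = Scoring()
) -> list[PairwiseIdentity]:
    """All unordered identity pairs per genome.

    ``groups`` maps genome_id -> {protein_id: ungapped sequence};
    genomes contributing fewer than two homologs are skipped.
    """
    results: list[PairwiseIdentity] = []
    for genome_id in sorted(groups):
        seqs = groups[genome_id]
        if any(not s for s in seqs.values()):
            raise IdentityError(f"genome {genome_id}: empty sequence")
        for pid_a, pid_b in itertools.combinations(sorted(seqs), 2):
            row_a, row_b, _ = global_align(seqs[pid_a], seqs[pid_b], scoring)
            aligned, identical = _column_counts(row_a, row_b, skip_shared_gaps=False)
            results.append(
                PairwiseIdentity(genome_id, pid_a, pid_b, aligned, identical)
            )
    return results


def flag_duplications(
    identities: list[PairwiseIdentity], threshold: float = 85.0
) -> list[tuple[PairwiseIdentity, str]]:
    """Flag pairs at or above an identity threshold as putative duplications.

    The default of 85% retains clear duplicate pairs (identical copies,
    and near-identical ones such as two copies at ~89% identity) while
    excluding distant within-genome paralogs.
    """
    if not 0 < threshold <= 100:
        raise IdentityError(f"threshold must be in (0, 100], got {threshold}")
    return [
        (ident, "putative-duplication")
        for ident in identities
        if ident.percent_identity >= threshold
    ]
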