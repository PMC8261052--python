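"""Genome- and taxon-level tabulation of validated homologs.

Builds per-genome complements (MerA copies, MerB copies, MerB-like
variant copies) from screening verdicts, then rolls them up into the
three standard report shapes: a phylum-level table of MerA/MerB-encoding
genome counts (with Proteobacteria broken out by class), per-domain
copy-number distributions, and the four-way MerA/MerB co-distribution
partition (A-only / B-only / both / neither).

Counting conventions follow the source screening scheme: a genome's MerA
complement includes canonical homologs and retained variants (the
605-variant class); its MerB complement includes canonical homologs
only, with the MerB-like classes (99Ser, 117alt) tallied separately and
excluded from co-distribution by default (``include_merb_like`` switches
this).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .screen import ScreenVerdict

__all__ = [
    "GenomeInventory",
    "InventoryError",
    "build_inventory",
    "rollup",
    "copy_number_distribution",
    "codistribution_partition",
    "pct",
    "inventories_to_frame",
    "frame_to_inventories",
    "DOMAIN_GROUPS",
    "MERB_LIKE_LABELS",
]

DOMAIN_GROUPS = ("Archaea", "Bacteria", "Plasmid:Bacteria")

#: Variant classes counted as MerB-like rather than MerB.
MERB_LIKE_LABELS = ("99Ser", "117alt")


class InventoryError(ValueError):
    """Tabulation input is inconsistent."""


@dataclass(frozen=True)
class GenomeInventory:
    """Per-genome complement of validated homologs."""

    genome_id: str
    domain: str
    phylum: str = "unclassified"
    class_: str | None = None
    deposit_type: str = "isolate"
    merA_count: int = 0
    merB_count: int = 0
    merB_like_counts: dict[str, int] = field(default_factory=dict)

    def codist(self, include_merb_like: bool = False) -> str:
        """Co-distribution class of this genome."""
        b = self.merB_count
        if include_merb_like:
            b += sum(self.merB_like_counts.values())
        if self.merA_count > 0 and b > 0:
            return "both"
        if self.merA_count > 0:
            return "A-only"
        if b > 0:
            return "B-only"
        return "neither"


def pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage ``100*numerator/denominator``, half-away-from-zero.

    Reports in the field round this way (13.8%, 7.75%, 0.6%); the number
    of decimals is configurable per report column.
    """
    if denominator == 0:
        raise InventoryError("pct: zero denominator")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def _retained(verdict: ScreenVerdict) -> bool:
    return verdict.status in ("canonical", "variant")


def build_inventory(
    verdicts_A: list[ScreenVerdict],
    verdicts_B: list[ScreenVerdict],
    meta: pd.DataFrame,
    protein_genomes_A: dict[str, str] | None = None,
    protein_genomes_B: dict[str, str] | None = None,
) -> list[GenomeInventory]:
    """Assemble per-genome complements from two screening runs.

    ``meta`` is the genome metadata table (columns: genome_id, domain,
    phylum, class, deposit_type); every genome in it yields an inventory
    row, including genomes with no retained homolog ("neither" class).
    ``protein_genomes_*`` map protein ids to genome ids; they default to
    ``meta`` carrying one row per protein (column protein_id).
    """
    meta = meta.fillna({"class": "", "phylum": "unclassified"})
    if protein_genomes_A is None or protein_genomes_B is None:
        if "protein_id" not in meta.columns:
            raise InventoryError(
                "meta lacks protein_id; pass protein→genome maps explicitly"
            )
        lookup = dict(zip(meta["protein_id"], meta["genome_id"]))
        protein_genomes_A = protein_genomes_A or lookup
        protein_genomes_B = protein_genomes_B or lookup

    a_counts: Counter[str] = Counter()
    b_counts: Counter[str] = Counter()
    b_like: dict[str, Counter[str]] = defaultdict(Counter)
    for v in verdicts_A:
        gid = _genome_of(v, protein_genomes_A)
        if _retained(v):
            a_counts[gid] += 1
    for v in verdicts_B:
        gid = _genome_of(v, protein_genomes_B)
        if v.status == "canonical":
            b_counts[gid] += 1
        elif v.status == "variant":
            # A MerB-like variant: tally under each of its labels.
            for label in v.variant_labels:
                b_like[gid][label] += 1

    genome_rows = meta.drop_duplicates("genome_id")
    known = set(genome_rows["genome_id"])
    orphans = (set(a_counts) | set(b_counts) | set(b_like)) - known
    if orphans:
        raise InventoryError(
            f"verdicts reference genomes absent from metadata: {sorted(orphans)[:5]}"
        )

    inventories = []
    for row in genome_rows.to_dict("records"):
        gid = row["genome_id"]
        inventories.append(
            GenomeInventory(
                genome_id=gid,
                domain=row["domain"],
                phylum=row.get("phylum", "unclassified"),
                class_=row.get("class") or row.get("class_") or None,
                deposit_type=row.get("deposit_type", "isolate"),
                merA_count=a_counts.get(gid, 0),
                merB_count=b_counts.get(gid, 0),
                merB_like_counts=dict(b_like.get(gid, {})),
            )
        )
    return inventories


def inventories_to_frame(inventories: list[GenomeInventory]) -> pd.DataFrame:
    """Flatten inventories to a table (MerB-like labels as columns)."""
    rows = []
    for inv in inventories:
        row = {
            "genome_id": inv.genome_id,
            "domain": inv.domain,
            "phylum": inv.phylum,
            "class": inv.class_ or "",
            "deposit_type": inv.deposit_type,
            "merA_count": inv.merA_count,
            "merB_count": inv.merB_count,
        }
        for label in MERB_LIKE_LABELS:
            row[f"merB_like_{label}"] = inv.merB_like_counts.get(label, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_inventories(frame: pd.DataFrame) -> list[GenomeInventory]:
    """Inverse of :func:`inventories_to_frame`."""
    out = []
    like_cols = [c for c in frame.columns if c.startswith("merB_like_")]
    for row in frame.fillna("").to_dict("records"):
        like = {
            c.removeprefix("merB_like_"): int(row[c])
            for c in like_cols
            if int(row[c]) > 0
        }
        out.append(
            GenomeInventory(
                genome_id=str(row["genome_id"]),
                domain=row["domain"],
                phylum=row.get("phylum") or "unclassified",
                class_=row.get("class") or None,
                deposit_type=row.get("deposit_type") or "isolate",
                merA_count=int(row["merA_count"]),
                merB_count=int(row["merB_count"]),
                merB_like_counts=like,
            )
        )
    return out


def _genome_of(v: ScreenVerdict, lookup: dict[str, str]) -> str:
    try:
        return lookup[v.protein_id]
    except KeyError:
        raise InventoryError(
            f"no genome mapping for protein {v.protein_id!r}"
        ) from None


def _taxon_key(inv: GenomeInventory) -> tuple[str, str]:
    """Rollup row key: phylum, or class for Proteobacteria."""
    if inv.phylum == "Proteobacteria" and inv.class_:
        return inv.domain, f"Proteobacteria/{inv.class_}"
    return inv.domain, inv.phylum


def rollup(
    inventories: list[GenomeInventory], include_merb_like: bool = False
) -> pd.DataFrame:
    """Phylum-level table of MerA- and MerB-encoding genome counts.

    Rows are keyed by (domain group, taxon) where taxon is the phylum,
    or ``Proteobacteria/<class>`` for proteobacterial genomes. Domain
    marginal rows (taxon ``"ALL"``) are appended and satisfy the sum
    invariant by construction of the input.
    """
    rows: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for inv in inventories:
        b = inv.merB_count + (
            sum(inv.merB_like_counts.values()) if include_merb_like else 0
        )
        key = _taxon_key(inv)
        if inv.merA_count > 0:
            rows[key]["merA_genomes"] += 1
        if b > 0:
            rows[key]["merB_genomes"] += 1

    records = []
    marginals: dict[str, Counter] = defaultdict(Counter)
    for (domain, taxon) in sorted(rows):
        c = rows[(domain, taxon)]
        records.append(
            {
                "domain": domain,
                "taxon": taxon,
                "merA_genomes": c["merA_genomes"],
                "merB_genomes": c["merB_genomes"],
            }
        )
        marginals[domain] += c
    for domain in sorted(marginals):
        c = marginals[domain]
        records.append(
            {
                "domain": domain,
                "taxon": "ALL",
                "merA_genomes": c["merA_genomes"],
                "merB_genomes": c["merB_genomes"],
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["domain", "taxon", "merA_genomes", "merB_genomes"]
    )


def copy_number_distribution(
    inventories: list[GenomeInventory], which: str
) -> dict[str, dict[int, int]]:
    """Copies-per-genome histogram per domain group, zero copies excluded.

    Returns ``{domain_group: {copies: n_genomes, ...}}``; the per-group
    total of genomes encoding the marker is the sum over the histogram.
    """
    if which not in ("MerA", "MerB"):
        raise InventoryError(f"which must be MerA or MerB, got {which!r}")
    dist: dict[str, Counter[int]] = defaultdict(Counter)
    for inv in inventories:
        n = inv.merA_count if which == "MerA" else inv.merB_count
        if n > 0:
            dist[inv.domain][n] += 1
    return {domain: dict(sorted(c.items())) for domain, c in sorted(dist.items())}


def codistribution_partition(
    inventories: list[GenomeInventory],
    include_merb_like: bool = False,
    total_genomes: int | None = None,
) -> dict[str, int]:
    """Four-way MerA/MerB co-distribution counts.

    ``total_genomes``, when given, sets the partition total so that the
    "neither" class covers genomes not present in ``inventories`` (e.g.
    when only marker-positive genomes were inventoried).
    """
    counts = Counter(inv.codist(include_merb_like) for inv in inventories)
    out = {k: counts.get(k, 0) for k in ("A-only", "B-only", "both", "neither")}
    if total_genomes is not None:
        listed = sum(out.values())
        if total_genomes < listed:
            raise InventoryError(
                f"total_genomes {total_genomes} < {listed} inventoried genomes"
            )
        out["neither"] = total_genomes - (out["A-only"] + out["B-only"] + out["both"])
    return out
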