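"""Seeded synthetic cohorts with planted ground truth.

Generates everything the pipeline consumes — candidate protein
sequences, reference-anchored alignments, genome metadata, and a
taxonomy-clustered tree — from a single seed, together with the planted
truth (per-protein signature class, per-genome complement and
co-distribution class, per-lineage trait counts), so every stage can be
tested end to end without any database download.

Sequences are built from short bundled reference templates that carry
the signature positions at scaled coordinates (toy length ~120 for the
mercuric-reductase marker, ~80 for the lyase marker; see
:data:`MERA_COORD_MAP` / :data:`MERB_COORD_MAP` for the mapping to the
literature numbering 207/212/264/605/628/629 and 96/99/117/159).
Screening logic is coordinate-relative, so nothing is lost by testing at
toy length. Planted variants mutate exactly their designated position;
rejects mutate an essential position; ambiguous copies carry an X at a
signature position. Alignments are produced by construction
(template-anchored columns plus injected insertion columns and gap
deletions), never by running an aligner.

Default rates mirror the statistical structure of the surveyed genome
collection: ~7.8% of genomes encode the reductase, a multi-copy tail up
to 8 copies per genome, ~13.5% of reductase-positive genomes also encode
the lyase, and small variant fractions (605-swap ~0.6% of reductase
homologs; 99Ser rare and 117alt common among lyase-like homologs).

Separate pseudorandom streams are derived per output kind, so adding
one output never perturbs the others under the same seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alnmap import Alignment
from .inventory import GenomeInventory
from .screen import HomologRecord
from .sigdb import SignatureProfile, SignaturePosition, builtin_profile

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "write_cohort",
    "fixture_tables",
    "toy_profile",
    "toy_reference",
    "MERA_COORD_MAP",
    "MERB_COORD_MAP",
]

# ---------------------------------------------------------------------------
# Toy reference templates
# ---------------------------------------------------------------------------

#: Literature position -> 1-based toy position for the reductase marker.
MERA_COORD_MAP = {207: 31, 212: 36, 264: 51, 605: 101, 628: 111, 629: 112}
#: Literature position -> 1-based toy position for the lyase marker.
MERB_COORD_MAP = {96: 21, 99: 24, 117: 41, 159: 61}

MERA_TOY_LENGTH = 120
MERB_TOY_LENGTH = 80

_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _make_template(length: int, signature: dict[int, str], seed: int) -> str:
    rng = np.random.default_rng(seed)
    residues = rng.choice(_ALPHABET, size=length)
    for pos1, aa in signature.items():
        residues[pos1 - 1] = aa
    return "".join(residues)


# Canonical residues of the bacterial reference proteins at toy coordinates.
_MERA_SIGNATURE = {31: "C", 36: "C", 51: "Y", 101: "Y", 111: "C", 112: "C"}
_MERB_SIGNATURE = {21: "C", 24: "D", 41: "C", 61: "C"}

#: Bundled toy reference sequences (bacterial canonical state).
MERA_TEMPLATE = _make_template(MERA_TOY_LENGTH, _MERA_SIGNATURE, seed=7042)
MERB_TEMPLATE = _make_template(MERB_TOY_LENGTH, _MERB_SIGNATURE, seed=7043)

TOY_REFERENCE_IDS = {"MerA": "REF_MerA_toy", "MerB": "REF_MerB_toy"}


def toy_reference(name: str) -> tuple[str, str]:
    """(reference id, ungapped template sequence) for a toy marker."""
    if name == "MerA":
        return TOY_REFERENCE_IDS["MerA"], MERA_TEMPLATE
    if name == "MerB":
        return TOY_REFERENCE_IDS["MerB"], MERB_TEMPLATE
    raise KeyError(name)


def _remap_position(p: SignaturePosition, coord_map: dict[int, int]) -> SignaturePosition:
    from dataclasses import replace

    return replace(p, ref_position=coord_map[p.ref_position])


def toy_profile(name: str) -> SignatureProfile:
    """Built-in profile remapped onto the toy template coordinates."""
    base = builtin_profile(name)
    coord_map = MERA_COORD_MAP if name == "MerA" else MERB_COORD_MAP
    return SignatureProfile(
        name=base.name,
        reference_id=TOY_REFERENCE_IDS[name],
        positions=tuple(_remap_position(p, coord_map) for p in base.positions),
        paired_positions=tuple(
            (coord_map[a], coord_map[b]) for a, b in base.paired_positions
        ),
        domain_conditional={
            domain: {
                coord_map[n]: _remap_position(p, coord_map)
                for n, p in overrides.items()
            }
            for domain, overrides in base.domain_conditional.items()
        },
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_taxa() -> dict[tuple[str, str, str | None], int]:
    # A two-domain, multi-phylum cohort proportioned roughly like the
    # surveyed collection (Proteobacteria-heavy Bacteria, two archaeal
    # phyla), 500 genomes total.
    return {
        ("Bacteria", "Proteobacteria", "Gammaproteobacteria"): 150,
        ("Bacteria", "Proteobacteria", "Alphaproteobacteria"): 50,
        ("Bacteria", "Proteobacteria", "Betaproteobacteria"): 30,
        ("Bacteria", "Firmicutes", None): 100,
        ("Bacteria", "Actinobacteria", None): 80,
        ("Bacteria", "Bacteroidetes", None): 30,
        ("Archaea", "Crenarchaeota", None): 30,
        ("Archaea", "Euryarchaeota", None): 30,
    }


def _default_copy_dist() -> dict[int, float]:
    # Multi-copy tail as in the surveyed bacterial genomes (most genomes
    # single-copy; up to 8 copies).
    return {1: 0.88, 2: 0.10, 3: 0.015, 4: 0.004, 8: 0.001}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a synthetic cohort.

    Probabilities default to the rates of the real survey: marker
    prevalences, conditional co-occurrence, copy-number tail, and
    variant fractions. ``indel_rate`` injects per-sequence insertion
    columns / gap deletions into the constructed alignments;
    ``monophyly_violation`` is the per-tip probability of being placed
    outside its taxon's subtree.
    """

    seed: int = 0
    n_genomes: dict[tuple[str, str, str | None], int] = field(
        default_factory=_default_taxa
    )
    p_merA: float = 0.078
    p_merB_given_merA: float = 0.135
    p_merB_given_no_merA: float = 0.012
    copy_dist_A: dict[int, float] = field(default_factory=_default_copy_dist)
    copy_dist_B: dict[int, float] = field(default_factory=_default_copy_dist)
    frac_605_variant: float = 0.006
    frac_99ser: float = 0.007
    frac_117alt: float = 0.29
    frac_reject: float = 0.0
    frac_ambiguous: float = 0.0
    background_sub_rate: float = 0.02
    indel_rate: float = 0.0
    monophyly_violation: float = 0.0
    deposit_probs: dict[str, float] = field(
        default_factory=lambda: {"isolate": 0.84, "MAG": 0.115, "SCG": 0.045}
    )

    def validate(self) -> None:
        for name, p in [
            ("p_merA", self.p_merA),
            ("p_merB_given_merA", self.p_merB_given_merA),
            ("p_merB_given_no_merA", self.p_merB_given_no_merA),
            ("indel_rate", self.indel_rate),
            ("monophyly_violation", self.monophyly_violation),
            ("background_sub_rate", self.background_sub_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        for which, dist in [("A", self.copy_dist_A), ("B", self.copy_dist_B)]:
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"copy_dist_{which} does not sum to 1")
            if any(k < 1 for k in dist):
                raise ValueError(f"copy_dist_{which} has non-positive copies")
        fa = self.frac_605_variant + self.frac_reject + self.frac_ambiguous
        fb = (
            self.frac_99ser
            + self.frac_117alt
            + self.frac_reject
            + self.frac_ambiguous
        )
        if fa > 1.0 or fb > 1.0:
            raise ValueError("variant fractions exceed 1")
        if any(n < 0 for n in self.n_genomes.values()):
            raise ValueError("negative genome count")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a simulated cohort."""

    protein_status: dict[str, str]
    protein_labels: dict[str, frozenset[str]]
    merA_counts: dict[str, int]
    merB_counts: dict[str, int]
    merB_like_counts: dict[str, dict[str, int]]
    genome_codist: dict[str, str]
    clade_traits: dict[str, tuple[int, int]]
    clade_tips: dict[str, tuple[str, ...]]


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    genome_meta: pd.DataFrame
    protein_meta: pd.DataFrame
    records_A: list[HomologRecord]
    records_B: list[HomologRecord]
    aln_A: Alignment
    aln_B: Alignment
    newick: str
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

_MERA_CLASSES = ("canonical", "605-variant", "reject", "ambiguous")
_MERB_CLASSES = ("canonical", "99Ser", "117alt", "reject", "ambiguous")


def _sample_class(rng, classes, probs) -> str:
    return classes[rng.choice(len(classes), p=probs)]


def _mutate(seq: list[str], pos1: int, rng, forbid: str) -> None:
    choices = [aa for aa in _ALPHABET if aa != forbid]
    seq[pos1 - 1] = choices[rng.integers(len(choices))]


def _build_sequence(
    marker: str, domain: str, cls: str, rng, sub_rate: float
) -> str:
    """Plant exactly the designated signature state; mutate background."""
    if marker == "MerA":
        seq = list(MERA_TEMPLATE)
        cmap = MERA_COORD_MAP
        if domain == "Archaea":
            seq[cmap[605] - 1] = "F"  # archaeal canonical state
        if cls == "605-variant":
            seq[cmap[605] - 1] = "Y" if domain == "Archaea" else "F"
        elif cls == "reject":
            _mutate(seq, cmap[207], rng, forbid="C")
        elif cls == "ambiguous":
            seq[cmap[264] - 1] = "X"
        signature_cols = set(cmap.values())
    else:
        seq = list(MERB_TEMPLATE)
        cmap = MERB_COORD_MAP
        if cls == "99Ser":
            seq[cmap[99] - 1] = "S"
        elif cls == "117alt":
            choices = [aa for aa in "ADEGHKLNQRSTV"]
            seq[cmap[117] - 1] = choices[rng.integers(len(choices))]
        elif cls == "reject":
            _mutate(seq, cmap[96], rng, forbid="C")
        elif cls == "ambiguous":
            seq[cmap[96] - 1] = "X"
        signature_cols = set(cmap.values())
    if sub_rate > 0:
        for i in range(len(seq)):
            if (i + 1) not in signature_cols and rng.random() < sub_rate:
                seq[i] = _ALPHABET[rng.integers(len(_ALPHABET))]
    return "".join(seq)


def _class_status(marker: str, cls: str) -> tuple[str, frozenset[str]]:
    if cls == "canonical":
        return "canonical", frozenset()
    if cls in ("reject", "ambiguous"):
        return cls, frozenset()
    return "variant", frozenset({cls})


def _build_alignment(
    reference_id: str,
    template: str,
    rows: list[tuple[str, str]],
    signature_cols: set[int],
    indel_rate: float,
    rng,
) -> tuple[Alignment, list[tuple[str, str]]]:
    """Template-anchored alignment with optional per-row indels.

    Returns the alignment (reference row first) and the possibly
    indel-modified ungapped sequences per row. Insertions get a private
    column (gap in all other rows); deletions put a gap at a non-signature
    template column of the affected row.
    """
    n_cols = len(template)
    insertions: list[tuple[int, str, str]] = []  # (after_col0, row_id, residues)
    deletions: dict[str, set[int]] = {}
    safe_cols = [c for c in range(n_cols) if (c + 1) not in signature_cols]
    for row_id, _ in rows:
        if indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                after = int(rng.choice(safe_cols))
                length = int(rng.integers(1, 4))
                residues = "".join(
                    _ALPHABET[rng.integers(len(_ALPHABET))] for _ in range(length)
                )
                insertions.append((after, row_id, residues))
            else:
                deletions[row_id] = {int(rng.choice(safe_cols))}

    # Column layout: template column c, then any insertion columns after c.
    ins_after: dict[int, list[tuple[str, str]]] = {}
    for after, row_id, residues in insertions:
        ins_after.setdefault(after, []).append((row_id, residues))

    def gapped_row(row_id: str, seq: str) -> str:
        dele = deletions.get(row_id, set())
        out = []
        for c in range(n_cols):
            out.append("-" if c in dele else seq[c])
            for owner, residues in ins_after.get(c, []):
                out.append(residues if owner == row_id else "-" * len(residues))
        return "".join(out)

    aligned = [(reference_id, gapped_row("__ref__", template))]
    ungapped: list[tuple[str, str]] = []
    for row_id, seq in rows:
        g = gapped_row(row_id, seq)
        aligned.append((row_id, g))
        ungapped.append((row_id, g.replace("-", "")))
    return Alignment(tuple(aligned)), ungapped


def _random_subtree(tips: list[str], rng) -> str:
    """Random sequential-join binary subtree over the given tip labels."""
    nodes = [f"{t}:{rng.uniform(0.01, 0.3):.4f}" for t in tips]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.uniform(0.01, 0.3):.4f}")
    return nodes[0]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort with its planted truth."""
    config.validate()
    rng_genomes = np.random.default_rng([config.seed, 1])
    rng_seq = np.random.default_rng([config.seed, 2])
    rng_aln = np.random.default_rng([config.seed, 3])
    rng_tree = np.random.default_rng([config.seed, 4])

    probs_a = np.array(
        [
            1.0 - config.frac_605_variant - config.frac_reject - config.frac_ambiguous,
            config.frac_605_variant,
            config.frac_reject,
            config.frac_ambiguous,
        ]
    )
    probs_b = np.array(
        [
            1.0
            - config.frac_99ser
            - config.frac_117alt
            - config.frac_reject
            - config.frac_ambiguous,
            config.frac_99ser,
            config.frac_117alt,
            config.frac_reject,
            config.frac_ambiguous,
        ]
    )
    copies_a = sorted(config.copy_dist_A)
    pa = np.array([config.copy_dist_A[c] for c in copies_a])
    copies_b = sorted(config.copy_dist_B)
    pb = np.array([config.copy_dist_B[c] for c in copies_b])
    deposits = list(config.deposit_probs)
    pdep = np.array([config.deposit_probs[d] for d in deposits])
    pdep = pdep / pdep.sum()

    genome_rows = []
    protein_rows = []
    records_A: list[HomologRecord] = []
    records_B: list[HomologRecord] = []
    truth = PlantedTruth({}, {}, {}, {}, {}, {}, {}, {})
    g = 0
    for (domain, phylum, class_), n in sorted(config.n_genomes.items()):
        for _ in range(n):
            g += 1
            gid = f"G{g:05d}"
            deposit = deposits[rng_genomes.choice(len(deposits), p=pdep)]
            genome_rows.append(
                {
                    "genome_id": gid,
                    "domain": domain,
                    "phylum": phylum,
                    "class": class_ or "",
                    "deposit_type": deposit,
                }
            )
            has_a = rng_genomes.random() < config.p_merA
            p_b = (
                config.p_merB_given_merA if has_a else config.p_merB_given_no_merA
            )
            has_b = rng_genomes.random() < p_b

            n_a_retained = 0
            n_b_canonical = 0
            b_like: Counter[str] = Counter()
            if has_a:
                n_copies = copies_a[rng_genomes.choice(len(copies_a), p=pa)]
                for c in range(n_copies):
                    pid = f"{gid}_A{c + 1}"
                    cls = _sample_class(rng_genomes, _MERA_CLASSES, probs_a)
                    seq = _build_sequence(
                        "MerA", domain, cls, rng_seq, config.background_sub_rate
                    )
                    status, labels = _class_status("MerA", cls)
                    truth.protein_status[pid] = status
                    truth.protein_labels[pid] = labels
                    if status in ("canonical", "variant"):
                        n_a_retained += 1
                    records_A.append(
                        HomologRecord(pid, gid, domain, phylum, class_, deposit, seq)
                    )
                    protein_rows.append(
                        {"protein_id": pid, "genome_id": gid, "marker": "MerA"}
                    )
            if has_b:
                n_copies = copies_b[rng_genomes.choice(len(copies_b), p=pb)]
                for c in range(n_copies):
                    pid = f"{gid}_B{c + 1}"
                    cls = _sample_class(rng_genomes, _MERB_CLASSES, probs_b)
                    seq = _build_sequence(
                        "MerB", domain, cls, rng_seq, config.background_sub_rate
                    )
                    status, labels = _class_status("MerB", cls)
                    truth.protein_status[pid] = status
                    truth.protein_labels[pid] = labels
                    if status == "canonical":
                        n_b_canonical += 1
                    elif status == "variant":
                        for label in labels:
                            b_like[label] += 1
                    records_B.append(
                        HomologRecord(pid, gid, domain, phylum, class_, deposit, seq)
                    )
                    protein_rows.append(
                        {"protein_id": pid, "genome_id": gid, "marker": "MerB"}
                    )
            truth.merA_counts[gid] = n_a_retained
            truth.merB_counts[gid] = n_b_canonical
            truth.merB_like_counts[gid] = dict(b_like)
            if n_a_retained > 0 and n_b_canonical > 0:
                truth.genome_codist[gid] = "both"
            elif n_a_retained > 0:
                truth.genome_codist[gid] = "A-only"
            elif n_b_canonical > 0:
                truth.genome_codist[gid] = "B-only"
            else:
                truth.genome_codist[gid] = "neither"

    aln_A, ungapped_a = _build_alignment(
        TOY_REFERENCE_IDS["MerA"],
        MERA_TEMPLATE,
        [(r.protein_id, r.sequence) for r in records_A],
        set(MERA_COORD_MAP.values()),
        config.indel_rate,
        rng_aln,
    )
    aln_B, ungapped_b = _build_alignment(
        TOY_REFERENCE_IDS["MerB"],
        MERB_TEMPLATE,
        [(r.protein_id, r.sequence) for r in records_B],
        set(MERB_COORD_MAP.values()),
        config.indel_rate,
        rng_aln,
    )
    # Indels may have edited the raw sequences; keep records consistent.
    seq_a = dict(ungapped_a)
    records_A = [
        HomologRecord(
            r.protein_id, r.genome_id, r.domain, r.phylum, r.class_,
            r.deposit_type, seq_a[r.protein_id],
        )
        for r in records_A
    ]
    seq_b = dict(ungapped_b)
    records_B = [
        HomologRecord(
            r.protein_id, r.genome_id, r.domain, r.phylum, r.class_,
            r.deposit_type, seq_b[r.protein_id],
        )
        for r in records_B
    ]

    # Tree over retained reductase homologs, clustered by rank label.
    by_record = {r.protein_id: r for r in records_A}
    tip_group: dict[str, str] = {}
    labels = []
    for r in records_A:
        if truth.protein_status[r.protein_id] not in ("canonical", "variant"):
            continue
        label = (
            r.class_
            if r.phylum == "Proteobacteria" and r.class_
            else r.phylum
        )
        tip_group[r.protein_id] = label
        if label not in labels:
            labels.append(label)
    if config.monophyly_violation > 0 and len(labels) > 1:
        for pid in sorted(tip_group):
            if rng_tree.random() < config.monophyly_violation:
                others = [l for l in labels if l != tip_group[pid]]
                tip_group[pid] = others[int(rng_tree.integers(len(others)))]

    subtrees = []
    truth.clade_tips = {}
    truth.clade_traits = {}
    for label in labels:
        tips = sorted(p for p, l in tip_group.items() if l == label)
        if not tips:
            continue
        subtrees.append(_random_subtree(tips, rng_tree))
        truth.clade_tips[label] = tuple(tips)
        genomes = {by_record[p].genome_id for p in tips}
        truth.clade_traits[label] = (
            sum(1 for gg in genomes if truth.merB_counts[gg] > 0),
            sum(
                1
                for gg in genomes
                if sum(truth.merB_like_counts[gg].values()) > 0
            ),
        )
    if len(subtrees) == 0:
        newick = ";"
    elif len(subtrees) == 1:
        newick = f"({subtrees[0]});"
    else:
        newick = "(" + ",".join(subtrees) + ");"

    return SimulatedCohort(
        config=config,
        genome_meta=pd.DataFrame(genome_rows),
        protein_meta=pd.DataFrame(protein_rows),
        records_A=records_A,
        records_B=records_B,
        aln_A=aln_A,
        aln_B=aln_B,
        newick=newick,
        truth=truth,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Write cohort files (FASTA, aligned FASTA, TSVs, Newick) to a directory."""
    import pathlib

    from .alnmap import write_alignment

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def fasta(records, name):
        p = out / name
        with open(p, "w", encoding="utf-8") as fh:
            for r in records:
                fh.write(f">{r.protein_id}\n{r.sequence}\n")
        return str(p)

    paths["seqs_A"] = fasta(cohort.records_A, "merA.faa")
    paths["seqs_B"] = fasta(cohort.records_B, "merB.faa")
    for name, aln in [("aln_A", cohort.aln_A), ("aln_B", cohort.aln_B)]:
        p = out / f"{name[-1].lower()}_aligned.afa"
        write_alignment(aln, str(p))
        paths[name] = str(p)
    meta_cols = [
        "protein_id", "genome_id", "marker",
        "domain", "phylum", "class", "deposit_type",
    ]
    proteins = cohort.protein_meta.merge(cohort.genome_meta, on="genome_id")
    p = out / "proteins.tsv"
    proteins[meta_cols].to_csv(p, sep="\t", index=False)
    paths["protein_meta"] = str(p)
    p = out / "genomes.tsv"
    cohort.genome_meta.to_csv(p, sep="\t", index=False)
    paths["genome_meta"] = str(p)
    p = out / "merA_tree.nwk"
    p.write_text(cohort.newick + "\n", encoding="utf-8")
    paths["tree"] = str(p)
    return paths


# ---------------------------------------------------------------------------
# Fixture tables: the published marginal structure, as inventories
# ---------------------------------------------------------------------------

# 2020 columns of the phylum-level table: (taxon, class, MerA genomes,
# MerB genomes) per domain group. Proteobacteria appear as class rows.
_T1_ARCHAEA = [
    ("Candidatus Bathyarchaeota", None, 1, 0),
    ("Candidatus Diapherotrites", None, 1, 0),
    ("Candidatus Geoarchaeota", None, 4, 0),
    ("Candidatus Geothermarchaeota", None, 2, 0),
    ("Candidatus Heimdallarchaeota", None, 1, 3),
    ("Candidatus Micrarchaeota", None, 22, 0),
    ("Candidatus Odinarchaeota", None, 1, 0),
    ("Candidatus Parvarchaeota", None, 10, 0),
    ("Crenarchaeota", None, 139, 0),
    ("Euryarchaeota", None, 65, 8),
    ("Nanoarchaeota", None, 1, 0),
    ("Thaumarchaeota", None, 10, 0),
    ("unclassified", None, 14, 0),
]

_T1_BACTERIA = [
    ("Acidobacteria", None, 7, 0),
    ("Actinobacteria", None, 958, 468),
    ("Aquificae", None, 7, 0),
    ("Armatimonadetes", None, 1, 0),
    ("Bacteroidetes", None, 131, 3),
    ("Balneolaeota", None, 4, 0),
    ("Candidate division GAL15", None, 1, 0),
    ("Candidate division NC10", None, 0, 1),
    ("Candidate division Zixibacteria", None, 0, 1),
    ("Candidatus Atribacteria", None, 1, 0),
    ("Candidatus Azambacteria", None, 1, 0),
    ("Candidatus Bipolaricaulota", None, 1, 0),
    ("Candidatus Blackburnbacteria", None, 1, 0),
    ("Candidatus Daviesbacteria", None, 7, 0),
    ("Candidatus Giovannonibacteria", None, 10, 0),
    ("Candidatus Gottesmanbacteria", None, 1, 0),
    ("Candidatus Kaiserbacteria", None, 1, 0),
    ("Candidatus Kryptonia", None, 1, 0),
    ("Candidatus Microgenomates", None, 2, 0),
    ("Candidatus Pacebacteria", None, 1, 0),
    ("Candidatus Parcubacteria", None, 2, 0),
    ("Candidatus Peregrinibacteria", None, 5, 0),
    ("Candidatus Roizmanbacteria", None, 2, 0),
    ("Candidatus Rokubacteria", None, 2, 1),
    ("Candidatus Sumerlaeota", None, 1, 0),
    ("Chlamydiae", None, 1, 1),
    ("Chloroflexi", None, 32, 7),
    ("Cyanobacteria", None, 1, 0),
    ("Deferribacteres", None, 2, 0),
    ("Deinococcus-Thermus", None, 14, 2),
    ("Firmicutes", None, 960, 797),
    ("Fusobacteria", None, 0, 1),
    ("Gemmatimonadetes", None, 0, 1),
    ("Ignavibacteriae", None, 15, 0),
    ("Nitrospirae", None, 18, 6),
    ("Planctomycetes", None, 1, 0),
    ("Proteobacteria", "Alphaproteobacteria", 668, 84),
    ("Proteobacteria", "Betaproteobacteria", 412, 72),
    ("Proteobacteria", "Gammaproteobacteria", 2869, 298),
    ("Proteobacteria", "Deltaproteobacteria", 37, 10),
    ("Proteobacteria", "Epsilonproteobacteria", 1, 0),
    ("Proteobacteria", "Zetaproteobacteria", 27, 4),
    ("Proteobacteria", "Acidithiobacillia", 25, 6),
    ("Proteobacteria", "Hydrogenophilalia", 2, 1),
    ("Proteobacteria", "Oligoflexia", 6, 2),
    ("Proteobacteria", "Candidatus Muproteobacteria", 1, 0),
    ("Proteobacteria", "Unclassified", 2, 1),
    ("Rhodothermaeota", None, 1, 0),
    ("Spirochaetes", None, 3, 5),
    ("Synergistetes", None, 0, 3),
    ("Tenericutes", None, 11, 0),
    ("Verrucomicrobia", None, 7, 0),
    ("unclassified", None, 10, 3),
]

_T1_PLASMID = [
    ("Proteobacteria", "Alphaproteobacteria", 1, 1),
    ("Proteobacteria", "Betaproteobacteria", 1, 0),
    ("Proteobacteria", "Gammaproteobacteria", 25, 4),
    ("Proteobacteria", "Unclassified", 2, 1),
]

# Copies-per-genome histograms per domain group.
_T2_MERA = {
    "Archaea": {1: 270, 3: 1},
    "Bacteria": {1: 5497, 2: 668, 3: 74, 4: 29, 5: 2, 6: 3, 8: 1},
    "Plasmid:Bacteria": {1: 28, 2: 1},
}
_T2_MERB = {
    "Archaea": {1: 11},
    "Bacteria": {1: 1685, 2: 64, 3: 15, 4: 13, 8: 1},
    "Plasmid:Bacteria": {1: 5, 2: 1},
}

# Genomes encoding both markers, per domain group (from the published
# co-distribution: 889 total = 6 archaeal + 878 bacterial + 5 plasmid).
_BOTH = {"Archaea": 6, "Bacteria": 878, "Plasmid:Bacteria": 5}

#: Genomes queried per domain group (partition denominators).
FIXTURE_TOTALS = {"Archaea": 1959, "Bacteria": 80925, "Plasmid:Bacteria": 1148}

_T1 = {"Archaea": _T1_ARCHAEA, "Bacteria": _T1_BACTERIA, "Plasmid:Bacteria": _T1_PLASMID}


def fixture_tables() -> tuple[list[GenomeInventory], dict[str, int]]:
    """Genome inventories whose marginals equal the published tables.

    Counts only — no sequences. Per taxon row, genomes encoding both
    markers are assigned greedily in table order until the published
    per-domain overlap is reached; copy numbers are then dealt to
    marker-positive genomes per the published per-domain histograms
    (largest copy numbers first). Returns the inventory list and the
    per-domain totals of genomes queried (for partition denominators).
    """
    inventories: list[GenomeInventory] = []
    g = 0
    for domain, rows in _T1.items():
        remaining_both = _BOTH[domain]
        genomes_a: list[int] = []  # indices into inventories, merA-positive
        genomes_b: list[int] = []
        for taxon, class_, n_a, n_b in rows:
            both = min(n_a, n_b, remaining_both)
            remaining_both -= both
            phylum = taxon if class_ is None else "Proteobacteria"
            for kind, count in [("both", both), ("A", n_a - both), ("B", n_b - both)]:
                for _ in range(count):
                    g += 1
                    idx = len(inventories)
                    inventories.append(
                        GenomeInventory(
                            genome_id=f"FX{g:05d}",
                            domain=domain,
                            phylum=phylum,
                            class_=class_,
                            merA_count=1 if kind in ("both", "A") else 0,
                            merB_count=1 if kind in ("both", "B") else 0,
                        )
                    )
                    if kind in ("both", "A"):
                        genomes_a.append(idx)
                    if kind in ("both", "B"):
                        genomes_b.append(idx)
        if remaining_both:
            raise AssertionError(
                f"{domain}: could not place {remaining_both} dual-marker genomes"
            )
        # Deal copy numbers, largest first, to marker-positive genomes.
        for hist, positive, attr in [
            (_T2_MERA[domain], genomes_a, "merA_count"),
            (_T2_MERB[domain], genomes_b, "merB_count"),
        ]:
            if sum(hist.values()) != len(positive):
                raise AssertionError(
                    f"{domain} {attr}: histogram total {sum(hist.values())} != "
                    f"{len(positive)} marker-positive genomes"
                )
            pos_iter = iter(positive)
            for copies in sorted(hist, reverse=True):
                for _ in range(hist[copies]):
                    idx = next(pos_iter)
                    inv = inventories[idx]
                    kwargs = {
                        "genome_id": inv.genome_id,
                        "domain": inv.domain,
                        "phylum": inv.phylum,
                        "class_": inv.class_,
                        "deposit_type": inv.deposit_type,
                        "merA_count": inv.merA_count,
                        "merB_count": inv.merB_count,
                        "merB_like_counts": inv.merB_like_counts,
                    }
                    kwargs[attr] = copies
                    inventories[idx] = GenomeInventory(**kwargs)
    return inventories, dict(FIXTURE_TOTALS)
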