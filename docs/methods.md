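# Methods

This note documents the models, conventions, and design decisions
behind each `merscreen` stage, and what the synthetic tests do and do
not demonstrate about real survey data.

## Signature profiles and screening

A profile is a set of reference-numbered residue requirements. The
coordinates are 1-based positions in the *ungapped* reference protein
(the literature convention: MerA numbered on *B. cereus* RC607, MerB on
plasmid R831b); the profile itself is alignment-independent, and all
coordinate work is delegated to the alignment map. Internally, columns
are 0-based; every user-facing report prints reference numbering only.
`'.'` gaps are normalised to `'-'` and residues are upper-cased, to
tolerate common aligned-FASTA dialects.

Position rules come in three forms:

* **essential, reject-on-other** (MerA 207/212/264/628/629; MerB
  96/159): any standard residue other than the canonical one, a gap, or
  a missing position invalidates the homolog call;
* **domain-conditional** (MerA 605): canonical Y for Bacteria (records
  labelled `Plasmid:Bacteria` evaluate under bacterial rules) and F for
  Archaea, with the swapped residue retained as the `605-variant` class
  and any third residue rejecting. Records with unknown domain accept
  either residue and emit a warning, since a domain-conditional rule
  cannot be applied blind;
* **variant-eligible** (MerB 99 and 117): D99 with S defining `99Ser`;
  C117 with a wildcard rule mapping any substitution to `117alt`. A
  residue at 99 that is neither D nor S is flagged `unclassified-99` and
  retained with a warning rather than rejected — the survey literature
  defines only the 99Ser class, and inventing a reject rule silently
  would bias counts.

`X`, and any non-standard character, at a signature position yields
"ambiguous", never a reject: sequencing artifacts should not masquerade
as biology. A gap at a variant-eligible position is likewise ambiguous,
because the named variant classes are defined by observed residues, not
absences. The vicinal pair 628/629 fails jointly: if either member
fails, both are reported failed.

Verdict precedence is **reject > ambiguous > variant > canonical**. The
one non-obvious case: a record carrying a variant label at one position
and an unreadable residue at another is reported *ambiguous* (with the
label retained on the verdict), since the full signature could not be
certified. Candidates entirely missing the C-terminal region screen as
rejects with a distinct `missing-position` / `gap-at-essential` reason
code, so users can audit truncated ORFs separately.

Profiles round-trip through a flat TOML config (`name`, `reference_id`,
optional `paired_positions`, one `[[position]]` block per position with
`ref_position`, `canonical`, `reject_on_other`, `essential`, and
nested `[[position.variant]]` rules where `residues = "*"` is the
wildcard; per-domain overrides under `[domain."<name>"]`). The built-in
profiles serialize to exactly this format, which doubles as the schema
reference.

## Alignment mapping and trimming

`build_map` numbers the non-gap columns of the reference row 1..L and
is, by construction, a bijection between reference positions and those
columns. `trim_nterminal` drops all columns left of a chosen reference
position — used to remove the N-terminal metal-binding (NmerA) region
before exporting tree-ready alignment blocks. The cut point is an
explicit required parameter (a sensible choice is the profile's
smallest signature position minus a margin); no published boundary is
assumed. Screening operates on the untrimmed alignment; trimming is
only applied for tree-bound exports.

## Inventory and counting conventions

A genome's MerA complement counts canonical homologs **plus retained
variants** (the 605-variant class). Its MerB complement counts
canonical homologs only; MerB-like classes (99Ser, 117alt) are tallied
separately and excluded from the co-distribution partition by default,
matching the source counting scheme that distinguishes "MerB" from
"MerB-like" throughout. `include_merb_like` switches the alternative
convention on everywhere it matters.

Roll-ups key rows by phylum, except Proteobacteria which is broken out
by class. `Plasmid:Bacteria` is a domain group of its own. Taxonomy
labels are taken verbatim (no synonymy resolution); `unclassified` is a
legitimate literal label.

Percentages are rounded half-away-from-zero (printed survey values mix
one and two decimals — 13.8%, 7.75%, 0.6% — so the decimal count is
configurable per report column; default 1).

## Pairwise identity

Duplicate analysis computes percent identity over an end-to-end
Needleman–Wunsch alignment with identity-oriented scoring (match +1,
mismatch 0, linear gap −1): the quantity of interest is percent
identity, not substitution-matrix similarity. Traceback ties break
deterministically diagonal > up > left. The denominator is the full
alignment length including end gaps; gap-aligned columns are never
identical. An alternative mode (`aligned_row_identity`) computes
identity on rows of a supplied multiple alignment instead, dropping
columns gapped in both rows — both conventions are provided because the
convention used by the original web tooling in this field is not
documented. Identity is symmetric with self-identity exactly 100, but it
is **not** a metric: no transitivity is assumed anywhere.

The duplication flag threshold defaults to 85% — low enough to retain
clearly duplicated pairs (identical copies; near-identical pairs around
89%) and high enough to exclude distant within-genome paralogs.

## Tree collapsing and trait annotation

Collapsing uses rooted monophyly after optional outgroup rooting (the
reference figures in this field are outgroup-rooted, e.g. on
dihydrolipoamide dehydrogenases). A maximal clade whose tips all share
one rank label (phylum; class for Proteobacteria) and contain no
outgroup tip is replaced by a pseudo-tip; clades mixing labels are never
collapsed automatically. K identifiers are assigned in preorder
(root-to-tip, left-to-right) traversal order — they are arbitrary
stable identifiers, not meant to match any published figure's numbering,
and may renumber if child order is rotated (clade membership does not).
Singleton tips keep their own ids and get no K identifier. "Mixed"
lineages are supported only as explicitly supplied monophyletic tip
sets, because published mixed groups are figure-level judgments, not an
algorithmic rank rule. Internal-node support values are parsed and
carried through but play no role in collapsing.

Trait annotation counts, per collapsed clade, the *distinct* member
genomes with a canonical MerB and, separately, with any MerB-like
variant — a genome contributing several tips counts once.

## Synthetic cohorts and what they show

The generator emulates the statistical structure of a large genome
survey: marker prevalence (~7.8% of genomes MerA-positive by default),
conditional MerB co-occurrence (~13.5% of MerA-positive genomes), a
single-copy-dominated copy-number tail reaching 8 copies, two domains
with multiple phyla and Proteobacteria split by class, small variant
fractions, and a taxonomy-clustered tree with a configurable
monophyly-violation rate. Sequences are built from bundled toy
templates (~120 residues for the reductase marker, ~80 for the lyase)
carrying the signature positions at scaled coordinates
(207/212/264/605/628/629 → 31/36/51/101/111/112; 96/99/117/159 →
21/24/41/61). Screening logic is coordinate-relative, so toy length
loses nothing while keeping tests fast. Variants mutate exactly their
designated position; rejects mutate an essential position; ambiguous
copies carry an X. Alignments are produced by construction
(template-anchored columns plus injected per-sequence insertion columns
and gap deletions) — never by running an aligner.

What passing planted-truth tests show: the screening, inventory, and
annotation logic is exact on inputs whose alignments are correct and
whose variation is confined to the modelled classes. What they do not
show: robustness to misalignment, to real substitution processes, to
homology-search noise, or to taxonomy misassignment — none of which the
generator models. Pseudorandom streams are partitioned per output kind,
so adding one output never perturbs the others under the same seed.

Separately, `fixture_tables()` emits count-only genome inventories
whose marginals equal the published phylum-level table, the per-domain
copy-number histograms, and the co-distribution partition of an 84,032-
genome survey. Dual-marker genomes are assigned greedily in table order
until each domain's published overlap (6 archaeal, 878 bacterial, 5
plasmid) is reached; copy numbers are then dealt largest-first to
marker-positive genomes. Any self-consistent assignment reproduces the
same marginals; the greedy one is deterministic.

## Problem sizes and numerical checks

The test suite runs planted-truth recovery on 500-genome cohorts (both
at survey rates and at a denser configuration that exercises every
verdict class), checks the aligner against exhaustive enumeration of
all global alignments for every sequence pair up to length 3 over a
4-letter alphabet plus a seeded sample of longer pairs (≤ 6), and
checks the monophyly test against exhaustive clade enumeration on 1000
random trees of up to 12 tips. The whole suite completes in a few
seconds on one CPU.

## Known limitations

* No alignment or tree inference: the package consumes alignments and
  Newick trees produced elsewhere, by design.
* Homology search (candidate retrieval) is out of scope; candidates are
  assumed gathered upstream.
* Published survey totals are not all mutually consistent (e.g. a text
  multi-copy total that differs from the corresponding table's row
  sums); the fixtures follow the structured tables, and the package
  computes self-consistent tables rather than reproducing both.
* Taxonomic labels are not resolved against any nomenclature service.
* The identity module intentionally offers no local alignment or
  similarity (BLOSUM) percentages.
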