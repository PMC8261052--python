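# merscreen

Signature-residue screening, inventory, and phylogeny annotation of
mercury-detoxification protein homologs.

## The problem

Prokaryotes detoxify mercury through the *mer* operon: mercuric
reductase (**MerA**) reduces Hg(II) to volatile Hg(0), and
organomercurial lyase (**MerB**) cleaves the C–Hg bond of compounds such
as methylmercury. Comparative surveys of MerA/MerB across thousands of
isolate genomes, metagenome-assembled genomes (MAGs), and single-cell
genomes hinge on one curation step: a BLAST hit is only called a
functional homolog if it carries the experimentally established
signature residues, read off at reference-numbered positions of a
multiple alignment —

* **MerA** (numbering of *Bacillus cereus* RC607 MerA): the redox-active
  pair C207/C212, the conserved Y264, position 605 (Y in Bacteria, F in
  Archaea; the swapped residue defines the retained *605-variant*
  class), and the C-terminal vicinal pair C628/C629;
* **MerB** (numbering of plasmid R831b MerB): C96, D99, C117, C159, with
  the MerB-like classes *99Ser* (S replacing D99) and *117alt* (any
  substitution of C117).

`merscreen` mechanizes that inspection and everything downstream of it:
per-genome copy numbers, phylum/class roll-ups, the MerA/MerB
co-distribution partition (A-only / B-only / both / neither),
within-genome percent identity of duplicate copies (Needleman–Wunsch,
identity = 100·identical/aligned columns), and taxonomy-constrained
collapsing of a MerA phylogeny with MerB presence boxes per collapsed
clade. A seeded synthetic-data module generates cohorts with planted
ground truth so the whole pipeline is testable offline.

It is intended for microbial ecologists and molecular evolution groups
running or auditing *mer* surveys, and for anyone who needs a tested
reference implementation of reference-numbered signature screening.

## Worked example

Screen a bacterial MerB candidate whose position 99 carries serine:

```python
from merscreen import Alignment, HomologRecord, build_map, screen_sequence
from merscreen.sigdb import builtin_profile

profile = builtin_profile("MerB")
ref = query = ...  # rows of a reference-anchored alignment
aln = Alignment(((profile.reference_id, ref), ("IMG_000123", query)))
amap = build_map(aln, profile.reference_id)
verdict = screen_sequence(
    HomologRecord("IMG_000123", "genome_42", "Bacteria"), aln, amap, profile
)
print(verdict.status, sorted(verdict.variant_labels))
for r in verdict.per_position_report:
    print(r.ref_position, r.observed, r.outcome)
```

prints

```
variant ['99Ser']
96 C canonical
99 S variant:99Ser
117 C canonical
159 C canonical
```

i.e. the candidate is not a canonical MerB but a retained MerB-like
*99Ser* variant — every essential cysteine holds, and the one deviation
is the named serine substitution. Tabulating the bundled count fixtures
(genome inventories whose marginals encode a published 84,032-genome
survey) gives the co-distribution partition:

```python
from merscreen import codistribution_partition, fixture_tables

inventories, totals = fixture_tables()
print(codistribution_partition(inventories, total_genomes=sum(totals.values())))
```

```
{'A-only': 5685, 'B-only': 906, 'both': 889, 'neither': 76552}
```

5685 genomes encode MerA without MerB, 906 encode MerB without any MerA
(slightly over half of all MerB-encoding genomes — the observation that
motivates looking for MerA-independent Hg(II) detoxification), and 889
encode both.

## Command line

Each pipeline stage is also a subcommand of the `merscreen` console
script: `screen`, `tabulate`, `identity`, `collapse-tree`, `simulate`,
`fixtures`, and `run-all` (screen A → screen B → inventory → identity →
tree collapse, with a checksum manifest per stage). For example:

```
merscreen simulate --seed 7 --out sim/
merscreen run-all --data sim/ --out run/
```

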