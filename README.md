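# mitocharacter

Characterization analytics for annotated circular mitochondrial genomes,
aimed at the descriptive half of a mitogenome paper: per-region nucleotide
composition and strand skews, codon usage (RSCU), start/stop-codon
classification including polyadenylation-completed incomplete stops,
circular junction arithmetic (overlaps and intergenic spacers), avian
control-region gene-order classification, and 13-PCG supermatrix
preparation for downstream phylogenetics.

It is written for people who already *have* an annotation (GenBank record or
a coordinate table) — typically of a bird or other vertebrate mitogenome —
and want the derived numbers recomputed reproducibly instead of by
spreadsheet: annotation tables in the literature are not always internally
consistent, so every derived column (gene length, intergenic length,
content, skew, RSCU) is recomputed from coordinates and sequence, and
discrepancies against the printed values are flagged rather than inherited.

## The quantities

For base counts (or percentages) A, C, G, T of a region:

- AT content = A + T, GC content = G + C
- AT-skew = (A − T) / (A + T)
- GC-skew = (G − C) / (G + C)

For a codon *c* with count *n(c)* in a synonymous family *F* of size |F|:

- RSCU(c) = n(c) · |F| / Σ_{c'∈F} n(c')

so RSCU averages to 1 within each family. A CDS whose length is not a
multiple of 3 ends in an incomplete stop (T·· or TA·), completed to UAA by
post-transcriptional polyadenylation; `mitocharacter` classifies these from
length mod 3 and verifies the terminal nucleotides.

Junction gaps on a circular genome of length L are
`next.start − prev.stop − 1`, with the origin-spanning junction computed
modulo L; negative gaps are overlaps. The gene order around the control
region(s) is extracted in a rotation-invariant window (nad5 → 12S by
default) and classified into the standard avian rearrangement classes
(ancestral, duplicate CR, remnant CR2, duplicate tRNA-Thr/CR).

## Worked example

Generate a synthetic duplicated-control-region genome (architecture-
isomorphic to a real 17,827 bp passerine mitogenome, with known ground
truth) and characterize it:

```bash
mitocharacter simulate --template duplicate_CR --seed 42 --out-prefix demo
mitocharacter characterize --genbank demo.gb --out-prefix demo_run
cat demo_run.summary.txt
```

```
Genome synthetic_duplicate_CR_42: circular, 17827 bp, 39 annotated features (13 PCGs, 22 tRNAs, 2 rRNAs, 2 control regions).
Gene order (nad5/cob/trnT/CR1/trnP/nad6/trnE/CR2/trnF/12S): classified as duplicate_CR.
Overlaps: 33 nt in 10 pairs; longest 10 nt between atp8 and atp6.
Intergenic spacers: 997 nt in 22 locations; longest 311 nt between trnT and CR1.
Incomplete stop codons (completed by polyadenylation): cox3, nad4.
tRNAs: 22 totalling 1547 bp (8.68% of the genome); longest trnL2 (75 bp), shortest trnC/trnS1 (66 bp).
```

Reading: the genome carries 39 features; its order around the control
regions matches the "duplicate CR" avian rearrangement (a second,
similar-length control region between trnE and trnF); the tightest gene
packing is a 10 nt overlap between atp8 and atp6; and two genes (cox3,
nad4) end on a single T that polyadenylation completes to a UAA stop.

RSCU from the bundled published codon counts of the reference genome
(GenBank MT457820):

```python
>>> from mitocharacter.refdata import reference_codon_usage
>>> from mitocharacter.codons import compute_rscu
>>> table = reference_codon_usage()
>>> counts = dict(zip(table["codon"], table["count"]))
>>> rscu = compute_rscu(counts, decimals=2).set_index("codon")
>>> float(rscu.loc["UUC", "rscu"]), float(rscu.loc["AGC", "rscu"])
(1.47, 1.46)
```

UUC is used ~1.5× more than expected under uniform usage within the
two-member Phe family; AGC likewise within the six-member Ser family.

The full report bundle written by `characterize` comprises the annotation
echo with recomputed lengths/gaps, a per-region composition/skew table, a
codon-count + RSCU table, an architecture JSON (junctions, extrema,
gene-order classification) and the one-page summary above. All reports are
deterministic: identical inputs and flags give byte-identical files.

## Acceptance script

`scripts/acceptance.py` recomputes the headline codon-usage replication
values by running the package on the bundled published codon-count table
(RSCU of the probe codons UUC and AGC under the default synonymous-family
map) and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `mitocharacter.annotation` — GenBank/TSV/FASTA I/O, coordinate arithmetic,
  name normalization, validation.
- `mitocharacter.composition` — base composition, AT/GC content and skews,
  per-region-class table, reported-table consistency checking.
- `mitocharacter.codons` — codon extraction/counting (two source modes),
  RSCU, synonymous-family maps, start/stop classification.
- `mitocharacter.architecture` — junctions, overlap/spacer summary, gene
  order extraction + classification, tRNA table, reconciliation reports.
- `mitocharacter.phylo` — 13-PCG supermatrix (FASTA/PHYLIP/partitions),
  p-distances, NJ preview tree.
- `mitocharacter.simulate` — synthetic circular genomes with exact ground
  truth; four gene-order templates.
- `mitocharacter.cli` / `mitocharacter.report` — `mitocharacter`
  command-line tool and report rendering.

See `docs/methods.md` for the conventions, defaults and known limitations.
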