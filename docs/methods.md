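# Methods and conventions

This note records the conventions, defaults and numerical choices behind
`mitocharacter`, and what its synthetic-data tests do and do not establish.

## Coordinates and junction arithmetic

All coordinates are 1-based inclusive (the GenBank convention); conversion
to 0-based half-open happens only inside I/O code. A feature with
`stop < start` spans the origin of a circular genome and has length
`(L − start + 1) + stop`. Between adjacent features the gap is
`next.start − prev.stop − 1`; on a circular genome the list of junctions
closes the circle with `(first.start + L) − last.stop − 1`, so N features
yield N junctions. Negative gaps are overlaps. With no three features
sharing a position, `Σ feature lengths + Σ gaps = L` exactly; triple
overlaps are detected and warned about, since they break this identity's
interpretation (junctions remain pairwise-adjacent).

The `length` and `intergenic` columns of input tables are treated as
advisory. They are always recomputed from coordinates; `reconcile_with_reported`
lists every cell where a printed table disagrees with its own coordinates.
The bundled reference table (GenBank MT457820) has two such cells — one
junction printed with a dropped minus sign (1 for −1) and the
origin-spanning junction printed one nucleotide short (175 for 176) — and
its companion composition table has one underivable cell (tRNA G+C printed
42.89 where its own printed G and C sum to 42.86). These are flagged, never
silently adopted, and the flagged values are deliberately left failing in
the replication test that demands cell-exact agreement.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C). Both are scale-invariant
(counts or percentages) and antisymmetric; a zero denominator yields NaN
(reported as missing, never 0). Only unambiguous A/C/G/T enter
denominators; IUPAC ambiguity codes are counted separately.

Per-class rows (PCGs / tRNAs / rRNAs / CRs) are computed on the
concatenation of member-feature slices taken on the reference (H) strand
regardless of coding strand. Published per-class tables do not state their
strand convention and are not reproducible without the underlying sequence;
the reference-strand choice is recorded in every report's metadata header
and `--orient-by-strand` selects the alternative (reverse-complementing
L-strand members first).

Report rounding is half-up (ties away from zero) to 2 decimals — the
rounding that every checkable published cell obeys; Python's banker's
rounding would disagree on exact ties. Internal arithmetic is full
precision.

## Codon usage

Two counting modes exist because published "PCG codon" totals are sometimes
the whole genome read in frame 1 rather than the genes themselves:

- `pcg_concat` (default): strand-oriented CDS of each protein-coding gene,
  complete in-frame codons only (incomplete terminal codons are not codons
  and are excluded);
- `whole_genome_frame1`: the entire reference strand in frame 1, giving
  ⌊L/3⌋ codons (5,942 for a 17,827 bp genome).

RSCU uses the standard-code synonymous families by default (six-member
Leu/Ser/Arg, three-member UAA/UAG/UGA stop family): this is the grouping
published mitochondrial RSCU tables conventionally obey, even though the
sequences are translated with the vertebrate mitochondrial code. The
vertebrate-mitochondrial grouping (AGA/AGG as stops, UGA→Trp, AUA→Met) is
available via `code="vertebrate_mitochondrial"`. Family maps are derived
from Biopython's codon tables, not hand-rolled. Families with zero total
count get NaN RSCU. Within every family of positive total, RSCU sums to the
family size exactly (pre-rounding) and is invariant under uniform scaling
of counts — both are property-tested.

Stop classification is driven by CDS length mod 3: 0 → complete stop (must
be TAA/TAG/AGA/AGG, else warned), 1 → incomplete "T(AA)" (final nt must be
T), 2 → incomplete "TA(A)" (final dinucleotide TA). All checks warn rather
than fail: annotations with unusual starts/stops are reported, not
rejected.

## Gene-order classification

The order window is extracted from the first anchor (default nad5) through
the second (default 12S) walking the circle, so it is invariant under
rotation of the coordinate origin; control regions are numbered CR1/CR2 by
occurrence within the window. Classification rules, in precedence order:
duplicated trnT with an adjacent CR copy → `duplicate_trnT_CR`; a single CR
between trnE and trnF → `ancestral`; two CRs with the second shorter than
50% of the first → `remnant_CR2`; two CRs placed trnT–CR–trnP and
trnE–CR–trnF, both ≥ 50% of the longer → `duplicate_CR`; anything else →
`unrecognized` (a value, not an error). The 50% relative-length threshold
is this package's convention — the rearrangement nomenclature names the
categories without a quantitative rule — and is configurable
(`--remnant-threshold`).

A spacer longer than 500 bp with no adjacent annotated control region
triggers a validator warning: an unannotated CR would otherwise silently
inflate spacer totals. Extremum ties (longest overlap/spacer, longest/
shortest tRNA) break by first occurrence from position 1; tRNA ties are
reported as lists.

## Supermatrix and NJ preview

The 13 PCGs are concatenated in the fixed order nad1, nad2, cox1, cox2,
atp8, atp6, cox3, nad3, nad4l, nad4, nad5, cob, nad6 (a package convention;
the order only needs to be stable and partition-documented). No alignment
is performed: per-gene blocks are padded with `-` at the 3' end to the
longest copy. This is adequate for same-family mitogenomes fed to an
external aligner/inference tool, and deliberately inadequate as an
alignment substitute. p-distance ignores sites where either row is gapped
(NaN if none remain). Neighbor joining is delegated to scikit-bio behind
this module's interface; taxa are sorted by label first so ties are
deterministic, and negative branch lengths are clamped to zero with a
warning. Bayesian/ML inference, model selection and support values are out
of scope.

## Synthetic genomes

`simulate.generate_genome` builds a circular genome from a template gene
order, per-feature lengths, a per-junction gap plan, a base-composition
target and per-codon weights, with a single seeded `numpy` generator
threaded through all sampling (same spec + seed ⇒ byte-identical FASTA,
GenBank and truth JSON). Defaults are the bundled reference genome's
architecture: the default `duplicate_CR` genome is 17,827 bp with the
reference's 39 feature lengths and junction gaps (including the 10 nt
atp8/atp6 overlap and 311 nt trnT–CR1 spacer). The `ancestral` template
uses a 1,153 bp single control region (a typical passerine value, since a
duplicated-CR reference provides none) and the `remnant_CR2` template an
80 bp second copy; non-reference templates default to 1 nt junctions with a
100 nt origin gap. Codon weights default to the bundled published counts,
with UAA/UAG/UGA zeroed inside PCG bodies.

PCG construction: background bases are drawn from the composition target,
then each CDS (ATG + weighted body codons + the stop implied by length mod
3) is written in genome order, L-strand genes as reverse complements.
Because planned overlaps let a later gene overwrite an earlier one's tail,
start codons and then stop parts are re-stamped after all bodies are
written, so every PCG keeps both contracts; in overlap regions the earlier
gene's body codons are whatever the final sequence says, and the recorded
truth (per-class base tallies, per-gene codon counts) is recomputed from
the final sequence by direct tallying, independent of the analysis code
paths it is used to test. The origin junction must be a spacer (gap ≥ 0);
an origin-spanning feature is not generatable.

What a green round-trip establishes: exact agreement of every stage with a
known-truth genome across all four templates and randomized lengths/gaps —
i.e. the bookkeeping (coordinates, strands, wrapping, counting, rounding)
is right. What it does not establish: realism. Synthetic genomes have iid
background composition, no within-genome regional heterogeneity beyond the
planned PCG codon bias, no control-region repeat structure, and no
evolutionary relationship between seeds, so cross-taxon distances from
synthetic data are near-saturation and only exercise the mechanics of the
supermatrix/NJ code.

## Degenerate inputs and failure behaviour

Empty sequences, empty feature tables, wrapping features on linear genomes,
non-partition family maps, all-zero codon weights, unrealizable synthetic
specs and non-symmetric distance matrices raise errors naming the offender.
Inconsistent advisory columns, non-canonical codons, anticodon mismatches
and suspicious spacers warn and continue. The `characterize` pipeline skips
sequence-dependent stages with a notice when given coordinates only, and
removes partial outputs if a stage fails. Reports carry a `# key: value`
metadata header recording the flags in force and contain no timestamps, so
identical runs are byte-identical.
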