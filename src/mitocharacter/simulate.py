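"""Synthetic circular mitogenomes with known ground truth.

The generator emits a sequence + annotation pair built from a chosen avian
gene-order template, per-feature lengths, a per-junction gap/overlap plan, a
target base composition, and a codon-usage bias — and records the exact
truth (per-class base tallies, per-gene codon counts, junction gaps, gene
order class) so every analysis stage can be verified bit-for-bit without any
real data. Defaults mirror the bundled reference genome's architecture: the
default template is ``duplicate_CR`` with the reference feature lengths and
junction gaps, so the default synthetic genome is architecture-isomorphic to
a real duplicated-control-region passerine mitogenome without containing its
sequence.

Truth tallies are recomputed from the final emitted sequence by direct
loops, independently of the analysis modules they are used to test.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .annotation import (
    Feature,
    GenomeAnnotation,
    feature_length,
    reverse_complement,
    write_fasta,
    write_genbank,
)
from .codons import ALL_CODONS
from .refdata import canonical_anticodons, reference_annotation, reference_codon_usage

#: default base composition (A, C, G, T), matching a typical passerine mitogenome
DEFAULT_COMPOSITION = (0.2945, 0.3281, 0.1448, 0.2326)

#: stop codons never emitted inside a generated PCG body (RNA alphabet)
_BODY_STOPS = {"UAA", "UAG", "UGA"}

#: single control region length used by the ancestral template (typical
#: passerine CR size; the duplicated-CR reference has no single-CR value)
ANCESTRAL_CR_LENGTH = 1153

REMNANT_CR2_LENGTH = 80

_CLASS_OF_TEMPLATE = {
    "ancestral": "ancestral",
    "duplicate_CR": "duplicate_CR",
    "remnant_CR2": "remnant_CR2",
    "duplicate_trnT_CR": "duplicate_trnT_CR",
}


def _reference_layout() -> tuple[list[tuple[str, str, str]], dict[str, int], list[int]]:
    """(name, ftype, strand) list, lengths and junction gaps of the bundled
    reference genome, recomputed from its coordinates."""
    ann = reference_annotation()
    order = [(f.name, f.ftype, f.strand) for f in ann]
    lengths = {f.name: feature_length(f, ann.length, ann.circular) for f in ann}
    gaps = []
    feats = ann.features
    for prev, nxt in zip(feats, feats[1:]):
        gaps.append(nxt.start - prev.stop - 1)
    gaps.append((feats[0].start + ann.length) - feats[-1].stop - 1)
    return order, lengths, gaps


def template_order(template: str) -> list[tuple[str, str, str]]:
    """Feature order (name, ftype, strand) for a named gene-order template."""
    base, _, _ = _reference_layout()
    head = base[: base.index(("trnT", "tRNA", "H")) + 1]  # ... cob, trnT
    tails = {
        "duplicate_CR": [("CR1", "CR", "H"), ("trnP", "tRNA", "L"),
                         ("nad6", "PCG", "L"), ("trnE", "tRNA", "L"),
                         ("CR2", "CR", "H")],
        "remnant_CR2": [("CR1", "CR", "H"), ("trnP", "tRNA", "L"),
                        ("nad6", "PCG", "L"), ("trnE", "tRNA", "L"),
                        ("CR2", "CR", "H")],
        "ancestral": [("trnP", "tRNA", "L"), ("nad6", "PCG", "L"),
                      ("trnE", "tRNA", "L"), ("CR", "CR", "H")],
        "duplicate_trnT_CR": [("CR1", "CR", "H"), ("trnT2", "tRNA", "H"),
                              ("trnP", "tRNA", "L"), ("nad6", "PCG", "L"),
                              ("trnE", "tRNA", "L"), ("CR2", "CR", "H")],
    }
    if template not in tails:
        raise ValueError(f"unknown template {template!r}; choose from {sorted(tails)}")
    return head + tails[template]


@dataclass
class SyntheticSpec:
    """Full description of a synthetic genome; every field has a realistic
    default derived from the reference layout."""

    template: str = "duplicate_CR"
    gene_lengths: dict[str, int] = field(default_factory=dict)
    gaps: list[int] = field(default_factory=list)
    composition: tuple[float, float, float, float] = DEFAULT_COMPOSITION  # A, C, G, T
    rscu_weights: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        order = template_order(self.template)
        _, ref_lengths, ref_gaps = _reference_layout()
        defaults = dict(ref_lengths)
        defaults.setdefault("CR", ANCESTRAL_CR_LENGTH)
        defaults.setdefault("trnT2", defaults["trnT"])
        if self.template == "remnant_CR2":
            defaults["CR2"] = REMNANT_CR2_LENGTH
        lengths = {name: self.gene_lengths.get(name, defaults[name])
                   for name, _, _ in order}
        self.gene_lengths = lengths
        if not self.gaps:
            if self.template == "duplicate_CR":
                self.gaps = list(ref_gaps)
            else:
                self.gaps = [1] * (len(order) - 1) + [100]
        if len(self.gaps) != len(order):
            raise ValueError(
                f"gap plan must have one entry per feature ({len(order)}), got {len(self.gaps)}"
            )
        self.validate(order)

    def validate(self, order) -> None:
        if any(l < 1 for l in self.gene_lengths.values()):
            raise ValueError("feature lengths must be >= 1")
        if abs(sum(self.composition) - 1.0) > 1e-6:
            raise ValueError("composition target must sum to 1")
        if self.genome_length <= 0:
            raise ValueError("unrealizable spec: non-positive genome length")
        if self.gaps[-1] < 0:
            raise ValueError("the origin (wrap) junction may not be an overlap")
        names = [n for n, _, _ in order]
        for i, gap in enumerate(self.gaps[:-1]):
            if gap < 0 and -gap >= min(self.gene_lengths[names[i]],
                                       self.gene_lengths[names[i + 1]]):
                raise ValueError(
                    f"overlap at {names[i]}->{names[i + 1]} swallows a whole feature"
                )

    @property
    def genome_length(self) -> int:
        return sum(self.gene_lengths.values()) + sum(self.gaps)


@dataclass
class SyntheticTruth:
    """Exact ground truth recorded at generation time."""

    genome_length: int
    gene_order_class: str
    class_base_counts: dict[str, dict[str, int]]
    pcg_codon_counts: dict[str, dict[str, int]]
    junction_gaps: list[int]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def sample_codons(rscu_weights: dict[str, float], n: int, seed=0) -> list[str]:
    """Draw ``n`` codons (DNA alphabet) multinomially, proportional to the
    given per-codon weights (RNA or DNA keys). ``seed`` may be an int or a
    ``numpy.random.Generator``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = {k.upper().replace("T", "U"): float(v) for k, v in rscu_weights.items()}
    codons = [c for c in ALL_CODONS if weights.get(c, 0.0) > 0]
    if any(v < 0 for v in weights.values()):
        raise ValueError("codon weights must be non-negative")
    if not codons:
        raise ValueError("all codon weights are zero")
    if n == 0:
        return []
    p = np.array([weights[c] for c in codons])
    p = p / p.sum()
    draws = rng.choice(len(codons), size=n, p=p)
    return [codons[i].replace("U", "T") for i in draws]


def default_codon_weights(exclude_stops: bool = True) -> dict[str, float]:
    """Codon weights proportional to the bundled reference codon counts."""
    df = reference_codon_usage()
    weights = {row.codon: float(row.count) for row in df.itertuples(index=False)}
    if exclude_stops:
        for stop in _BODY_STOPS:
            weights[stop] = 0.0
    return weights


_STOP_PART = {0: "TAA", 1: "T", 2: "TA"}


def generate_genome(spec: SyntheticSpec) -> tuple[str, GenomeAnnotation, SyntheticTruth]:
    """Generate (sequence, annotation, truth) for a spec; deterministic given
    the spec's seed.

    PCGs begin with ATG and end with the stop implied by their length mod 3
    (complete TAA, or an incomplete T / TA completed by polyadenylation);
    L-strand features are embedded as reverse complements. Where planned
    overlaps make two PCGs share sequence, start codons and stop parts are
    stamped last so both contracts hold.
    """
    order = template_order(spec.template)
    rng = np.random.default_rng(spec.seed)
    length = spec.genome_length

    # coordinates from lengths + gap plan
    coords: dict[str, tuple[int, int]] = {}
    cursor = 1
    for (name, _, _), gap in zip(order, spec.gaps):
        start = cursor
        stop = start + spec.gene_lengths[name] - 1
        coords[name] = (start, stop)
        cursor = stop + gap + 1
    assert cursor - 1 == length

    pA, pC, pG, pT = spec.composition
    arr = rng.choice(np.array(list("ACGT")), size=length, p=[pA, pC, pG, pT])

    body_weights = dict(spec.rscu_weights or default_codon_weights())
    for stop in _BODY_STOPS:
        body_weights[stop.replace("U", "T")] = 0.0
        body_weights[stop] = 0.0

    def _write(start: int, text: str) -> None:
        arr[start - 1: start - 1 + len(text)] = list(text)

    pcgs = [(name, strand) for name, ftype, strand in order if ftype == "PCG"]
    stop_parts: dict[str, str] = {}
    for name, strand in pcgs:
        start, stop = coords[name]
        ln = stop - start + 1
        stop_part = _STOP_PART[ln % 3]
        stop_parts[name] = stop_part
        n_body = ln // 3 - 1 - (1 if ln % 3 == 0 else 0)
        if n_body < 0:
            raise ValueError(f"PCG {name} too short for start + stop codons")
        cds = "ATG" + "".join(sample_codons(body_weights, n_body, rng)) + stop_part
        _write(start, reverse_complement(cds) if strand == "L" else cds)

    # overlaps may have clobbered earlier starts/stops: stamp starts, then stops
    for name, strand in pcgs:
        start, stop = coords[name]
        if strand == "H":
            _write(start, "ATG")
        else:
            _write(stop - 2, reverse_complement("ATG"))
    for name, strand in pcgs:
        start, stop = coords[name]
        sp = stop_parts[name]
        if strand == "H":
            _write(stop - len(sp) + 1, sp)
        else:
            _write(start, reverse_complement(sp))

    seq = "".join(arr)

    anticodons = canonical_anticodons()
    features = []
    for name, ftype, strand in order:
        start, stop = coords[name]
        features.append(Feature(
            name=name, ftype=ftype, strand=strand, start=start, stop=stop,
            anticodon=anticodons.get("trnT" if name == "trnT2" else name)
            if ftype == "tRNA" else None,
            start_codon="ATG" if ftype == "PCG" else None,
            stop_codon=(stop_parts[name] if stop_parts[name] == "TAA"
                        else {"T": "T(AA)", "TA": "TA(A)"}[stop_parts[name]])
            if ftype == "PCG" else None,
        ))
    ann = GenomeAnnotation(f"synthetic_{spec.template}_{spec.seed}", length, True, features)

    truth = SyntheticTruth(
        genome_length=length,
        gene_order_class=_CLASS_OF_TEMPLATE[spec.template],
        class_base_counts=_class_tallies(seq, order, coords),
        pcg_codon_counts=_pcg_codon_tallies(seq, order, coords),
        junction_gaps=list(spec.gaps),
        seed=spec.seed,
    )
    return seq, ann, truth


def _class_tallies(seq: str, order, coords) -> dict[str, dict[str, int]]:
    cls_of = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs", "CR": "CRs"}
    tallies: dict[str, Counter] = {"mtDNA": Counter(seq)}
    for name, ftype, _ in order:  # reference-strand slices, annotation order
        start, stop = coords[name]
        tallies.setdefault(cls_of[ftype], Counter()).update(seq[start - 1: stop])
    return {cls: dict(cnt) for cls, cnt in tallies.items()}


def _pcg_codon_tallies(seq: str, order, coords) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for name, ftype, strand in order:
        if ftype != "PCG":
            continue
        start, stop = coords[name]
        cds = seq[start - 1: stop]
        if strand == "L":
            cds = reverse_complement(cds)
        n = len(cds) // 3 * 3
        out[name] = dict(Counter(cds[i:i + 3] for i in range(0, n, 3)))
    return out


def emit(spec: SyntheticSpec, out_prefix: str) -> tuple[str, GenomeAnnotation, SyntheticTruth]:
    """Generate and write ``<prefix>.fasta``, ``<prefix>.gb`` and
    ``<prefix>.truth.json``."""
    seq, ann, truth = generate_genome(spec)
    write_fasta(ann.genome_id, seq, f"{out_prefix}.fasta")
    write_genbank(ann, seq, f"{out_prefix}.gb")
    truth.to_json(f"{out_prefix}.truth.json")
    return seq, ann, truth
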