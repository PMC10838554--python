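"""Reading, validating and writing annotated circular mitogenomes.

Coordinates are 1-based inclusive throughout (the GenBank convention and the
convention of published mitogenome annotation tables); conversion to 0-based
half-open happens only at I/O boundaries. A feature with ``stop < start`` is
an origin-spanning ("wrapping") feature and is only legal on a circular
genome.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.Seq import reverse_complement as _bio_revcomp
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "CR")
STRANDS = ("H", "L")

#: the 13 vertebrate mitochondrial protein-coding genes, canonical names
PCG_NAMES = (
    "nad1", "nad2", "cox1", "cox2", "atp8", "atp6", "cox3",
    "nad3", "nad4l", "nad4", "nad5", "cob", "nad6",
)


class AnnotationError(ValueError):
    """Raised when an annotation violates its structural invariants."""


class AnnotationWarning(UserWarning):
    """Non-fatal annotation inconsistency (e.g. a stated length that does not
    match the coordinates)."""


@dataclass(frozen=True)
class Feature:
    """One annotated element of a mitogenome.

    ``start``/``stop`` are 1-based inclusive; ``stop < start`` denotes an
    origin-spanning feature on a circular genome. ``strand`` is ``"H"``
    (heavy, the reference strand) or ``"L"`` (light, reverse complement).
    """

    name: str
    ftype: str
    strand: str
    start: int
    stop: int
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise AnnotationError(f"{self.name}: unknown feature type {self.ftype!r}")
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.name}: strand must be H or L, got {self.strand!r}")
        if self.start < 1 or self.stop < 1:
            raise AnnotationError(f"{self.name}: coordinates must be >= 1")
        if self.ftype == "CR" and (self.start_codon or self.stop_codon):
            raise AnnotationError(f"{self.name}: control regions carry no codon attributes")

    @property
    def wraps(self) -> bool:
        return self.stop < self.start


@dataclass
class GenomeAnnotation:
    """Ordered feature list plus genome length and circularity.

    Features are kept sorted by ascending start coordinate.
    """

    genome_id: str
    length: int
    circular: bool
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise AnnotationError("genome length must be positive")
        self.features = sorted(self.features, key=lambda f: (f.start, f.stop))
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise AnnotationError(f"duplicate feature names: {sorted(dupes)}")
        for f in self.features:
            if f.start > self.length or f.stop > self.length:
                raise AnnotationError(
                    f"{f.name}: coordinates {f.start}..{f.stop} exceed genome length {self.length}"
                )
            if f.wraps and not self.circular:
                raise AnnotationError(f"{f.name}: wrapping feature on a non-circular genome")

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]

    @property
    def pcgs(self) -> list[Feature]:
        return self.of_type("PCG")


def feature_length(f: Feature, genome_length: int, circular: bool = True) -> int:
    """Length in nucleotides of a feature, wrap-aware.

    Non-wrapping: ``stop - start + 1``. Wrapping on a circular genome:
    ``(genome_length - start + 1) + stop``.
    """
    if not f.wraps:
        return f.stop - f.start + 1
    if not circular:
        raise AnnotationError(f"{f.name}: wrapping feature on a non-circular genome")
    return (genome_length - f.start + 1) + f.stop


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity codes, case preserved."""
    return _bio_revcomp(seq)


def extract_feature_sequence(seq: str, f: Feature, circular: bool = True) -> str:
    """Strand-oriented sequence of a feature.

    H-strand features return the reference slice as-is; L-strand features
    return its reverse complement. Origin-spanning features concatenate the
    tail and head slices before orienting.
    """
    if f.stop > len(seq) or f.start > len(seq):
        raise AnnotationError(f"{f.name}: coordinates exceed sequence length {len(seq)}")
    if f.wraps:
        if not circular:
            raise AnnotationError(f"{f.name}: wrapping feature on a non-circular genome")
        raw = seq[f.start - 1:] + seq[: f.stop]
    else:
        raw = seq[f.start - 1: f.stop]
    return reverse_complement(raw) if f.strand == "L" else raw


# ---------------------------------------------------------------------------
# name normalization

_LEU_SER_BY_ANTICODON = {
    "TAA": "trnL2", "UAA": "trnL2",
    "TAG": "trnL1", "UAG": "trnL1",
    "TGA": "trnS2", "UGA": "trnS2",
    "GCT": "trnS1", "GCU": "trnS1",
}

_name_map_cache: dict[str, str] | None = None


def _name_map() -> dict[str, str]:
    global _name_map_cache
    if _name_map_cache is None:
        text = resources.files("mitocharacter.data").joinpath("gene_name_map.tsv").read_text()
        mapping: dict[str, str] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("alias\t"):
                continue
            alias, canonical = line.split("\t")
            mapping[alias] = canonical
        _name_map_cache = mapping
    return _name_map_cache


def _squash(name: str) -> str:
    return re.sub(r"[\s_\-()]+", "", name).lower()


def normalize_name(raw: str, anticodon: str | None = None) -> str:
    """Map a GenBank-style gene/product name to its canonical form.

    Unknown names pass through unchanged. Leu/Ser tRNAs are disambiguated by
    anticodon when the name alone is ambiguous (``trnL`` -> ``trnL1``/``trnL2``).
    """
    canonical = _name_map().get(_squash(raw), raw)
    if canonical in ("trnL", "trnS") and anticodon:
        canonical = _LEU_SER_BY_ANTICODON.get(anticodon.upper(), canonical)
    return canonical


def infer_ftype(name: str) -> str:
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low in ("12s", "16s") or low.startswith("rrn"):
        return "rRNA"
    if low.startswith("cr") or "loop" in low or "control" in low:
        return "CR"
    return "PCG"


def _assign_cr_copies(names: list[str]) -> list[str]:
    """Rename bare 'CR' control regions to CR1/CR2/... by order of appearance."""
    n_cr = sum(1 for n in names if n == "CR")
    if n_cr <= 1:
        return names
    out, i = [], 0
    for n in names:
        if n == "CR":
            i += 1
            out.append(f"CR{i}")
        else:
            out.append(n)
    return out


# ---------------------------------------------------------------------------
# tabular I/O

_META_RE = re.compile(r"^#\s*([A-Za-z_][\w]*)\s*:\s*(.+?)\s*$")


def parse_feature_table(
    rows: pd.DataFrame | Iterable[dict],
    genome_length: int | None = None,
    circular: bool = True,
    genome_id: str = "genome",
) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from tabular records.

    Required columns: ``gene`` (or ``name``), ``strand``, ``start``, ``stop``.
    Optional columns ``length``, ``anticodon``, ``start_codon``, ``stop_codon``
    are carried along; the length column is advisory — it is cross-checked
    against the coordinates and inconsistencies raise an
    :class:`AnnotationWarning` (never an error).
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if df.empty:
        raise AnnotationError("no features")
    df = df.rename(columns={"name": "gene"})
    for col in ("gene", "strand", "start", "stop"):
        if col not in df.columns:
            raise AnnotationError(f"missing required column {col!r}")

    if genome_length is None:
        genome_length = int(df["stop"].max())

    def _opt(row, col):
        if col not in df.columns:
            return None
        v = getattr(row, col)
        if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
            return None
        return str(v).strip()

    names = [normalize_name(str(r.gene).strip(), _opt(r, "anticodon"))
             for r in df.itertuples(index=False)]
    names = _assign_cr_copies(names)

    features: list[Feature] = []
    inconsistent: list[str] = []
    for name, row in zip(names, df.itertuples(index=False)):
        ftype = infer_ftype(name)
        f = Feature(
            name=name,
            ftype=ftype,
            strand=str(row.strand).strip(),
            start=int(row.start),
            stop=int(row.stop),
            anticodon=_opt(row, "anticodon"),
            start_codon=None if ftype == "CR" else _opt(row, "start_codon"),
            stop_codon=None if ftype == "CR" else _opt(row, "stop_codon"),
        )
        stated = _opt(row, "length")
        if stated is not None:
            computed = feature_length(f, genome_length, circular)
            if int(stated) != computed:
                inconsistent.append(f"{name}: stated {stated} vs computed {computed}")
        features.append(f)

    if inconsistent:
        warnings.warn(
            "length column inconsistent with coordinates: " + "; ".join(inconsistent),
            AnnotationWarning,
            stacklevel=2,
        )
    return GenomeAnnotation(genome_id, genome_length, circular, features)


def read_feature_table(path) -> GenomeAnnotation:
    """Read a TSV feature table, honouring ``# key: value`` metadata lines
    (``genome_id``, ``genome_length``, ``circular``)."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    meta: dict[str, str] = {}
    for line in text.splitlines():
        m = _META_RE.match(line)
        if m and m.group(1) != "note":
            meta[m.group(1)] = m.group(2)
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
    df["start"] = df["start"].astype(int)
    df["stop"] = df["stop"].astype(int)
    return parse_feature_table(
        df,
        genome_length=int(meta["genome_length"]) if "genome_length" in meta else None,
        circular=meta.get("circular", "true").lower() in ("true", "1", "yes"),
        genome_id=meta.get("genome_id", "genome"),
    )


def write_feature_table(ann: GenomeAnnotation, path) -> None:
    """Write a normalized TSV feature table with recomputed length column."""
    lines = [
        f"# genome_id: {ann.genome_id}",
        f"# genome_length: {ann.length}",
        f"# circular: {str(ann.circular).lower()}",
        "gene\tstrand\tstart\tstop\tlength\tanticodon\tstart_codon\tstop_codon",
    ]
    for f in ann:
        lines.append("\t".join([
            f.name, f.strand, str(f.start), str(f.stop),
            str(feature_length(f, ann.length, ann.circular)),
            f.anticodon or "", f.start_codon or "", f.stop_codon or "",
        ]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GenBank / FASTA

_GENBANK_FTYPES = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}


def parse_genbank(text: str) -> tuple[GenomeAnnotation, str]:
    """Parse a single-record GenBank flat file into an annotation + sequence.

    CDS features map to PCGs, tRNA/rRNA to their classes, D-loop (or
    misc_feature whose note mentions a control region) to CR. Locations on
    the complement map to the L strand; a join spanning the origin maps to a
    wrapping feature.
    """
    first_line = text.lstrip().splitlines()[0] if text.strip() else "<empty>"
    try:
        record = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad headers
        raise AnnotationError(f"malformed GenBank record near {first_line!r}: {exc}") from exc

    seq = str(record.seq).upper()
    circular = record.annotations.get("topology", "").lower() == "circular"
    length = len(seq)

    kept: list[tuple[str, str, str, int, int, str | None]] = []
    for feat in record.features:
        ftype = _GENBANK_FTYPES.get(feat.type)
        if ftype is None:
            if feat.type == "misc_feature":
                note = " ".join(feat.qualifiers.get("note", [])).lower()
                if "control region" in note or "d-loop" in note:
                    ftype = "CR"
            if ftype is None:
                continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [feat.type])[0]
        anticodon = None
        if "anticodon" in quals:
            m = re.search(r"seq\s*:\s*([a-zA-Z]{3})", quals["anticodon"][0])
            anticodon = m.group(1).upper() if m else quals["anticodon"][0].upper()[:3]
        loc = feat.location
        strand = "L" if loc.strand == -1 else "H"
        parts = loc.parts
        if len(parts) > 1 and int(parts[0].end) == length and int(parts[1].start) == 0:
            start, stop = int(parts[0].start) + 1, int(parts[-1].end)  # wraps origin
        else:
            start, stop = int(loc.start) + 1, int(loc.end)
        if stop > length and not (stop < start):
            raise AnnotationError(f"feature {raw} beyond sequence length {length}")
        kept.append((raw, ftype, strand, start, stop, anticodon))

    names = _assign_cr_copies(
        ["CR" if ftype == "CR" else normalize_name(raw, ac)
         for raw, ftype, _, _, _, ac in kept]
    )
    features = [
        Feature(name=name, ftype=ftype, strand=strand, start=start, stop=stop, anticodon=ac)
        for name, (raw, ftype, strand, start, stop, ac) in zip(names, kept)
    ]
    ann = GenomeAnnotation(record.id or record.name, length, circular, features)
    return ann, seq


def write_genbank(ann: GenomeAnnotation, seq: str, path) -> None:
    """Write annotation + sequence as a single-record GenBank flat file."""
    record = SeqRecord(
        Seq(seq),
        id=ann.genome_id,
        name=re.sub(r"\W", "_", ann.genome_id)[:16],
        description="mitocharacter annotation",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if ann.circular else "linear",
        },
    )
    inverse = {v: k for k, v in _GENBANK_FTYPES.items()}
    for f in ann:
        strand = -1 if f.strand == "L" else 1
        if f.wraps:
            loc = CompoundLocation([
                FeatureLocation(f.start - 1, ann.length, strand),
                FeatureLocation(0, f.stop, strand),
            ])
        else:
            loc = FeatureLocation(f.start - 1, f.stop, strand)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["note"] = [f"anticodon:{f.anticodon}"]
        record.features.append(SeqFeature(loc, type=inverse[f.ftype], qualifiers=quals))
    SeqIO.write(record, path, "genbank")


def read_fasta(path) -> str:
    record = SeqIO.read(path, "fasta")
    return str(record.seq).upper()


def write_fasta(genome_id: str, seq: str, path) -> None:
    SeqIO.write(SeqRecord(Seq(seq), id=genome_id, description=""), path, "fasta")


def validation_report(ann: GenomeAnnotation, seq: str | None = None) -> dict:
    """JSON-able validation report: coordinate sanity and non-ACGT characters."""
    problems: list[str] = []
    non_acgt: dict[str, int] = {}
    if seq is not None:
        if len(seq) != ann.length:
            problems.append(f"sequence length {len(seq)} != annotated length {ann.length}")
        for ch in seq:
            if ch not in "ACGT":
                non_acgt[ch] = non_acgt.get(ch, 0) + 1
    for f in ann:
        if f.wraps and not ann.circular:
            problems.append(f"{f.name}: wraps on non-circular genome")
    return {
        "genome_id": ann.genome_id,
        "n_features": len(ann),
        "problems": problems,
        "non_acgt_counts": non_acgt,
        "ok": not problems,
    }
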