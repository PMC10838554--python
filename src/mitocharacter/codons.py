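"""Codon counting, relative synonymous codon usage (RSCU), and start/stop
codon classification for mitochondrial protein-coding genes.

RSCU of a codon is its observed count divided by the count expected if all
codons of its synonymous family were used equally:

    RSCU(c) = count(c) * n_family / sum(counts over the family)

so each family's RSCU values average to 1. The default synonymous-family
grouping follows the *standard* genetic code (six-member Leu/Ser/Arg
families, a three-member UAA/UAG/UGA stop family), which is the grouping
published mitogenome codon tables conventionally obey; the vertebrate
mitochondrial grouping (AGA/AGG as stops, UGA read as Trp) is available via
``code="vertebrate_mitochondrial"``. Protein-level translation, in contrast,
always presumes the vertebrate mitochondrial code — that is what makes
one- and two-nucleotide incomplete stops (completed to UAA by
polyadenylation) meaningful.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

from ._util import MISSING, round_half_up
from .annotation import Feature, GenomeAnnotation, extract_feature_sequence

COMPLETE_STOPS = ("TAA", "TAG", "AGA", "AGG")

_CODE_IDS = {"standard": 1, "vertebrate_mitochondrial": 2}

ALL_CODONS = tuple(
    a + b + c for a in "UCAG" for b in "UCAG" for c in "UCAG"
)


def synonymous_families(code: str = "standard") -> dict[str, str]:
    """Codon -> family label (one-letter amino acid, ``*`` for stop) under the
    named genetic code. Codons are in the RNA alphabet."""
    try:
        table = CodonTable.unambiguous_rna_by_id[_CODE_IDS[code]]
    except KeyError:
        raise ValueError(f"unknown genetic code {code!r}") from None
    fam = {codon: "*" for codon in table.stop_codons}
    fam.update(table.forward_table)
    return {codon: fam[codon] for codon in ALL_CODONS}


@dataclass
class CodonCounts:
    """Counts over all 64 codons (RNA alphabet)."""

    counts: dict[str, int]
    source: str
    code: str = "standard"

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            key = codon.upper().replace("T", "U")
            if key not in full:
                raise ValueError(f"not a codon: {codon!r}")
            full[key] += int(n)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def extract_codons(cds: str) -> tuple[list[str], str]:
    """Split a CDS into complete in-frame codons plus a 0-2 nt residual tail.

    The tail (an incomplete terminal codon) is never counted as a codon.
    """
    cds = cds.upper()
    n = len(cds) // 3 * 3
    return [cds[i:i + 3] for i in range(0, n, 3)], cds[n:]


def count_codons(
    ann: GenomeAnnotation,
    seq: str,
    source_mode: str = "pcg_concat",
    code: str = "standard",
) -> CodonCounts:
    """Count codons either over the strand-oriented concatenated PCGs
    (``pcg_concat``) or over the entire reference strand read in frame 1
    (``whole_genome_frame1``). Incomplete terminal codons are excluded.
    """
    if source_mode == "pcg_concat":
        counter: Counter[str] = Counter()
        for f in ann.pcgs:
            cds = extract_feature_sequence(seq, f, ann.circular)
            if len(cds) < 3:
                raise ValueError(f"PCG {f.name} shorter than one codon ({len(cds)} nt)")
            codons, _ = extract_codons(cds)
            counter.update(codons)
    elif source_mode == "whole_genome_frame1":
        codons, _ = extract_codons(seq)
        counter = Counter(codons)
    else:
        raise ValueError(f"unknown source_mode {source_mode!r}")
    counter = Counter({k: v for k, v in counter.items() if set(k) <= set("ACGT")})
    return CodonCounts(dict(counter), source=source_mode, code=code)


def compute_rscu(
    cc: CodonCounts | dict[str, int],
    family_map: dict[str, str] | None = None,
    decimals: int | None = None,
) -> pd.DataFrame:
    """RSCU table from codon counts.

    ``family_map`` must partition the 64 codons into synonymous families
    (default: standard-code families). Families with zero total count get
    NaN RSCU. Pass ``decimals`` to round for reporting.
    """
    if not isinstance(cc, CodonCounts):
        cc = CodonCounts(dict(cc), source="external")
    if family_map is None:
        family_map = synonymous_families(cc.code)
    if sorted(family_map) != sorted(ALL_CODONS):
        raise ValueError("family_map must assign every one of the 64 codons exactly once")

    fam_totals: dict[str, int] = {}
    fam_sizes: dict[str, int] = {}
    for codon, fam in family_map.items():
        fam_totals[fam] = fam_totals.get(fam, 0) + cc.counts[codon]
        fam_sizes[fam] = fam_sizes.get(fam, 0) + 1

    rows = []
    for codon in ALL_CODONS:
        fam = family_map[codon]
        total = fam_totals[fam]
        rscu = cc.counts[codon] * fam_sizes[fam] / total if total > 0 else MISSING
        if decimals is not None:
            rscu = round_half_up(rscu, decimals)
        rows.append({"codon": codon, "family": fam, "count": cc.counts[codon], "rscu": rscu})
    df = pd.DataFrame(rows)
    df.attrs["total"] = cc.total
    df.attrs["source"] = cc.source
    return df


def codon_label(codon: str, family: str) -> str:
    """Render a codon the way codon-usage tables print it, e.g. ``CUA(L)``."""
    return f"{codon}({family})"


def codon_family_totals(rscu: pd.DataFrame) -> pd.DataFrame:
    """Per-family codon totals, ranked most to least frequent.

    Stop families are excluded from the most/least ranking semantics but are
    still listed (family ``*``). Ties break alphabetically by family label.
    """
    totals = (
        rscu.groupby("family", as_index=False)["count"].sum()
        .sort_values(["count", "family"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    coding = totals[(totals["family"] != "*") & (totals["count"] > 0)]
    totals.attrs["most_frequent"] = coding.iloc[0]["family"] if len(coding) else None
    totals.attrs["least_frequent"] = coding.iloc[-1]["family"] if len(coding) else None
    return totals


# ---------------------------------------------------------------------------
# start / stop classification

@dataclass(frozen=True)
class StopClassification:
    """Start codon and stop-codon class of one protein-coding gene.

    ``stop_kind`` is ``complete`` (TAA/TAG/AGA/AGG), ``incomplete_T`` (CDS
    length mod 3 = 1, a lone T completed to UAA by polyadenylation) or
    ``incomplete_TA`` (mod 3 = 2). ``stop_text`` is the conventional
    rendering, e.g. ``"TAA"`` or ``"T(AA)"``.
    """

    gene: str
    start_codon: str
    stop_kind: str
    stop_text: str
    warnings: tuple[str, ...] = ()


def stop_kind_from_length(cds_length: int) -> str:
    """Stop-codon class implied by a CDS length alone: a CDS whose length is
    not a multiple of 3 must end in an incomplete (polyadenylation-completed)
    stop."""
    return {0: "complete", 1: "incomplete_T", 2: "incomplete_TA"}[cds_length % 3]


def classify_start_stop(gene: Feature | str, cds: str) -> StopClassification:
    """Classify the initiation and termination codon of a strand-oriented CDS."""
    name = gene.name if isinstance(gene, Feature) else str(gene)
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError(f"{name}: CDS shorter than one codon")
    start = cds[:3]
    warns: list[str] = []
    if start != "ATG":
        warns.append(f"non-ATG start codon {start}")
    kind = stop_kind_from_length(len(cds))
    if kind == "complete":
        stop_text = cds[-3:]
        if stop_text not in COMPLETE_STOPS:
            warns.append(f"non-canonical terminal codon {stop_text}")
    elif kind == "incomplete_T":
        stop_text = "T(AA)"
        if cds[-1] != "T":
            warns.append(f"length mod 3 = 1 but final nucleotide is {cds[-1]}, not T")
    else:
        stop_text = "TA(A)"
        if cds[-2:] != "TA":
            warns.append(f"length mod 3 = 2 but final dinucleotide is {cds[-2:]}, not TA")
    return StopClassification(name, start, kind, stop_text, tuple(warns))


def incomplete_stop_genes(ann: GenomeAnnotation) -> dict[str, str]:
    """Genes with incomplete stop codons, inferred from coordinates alone.

    Returns ``{gene: stop_kind}`` for every PCG whose length is not a
    multiple of 3.
    """
    from .annotation import feature_length

    out: dict[str, str] = {}
    for f in ann.pcgs:
        kind = stop_kind_from_length(feature_length(f, ann.length, ann.circular))
        if kind != "complete":
            out[f.name] = kind
    return out
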