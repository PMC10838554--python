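"""Base composition, AT/GC content and strand skews per region class.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C) measure
compositional asymmetry between the two strands; both are scale-invariant,
so counts and percentages give identical values. Reports round half-up to
two decimals; internal arithmetic keeps full precision.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from ._util import MISSING, round_half_up
from .annotation import GenomeAnnotation, extract_feature_sequence, feature_length

#: region classes, in report order
REGION_CLASSES = ("mtDNA", "PCGs", "tRNAs", "rRNAs", "CRs")
_CLASS_OF_FTYPE = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs", "CR": "CRs"}


@dataclass(frozen=True)
class CompositionStats:
    """Base fractions (percent), AT/GC content and skews for one region."""

    n: int
    fracA: float
    fracC: float
    fracG: float
    fracT: float
    at_content: float
    gc_content: float
    at_skew: float
    gc_skew: float
    ambiguous: int = 0

    def rounded(self, decimals: int = 2) -> "CompositionStats":
        r = lambda x: round_half_up(x, decimals)
        return CompositionStats(
            self.n, r(self.fracA), r(self.fracC), r(self.fracG), r(self.fracT),
            r(self.at_content), r(self.gc_content), r(self.at_skew), r(self.gc_skew),
            self.ambiguous,
        )


def at_skew(a: float, t: float) -> float:
    """(A - T) / (A + T); accepts counts or percentages. Undefined (NaN) when
    A + T = 0."""
    if a + t == 0:
        return MISSING
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float:
    """(G - C) / (G + C); NaN when G + C = 0."""
    if g + c == 0:
        return MISSING
    return (g - c) / (g + c)


def base_composition(seq: str) -> CompositionStats:
    """Composition statistics of a sequence.

    Only A/C/G/T enter the denominator; ambiguity codes (N, R, Y, ...) are
    counted separately and reported via ``ambiguous``.
    """
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    a, c, g, t = (counts.get(b, 0) for b in "ACGT")
    n = a + c + g + t
    if n == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T")
    pct = lambda x: 100.0 * x / n
    return CompositionStats(
        n=n,
        fracA=pct(a), fracC=pct(c), fracG=pct(g), fracT=pct(t),
        at_content=pct(a + t), gc_content=pct(g + c),
        at_skew=at_skew(a, t), gc_skew=gc_skew(g, c),
        ambiguous=len(seq) - n,
    )


def region_composition_table(
    seq: str,
    ann: GenomeAnnotation,
    orient_by_strand: bool = False,
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-region-class composition table (one row per class plus mtDNA).

    Each class sequence is the concatenation, in annotation order, of the
    member features' slices. By default slices are taken on the reference
    (H) strand regardless of the feature's coding strand; pass
    ``orient_by_strand=True`` to reverse-complement L-strand members instead.
    Classes with no members are omitted.
    """
    if len(seq) != ann.length:
        raise ValueError(f"sequence length {len(seq)} != annotated length {ann.length}")
    pieces: dict[str, list[str]] = {cls: [] for cls in REGION_CLASSES[1:]}
    for f in ann:
        if orient_by_strand:
            piece = extract_feature_sequence(seq, f, ann.circular)
        elif f.wraps:
            piece = seq[f.start - 1:] + seq[: f.stop]
        else:
            piece = seq[f.start - 1: f.stop]
        pieces[_CLASS_OF_FTYPE[f.ftype]].append(piece)

    rows: dict[str, CompositionStats] = {"mtDNA": base_composition(seq)}
    for cls in REGION_CLASSES[1:]:
        if pieces[cls]:
            rows[cls] = base_composition("".join(pieces[cls]))

    df = pd.DataFrame(
        [
            {"region": cls, "size": st.n,
             "A": st.fracA, "C": st.fracC, "T": st.fracT, "G": st.fracG,
             "at_content": st.at_content, "gc_content": st.gc_content,
             "at_skew": st.at_skew, "gc_skew": st.gc_skew}
            for cls, st in ((c, rows[c].rounded(decimals)) for c in rows)
        ]
    )
    df.attrs["orient_by_strand"] = orient_by_strand
    return df


def derived_cells(row) -> dict[str, float]:
    """Recompute the four derived cells (A+T, G+C, skews) of a composition
    table row from its A/C/T/G percentages, rounded to 2 decimals."""
    return {
        "at_content": round_half_up(row["A"] + row["T"]),
        "gc_content": round_half_up(row["G"] + row["C"]),
        "at_skew": round_half_up(at_skew(row["A"], row["T"])),
        "gc_skew": round_half_up(gc_skew(row["G"], row["C"])),
    }


def check_reported_table(df: pd.DataFrame) -> pd.DataFrame:
    """Consistency check of a reported composition table.

    For every row, the derived cells are recomputed from the printed base
    percentages and compared with the printed derived cells; the returned
    frame lists one record per mismatching cell (empty means fully
    internally consistent).
    """
    mismatches = []
    for _, row in df.iterrows():
        for cell, recomputed in derived_cells(row).items():
            printed = float(row[cell])
            if abs(recomputed - printed) > 1e-9:
                mismatches.append({
                    "region": row["region"], "cell": cell,
                    "printed": printed, "recomputed": recomputed,
                })
    return pd.DataFrame(mismatches, columns=["region", "cell", "printed", "recomputed"])


def region_sizes(ann: GenomeAnnotation) -> dict[str, int]:
    """Total annotated length per region class (coordinate arithmetic only)."""
    out: dict[str, int] = {"mtDNA": ann.length}
    for f in ann:
        cls = _CLASS_OF_FTYPE[f.ftype]
        out[cls] = out.get(cls, 0) + feature_length(f, ann.length, ann.circular)
    return out
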