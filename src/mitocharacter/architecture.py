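"""Circular-genome architecture: junction gaps/overlaps, feature-class
summaries, and avian gene-order rearrangement classification.

Junction gaps are always recomputed from coordinates (``next.start -
prev.stop - 1``, wrapping modulo the genome length at the origin junction);
the intergenic column of an input table is advisory only and can be
reconciled against the recomputed values with :func:`reconcile_with_reported`.

Avian mitogenomes fall into a small set of gene orders around the control
region (CR): the ancestral order carries a single CR between trnE and trnF;
the "duplicate CR" order carries a second, similar CR between trnT and trnP;
the "remnant CR2" order carries a degenerate (shortened) second copy; and
the "duplicate tRNA-Thr/CR" order duplicates trnT along with the CR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .annotation import Feature, GenomeAnnotation, feature_length
from .refdata import canonical_anticodons

GENE_ORDER_CLASSES = (
    "ancestral", "remnant_CR2", "duplicate_CR", "duplicate_trnT_CR", "unrecognized",
)

#: default anchor window for gene-order extraction
DEFAULT_ANCHOR_WINDOW = ("nad5", "12S")


class ArchitectureWarning(UserWarning):
    pass


@dataclass(frozen=True)
class Junction:
    """Gap between two adjacent features; negative gap = overlap."""

    prev: Feature
    next: Feature
    gap: int
    wraps: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return (self.prev.name, self.next.name)


@dataclass
class ArchitectureSummary:
    overlap_pairs: int
    overlap_total: int
    longest_overlap: tuple[tuple[str, str], int] | None
    spacer_count: int
    spacer_total: int
    longest_spacer: tuple[tuple[str, str], int] | None
    gene_order: list[str] | None = None
    gene_order_class: str | None = None

    def to_dict(self) -> dict:
        def _ext(e):
            return None if e is None else {"pair": list(e[0]), "nt": e[1]}
        return {
            "overlap_pairs": self.overlap_pairs,
            "overlap_total": self.overlap_total,
            "longest_overlap": _ext(self.longest_overlap),
            "spacer_count": self.spacer_count,
            "spacer_total": self.spacer_total,
            "longest_spacer": _ext(self.longest_spacer),
            "gene_order": self.gene_order,
            "gene_order_class": self.gene_order_class,
        }


def junction_table(ann: GenomeAnnotation) -> list[Junction]:
    """All adjacent-feature junctions in genome order.

    A circular genome with N features has N junctions (the last one wraps the
    origin); a linear genome has N-1. Gaps come from coordinates only.
    """
    feats = ann.features
    if len(feats) < 2:
        return []
    junctions = []
    for prev, nxt in zip(feats, feats[1:]):
        junctions.append(Junction(prev, nxt, nxt.start - prev.stop - 1))
    if ann.circular:
        last, first = feats[-1], feats[0]
        junctions.append(
            Junction(last, first, (first.start + ann.length) - last.stop - 1, wraps=True)
        )
    for a, b, c in zip(feats, feats[1:], feats[2:]):
        if c.start <= a.stop:
            warnings.warn(
                f"features {a.name}/{b.name}/{c.name} share positions (triple overlap)",
                ArchitectureWarning, stacklevel=2,
            )
    return junctions


def architecture_summary(
    junctions: list[Junction],
    ann: GenomeAnnotation | None = None,
    remnant_threshold: float = 0.5,
) -> ArchitectureSummary:
    """Overlap/spacer totals and extrema; gene-order classification when the
    annotation is supplied. Ties for extrema break by first occurrence in
    genome order."""
    overlaps = [j for j in junctions if j.gap < 0]
    spacers = [j for j in junctions if j.gap > 0]
    longest_overlap = max(overlaps, key=lambda j: -j.gap, default=None)
    longest_spacer = max(spacers, key=lambda j: j.gap, default=None)
    summary = ArchitectureSummary(
        overlap_pairs=len(overlaps),
        overlap_total=sum(-j.gap for j in overlaps),
        longest_overlap=None if longest_overlap is None
        else (longest_overlap.pair, -longest_overlap.gap),
        spacer_count=len(spacers),
        spacer_total=sum(j.gap for j in spacers),
        longest_spacer=None if longest_spacer is None
        else (longest_spacer.pair, longest_spacer.gap),
    )
    if ann is not None:
        try:
            order = extract_gene_order(ann)
            lengths = {f.name: feature_length(f, ann.length, ann.circular) for f in ann}
            summary.gene_order = order
            summary.gene_order_class = classify_gene_order(order, lengths, remnant_threshold)
        except KeyError:
            summary.gene_order_class = "unrecognized"
    return summary


def extract_gene_order(
    ann: GenomeAnnotation,
    anchor_window: tuple[str, str] = DEFAULT_ANCHOR_WINDOW,
) -> list[str]:
    """Feature labels in circular genome order from the first anchor through
    the second anchor inclusive.

    The result is invariant under rotation of the coordinate origin. Control
    regions are labelled CR1/CR2 by order of occurrence within the window.
    """
    first, last = anchor_window
    names = [f.name for f in ann.features]

    def _base(n: str) -> str:
        return "CR" if n.startswith("CR") else n

    bases = [_base(n) for n in names]
    missing = [a for a in anchor_window if _base(a) not in bases and a not in names]
    if missing:
        raise KeyError(f"anchor labels not in annotation: {missing}")
    i = bases.index(first) if first in bases else names.index(first)
    rotated = bases[i:] + bases[:i]
    try:
        j = rotated.index(last if last in rotated else _base(last))
    except ValueError:
        raise KeyError(f"anchor labels not in annotation: [{last!r}]") from None
    window = rotated[: j + 1]
    # number CR copies by occurrence inside the window
    n_cr = window.count("CR")
    if n_cr > 1:
        k = 0
        out = []
        for n in window:
            if n == "CR":
                k += 1
                out.append(f"CR{k}")
            else:
                out.append(n)
        window = out
    return window


def _cr_labels(order: list[str]) -> list[str]:
    return [n for n in order if n.startswith("CR")]


def _is_trnT(label: str) -> bool:
    return label == "trnT" or (label.startswith("trnT") and label[4:].isdigit())


def classify_gene_order(
    order: list[str],
    lengths: dict[str, int] | None = None,
    remnant_threshold: float = 0.5,
) -> str:
    """Classify an extracted gene-order window into an avian rearrangement
    class.

    Rules (in precedence order):

    - ``duplicate_trnT_CR``: trnT appears twice, with a CR copy adjacent to
      a trnT copy.
    - ``ancestral``: a single CR, sitting between trnE and trnF.
    - ``remnant_CR2``: two CRs where the second is shorter than
      ``remnant_threshold`` x the first's length.
    - ``duplicate_CR``: two CRs — one between trnT and trnP, one between
      trnE and trnF — both at least ``remnant_threshold`` x the longer
      copy's length.
    - otherwise ``unrecognized``.

    The relative-length threshold is a convention of this package (the
    rearrangement nomenclature names the categories without a quantitative
    rule).
    """
    lengths = lengths or {}
    crs = _cr_labels(order)
    trnT_count = sum(1 for n in order if _is_trnT(n))

    def _neighbors(label: str) -> tuple[str | None, str | None]:
        i = order.index(label)
        return (order[i - 1] if i > 0 else None,
                order[i + 1] if i < len(order) - 1 else None)

    def _between(label: str, before: str, after: str) -> bool:
        if label not in order:
            return False
        prev_, next_ = _neighbors(label)
        return prev_ == before and next_ == after

    if trnT_count >= 2 and crs:
        for cr in crs:
            prev_, next_ = _neighbors(cr)
            if (prev_ and _is_trnT(prev_)) or (next_ and _is_trnT(next_)):
                return "duplicate_trnT_CR"

    if len(crs) == 1:
        if _between(crs[0], "trnE", "trnF"):
            return "ancestral"
        return "unrecognized"

    if len(crs) == 2:
        first, second = crs
        len1, len2 = lengths.get(first), lengths.get(second)
        if len1 and len2 and len2 < remnant_threshold * len1:
            return "remnant_CR2"
        pos_ok = _between(first, "trnT", "trnP") and _between(second, "trnE", "trnF")
        if pos_ok:
            if len1 is None or len2 is None:
                return "duplicate_CR"
            longer = max(len1, len2)
            if min(len1, len2) >= remnant_threshold * longer:
                return "duplicate_CR"
        return "unrecognized"

    return "unrecognized"


def gene_order_string(order: list[str]) -> str:
    """Slash-separated rendering, e.g. ``nad5/cob/trnT/CR1/...``."""
    return "/".join(order)


def trna_table(ann: GenomeAnnotation) -> tuple[pd.DataFrame, dict]:
    """Per-tRNA report plus summary statistics.

    Anticodons are checked against the canonical vertebrate-mitochondrial
    table; mismatches are flagged in the ``anticodon_ok`` column.
    """
    trnas = ann.of_type("tRNA")
    if not trnas:
        raise ValueError("annotation contains no tRNA features")
    canonical = canonical_anticodons()
    rows = []
    for f in trnas:
        length = feature_length(f, ann.length, ann.circular)
        expected = canonical.get(f.name)
        rows.append({
            "trna": f.name, "strand": f.strand, "start": f.start, "stop": f.stop,
            "length": length, "anticodon": f.anticodon or "",
            "anticodon_ok": (f.anticodon or "").upper() == expected if expected and f.anticodon
            else None,
        })
    df = pd.DataFrame(rows)
    total = int(df["length"].sum())
    max_len, min_len = int(df["length"].max()), int(df["length"].min())
    summary = {
        "count": len(df),
        "total_length": total,
        "fraction_of_genome": total / ann.length,
        "mean_length": float(df["length"].mean()),
        "longest": df.loc[df["length"] == max_len, "trna"].tolist(),
        "longest_length": max_len,
        "shortest": df.loc[df["length"] == min_len, "trna"].tolist(),
        "shortest_length": min_len,
        "per_strand": df.groupby("strand")["trna"].count().to_dict(),
        "anticodon_mismatches": df.loc[df["anticodon_ok"] == False, "trna"].tolist(),  # noqa: E712
    }
    return df, summary


def reconcile_with_reported(ann: GenomeAnnotation, reported: pd.DataFrame) -> pd.DataFrame:
    """Compare recomputed lengths and junction gaps against a reported
    annotation table's ``length``/``intergenic`` columns.

    ``reported`` must carry a ``gene`` column whose (normalized) names match
    the annotation. Returns one record per disagreeing cell; published
    tables are not always internally consistent, and this reconciliation —
    not silent trust — is the contract.
    """
    recomputed_len = {f.name: feature_length(f, ann.length, ann.circular) for f in ann}
    recomputed_gap = {j.prev.name: j.gap for j in junction_table(ann)}
    records = []
    for _, row in reported.iterrows():
        gene = str(row["gene"])
        if gene not in recomputed_len:
            records.append({"gene": gene, "column": "gene", "printed": gene,
                            "recomputed": None})
            continue
        if "length" in reported.columns and pd.notna(row["length"]):
            printed = int(row["length"])
            if printed != recomputed_len[gene]:
                records.append({"gene": gene, "column": "length",
                                "printed": printed, "recomputed": recomputed_len[gene]})
        if "intergenic" in reported.columns and pd.notna(row["intergenic"]):
            printed = int(row["intergenic"])
            if gene in recomputed_gap and printed != recomputed_gap[gene]:
                records.append({"gene": gene, "column": "intergenic",
                                "printed": printed, "recomputed": recomputed_gap[gene]})
    return pd.DataFrame(records, columns=["gene", "column", "printed", "recomputed"])


def validate_spacers(ann: GenomeAnnotation, max_unannotated_spacer: int = 500) -> list[str]:
    """Warn-style check: a spacer longer than ``max_unannotated_spacer`` with
    no control region on either side usually means an unannotated CR."""
    msgs = []
    for j in junction_table(ann):
        if j.gap > max_unannotated_spacer and "CR" not in (j.prev.ftype, j.next.ftype):
            msgs.append(
                f"spacer of {j.gap} nt between {j.prev.name} and {j.next.name} "
                "has no adjacent control region annotation"
            )
    return msgs
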